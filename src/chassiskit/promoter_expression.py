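"""Reporter-based promoter characterization.

Turns plate-reader time courses of a fluorescent reporter (Ypet) into
wild-type-normalized, OD-gridded expression profiles, and from those derives
per-promoter summaries: a strength tier, a regulatory-pattern class, the
slope of normalized fluorescence against culture density, and the Pearson
correlation against a transcriptomic (RNA-seq) profile taken at the same
reference densities.

Conventions
-----------
* Culture density is OD730 (chosen to avoid pigment absorbance bands).
* Saturating samples are diluted before reading; the undiluted signal is
  fluorescence x dilution_factor.
* Normalization divides each sample's undiluted signal by the wild-type
  undiluted signal linearly interpolated at the same OD730 — never
  extrapolated; out-of-range samples are dropped with a warning.
* The reference OD grid (0.4, 0.7, 1.0, 3.0, 5.0) matches the densities at
  which the public PCC 7002 RNA-seq growth series was sampled, so reporter
  and transcript profiles are directly comparable.
* The regulatory classes follow the growth phases of light-limited batch
  culture: expression falling along growth is "linear phase", rising is
  "stationary phase", and within +/-30% relative change is constitutive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import linear_fit, mean_sd, pearson_r, two_sample_ttest_equal_var

__all__ = [
    "REFERENCE_OD_GRID",
    "FluorescenceSeries",
    "NormalizedProfile",
    "RnaSeqProfile",
    "PromoterCharacterization",
    "normalize_to_wildtype",
    "interpolate_at_reference_ods",
    "profile_from_series",
    "pooled_wildtype",
    "fit_expression_slope",
    "classify_regulatory_pattern",
    "classify_strength",
    "correlate_profiles",
    "characterize_promoter",
    "read_plate_csv",
    "read_rnaseq_tsv",
    "write_characterization_tsv",
]

#: Reference OD730 grid shared with the RNA-seq growth series.
REFERENCE_OD_GRID = (0.4, 0.7, 1.0, 3.0, 5.0)

#: Strength-tier cuts on mean normalized fluorescence (fold over wild type).
STRENGTH_CUTS = {"weak": 1.5, "moderate": 2.0, "strong": 10.0}


@dataclass(frozen=True)
class FluorescenceSeries:
    """One replicate's reporter time course.

    ``samples`` columns: time_h, od730, fluor (a.u.), dilution_factor.
    """

    strain_id: str
    replicate: int
    time_h: np.ndarray
    od730: np.ndarray
    fluor: np.ndarray
    dilution: np.ndarray

    def __post_init__(self):
        for name in ("time_h", "od730", "fluor", "dilution"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.od730 <= 0):
            raise ValueError("OD730 must be positive")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def undiluted(self) -> np.ndarray:
        """Detector-saturation-corrected signal."""
        return self.fluor * self.dilution


@dataclass(frozen=True)
class NormalizedProfile:
    """Wild-type-normalized fluorescence on the reference OD grid.

    ``values`` has shape (n_replicates, n_grid); missing grid points
    (outside the measured OD range) are NaN.
    """

    promoter_id: str
    od_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "od_grid", np.asarray(self.od_grid, dtype=float))
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if np.any(np.diff(self.od_grid) <= 0):
            raise ValueError("od_grid must be sorted ascending")
        if v.shape[1] != self.od_grid.size:
            raise ValueError("values width must match od_grid")

    @property
    def replicate_mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=0)


@dataclass(frozen=True)
class RnaSeqProfile:
    """Library-size-normalized transcript abundance at the reference grid."""

    locus: str
    od_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "od_grid", np.asarray(self.od_grid, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class PromoterCharacterization:
    promoter_id: str
    mean_norm_fluor: float
    sd_norm_fluor: float
    slope: float
    intercept: float
    regulatory_class: str
    strength_tier: str
    p_value_vs_wt: float
    correlation_r: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# normalization and gridding


def normalize_to_wildtype(
    strain: FluorescenceSeries, wildtype: FluorescenceSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a strain series to the wild type at matched OD730.

    Returns ``(od, value)`` arrays where value is the strain's undiluted
    signal divided by the wild-type undiluted signal linearly interpolated
    at the same OD. Strain samples whose OD falls outside the wild-type OD
    range are dropped with a warning (no extrapolation).
    """
    order = np.argsort(wildtype.od730)
    wt_od = wildtype.od730[order]
    wt_sig = wildtype.undiluted[order]
    lo, hi = wt_od[0], wt_od[-1]
    inside = (strain.od730 >= lo) & (strain.od730 <= hi)
    if not inside.all():
        warnings.warn(
            f"{(~inside).sum()} sample(s) of {strain.strain_id!r} outside wild-type "
            f"OD range [{lo:g}, {hi:g}] dropped"
        )
    od = strain.od730[inside]
    wt_at = np.interp(od, wt_od, wt_sig)
    return od, strain.undiluted[inside] / wt_at


def interpolate_at_reference_ods(
    od: np.ndarray,
    values: np.ndarray,
    od_grid=REFERENCE_OD_GRID,
) -> np.ndarray:
    """Linearly interpolate (OD, value) pairs onto the reference grid.

    Grid points outside the measured OD range come back as NaN rather than
    extrapolated values.
    """
    od = np.asarray(od, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(od_grid, dtype=float)
    order = np.argsort(od)
    od, values = od[order], values[order]
    out = np.interp(grid, od, values)
    out[(grid < od[0]) | (grid > od[-1])] = np.nan
    return out


def profile_from_series(
    series: list[FluorescenceSeries],
    wildtype: FluorescenceSeries,
    od_grid=REFERENCE_OD_GRID,
) -> NormalizedProfile:
    """Normalize each replicate to the wild type and grid the result."""
    if not series:
        raise ValueError("no replicate series")
    rows = []
    for s in series:
        od, vals = normalize_to_wildtype(s, wildtype)
        rows.append(interpolate_at_reference_ods(od, vals, od_grid))
    return NormalizedProfile(series[0].strain_id, np.asarray(od_grid, float), np.vstack(rows))


def pooled_wildtype(replicates: list[FluorescenceSeries]) -> FluorescenceSeries:
    """Average several wild-type replicates into one reference curve.

    The pooled curve is the mean undiluted signal over replicates,
    evaluated on the union of their OD supports restricted to the overlap
    (so every pooled point is an interpolation, never an extrapolation).
    """
    if not replicates:
        raise ValueError("no wild-type replicates")
    if len(replicates) == 1:
        return replicates[0]
    lo = max(r.od730.min() for r in replicates)
    hi = min(r.od730.max() for r in replicates)
    support = np.unique(np.concatenate([r.od730 for r in replicates]))
    support = support[(support >= lo) & (support <= hi)]
    if support.size < 2:
        raise ValueError("wild-type replicates share too little OD range to pool")
    sig = np.mean(
        [
            np.interp(support, r.od730[np.argsort(r.od730)], r.undiluted[np.argsort(r.od730)])
            for r in replicates
        ],
        axis=0,
    )
    return FluorescenceSeries(
        strain_id=replicates[0].strain_id,
        replicate=0,
        time_h=np.arange(support.size, dtype=float),
        od730=support,
        fluor=sig,
        dilution=np.ones_like(sig),
    )


# ---------------------------------------------------------------------------
# per-promoter summaries


def fit_expression_slope(profile: NormalizedProfile) -> tuple[float, float]:
    """OLS slope/intercept of replicate-mean normalized fluorescence vs OD."""
    mean = profile.replicate_mean
    keep = ~np.isnan(mean)
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-missing grid points")
    return linear_fit(profile.od_grid[keep], mean[keep])


def classify_regulatory_pattern(profile: NormalizedProfile, threshold: float = 0.30) -> str:
    """Classify constitutive / linear_phase / stationary_phase expression.

    The OLS line fitted to the replicate-mean profile is evaluated at the
    lowest and highest grid ODs; with relative change
    rho = (f_high - f_low) / f_low, expression is stationary_phase when
    rho > +threshold, linear_phase when rho < -threshold, constitutive
    otherwise. Being a ratio, the class is invariant to uniform scaling of
    the profile.
    """
    slope, intercept = fit_expression_slope(profile)
    lo, hi = profile.od_grid[0], profile.od_grid[-1]
    f1 = slope * lo + intercept
    f2 = slope * hi + intercept
    if f1 <= 0:
        raise ValueError("fitted value at the lowest OD is non-positive; relative change undefined")
    rho = (f2 - f1) / f1
    if rho > threshold:
        return "stationary_phase"
    if rho < -threshold:
        return "linear_phase"
    return "constitutive"


def classify_strength(mean_norm_fluor: float, p_value_vs_wt: float, alpha: float = 0.05) -> str:
    """Tier a promoter by mean fold-change over wild type.

    not_significant when p >= alpha or mean <= 1.5 (indistinguishable from
    background); weak in (1.5, 2); moderate in [2, 10); strong >= 10.
    The tier cuts reflect the empirical grouping of the PCC 7002 promoter
    library: moderate promoters run 2- to 6-fold over wild type and strong
    ones exceed 30-fold, so any cut in the empty 6-30-fold interval
    separates them identically; 10 is used.
    """
    if mean_norm_fluor <= 0:
        raise ValueError("mean normalized fluorescence must be positive")
    if p_value_vs_wt >= alpha or mean_norm_fluor <= STRENGTH_CUTS["weak"]:
        return "not_significant"
    if mean_norm_fluor < STRENGTH_CUTS["moderate"]:
        return "weak"
    if mean_norm_fluor < STRENGTH_CUTS["strong"]:
        return "moderate"
    return "strong"


def correlate_profiles(fluor: NormalizedProfile, rna: RnaSeqProfile) -> float:
    """Pearson r between replicate-mean fluorescence and transcript profile.

    Computed over the shared non-missing grid points; NaN when fewer than
    three remain or either vector is constant.
    """
    if not np.array_equal(fluor.od_grid, rna.od_grid):
        raise ValueError("profiles use different OD grids")
    mean = fluor.replicate_mean
    keep = ~np.isnan(mean) & ~np.isnan(rna.values)
    if keep.sum() < 3:
        return float("nan")
    return pearson_r(mean[keep], rna.values[keep])


def characterize_promoter(
    strain_series: list[FluorescenceSeries],
    wildtype_series: list[FluorescenceSeries],
    rna: RnaSeqProfile | None = None,
    od_grid=REFERENCE_OD_GRID,
    pattern_threshold: float = 0.30,
    alpha: float = 0.05,
) -> PromoterCharacterization:
    """Full per-promoter characterization from raw replicate time courses.

    The wild-type replicates are pooled into one reference curve for
    normalization; each wild-type replicate is also normalized against that
    pooled curve, and significance vs wild type is a two-sample
    equal-variance t test on per-replicate grid-mean normalized
    fluorescence (strain replicates vs wild-type replicates, two-tailed).
    """
    wt_pool = pooled_wildtype(wildtype_series)
    profile = profile_from_series(strain_series, wt_pool, od_grid)
    wt_profile = profile_from_series(wildtype_series, wt_pool, od_grid)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        strain_means = np.nanmean(profile.values, axis=1)
        wt_means = np.nanmean(wt_profile.values, axis=1)
    mean, sd = mean_sd(strain_means)

    if len(strain_means) >= 2 and len(wt_means) >= 2:
        try:
            p = two_sample_ttest_equal_var(strain_means, wt_means).p_two_tail
        except ValueError:
            # zero pooled variance with unequal means: infinitely separated
            p = 0.0 if not np.isclose(strain_means.mean(), wt_means.mean()) else 1.0
    else:
        p = float("nan")

    slope, intercept = fit_expression_slope(profile)
    reg_class = classify_regulatory_pattern(profile, pattern_threshold)
    tier = classify_strength(mean, p if not np.isnan(p) else 1.0, alpha)
    r = correlate_profiles(profile, rna) if rna is not None else float("nan")
    return PromoterCharacterization(
        promoter_id=profile.promoter_id,
        mean_norm_fluor=mean,
        sd_norm_fluor=sd,
        slope=slope,
        intercept=intercept,
        regulatory_class=reg_class,
        strength_tier=tier,
        p_value_vs_wt=p,
        correlation_r=r,
    )


# ---------------------------------------------------------------------------
# file I/O


def read_plate_csv(path: str) -> dict[tuple[str, int], FluorescenceSeries]:
    """Read plate-reader time courses.

    Columns: strain_id, replicate, time_h, od730, fluor, dilution.
    Returns a dict keyed by (strain_id, replicate).
    """
    df = pd.read_csv(path)
    required = {"strain_id", "replicate", "time_h", "od730", "fluor", "dilution"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    out = {}
    for (sid, rep), g in df.groupby(["strain_id", "replicate"]):
        g = g.sort_values("time_h")
        out[(str(sid), int(rep))] = FluorescenceSeries(
            strain_id=str(sid),
            replicate=int(rep),
            time_h=g["time_h"].to_numpy(),
            od730=g["od730"].to_numpy(),
            fluor=g["fluor"].to_numpy(),
            dilution=g["dilution"].to_numpy(),
        )
    return out


def read_rnaseq_tsv(path: str, od_grid=REFERENCE_OD_GRID) -> dict[str, RnaSeqProfile]:
    """Read transcript profiles (columns: locus, od, value; TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "od", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RNA-seq TSV missing columns: {sorted(missing)}")
    grid = np.asarray(od_grid, dtype=float)
    out = {}
    for locus, g in df.groupby("locus"):
        g = g.sort_values("od")
        if not np.allclose(g["od"].to_numpy(), grid):
            raise ValueError(f"locus {locus!r} ODs do not match the reference grid")
        out[str(locus)] = RnaSeqProfile(str(locus), grid, g["value"].to_numpy())
    return out


def write_characterization_tsv(
    results: list[PromoterCharacterization], path: str, header_lines=()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "promoter_id\tmean_norm_fluor\tsd_norm_fluor\tslope\tregulatory_class"
            "\tstrength_tier\tp_value_vs_wt\tcorrelation_r\n"
        )
        for c in results:
            fh.write(
                f"{c.promoter_id}\t{c.mean_norm_fluor:.4g}\t{c.sd_norm_fluor:.4g}"
                f"\t{c.slope:.4g}\t{c.regulatory_class}\t{c.strength_tier}"
                f"\t{c.p_value_vs_wt:.4g}\t{c.correlation_r:.4g}\n"
            )
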