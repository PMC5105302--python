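"""Synthetic-data generators with planted ground truth.

Every input the analysis stages consume can be generated here: batch-growth
OD730 curves, reporter fluorescence time courses, qPCR CT tables, genome
annotations with planted intergenic gaps, and Poisson colony counts at a
planted transformation efficiency. Each generator's noise-free output is
inverted exactly by the corresponding analysis stage, so recovery of the
planted truth is a testable round trip.

Randomness discipline: every generator call derives its own pseudo-random
stream from ``(seed, call-site label)``, so adding a generator or reordering
calls never perturbs previously generated fixtures, and a fixed seed gives
byte-identical outputs.

Growth model
------------
Under constant moderate light, cyanobacterial batch cultures show a very
short exponential phase followed by a long linear, light-limited phase.
The generator is piecewise exponential-then-linear with continuity at the
switch density: OD(t) = od0 * exp(mu t) until OD reaches ``od_switch``,
then od_switch + linear_rate * (t - t_switch). The default linear rate
(0.0334 OD730/h) is the measured wild-type rate for PCC 7002 under
standard conditions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from math import log, log2

import numpy as np
import pandas as pd

from .neutral_sites import AnnotationRecord
from .promoter_expression import REFERENCE_OD_GRID, FluorescenceSeries
from .transformation import DS_DNA_G_PER_MOL_PER_BP, TransformationObservation

__all__ = [
    "GrowthModel",
    "PromoterTruth",
    "SimConfig",
    "simulate_growth",
    "simulate_fluorescence",
    "simulate_qpcr",
    "generate_annotation",
    "simulate_transformation",
    "write_truth_yaml",
    "PATTERN_RELATIVE_CHANGE",
    "WT_FLUOR_PER_OD",
]

#: Wild-type (autofluorescence) signal per OD730 unit, arbitrary units.
WT_FLUOR_PER_OD = 1000.0

#: Detector saturation level; saturating samples are recorded diluted.
SATURATION_AU = 20000.0

#: Planted relative change between the lowest and highest reference OD for
#: each regulatory pattern — +/-0.6 sits well past the +/-0.30
#: classification boundary, mimicking the clearly-regulated promoters.
PATTERN_RELATIVE_CHANGE = {
    "constitutive": 0.0,
    "stationary_phase": 0.6,
    "linear_phase": -0.6,
}

# Baseline threshold cycles for the simulated assay: the housekeeping
# reference amplifies around cycle 20, the target around 24 in the dark.
_CT_REFERENCE = 20.0
_CT_TARGET_DARK = 24.0


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream per (seed, call-site label)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(label.encode()),))
    )


@dataclass(frozen=True)
class GrowthModel:
    """Piecewise exponential-then-linear batch growth."""

    od0: float = 0.05
    mu: float = 0.27  # 1/h, ~2.6 h doubling in the brief exponential phase
    od_switch: float = 0.3
    linear_rate: float = 0.0334  # OD730/h, light-limited phase
    duration: float = 192.0  # h; covers the OD 0.4-5.0 reference range

    def __post_init__(self):
        if self.od0 <= 0 or self.od_switch <= 0 or self.duration <= 0:
            raise ValueError("od0, od_switch and duration must be positive")
        if self.linear_rate <= 0:
            raise ValueError("linear_rate must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.od_switch < self.od0:
            raise ValueError("od_switch must be >= od0")
        if self.mu == 0 and self.od_switch != self.od0:
            raise ValueError("mu = 0 requires od_switch == od0 (no exponential phase)")

    @property
    def t_switch(self) -> float:
        if self.mu == 0:
            return 0.0
        return log(self.od_switch / self.od0) / self.mu


@dataclass(frozen=True)
class PromoterTruth:
    """Planted ground truth for one promoter-reporter strain."""

    promoter_id: str
    strength: float = 1.0  # mean normalized fluorescence, fold over wild type
    pattern: str = "constitutive"
    light_dark_ratio: float = 1.0
    noise_cv: float = 0.1

    def __post_init__(self):
        if self.strength <= 0:
            raise ValueError("strength must be positive")
        if self.light_dark_ratio <= 0:
            raise ValueError("light_dark_ratio must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.pattern not in PATTERN_RELATIVE_CHANGE:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_biological_replicates: int = 3
    n_technical_replicates: int = 3  # qPCR convention
    ct_sd: float = 0.2  # cycles, additive technical noise
    sampling_times: tuple = ()  # h; empty = every 48 h over the model duration

    def __post_init__(self):
        if self.n_biological_replicates < 1 or self.n_technical_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be non-negative")


# ---------------------------------------------------------------------------
# growth


def simulate_growth(model: GrowthModel, times) -> list[tuple[float, float]]:
    """OD730 trajectory at the requested times (h, sorted ascending)."""
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    ts = model.t_switch
    od = np.where(
        times <= ts,
        model.od0 * np.exp(model.mu * times),
        model.od_switch + model.linear_rate * (times - ts),
    )
    return list(zip(times.tolist(), od.tolist()))


def _default_times(model: GrowthModel) -> np.ndarray:
    return np.arange(0.0, model.duration + 1e-9, 48.0)


# ---------------------------------------------------------------------------
# fluorescence


def _shape_factor(od: np.ndarray, pattern: str, od_grid=REFERENCE_OD_GRID) -> np.ndarray:
    """Normalized-expression shape, linear in OD, grid-mean scaled to 1."""
    grid = np.asarray(od_grid, dtype=float)
    rho = PATTERN_RELATIVE_CHANGE[pattern]
    lo, hi = grid[0], grid[-1]
    raw = 1.0 + rho * (np.asarray(od, float) - lo) / (hi - lo)
    grid_mean = float(np.mean(1.0 + rho * (grid - lo) / (hi - lo)))
    return raw / grid_mean


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma2**0.5, size=size)


def _make_series(strain_id, replicate, times, ods, expected, rng, cv):
    noisy = expected * _lognormal_noise(rng, cv, expected.shape)
    dilution = np.ones_like(noisy)
    sat = noisy > SATURATION_AU
    if sat.any():
        dilution[sat] = 10.0 ** np.ceil(np.log10(noisy[sat] / SATURATION_AU))
    return FluorescenceSeries(
        strain_id=strain_id,
        replicate=replicate,
        time_h=times,
        od730=ods,
        fluor=noisy / dilution,
        dilution=dilution,
    )


def simulate_fluorescence(
    truth: PromoterTruth,
    growth,
    cfg: SimConfig,
    od_grid=REFERENCE_OD_GRID,
) -> tuple[list[FluorescenceSeries], list[FluorescenceSeries]]:
    """Reporter time courses for a promoter strain plus wild-type controls.

    Returns ``(strain_series, wildtype_series)``, one per biological
    replicate each. The noise-free normalized expectation at the reference
    ODs is ``strength`` times the pattern shape (flat for constitutive,
    rising for stationary-phase, falling for linear-phase expression); the
    wild type has strength 1 by construction. Signals above the detector
    saturation level are recorded diluted, as a plate reader operator would.
    """
    growth = list(growth)
    times = np.asarray([t for t, _ in growth], dtype=float)
    ods = np.asarray([o for _, o in growth], dtype=float)
    grid = np.asarray(od_grid, dtype=float)
    if ods.min() > grid[0] or ods.max() < grid[-1]:
        raise ValueError(
            f"growth OD range [{ods.min():g}, {ods.max():g}] does not cover the "
            f"reference grid [{grid[0]:g}, {grid[-1]:g}]"
        )
    wt_expected = WT_FLUOR_PER_OD * ods
    strain_expected = truth.strength * _shape_factor(ods, truth.pattern, od_grid) * wt_expected

    strains, wildtypes = [], []
    for rep in range(1, cfg.n_biological_replicates + 1):
        rng_s = _rng(cfg.seed, f"fluor:{truth.promoter_id}:rep{rep}")
        rng_w = _rng(cfg.seed, f"fluor:wildtype:{truth.promoter_id}:rep{rep}")
        strains.append(
            _make_series(truth.promoter_id, rep, times, ods, strain_expected, rng_s, truth.noise_cv)
        )
        wildtypes.append(
            _make_series("wildtype", rep, times, ods, wt_expected, rng_w, truth.noise_cv)
        )
    return strains, wildtypes


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(truth: PromoterTruth, cfg: SimConfig, include_controls: bool = True) -> pd.DataFrame:
    """Technical-replicate CT table for one strain under light and dark.

    The target gene's light CT sits ``-log2(light_dark_ratio)`` cycles from
    its dark CT in expectation; the reference gene is condition-invariant in
    expectation. A random per-(replicate, condition) plate offset shifts
    both genes together — it cancels exactly in dCT, which the analysis
    relies on. Technical replicates are i.i.d. Gaussian around the cell
    mean with SD ``cfg.ct_sd``. No-template control rows (gene ``ntc``) are
    appended so readers must exclude them.
    """
    rows = []
    for rep in range(1, cfg.n_biological_replicates + 1):
        rng = _rng(cfg.seed, f"qpcr:{truth.promoter_id}:rep{rep}")
        for condition in ("light", "dark"):
            offset = rng.normal(0.0, 0.5)  # plate-to-plate shift, cancels in dCT
            target_mean = _CT_TARGET_DARK + offset
            if condition == "light":
                target_mean -= log2(truth.light_dark_ratio)
            ref_mean = _CT_REFERENCE + offset
            for tech in range(1, cfg.n_technical_replicates + 1):
                rows.append(
                    (truth.promoter_id, "target", condition, rep, tech,
                     target_mean + rng.normal(0.0, cfg.ct_sd) if cfg.ct_sd else target_mean)
                )
                rows.append(
                    (truth.promoter_id, "reference", condition, rep, tech,
                     ref_mean + rng.normal(0.0, cfg.ct_sd) if cfg.ct_sd else ref_mean)
                )
            if include_controls:
                rows.append((truth.promoter_id, "ntc", condition, rep, 1, 38.0))
    return pd.DataFrame(
        rows,
        columns=["strain_id", "gene", "condition", "biological_replicate",
                 "technical_replicate", "ct"],
    )


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_genes: int,
    planted_gaps,
    chrom_len: int,
    seed: int,
    chrom: str = "chr",
    max_spacer: int = 200,
) -> list[AnnotationRecord]:
    """Annotation whose feature-free runs are exactly the planted gaps.

    Features tile the chromosome end to end except for the planted gaps and
    random inter-feature spacers no longer than ``max_spacer`` (kept far
    below any realistic detection threshold). Planted gaps must be
    non-overlapping, lie strictly inside the chromosome, and leave room for
    at least one gene between consecutive gaps and at the chromosome ends.
    """
    gaps = sorted((int(s), int(e)) for s, e in planted_gaps)
    for s, e in gaps:
        if not (1 < s <= e < chrom_len):
            raise ValueError(f"planted gap ({s}, {e}) must lie strictly inside [1, {chrom_len}]")
    for (s1, e1), (s2, e2) in zip(gaps, gaps[1:]):
        if s2 <= e1 + 1:
            raise ValueError(f"planted gaps ({s1},{e1}) and ({s2},{e2}) overlap or abut")

    # segments to fill with genes
    bounds = [1]
    for s, e in gaps:
        bounds.append(s - 1)
        bounds.append(e + 1)
    bounds.append(chrom_len)
    segments = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
    min_gene = 150
    for s, e in segments:
        if e - s + 1 < min_gene:
            raise ValueError(f"segment ({s}, {e}) too short to host a gene")

    rng = _rng(seed, "annotation")
    non_gap = sum(e - s + 1 for s, e in segments)
    target = max(min_gene * 2, non_gap // max(n_genes, 1))
    records: list[AnnotationRecord] = []
    idx = 0
    for seg_start, seg_end in segments:
        pos = seg_start
        while True:
            idx += 1
            remaining = seg_end - pos + 1
            if remaining <= int(1.7 * target) + max_spacer:
                end = seg_end  # last gene closes the segment exactly
            else:
                end = pos + int(rng.integers(int(0.5 * target), int(1.5 * target))) - 1
            records.append(
                AnnotationRecord(
                    locus_tag=f"SYN_{idx:05d}",
                    chrom=chrom,
                    start=pos,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    feature_type="gene",
                )
            )
            if end >= seg_end:
                break
            pos = end + 1 + int(rng.integers(0, max_spacer + 1))
            if pos > seg_end:  # spacer overshot: stretch the last gene instead
                records[-1] = AnnotationRecord(
                    locus_tag=records[-1].locus_tag,
                    chrom=chrom,
                    start=records[-1].start,
                    end=seg_end,
                    strand=records[-1].strand,
                    feature_type="gene",
                )
                break
    return records


# ---------------------------------------------------------------------------
# transformation


def simulate_transformation(
    efficiency: float,
    fmol: float,
    dilution: float,
    frac_positive: float,
    seed: int,
    n_screened: int = 50,
    fragment_length: int = 4000,
    incubation_h: float = 24.0,
    arm_length: int = 500,
) -> TransformationObservation:
    """One transformation plate drawn at a planted efficiency (cfu/fmol).

    Colony counts are Poisson with mean
    ``efficiency * fmol / (dilution * frac_positive)`` — the inverse of the
    efficiency estimator, so the estimator is unbiased on this output. The
    PCR screen is binomial with success probability ``frac_positive``.
    """
    if efficiency < 0 or fmol <= 0 or dilution <= 0:
        raise ValueError("efficiency must be >= 0; fmol and dilution positive")
    if not (0 < frac_positive <= 1):
        raise ValueError("frac_positive must be in (0, 1]")
    rng = _rng(seed, "transformation")
    lam = efficiency * fmol / (dilution * frac_positive)
    cfu = int(rng.poisson(lam))
    n_positive = int(rng.binomial(n_screened, frac_positive))
    dna_mass = fmol * fragment_length * DS_DNA_G_PER_MOL_PER_BP / 1e9
    return TransformationObservation(
        cfu=cfu,
        dilution_factor=dilution,
        dna_mass=dna_mass,
        fragment_length=fragment_length,
        n_screened=n_screened,
        n_positive=n_positive,
        incubation_h=incubation_h,
        arm_length=arm_length,
    )


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_truth_yaml(truth, path: str) -> None:
    """Write a planted-truth sidecar (YAML) next to a simulated fixture."""
    import yaml

    if hasattr(truth, "__dataclass_fields__"):
        truth = asdict(truth)
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
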