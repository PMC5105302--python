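"""Transformation-efficiency quantification for natural transformation.

Efficiency is expressed as colony-forming units per fmol of DNA, corrected
for the fraction of colonies whose cassette integration is confirmed by PCR
screening:

    efficiency = (cfu x dilution_factor / fmol DNA) x (n_positive / n_screened)

fmol is derived from the plated DNA mass assuming an average double-stranded
DNA weight of 650 g/mol per base pair (configurable). The module also
summarizes homology-arm-length experiments: per (arm length, incubation
time) cell means with sample SD, pooled positive fractions, and simple
monotonicity diagnostics (efficiency should rise with arm length and with
incubation time).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stats import mean_sd

__all__ = [
    "TransformationObservation",
    "EfficiencyEstimate",
    "fmol_from_mass",
    "transformation_efficiency",
    "summarize_arm_experiment",
    "read_plates_csv",
    "DS_DNA_G_PER_MOL_PER_BP",
]

#: Average molecular weight of double-stranded DNA, g/mol per bp.
DS_DNA_G_PER_MOL_PER_BP = 650.0


@dataclass(frozen=True)
class TransformationObservation:
    """One transformation plate: colony count plus its screening record."""

    cfu: int
    dilution_factor: float
    dna_mass: float  # micrograms
    fragment_length: int  # bp
    n_screened: int
    n_positive: int
    incubation_h: float = 24.0
    arm_length: int = 0

    def __post_init__(self):
        if self.cfu < 0:
            raise ValueError("cfu must be non-negative")
        if not (0 <= self.n_positive <= self.n_screened):
            raise ValueError("need 0 <= n_positive <= n_screened")
        if self.dna_mass <= 0:
            raise ValueError("dna_mass must be positive")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")


@dataclass(frozen=True)
class EfficiencyEstimate:
    efficiency: float  # cfu per fmol
    positive_fraction: float
    fmol: float


def fmol_from_mass(
    dna_mass: float,
    fragment_length: int,
    g_per_mol_per_bp: float = DS_DNA_G_PER_MOL_PER_BP,
) -> float:
    """Convert a DNA mass (ug) of a linear fragment to fmol.

    fmol = mass_ug * 1e9 / (length_bp * 650). The round-number anchor:
    0.65 ug of a 1000 bp fragment is exactly 1000 fmol.
    """
    if dna_mass <= 0:
        raise ValueError("dna_mass must be positive")
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    return dna_mass * 1e9 / (fragment_length * g_per_mol_per_bp)


def transformation_efficiency(obs: TransformationObservation) -> EfficiencyEstimate:
    """Efficiency in cfu/fmol from one plate's observation."""
    if obs.n_screened == 0:
        raise ValueError("positive fraction undefined with n_screened = 0")
    fmol = fmol_from_mass(obs.dna_mass, obs.fragment_length)
    frac = obs.n_positive / obs.n_screened
    eff = obs.cfu * obs.dilution_factor / fmol * frac
    return EfficiencyEstimate(efficiency=eff, positive_fraction=frac, fmol=fmol)


def summarize_arm_experiment(observations: list[TransformationObservation]) -> pd.DataFrame:
    """Summarize a homology-arm-length experiment.

    Returns a DataFrame indexed by (arm_length, incubation_h) with columns
    ``efficiency_mean``, ``efficiency_sd``, ``positive_fraction_mean``,
    ``positive_fraction_sd``, ``n`` and two boolean attrs in ``.attrs``:
    ``monotone_in_arm_length`` / ``monotone_in_time`` (cell means
    non-decreasing along each axis, averaged over the other).
    """
    if not observations:
        raise ValueError("no observations")
    rows = []
    for obs in observations:
        est = transformation_efficiency(obs)
        rows.append(
            {
                "arm_length": obs.arm_length,
                "incubation_h": obs.incubation_h,
                "efficiency": est.efficiency,
                "positive_fraction": est.positive_fraction,
            }
        )
    df = pd.DataFrame(rows)

    def _agg(g):
        em, es = mean_sd(g["efficiency"])
        pm, ps = mean_sd(g["positive_fraction"])
        return pd.Series(
            {
                "efficiency_mean": em,
                "efficiency_sd": es,
                "positive_fraction_mean": pm,
                "positive_fraction_sd": ps,
                "n": len(g),
            }
        )

    out = (
        df.groupby(["arm_length", "incubation_h"])
        .apply(_agg, include_groups=False)
        .sort_index()
    )

    by_arm = out.groupby(level="arm_length")["efficiency_mean"].mean()
    by_time = out.groupby(level="incubation_h")["efficiency_mean"].mean()
    out.attrs["monotone_in_arm_length"] = bool(by_arm.is_monotonic_increasing)
    out.attrs["monotone_in_time"] = bool(by_time.is_monotonic_increasing)
    return out


def read_plates_csv(path: str) -> list[TransformationObservation]:
    """Read plate records (columns matching TransformationObservation)."""
    df = pd.read_csv(path)
    required = {"cfu", "dilution_factor", "dna_mass", "fragment_length", "n_screened", "n_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plates CSV missing columns: {sorted(missing)}")
    obs = []
    for _, row in df.iterrows():
        obs.append(
            TransformationObservation(
                cfu=int(row["cfu"]),
                dilution_factor=float(row["dilution_factor"]),
                dna_mass=float(row["dna_mass"]),
                fragment_length=int(row["fragment_length"]),
                n_screened=int(row["n_screened"]),
                n_positive=int(row["n_positive"]),
                incubation_h=float(row.get("incubation_h", 24.0)),
                arm_length=int(row.get("arm_length", 0)),
            )
        )
    return obs
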