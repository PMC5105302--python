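"""Diurnal light/dark relative quantification by the 2^-ddCT method.

Transcript levels of a reporter gene are compared 6 h into the light period
vs 6 h into the dark period of a 12:12 diurnal cycle. Quantification is the
standard comparative-CT scheme: technical-replicate threshold cycles are
averaged on the CT scale, the target gene is referenced to a stable
housekeeping gene (rnpA here) within each condition, and the light/dark
expression ratio is 2^-ddCT with ddCT = dCT(light) - dCT(dark). Perfect
amplification efficiency (doubling per cycle) is assumed.

Reported fold-changes use the signed convention: ratios >= 1 are reported
as-is (up-regulation in the light), ratios < 1 as the negative reciprocal
(-1/ratio, down-regulation in the light), so |signed| >= 1 always.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mean_sd, two_sample_ttest_equal_var

__all__ = [
    "QPCR_COLUMNS",
    "DiurnalFoldChange",
    "read_qpcr_csv",
    "validate_qpcr_table",
    "mean_technical_ct",
    "delta_ct",
    "delta_delta_ct",
    "to_signed_fold_change",
    "signed_to_ratio",
    "aggregate_biological",
    "analyze_diurnal",
    "summarize_diurnal",
    "write_diurnal_tsv",
]

QPCR_COLUMNS = ("strain_id", "gene", "condition", "biological_replicate", "technical_replicate", "ct")
_GENES = ("target", "reference")
_CONDITIONS = ("light", "dark")


@dataclass(frozen=True)
class DiurnalFoldChange:
    """Per-strain light:dark fold-change summary across biological replicates."""

    strain_id: str
    ratio: float  # light/dark expression ratio (> 0)
    signed: float  # signed convention, |signed| >= 1
    sd_signed: float  # SD of per-replicate signed values (nan if 1 replicate)
    significant: bool
    p_value: float = float("nan")
    n_replicates: int = 0


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and drop control rows (genes other than target/reference).

    No-template and no-RT controls are carried in the same table with their
    own gene labels (e.g. ``ntc``); they never enter averaging.
    """
    missing = set(QPCR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    t = table[table["gene"].isin(_GENES)].copy()
    bad_cond = set(t["condition"].unique()) - set(_CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    if (t["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return t


def read_qpcr_csv(path: str) -> pd.DataFrame:
    return validate_qpcr_table(pd.read_csv(path))


def mean_technical_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the CT scale.

    Returns one row per (strain_id, gene, condition, biological_replicate)
    with the arithmetic-mean CT. Raises if any required cell is absent.
    """
    t = validate_qpcr_table(table)
    means = (
        t.groupby(["strain_id", "gene", "condition", "biological_replicate"])["ct"]
        .mean()
        .reset_index()
    )
    for (sid, rep), g in means.groupby(["strain_id", "biological_replicate"]):
        have = set(zip(g["gene"], g["condition"]))
        need = {(gene, cond) for gene in _GENES for cond in _CONDITIONS}
        lack = need - have
        if lack:
            raise ValueError(f"strain {sid!r} replicate {rep}: missing cells {sorted(lack)}")
    return means


def delta_ct(means: pd.DataFrame) -> pd.DataFrame:
    """dCT = CT(target) - CT(reference) per (strain, condition, bio rep)."""
    wide = means.pivot_table(
        index=["strain_id", "biological_replicate", "condition"],
        columns="gene",
        values="ct",
    ).reset_index()
    wide["delta_ct"] = wide["target"] - wide["reference"]
    return wide[["strain_id", "biological_replicate", "condition", "delta_ct"]]


def delta_delta_ct(means: pd.DataFrame) -> pd.DataFrame:
    """Light/dark expression ratio per biological replicate.

    ddCT = dCT(light) - dCT(dark); ratio = 2^-ddCT. Adding any constant to
    all four CT values of a replicate (a plate offset) cancels.
    """
    dct = delta_ct(means)
    wide = dct.pivot_table(
        index=["strain_id", "biological_replicate"], columns="condition", values="delta_ct"
    ).reset_index()
    if wide[["light", "dark"]].isna().any().any():
        raise ValueError("every biological replicate needs both light and dark cells")
    wide["ddct"] = wide["light"] - wide["dark"]
    wide["ratio"] = 2.0 ** (-wide["ddct"])
    return wide[["strain_id", "biological_replicate", "light", "dark", "ddct", "ratio"]]


def to_signed_fold_change(ratio: float) -> float:
    """Map an expression ratio to the signed fold-change convention."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def signed_to_ratio(signed: float) -> float:
    """Inverse of :func:`to_signed_fold_change` (exact round trip)."""
    if abs(signed) < 1.0:
        raise ValueError("|signed fold-change| must be >= 1")
    return signed if signed >= 1.0 else -1.0 / signed


def aggregate_biological(per_replicate: pd.DataFrame, alpha: float = 0.05) -> list[DiurnalFoldChange]:
    """Aggregate per-replicate ratios into per-strain fold-changes.

    The mean and SD are taken over per-replicate *signed* fold-changes;
    significance is a two-sample equal-variance t test on the replicate
    dCT values, light vs dark, two-tailed. With a single biological
    replicate the SD is missing and significance is not computed.
    """
    out = []
    for sid, g in per_replicate.groupby("strain_id", sort=False):
        signed_vals = [to_signed_fold_change(r) for r in g["ratio"]]
        if len(signed_vals) >= 2:
            mean_signed, sd_signed = mean_sd(signed_vals)
            try:
                p = two_sample_ttest_equal_var(g["light"], g["dark"]).p_two_tail
            except ValueError:
                # zero pooled variance with unequal means: perfectly separated
                p = 0.0 if not np.isclose(g["light"].mean(), g["dark"].mean()) else 1.0
            significant = p < alpha
        else:
            mean_signed, sd_signed = signed_vals[0], float("nan")
            p, significant = float("nan"), False
        # |mean signed| can fall below 1 when replicates straddle ratio = 1;
        # clamp into the valid signed range before inverting.
        if abs(mean_signed) < 1.0:
            ratio = mean_signed if mean_signed > 0 else -1.0 / mean_signed
        else:
            ratio = signed_to_ratio(mean_signed)
        out.append(
            DiurnalFoldChange(
                strain_id=str(sid),
                ratio=ratio,
                signed=mean_signed,
                sd_signed=sd_signed,
                significant=bool(significant),
                p_value=p,
                n_replicates=len(signed_vals),
            )
        )
    return out


def analyze_diurnal(table: pd.DataFrame, alpha: float = 0.05) -> list[DiurnalFoldChange]:
    """Full pipeline: technical means -> ddCT ratios -> per-strain summary."""
    return aggregate_biological(delta_delta_ct(mean_technical_ct(table)), alpha=alpha)


def summarize_diurnal(results) -> dict:
    """Library-level diurnal summary.

    ``results`` is a list of DiurnalFoldChange or of signed fold-change
    numbers. Counts promoters more than twofold up in the light, between
    1.5- and 2-fold up, and down-regulated; the overall mean +/- SD is
    taken over expression *ratios* (negative signed values converted back
    via 1/|signed| before averaging).
    """
    signed = [r.signed if isinstance(r, DiurnalFoldChange) else float(r) for r in results]
    if not signed:
        raise ValueError("no results to summarize")
    ratios = [s if s > 0 else 1.0 / abs(s) for s in signed]
    mean_ratio, sd_ratio = mean_sd(ratios)
    return {
        "n": len(signed),
        "n_over_twofold": sum(1 for s in signed if s > 2.0),
        "n_1p5_to_2fold": sum(1 for s in signed if 1.5 < s <= 2.0),
        "n_down": sum(1 for s in signed if s < 0),
        "mean_ratio": mean_ratio,
        "sd_ratio": sd_ratio if not math.isnan(sd_ratio) else None,
    }


def write_diurnal_tsv(results: list[DiurnalFoldChange], path: str, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("strain_id\tsigned_fold_change\tsd\tsignificant\tp_value\tn_replicates\n")
        for r in results:
            star = "*" if r.significant else ""
            fh.write(
                f"{r.strain_id}\t{r.signed:.3g}{star}\t{r.sd_signed:.3g}"
                f"\t{r.significant}\t{r.p_value:.4g}\t{r.n_replicates}\n"
            )


def write_summary_json(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
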