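"""Published reference measurements for the PCC 7002 promoter library.

These small tables are the published per-promoter summaries for the
25-promoter Ypet reporter library in Synechococcus sp. PCC 7002 (24 native
promoters plus the rbc promoter). They serve as reference inputs for the
library-level summaries this package computes — strength-tier partitions
and diurnal light:dark statistics — and as anchors in the test suite.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_promoter_summary",
    "load_diurnal_fold_changes",
    "load_neutral_sites",
    "PCC7002_CHROM_LEN",
    "WT_LINEAR_GROWTH_RATE",
]

#: Length of the Synechococcus sp. PCC 7002 chromosome (bp).
PCC7002_CHROM_LEN = 3_008_047

#: Wild-type linear growth rate under standard conditions, OD730/h (+/- 0.0103 SD).
WT_LINEAR_GROWTH_RATE = 0.0334

# locus, mean Ypet fluorescence normalized to wild type, SD, significant vs
# wild type (two-tail p < 0.05), slope of normalized fluorescence vs OD730,
# Pearson r of fluorescence vs RNA-seq profile. Continuous-light conditions.
_PROMOTER_SUMMARY = [
    ("A0047", 1.322, 0.116, True, -0.0192, 0.0967),
    ("A0255", 1.073, 0.133, False, -0.0265, -0.722),
    ("A0304", 1.038, 0.158, False, -0.107, 0.715),
    ("A0318", 1.137, 0.135, True, 0.196, 0.212),
    ("A0670", 1.239, 0.442, False, 0.178, 0.678),
    ("A0740", 1.186, 0.0919, True, 3.83e-04, -0.628),
    ("A1173", 1.087, 0.0914, True, 0.172, 0.252),
    ("A1181", 1.074, 0.0937, False, -0.0108, -0.0121),
    ("A1731", 1.075, 0.0967, False, 0.0640, 0.181),
    ("A1798", 4.153, 2.17, True, 2.88, -0.335),  # rbc
    ("A1929", 1.046, 0.0866, False, -0.0547, 0.800),
    ("A1930", 2.338, 0.197, True, -0.107, 0.249),
    ("A1961", 2.076, 0.237, True, 0.744, 0.348),
    ("A1962", 1.059, 0.126, False, -0.0533, 0.256),
    ("A2062", 1.038, 0.00945, True, 0.0392, -0.0315),
    ("A2127", 1.073, 0.0576, True, 0.0583, 0.457),
    ("A2165", 1.205, 0.129, True, 0.148, 0.960),
    ("A2210", 1.129, 0.191, False, 0.163, -0.907),
    ("A2520", 31.88, 4.61, True, 35.4, -0.954),
    ("A2531", 2.340, 0.199, True, 0.105, -0.638),
    ("A2579", 33.51, 6.28, True, 30.2, -0.968),
    ("A2595", 1.061, 0.107, False, -0.0697, -0.972),
    ("A2596", 1.108, 0.0762, True, -0.0649, -0.895),
    ("A2663", 1.490, 0.169, True, 0.0140, -0.116),
    ("A2813", 3.486, 0.791, True, 0.108, -0.213),
]

# locus, signed light:dark fold-change (negative = down in the light), SD,
# significant (two-tail p < 0.05 on the light-vs-dark dCT values).
_DIURNAL_FOLD_CHANGES = [
    ("A0047", 1.01, 0.38, False),
    ("A0255", 1.01, 0.25, False),
    ("A0304", 1.29, 0.089, False),
    ("A0318", 1.39, 0.34, False),
    ("A0670", 1.31, 0.20, False),
    ("A0740", 1.44, 0.54, False),
    ("A1173", 1.41, 0.34, False),
    ("A1181", 1.79, 0.39, False),
    ("A1731", 1.85, 0.79, True),
    ("A1798", 1.16, 0.13, False),  # rbc
    ("A1929", -1.09, 0.30, False),
    ("A1930", 1.11, 0.017, False),
    ("A1961", -1.33, 0.30, False),
    ("A1962", 1.03, 0.39, False),
    ("A2062", 1.46, 0.23, False),
    ("A2127", 1.21, 0.40, False),
    ("A2165", 1.45, 0.015, True),
    ("A2210", -1.34, 0.44, False),
    ("A2520", 2.02, 0.90, False),
    ("A2531", 1.35, 0.031, False),
    ("A2579", 1.14, 0.45, False),
    ("A2595", 1.45, 0.42, False),
    ("A2596", -1.05, 0.10, False),
    ("A2663", 1.13, 0.31, False),
    ("A2813", 2.28, 0.73, False),
]

# start, end (1-based inclusive), left and right flanking locus tags.
_NEUTRAL_SITES = [
    ("NS1", 963_217, 964_242, "SYNPCC7002_A0932", "SYNPCC7002_A0933"),
    ("NS2", 1_247_018, 1_248_056, "SYNPCC7002_A1202", "SYNPCC7002_A1203"),
    ("NS3", 1_864_422, 1_865_821, "SYNPCC7002_A1778", "SYNPCC7002_A1779"),
]


def load_promoter_summary() -> pd.DataFrame:
    """Per-promoter continuous-light characterization (25 promoters)."""
    return pd.DataFrame(
        _PROMOTER_SUMMARY,
        columns=["locus", "mean_fluor", "sd_fluor", "significant", "fluor_slope", "correlation_r"],
    )


def load_diurnal_fold_changes() -> pd.DataFrame:
    """Per-promoter signed light:dark fold-changes (25 promoters)."""
    return pd.DataFrame(
        _DIURNAL_FOLD_CHANGES, columns=["locus", "signed", "sd", "significant"]
    )


def load_neutral_sites() -> pd.DataFrame:
    """The three verified/candidate neutral integration sites of PCC 7002."""
    return pd.DataFrame(
        _NEUTRAL_SITES, columns=["name", "start", "end", "left_locus", "right_locus"]
    )
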