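import numpy as np
import pytest

from chassiskit import synthetic_data as sd

#: The three neutral-site coordinate ranges of the PCC 7002 chromosome.
PLANTED_GAPS = [(963_217, 964_242), (1_247_018, 1_248_056), (1_864_422, 1_865_821)]
CHROM_LEN = 3_008_047


@pytest.fixture(scope="session")
def growth_model():
    return sd.GrowthModel()


@pytest.fixture(scope="session")
def growth_curve(growth_model):
    return sd.simulate_growth(growth_model, sd._default_times(growth_model))


@pytest.fixture(scope="session")
def planted_annotation():
    return sd.generate_annotation(500, PLANTED_GAPS, chrom_len=CHROM_LEN, seed=11)


def coverage_mask_gaps(records, chrom_len, min_len, circular=False):
    """Brute-force oracle: per-base boolean coverage scan."""
    covered = np.zeros(chrom_len, dtype=bool)  # index i = position i+1
    for r in records:
        covered[r.start - 1 : r.end] = True
    free = ~covered
    runs = []
    i = 0
    while i < chrom_len:
        if free[i]:
            j = i
            while j < chrom_len and free[j]:
                j += 1
            runs.append((i + 1, j))  # back to 1-based inclusive
            i = j
        else:
            i += 1
    if circular and len(runs) >= 2 and runs[0][0] == 1 and runs[-1][1] == chrom_len:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1]
        runs.append((last[0], first[1]))  # wrapped run, start > end
    out = []
    for s, e in runs:
        length = (e - s + 1) if s <= e else (chrom_len - s + 1) + e
        if length > min_len:
            out.append((s, e, length))
    return sorted(out)
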