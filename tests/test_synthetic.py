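"""Generator determinism, growth-curve shape, and planted-truth structure."""

import numpy as np
import pandas as pd
import pytest

from chassiskit import synthetic_data as sd
from chassiskit.neutral_sites import find_intergenic_gaps
from conftest import CHROM_LEN, PLANTED_GAPS


class TestGrowth:
    def test_linear_phase_increments(self, growth_model):
        """Well past the switch, successive ODs differ by linear_rate * dt."""
        times = [100.0, 110.0, 124.0]
        curve = sd.simulate_growth(growth_model, times)
        ods = [od for _, od in curve]
        assert ods[1] - ods[0] == pytest.approx(0.0334 * 10.0)
        assert ods[2] - ods[1] == pytest.approx(0.0334 * 14.0)

    def test_continuous_at_switch(self, growth_model):
        ts = growth_model.t_switch
        eps = 1e-6
        (_, before), (_, at), (_, after) = sd.simulate_growth(
            growth_model, [ts - eps, ts, ts + eps]
        )
        assert at == pytest.approx(growth_model.od_switch, rel=1e-6)
        assert after - before < 1e-4

    def test_degenerate_exponential_phase_is_pure_line(self):
        model = sd.GrowthModel(od0=0.3, mu=0.0, od_switch=0.3, linear_rate=0.05, duration=10)
        curve = sd.simulate_growth(model, [0.0, 1.0, 2.0])
        assert [od for _, od in curve] == pytest.approx([0.3, 0.35, 0.4])

    def test_monotone_non_decreasing(self, growth_model, growth_curve):
        ods = [od for _, od in growth_curve]
        assert all(b >= a for a, b in zip(ods, ods[1:]))

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            sd.GrowthModel(linear_rate=0.0)
        with pytest.raises(ValueError):
            sd.GrowthModel(mu=0.0, od_switch=0.4, od0=0.05)
        with pytest.raises(ValueError):
            sd.simulate_growth(sd.GrowthModel(), [2.0, 1.0])


class TestDeterminism:
    def test_fluorescence_byte_identical(self, growth_curve):
        truth = sd.PromoterTruth("p", strength=3.0, noise_cv=0.2)
        cfg = sd.SimConfig(seed=99)
        a, wa = sd.simulate_fluorescence(truth, growth_curve, cfg)
        b, wb = sd.simulate_fluorescence(truth, growth_curve, cfg)
        for x, y in zip(a + wa, b + wb):
            assert x.fluor.tobytes() == y.fluor.tobytes()
            assert x.dilution.tobytes() == y.dilution.tobytes()

    def test_qpcr_and_annotation_and_plates_deterministic(self):
        truth = sd.PromoterTruth("p", light_dark_ratio=1.4)
        cfg = sd.SimConfig(seed=7)
        pd.testing.assert_frame_equal(sd.simulate_qpcr(truth, cfg), sd.simulate_qpcr(truth, cfg))
        a = sd.generate_annotation(50, [(5000, 7000)], 20000, seed=7)
        b = sd.generate_annotation(50, [(5000, 7000)], 20000, seed=7)
        assert a == b
        oa = sd.simulate_transformation(0.1, 250, 1, 0.5, seed=7)
        ob = sd.simulate_transformation(0.1, 250, 1, 0.5, seed=7)
        assert oa == ob

    def test_streams_isolated_by_label(self, growth_curve):
        """Different promoter IDs draw from independent streams."""
        cfg = sd.SimConfig(seed=1)
        a, _ = sd.simulate_fluorescence(sd.PromoterTruth("x", noise_cv=0.2), growth_curve, cfg)
        b, _ = sd.simulate_fluorescence(sd.PromoterTruth("y", noise_cv=0.2), growth_curve, cfg)
        assert not np.allclose(a[0].fluor, b[0].fluor)


class TestFluorescence:
    def test_wildtype_identity(self, growth_curve):
        truth = sd.PromoterTruth("p", strength=1.0, pattern="constitutive", noise_cv=0.0)
        strains, wts = sd.simulate_fluorescence(truth, growth_curve, sd.SimConfig(seed=0))
        assert np.allclose(strains[0].undiluted, wts[0].undiluted)

    def test_narrow_growth_range_rejected(self):
        truth = sd.PromoterTruth("p")
        narrow = [(0.0, 0.5), (10.0, 1.0)]
        with pytest.raises(ValueError, match="does not cover"):
            sd.simulate_fluorescence(truth, narrow, sd.SimConfig(seed=0))

    def test_saturated_samples_are_diluted(self, growth_curve):
        truth = sd.PromoterTruth("p", strength=50.0, noise_cv=0.0)
        strains, _ = sd.simulate_fluorescence(truth, growth_curve, sd.SimConfig(seed=0))
        s = strains[0]
        assert (s.dilution > 1).any()
        assert (s.fluor <= sd.SATURATION_AU + 1e-9).all()


class TestQpcr:
    def test_planted_ct_structure(self):
        truth = sd.PromoterTruth("p", light_dark_ratio=4.0)
        tbl = sd.simulate_qpcr(truth, sd.SimConfig(seed=0, ct_sd=0.0), include_controls=False)
        cell = tbl.groupby(["gene", "condition", "biological_replicate"])["ct"].mean()
        for rep in (1, 2, 3):
            # reference identical across conditions up to the plate offset,
            # which shifts target and reference together
            dct_light = cell[("target", "light", rep)] - cell[("reference", "light", rep)]
            dct_dark = cell[("target", "dark", rep)] - cell[("reference", "dark", rep)]
            assert dct_light - dct_dark == pytest.approx(-2.0)  # -log2(4)

    def test_replicate_counts_respected(self):
        cfg = sd.SimConfig(seed=0, n_biological_replicates=2, n_technical_replicates=4)
        tbl = sd.simulate_qpcr(sd.PromoterTruth("p"), cfg, include_controls=False)
        assert tbl["biological_replicate"].nunique() == 2
        assert tbl["technical_replicate"].nunique() == 4


class TestAnnotation:
    def test_planted_gaps_are_the_only_large_runs(self, planted_annotation):
        gaps = find_intergenic_gaps(planted_annotation, CHROM_LEN, min_len=1000)
        assert [(g.start, g.end) for g in gaps] == PLANTED_GAPS

    def test_no_gaps_when_none_planted(self):
        recs = sd.generate_annotation(30, [], 50000, seed=2)
        assert find_intergenic_gaps(recs, 50000, min_len=1000) == []

    def test_overlapping_planted_gaps_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sd.generate_annotation(10, [(100, 300), (250, 500)], 10000, seed=0)
        with pytest.raises(ValueError, match="inside"):
            sd.generate_annotation(10, [(1, 300)], 10000, seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_layouts_tile_except_planted_gaps(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = int(rng.integers(20_000, 60_000))
        g1 = int(rng.integers(2000, chrom_len // 2 - 2000))
        g2 = int(rng.integers(chrom_len // 2 + 2000, chrom_len - 3000))
        planted = [(g1, g1 + int(rng.integers(1001, 2000))),
                   (g2, g2 + int(rng.integers(1001, 2000)))]
        recs = sd.generate_annotation(40, planted, chrom_len, seed=seed)
        gaps = find_intergenic_gaps(recs, chrom_len, min_len=1000)
        assert [(g.start, g.end) for g in gaps] == planted


class TestTransformation:
    def test_zero_efficiency_zero_colonies(self):
        for seed in range(10):
            assert sd.simulate_transformation(0.0, 250, 1, 0.5, seed=seed).cfu == 0

    def test_screen_counts_average_planted_fraction(self):
        pos = [
            sd.simulate_transformation(0.1, 250, 1, 0.34, seed=s).n_positive
            for s in range(300)
        ]
        assert np.mean(pos) == pytest.approx(17.0, abs=1.0)


def test_truth_yaml_sidecar(tmp_path):
    truth = sd.PromoterTruth("p", strength=2.0)
    out = tmp_path / "truth.yaml"
    sd.write_truth_yaml(truth, str(out))
    import yaml

    loaded = yaml.safe_load(out.read_text())
    assert loaded["promoter_id"] == "p" and loaded["strength"] == 2.0
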