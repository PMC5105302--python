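"""Normalization, gridding, and promoter classification."""

import numpy as np
import pytest

from chassiskit import datasets
from chassiskit import synthetic_data as sd
from chassiskit.promoter_expression import (
    REFERENCE_OD_GRID,
    FluorescenceSeries,
    NormalizedProfile,
    RnaSeqProfile,
    characterize_promoter,
    classify_regulatory_pattern,
    classify_strength,
    correlate_profiles,
    fit_expression_slope,
    interpolate_at_reference_ods,
    normalize_to_wildtype,
    pooled_wildtype,
    profile_from_series,
)


def _series(strain, ods, fluor, dilution=None, replicate=1):
    ods = np.asarray(ods, float)
    return FluorescenceSeries(
        strain_id=strain,
        replicate=replicate,
        time_h=np.arange(ods.size, dtype=float),
        od730=ods,
        fluor=np.asarray(fluor, float),
        dilution=np.ones(ods.size) if dilution is None else np.asarray(dilution, float),
    )


WT = _series("wt", [0.2, 0.5, 1.0, 2.0, 4.0, 6.0], [200, 500, 1000, 2000, 4000, 6000])


class TestNormalization:
    def test_self_normalization_is_unity(self):
        od, vals = normalize_to_wildtype(WT, WT)
        assert np.allclose(vals, 1.0)

    def test_constant_fold_recovered_exactly(self):
        strain = _series("s", WT.od730, WT.fluor * 31.88)
        _, vals = normalize_to_wildtype(strain, WT)
        assert np.allclose(vals, 31.88)

    def test_dilution_factor_restores_undiluted_signal(self):
        strain = _series("s", WT.od730, WT.fluor * 0.2, dilution=np.full(6, 10.0))
        _, vals = normalize_to_wildtype(strain, WT)
        assert np.allclose(vals, 2.0)

    def test_piecewise_linear_wildtype_interpolated_exactly(self):
        # wt signal piecewise linear in OD; strain sampled at off-node ODs
        strain_ods = np.array([0.3, 0.75, 1.5, 3.0, 5.0])
        wt_at = np.interp(strain_ods, WT.od730, WT.undiluted)
        strain = _series("s", strain_ods, 4.0 * wt_at)
        _, vals = normalize_to_wildtype(strain, WT)
        assert np.allclose(vals, 4.0)

    def test_out_of_range_samples_dropped_with_warning(self):
        strain = _series("s", [0.1, 1.0, 8.0], [10, 1000, 9000])
        with pytest.warns(UserWarning, match="outside wild-type"):
            od, vals = normalize_to_wildtype(strain, WT)
        assert od.tolist() == [1.0]


class TestGridding:
    def test_midpoint(self):
        out = interpolate_at_reference_ods([0.2, 0.6], [2.0, 4.0], od_grid=[0.4])
        assert out[0] == pytest.approx(3.0)

    def test_identity_on_grid(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.allclose(interpolate_at_reference_ods(grid, vals), vals)

    def test_exact_on_piecewise_linear_truth(self):
        rng = np.random.default_rng(1)
        ods = np.sort(rng.uniform(0.2, 6.0, 15))
        ods[0], ods[-1] = 0.2, 6.0
        truth = lambda od: 3.0 * od + 0.5  # noqa: E731
        out = interpolate_at_reference_ods(ods, truth(ods))
        assert np.allclose(out, truth(np.asarray(REFERENCE_OD_GRID)))

    def test_out_of_range_grid_points_missing(self):
        out = interpolate_at_reference_ods([0.5, 2.0], [1.0, 1.0])
        assert np.isnan(out[0]) and np.isnan(out[-1])
        assert not np.isnan(out[2])


class TestSlopeAndPattern:
    def test_flat_profile(self):
        prof = NormalizedProfile("p", REFERENCE_OD_GRID, np.ones((2, 5)))
        slope, _ = fit_expression_slope(prof)
        assert slope == pytest.approx(0.0)
        assert classify_regulatory_pattern(prof) == "constitutive"

    def test_exact_line(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        prof = NormalizedProfile("p", grid, 2.0 * grid)
        assert fit_expression_slope(prof) == pytest.approx((2.0, 0.0))

    def test_thirty_percent_rule(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        rising = NormalizedProfile("p", grid, 1.0 + 0.5 * (grid - 0.4) / 4.6)
        falling = NormalizedProfile("p", grid, 1.0 - 0.5 * (grid - 0.4) / 4.6)
        near_flat = NormalizedProfile("p", grid, 1.0 + 0.2 * (grid - 0.4) / 4.6)
        assert classify_regulatory_pattern(rising) == "stationary_phase"
        assert classify_regulatory_pattern(falling) == "linear_phase"
        assert classify_regulatory_pattern(near_flat) == "constitutive"

    def test_pattern_invariant_to_uniform_scaling(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        base = 1.0 + 0.5 * (grid - 0.4) / 4.6
        for scale in (0.01, 1.0, 500.0):
            prof = NormalizedProfile("p", grid, scale * base)
            assert classify_regulatory_pattern(prof) == "stationary_phase"

    def test_nonpositive_baseline_rejected(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        prof = NormalizedProfile("p", grid, 0.1 * (grid - 0.5))
        with pytest.raises(ValueError, match="non-positive"):
            classify_regulatory_pattern(prof)


class TestStrengthTiers:
    @pytest.mark.parametrize(
        "mean,p,tier",
        [
            (1.0, 0.001, "not_significant"),
            (4.0, 0.5, "not_significant"),
            (1.8, 0.01, "weak"),
            (4.153, 0.01, "moderate"),
            (33.51, 0.01, "strong"),
        ],
    )
    def test_tier_rules(self, mean, p, tier):
        assert classify_strength(mean, p) == tier

    def test_published_library_partition(self):
        """The 25-promoter reference library splits 5 moderate / 2 strong,
        with exactly 7 significant promoters above 1.5-fold."""
        df = datasets.load_promoter_summary()
        tiers = [
            classify_strength(m, 0.01 if sig else 0.5)
            for m, sig in zip(df.mean_fluor, df.significant)
        ]
        above = [
            (m, s) for m, s, sig in zip(df.mean_fluor, tiers, df.significant)
            if sig and m > 1.5
        ]
        assert len(above) == 7
        assert tiers.count("moderate") == 5
        assert tiers.count("strong") == 2


class TestCorrelation:
    def test_affine_transforms(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        rna = RnaSeqProfile("x", grid, np.array([1.0, 2.0, 2.5, 4.0, 6.0]))
        up = NormalizedProfile("x", grid, 0.3 * rna.values + 1.0)
        down = NormalizedProfile("x", grid, -0.3 * rna.values + 10.0)
        assert correlate_profiles(up, rna) == pytest.approx(1.0)
        assert correlate_profiles(down, rna) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(2)
        grid = np.asarray(REFERENCE_OD_GRID)
        f = rng.uniform(0.5, 5, 5)
        r = rng.uniform(0, 1e-3, 5)
        got = correlate_profiles(NormalizedProfile("x", grid, f), RnaSeqProfile("x", grid, r))
        want = np.cov(f, r)[0, 1] / (np.std(f, ddof=1) * np.std(r, ddof=1))
        assert got == pytest.approx(want, rel=1e-12)

    def test_too_few_shared_points_is_missing(self):
        grid = np.asarray(REFERENCE_OD_GRID)
        vals = np.array([1.0, 2.0, np.nan, np.nan, np.nan])
        prof = NormalizedProfile("x", grid, vals)
        rna = RnaSeqProfile("x", grid, np.arange(5.0))
        assert np.isnan(correlate_profiles(prof, rna))


class TestPipelineRoundTrip:
    @pytest.mark.parametrize("pattern", sorted(sd.PATTERN_RELATIVE_CHANGE))
    def test_noise_free_pattern_and_strength_recovery(self, pattern, growth_curve):
        truth = sd.PromoterTruth("p", strength=5.0, pattern=pattern, noise_cv=0.0)
        strains, wts = sd.simulate_fluorescence(truth, growth_curve, sd.SimConfig(seed=0))
        c = characterize_promoter(strains, wts)
        assert c.regulatory_class == pattern
        assert c.mean_norm_fluor == pytest.approx(5.0, rel=1e-9)
        assert c.strength_tier == "moderate"

    def test_normalize_then_grid_commutes_on_piecewise_linear_input(self):
        """Normalizing then gridding equals gridding raw signals then
        normalizing, when both signals are linear in OD."""
        ods = np.array([0.3, 0.8, 1.5, 2.5, 4.0, 5.5])
        wt = _series("wt", ods, 1000 * ods)
        strain = _series("s", ods, 3000 * ods)
        od, vals = normalize_to_wildtype(strain, wt)
        route1 = interpolate_at_reference_ods(od, vals)
        grid_strain = interpolate_at_reference_ods(ods, strain.undiluted)
        grid_wt = interpolate_at_reference_ods(ods, wt.undiluted)
        route2 = grid_strain / grid_wt
        assert np.allclose(route1, route2)

    def test_pooled_wildtype_averages_replicates(self):
        wt1 = _series("wt", [0.2, 1.0, 6.0], [180, 900, 5400], replicate=1)
        wt2 = _series("wt", [0.2, 1.0, 6.0], [220, 1100, 6600], replicate=2)
        pooled = pooled_wildtype([wt1, wt2])
        assert np.allclose(pooled.undiluted, [200, 1000, 6000])

    def test_profile_from_series_requires_input(self):
        with pytest.raises(ValueError):
            profile_from_series([], WT)
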