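import numpy as np
import pytest

from popdemix import (
    EffectSpec,
    averaged_projections,
    bootstrap_bands,
    build_rate_tensor,
    distance_curve,
    factor_distance_curves,
    fit_dpca,
    generate_population,
    randomization_compare,
)


def _pair_spec(design, param_frac, visual_frac, lo, hi, seed, **kw):
    """Both factors' effects confined to bins [lo, hi)."""
    prof = np.zeros((1, design.n_bins))
    prof[0, lo:hi] = 1.0
    ci = 1.0 - param_frac - visual_frac - 0.02
    kw.setdefault("noise_model", "gaussian")
    kw.setdefault("noise_sigma_hz", 1.0)
    kw.setdefault("baseline_hz", 40.0)
    kw.setdefault("signal_std_hz", 8.0)
    return EffectSpec(
        target_fractions={
            "condition_independent": ci,
            "parameter": param_frac,
            "visual": visual_frac,
            "interaction": 0.02,
        },
        temporal_profiles={"parameter": prof, "visual": prof},
        trials_per_condition=(4, 6),
        seed=seed,
        **kw,
    )


class TestDistanceCurve:
    def test_identical_curves_give_zero(self):
        a = np.random.default_rng(0).standard_normal(20)
        np.testing.assert_allclose(distance_curve(a, a), 0.0)

    def test_constant_offset_single_component(self):
        a = np.random.default_rng(1).standard_normal(15)
        np.testing.assert_allclose(distance_curve(a + 2.0, a), 2.0, atol=1e-12)

    def test_two_component_euclidean_norm(self):
        a = np.array([[3.0], [4.0]])
        b = np.zeros((2, 1))
        assert distance_curve(a, b)[0] == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_curve(np.zeros(5), np.zeros(6))


class TestAveragedProjections:
    def test_level_curve_is_mean_over_other_factor(self, design_2x2, mixed_spec):
        rec = generate_population(design_2x2, 20, mixed_spec)
        t = build_rate_tensor(rec)
        res = fit_dpca(t, 3)
        curves = averaged_projections(res, t, "parameter")
        j = res.leading_component("parameter")
        proj = res.projections[j]
        np.testing.assert_allclose(
            curves["horizontal"][0], proj[0].mean(axis=0), atol=1e-9
        )
        np.testing.assert_allclose(
            curves["vertical"][0], proj[1].mean(axis=0), atol=1e-9
        )

    def test_unknown_level_rejected(self, design_2x2, mixed_spec):
        rec = generate_population(design_2x2, 10, mixed_spec)
        t = build_rate_tensor(rec)
        res = fit_dpca(t, 2)
        with pytest.raises(KeyError):
            averaged_projections(res, t, "parameter", levels=("horizontal", "oblique"))

    def test_sign_flip_invariance_of_distances(self, design_2x2, mixed_spec):
        rec = generate_population(design_2x2, 20, mixed_spec)
        t = build_rate_tensor(rec)
        res = fit_dpca(t, 2)
        p1, v1 = factor_distance_curves(res, t)
        # flip every decoder/projection sign; distances must not change
        for phi in res.decoders:
            res.decoders[phi] = -res.decoders[phi]
        res.projections = -res.projections
        p2, v2 = factor_distance_curves(res, t)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_allclose(v1, v2, atol=1e-9)


class TestBootstrapBands:
    def test_unequal_factors_separate_in_planted_window(self, design_2x2):
        rec = generate_population(
            design_2x2, 80, _pair_spec(design_2x2, 0.4, 0.1, 8, 24, seed=9)
        )
        res = bootstrap_bands(rec, n_bootstrap=40, seed=2)
        assert len(res.separation_intervals) == 1
        start, stop = res.separation_intervals[0]
        assert abs(start - 8) <= 3 and abs(stop - 24) <= 3

    def test_equal_factors_do_not_separate(self, design_2x2):
        rec = generate_population(
            design_2x2, 80, _pair_spec(design_2x2, 0.25, 0.25, 8, 24, seed=10)
        )
        res = bootstrap_bands(rec, n_bootstrap=40, seed=2)
        assert res.separation_intervals == []

    def test_bands_contain_point_curve_in_most_bins(self, design_2x2):
        rec = generate_population(
            design_2x2, 60, _pair_spec(design_2x2, 0.3, 0.2, 5, 25, seed=3)
        )
        res = bootstrap_bands(rec, n_bootstrap=40, seed=1)
        inside = (
            (res.parameter_ci[0] <= res.parameter_curve)
            & (res.parameter_curve <= res.parameter_ci[1])
        ).mean()
        assert inside >= 0.9

    def test_deterministic_under_seed(self, design_2x2, mixed_spec):
        rec = generate_population(design_2x2, 20, mixed_spec)
        a = bootstrap_bands(rec, n_bootstrap=25, seed=4)
        b = bootstrap_bands(rec, n_bootstrap=25, seed=4)
        np.testing.assert_array_equal(a.parameter_ci[0], b.parameter_ci[0])
        np.testing.assert_array_equal(a.visual_ci[1], b.visual_ci[1])
        assert a.separation_intervals == b.separation_intervals

    def test_few_resamples_warns(self, design_2x2, mixed_spec):
        rec = generate_population(design_2x2, 15, mixed_spec)
        with pytest.warns(UserWarning, match="unstable"):
            bootstrap_bands(rec, n_bootstrap=10, seed=0)

    def test_three_level_design_is_restricted_to_pair(self, design_3x2, mixed_spec):
        rec = generate_population(design_3x2, 30, mixed_spec)
        res = bootstrap_bands(
            rec, parameter_levels=("left", "right"), n_bootstrap=25, seed=0
        )
        assert res.parameter_levels == ("left", "right")
        assert res.parameter_curve.shape == (design_3x2.n_bins,)


class TestRandomization:
    def test_exchangeable_factors_are_calibrated(self, design_2x2):
        rec = generate_population(
            design_2x2, 80, _pair_spec(design_2x2, 0.25, 0.25, 8, 24, seed=12)
        )
        res = randomization_compare(rec, n_iter=40, seed=6)
        assert (res.p_values < 0.05).mean() <= 0.15
        assert res.randomization_intervals == []

    def test_dominant_factor_flagged_in_its_window(self, design_2x2):
        rec = generate_population(
            design_2x2, 80, _pair_spec(design_2x2, 0.48, 0.0, 8, 24, seed=13)
        )
        res = randomization_compare(rec, n_iter=40, seed=6, min_consecutive=10)
        assert len(res.randomization_intervals) == 1
        start, stop = res.randomization_intervals[0]
        assert abs(start - 8) <= 3 and abs(stop - 24) <= 3

    def test_minimum_p_is_one_over_iterations(self, design_2x2, mixed_spec):
        rec = generate_population(design_2x2, 20, mixed_spec)
        res = randomization_compare(rec, n_iter=20, seed=1)
        assert res.p_values.min() >= 1 / 20 - 1e-12
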