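import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdemix import (
    DemixedPCA,
    EffectSpec,
    build_rate_tensor,
    generate_population,
    noiseless_rates,
)
from popdemix.dpca import (
    explained_variance_split,
    fit_dpca,
    fit_pca,
    marginalize,
    marginalize_array,
    project_conditions,
)

from conftest import random_centered_tensor


class TestMarginalize:
    def test_hand_built_2x2_toy_recovered_exactly(self):
        # x[s, v] = a + b_s + c_v + d_sv with zero-mean b, c, d
        a = 2.0
        b = np.array([1.0, -1.0])
        c = np.array([0.5, -0.5])
        d = np.array([[0.25, -0.25], [-0.25, 0.25]])
        x = a + b[:, None] + c[None, :] + d
        Xc = (x - x.mean())[None, :, :, None]  # (1, 2, 2, 1), centered
        parts = marginalize(Xc).parts
        np.testing.assert_allclose(parts["condition_independent"], 0.0, atol=1e-12)
        np.testing.assert_allclose(
            parts["parameter"][0, :, :, 0], b[:, None] * np.ones((1, 2)), atol=1e-12
        )
        np.testing.assert_allclose(
            parts["visual"][0, :, :, 0], c[None, :] * np.ones((2, 1)), atol=1e-12
        )
        np.testing.assert_allclose(parts["interaction"][0, :, :, 0], d, atol=1e-12)

    def test_uniform_tensor_has_only_ci_part(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((8, 1, 1, 12))
        Xc = np.tile(base, (1, 3, 2, 1))
        Xc -= Xc.mean(axis=(1, 2, 3), keepdims=True)
        parts = marginalize(Xc).parts
        for label in ("parameter", "visual", "interaction"):
            np.testing.assert_allclose(parts[label], 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_parts_sum_to_input_and_satisfy_zero_means(self, seed):
        Xc = random_centered_tensor(np.random.default_rng(seed))
        parts = marginalize(Xc).parts
        np.testing.assert_allclose(sum(parts.values()), Xc, atol=1e-12)
        assert np.ptp(parts["condition_independent"], axis=(1, 2)).max() < 1e-12
        assert np.abs(parts["parameter"].mean(axis=1)).max() < 1e-12
        assert np.abs(parts["visual"].mean(axis=2)).max() < 1e-12
        assert np.abs(parts["interaction"].mean(axis=1)).max() < 1e-12
        assert np.abs(parts["interaction"].mean(axis=2)).max() < 1e-12

    def test_idempotent_projection(self):
        Xc = random_centered_tensor(np.random.default_rng(5))
        parts = marginalize(Xc).parts
        for label, part in parts.items():
            again = marginalize_array(part)
            np.testing.assert_allclose(again[label], part, atol=1e-10)
            for other, p in again.items():
                if other != label:
                    np.testing.assert_allclose(p, 0.0, atol=1e-10)

    def test_uncentered_input_rejected(self):
        X = np.ones((3, 2, 2, 4))
        with pytest.raises(ValueError, match="not centered"):
            marginalize(X)


class TestFitPCA:
    def test_rank_one_tensor_explained_by_first_component(self):
        u = np.random.default_rng(1).standard_normal(10)
        pattern = np.random.default_rng(2).standard_normal((2, 2, 6))
        pattern -= pattern.mean()
        Xc = u[:, None, None, None] * pattern[None]
        _, cum = fit_pca(Xc, 3)
        assert cum[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_cumulative_reaches_one(self):
        Xc = random_centered_tensor(np.random.default_rng(3), n=6, s=2, v=2, t=5)
        _, cum = fit_pca(Xc, 6)
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(cum) >= -1e-12)

    def test_matches_gram_matrix_eigenvalue_oracle(self):
        Xc = random_centered_tensor(np.random.default_rng(4), n=20, s=3, v=2, t=8)
        Xmat = Xc.reshape(20, -1)
        evals = np.sort(np.linalg.eigvalsh(Xmat @ Xmat.T))[::-1]
        expected = np.cumsum(evals) / evals.sum()
        _, cum = fit_pca(Xc, 20)
        np.testing.assert_allclose(cum, expected, atol=1e-9)

    def test_out_of_range_q_rejected(self):
        Xc = random_centered_tensor(np.random.default_rng(0), n=5)
        with pytest.raises(ValueError):
            fit_pca(Xc, 0)
        with pytest.raises(ValueError):
            fit_pca(Xc, 6)


class TestFitDPCA:
    def test_single_marginalization_limit_equals_pca(self, design_2x2):
        spec = EffectSpec(
            target_fractions={"condition_independent": 1.0},
            noise_model="none",
            seed=5,
        )
        X = noiseless_rates(design_2x2, 20, spec)
        Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
        res = fit_dpca(Xc, 2, reg=0.0)
        axes, cum_pca = fit_pca(Xc, 2)
        np.testing.assert_allclose(
            res.cumulative_variance_dpca[:2], cum_pca, atol=1e-6
        )
        D = res.decoders["condition_independent"]
        Q = np.linalg.qr(D.T)[0]
        cosines = np.linalg.svd(axes @ Q)[1]
        np.testing.assert_allclose(cosines, 1.0, atol=1e-6)

    def test_cumulative_never_exceeds_pca(self, design_3x2, mixed_spec):
        rec = generate_population(design_3x2, 30, mixed_spec)
        res = fit_dpca(build_rate_tensor(rec), 5)
        assert np.all(
            res.cumulative_variance_dpca <= res.cumulative_variance_pca + 1e-9
        )

    def test_recovers_planted_shares_under_mild_noise(self, design_3x2):
        spec = EffectSpec(
            target_fractions={
                "condition_independent": 0.58,
                "parameter": 0.24,
                "visual": 0.11,
                "interaction": 0.07,
            },
            noise_model="gaussian",
            noise_sigma_hz=0.5,
            baseline_hz=50.0,
            signal_std_hz=12.0,
            trials_per_condition=(7, 15),
            seed=13,
        )
        rec = generate_population(design_3x2, 60, spec)
        split = explained_variance_split(build_rate_tensor(rec).centered())
        for label, frac in spec.target_fractions.items():
            assert split[label] == pytest.approx(100 * frac, abs=2.0)

    def test_rank_q_beats_any_pca_axis_pair_per_marginalization(self):
        """Reduced-rank solution is at least as good as projecting the part
        onto any pair of PCA axes of the data."""
        Xc = random_centered_tensor(np.random.default_rng(11), n=10, s=2, v=2, t=6)
        parts = marginalize_array(Xc)
        res = fit_dpca(Xc, 2, reg=0.0)
        Xmat = Xc.reshape(10, -1)
        axes, _ = fit_pca(Xc, 6)
        for label, part in parts.items():
            Pmat = part.reshape(10, -1)
            F = res.encoders[label][:, :2]
            D = res.decoders[label][:2]
            err_dpca = np.sum((Pmat - F @ (D @ Xmat)) ** 2)
            for i, j in itertools.combinations(range(6), 2):
                U = axes[[i, j]].T
                err_pca = np.sum((Pmat - U @ (U.T @ Xmat)) ** 2)
                assert err_dpca <= err_pca + 1e-9

    def test_zero_reg_with_more_neurons_than_samples_rejected(self):
        Xc = random_centered_tensor(np.random.default_rng(0), n=30, s=2, v=2, t=3)
        with pytest.raises(ValueError, match="lambda > 0"):
            fit_dpca(Xc, 2, reg=0.0)

    def test_invariance_to_neuron_order_and_silent_neuron(self):
        Xc = random_centered_tensor(np.random.default_rng(8), n=12, s=2, v=2, t=8)
        res = fit_dpca(Xc, 3)
        perm = np.random.default_rng(1).permutation(12)
        res_p = fit_dpca(Xc[perm], 3)
        np.testing.assert_allclose(
            res_p.component_variances, res.component_variances, atol=1e-8
        )
        np.testing.assert_allclose(res_p.projections, res.projections, atol=1e-6)

        silent = np.concatenate([Xc, np.zeros((1, 2, 2, 8))])
        res_s = fit_dpca(silent, 3)
        np.testing.assert_allclose(
            res_s.component_variances, res.component_variances, atol=1e-8
        )
        for label in res.decoders:
            np.testing.assert_allclose(
                res_s.decoders[label][:, -1], 0.0, atol=1e-8
            )


class TestSelectReg:
    def test_returns_a_candidate_and_is_deterministic(self, small_population):
        from popdemix import select_reg

        t = build_rate_tensor(small_population)
        candidates = [0.0, 1.0, 100.0, 1e4]
        lam1 = select_reg(t, candidates=candidates, q_per_marginalization=3, seed=1)
        lam2 = select_reg(t, candidates=candidates, q_per_marginalization=3, seed=1)
        assert lam1 in candidates
        assert lam1 == lam2

    def test_noisy_data_prefers_nonzero_ridge_over_huge_one(self, design_2x2):
        from popdemix import select_reg

        spec = EffectSpec(
            target_fractions={
                "condition_independent": 0.5,
                "parameter": 0.3,
                "visual": 0.15,
                "interaction": 0.05,
            },
            noise_model="gaussian",
            noise_sigma_hz=3.0,
            baseline_hz=40.0,
            signal_std_hz=5.0,
            trials_per_condition=(5, 8),
            seed=2,
        )
        rec = generate_population(design_2x2, 25, spec)
        t = build_rate_tensor(rec)
        scale = float(np.sum(t.centered() ** 2))
        lam = select_reg(t, q_per_marginalization=4, seed=0)
        # an absurdly large ridge (shrinking everything to zero) never wins
        assert lam < scale

    def test_requires_trial_tensor(self, small_population):
        from popdemix import select_reg

        t = build_rate_tensor(small_population, keep_trials=False)
        with pytest.raises(ValueError, match="trial"):
            select_reg(t)


class TestVarianceSplitAndProjections:
    def test_pure_time_data_yields_100_percent_ci(self, design_2x2):
        spec = EffectSpec(
            target_fractions={"condition_independent": 1.0},
            noise_model="none",
            seed=1,
        )
        X = noiseless_rates(design_2x2, 15, spec)
        Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
        split = explained_variance_split(Xc)
        assert split["condition_independent"] == pytest.approx(100.0, abs=1e-9)
        assert sum(split.values()) == pytest.approx(100.0, abs=1e-9)

    def test_projection_shape_is_conditions_by_time(self, design_3x2, mixed_spec):
        rec = generate_population(design_3x2, 20, mixed_spec)
        t = build_rate_tensor(rec)
        res = fit_dpca(t, 3)
        proj = project_conditions(res, t)
        assert proj.shape == (res.n_components, 3, 2, design_3x2.n_bins)
        # sign convention: first condition's time-average is non-negative
        assert np.all(proj[:, 0, 0, :].mean(axis=1) >= -1e-9)

    def test_pure_visual_component_separates_light_dark_only(self, design_2x2):
        spec = EffectSpec(
            target_fractions={"visual": 0.7, "condition_independent": 0.3},
            noise_model="none",
            seed=6,
        )
        X = noiseless_rates(design_2x2, 20, spec)
        Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
        res = fit_dpca(Xc, 2)
        j = res.leading_component("visual")
        proj = res.projections[j]
        # identical across parameter levels, distinct across visual levels
        np.testing.assert_allclose(proj[0], proj[1], atol=1e-6)
        assert np.abs(proj[0, 0] - proj[0, 1]).max() > 1e-3

    def test_demixing_quality_projection_of_part_close_to_full(
        self, design_3x2, mixed_spec
    ):
        rec = generate_population(design_3x2, 40, mixed_spec)
        t = build_rate_tensor(rec)
        Xc = t.centered()
        res = fit_dpca(t, 3)
        parts = marginalize_array(Xc)
        j = res.leading_component("parameter")
        d = res.ordered_decoders()[j]
        full = (d @ Xc.reshape(Xc.shape[0], -1))
        part = (d @ parts["parameter"].reshape(Xc.shape[0], -1))
        # the decoding axis reads out mostly its own marginalization
        resid = np.linalg.norm(full - part) / np.linalg.norm(full)
        assert resid < 0.35


class TestEstimatorAPI:
    def test_fit_transform_and_params_round_trip(self, small_population):
        t = build_rate_tensor(small_population)
        est = DemixedPCA(n_components=4, reg="auto")
        assert est.get_params() == {"n_components": 4, "reg": "auto"}
        proj = est.fit_transform(t)
        np.testing.assert_allclose(proj, est.projections_)
        again = est.transform(t)
        np.testing.assert_allclose(again, proj, atol=1e-9)
        assert est.variance_split_.keys() == set(
            ("condition_independent", "parameter", "visual", "interaction")
        ) or set(est.variance_split_) == {
            "condition_independent",
            "parameter",
            "visual",
            "interaction",
        }

    def test_unfitted_transform_raises(self, small_population):
        t = build_rate_tensor(small_population)
        with pytest.raises(AttributeError):
            DemixedPCA().transform(t)

    def test_encoder_columns_unit_norm(self, small_population):
        est = DemixedPCA(n_components=3).fit(build_rate_tensor(small_population))
        for F in est.encoders_.values():
            np.testing.assert_allclose(
                np.linalg.norm(F, axis=0), 1.0, atol=1e-9
            )
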