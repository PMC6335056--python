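"""APC model prediction and grid fitting."""

import numpy as np
import pytest
from scipy import stats

import artiphys as ap
from artiphys.apc import pearson_p_value, wrapped_angle_diff


class TestPredict:
    def test_element_at_preferred_point_gives_k(self, toy_bank):
        s = ap.BoundaryShape("x", (ap.BoundaryElement(0.5, 90.0),
                                   ap.BoundaryElement(-0.2, 200.0)))
        p = ap.APCParams(0.5, 0.3, 90.0, 45.0, k=2.7)
        assert ap.apc_predict(p, s) == pytest.approx(2.7)

    def test_zero_scale_gives_zero_everywhere(self, toy_bank):
        p = ap.APCParams(0.5, 0.3, 90.0, 45.0, k=0.0)
        for s in toy_bank:
            assert ap.apc_predict(p, s) == 0.0

    def test_hand_computed_two_element_case(self):
        # winning element (0.5, 90 deg): curvature exponent exp(-0.5), angular 1
        s = ap.BoundaryShape("x", (ap.BoundaryElement(0.5, 90.0),
                                   ap.BoundaryElement(-0.3, 270.0)))
        p = ap.APCParams(1.0, 0.5, 90.0, 45.0, k=1.0)
        assert ap.apc_predict(p, s) == pytest.approx(np.exp(-0.5), abs=1e-4)

    def test_angular_wrapping_is_circular(self):
        assert wrapped_angle_diff(350.0, 10.0) == 20.0
        assert wrapped_angle_diff(10.0, 350.0) == 20.0
        assert wrapped_angle_diff(180.0, 0.0) == 180.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            ap.APCParams(0.5, 0.0, 90.0, 45.0)
        with pytest.raises(ValueError):
            ap.APCParams(0.5, 0.3, 90.0, -1.0)


class TestGrid:
    def test_default_grid_has_65536_candidates(self, full_grid):
        assert len(full_grid) == 16 ** 4

    def test_two_per_axis_gives_16(self):
        assert len(ap.build_grid(n_per_axis=2)) == 16

    def test_angular_mean_step(self, full_grid):
        steps = np.diff(full_grid.mu_a)
        assert np.allclose(steps, 338.0 / 15.0)

    def test_endpoints_match_ranges(self, full_grid):
        assert full_grid.mu_c[0] == -0.5 and full_grid.mu_c[-1] == 1.0
        assert full_grid.sigma_c[0] == pytest.approx(0.01)
        assert full_grid.sigma_c[-1] == pytest.approx(0.98)
        assert full_grid.sigma_a[0] == pytest.approx(23.0)
        assert full_grid.sigma_a[-1] == pytest.approx(171.0)

    def test_sd_axes_are_log_spaced(self, full_grid):
        ratios = full_grid.sigma_c[1:] / full_grid.sigma_c[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_lexicographic_candidate_order(self, full_grid):
        p0 = full_grid.params_at(0)
        p1 = full_grid.params_at(1)
        assert (p0.mu_c, p0.sigma_c, p0.mu_a) == (p1.mu_c, p1.sigma_c, p1.mu_a)
        assert p1.sigma_a == full_grid.sigma_a[1]
        last = full_grid.params_at(len(full_grid) - 1)
        assert last.mu_c == full_grid.mu_c[-1]

    def test_nonpositive_sd_endpoint_rejected(self):
        with pytest.raises(ValueError):
            ap.build_grid({"sigma_c": (0.0, 1.0)})


class TestFit:
    def test_noise_free_self_consistency(self, bank, small_grid, small_pred):
        truth = small_grid.params_at(137)
        x = np.array([ap.apc_predict(truth, s) for s in bank])
        fit = ap.fit_apc(x, bank, small_grid, pred=small_pred)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.candidate_index == 137
        assert fit.params.k == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_oracle_equivalence(self, toy_bank):
        """Exhaustive independent re-evaluation of every candidate picks the
        same winner as the vectorized fitter."""
        grid = ap.build_grid(n_per_axis=2)
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, len(toy_bank))
        fit = ap.fit_apc(x, toy_bank, grid)
        best_r, best_idx = -np.inf, None
        for idx, params in enumerate(grid.iter_params()):
            pred = np.array([ap.apc_predict(params, s) for s in toy_bank])
            if np.std(pred) == 0:
                continue
            r = stats.pearsonr(x, pred).statistic
            if r > best_r:
                best_r, best_idx = r, idx
        assert fit.candidate_index == best_idx
        assert fit.r == pytest.approx(best_r, abs=1e-12)

    def test_scale_invariance_of_fit(self, bank, small_grid, small_pred):
        truth = small_grid.params_at(42)
        x = np.array([ap.apc_predict(truth, s) for s in bank]) + 0.01
        f1 = ap.fit_apc(x, bank, small_grid, pred=small_pred)
        f2 = ap.fit_apc(3.7 * x, bank, small_grid, pred=small_pred)
        assert f1.candidate_index == f2.candidate_index
        assert f1.r == pytest.approx(f2.r, abs=1e-12)
        assert f2.params.k == pytest.approx(3.7 * f1.params.k, rel=1e-9)

    def test_constant_responses_flagged_degenerate(self, toy_bank):
        grid = ap.build_grid(n_per_axis=2)
        fit = ap.fit_apc(np.ones(len(toy_bank)), toy_bank, grid)
        assert fit.degenerate and np.isnan(fit.r)

    def test_p_value_matches_reference(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        r, p_ref = stats.pearsonr(x, y)
        assert pearson_p_value(r, 50) == pytest.approx(p_ref, rel=1e-9)

    def test_fitted_r_degrades_monotonically_with_noise(self, bank, small_grid,
                                                        small_pred):
        truth = small_grid.params_at(99)
        base = np.array([ap.apc_predict(truth, s) for s in bank])
        medians = []
        for sd in (0.0, 0.3, 1.0, 3.0):
            rs = []
            for seed in range(7):
                rng = np.random.default_rng(1000 + seed)
                x = base + rng.normal(0, sd, len(base))
                rs.append(ap.fit_apc(x, bank, small_grid, pred=small_pred).r)
            medians.append(np.median(rs))
        assert all(a >= b for a, b in zip(medians, medians[1:]))

    def test_recovery_within_one_grid_step_at_high_snr(self, bank, full_grid,
                                                       full_pred):
        """Gaussian noise at SNR >= 10: means recovered to one grid step."""
        step_c = np.diff(full_grid.mu_c)[0]
        step_a = np.diff(full_grid.mu_a)[0]
        hits = 0
        n_units = 20
        for seed in range(n_units):
            rng = np.random.default_rng(500 + seed)
            truth = full_grid.params_at(int(rng.integers(len(full_grid))))
            x = np.array([ap.apc_predict(truth, s) for s in bank])
            x = x + rng.normal(0, x.std() / 10, len(x))
            fit = ap.fit_apc(x, bank, full_grid, pred=full_pred)
            da = abs(fit.params.mu_a - truth.mu_a)
            da = min(da, 360 - da)
            if da <= step_a + 1e-9 and abs(fit.params.mu_c - truth.mu_c) <= step_c + 1e-9:
                hits += 1
        assert hits >= int(0.95 * n_units)


class TestShuffleControl:
    def test_shuffle_preserves_value_multiset(self):
        x = np.arange(20, dtype=float)
        y = ap.shuffle_control(x, seed=4)
        assert sorted(y) == sorted(x)
        assert not np.array_equal(x, y)

    def test_shuffle_deterministic(self):
        x = np.arange(50, dtype=float)
        assert np.array_equal(ap.shuffle_control(x, 9), ap.shuffle_control(x, 9))

    def test_shuffling_collapses_fit_quality(self, bank, small_grid, small_pred):
        truth = small_grid.params_at(77)
        x = np.array([ap.apc_predict(truth, s) for s in bank])
        wins = 0
        for seed in range(10):
            r_int = ap.fit_apc(x, bank, small_grid, pred=small_pred).r
            r_shuf = ap.fit_apc(ap.shuffle_control(x, seed), bank, small_grid,
                                pred=small_pred).r
            wins += r_int > r_shuf
        assert wins == 10
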