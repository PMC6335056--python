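"""TI metric, separability index, position profiles and CRF estimation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import artiphys as ap
from artiphys.invariance import SWEEP_CENTERS


def mat(values, positions=None):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(values.shape[1])
    return ap.ResponseMatrix(values, positions)


class TestPositionCorrelation:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        prof = ap.position_correlation(mat(np.column_stack([col] * 4)))
        assert np.allclose(prof.corr_value, 1.0)

    def test_sign_flipped_column_gives_minus_one(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        prof = ap.position_correlation(mat(np.column_stack([col, -col])),
                                       reference=0)
        assert prof.corr_value[1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((362, 5))
        prof = ap.position_correlation(mat(v), reference=2)
        off = np.delete(prof.corr_value, 2)
        assert np.all(np.abs(off) < 0.15)
        assert prof.corr_value[2] == 1.0

    def test_constant_offref_column_is_nan(self):
        col = np.array([1.0, 2.0, 5.0])
        v = np.column_stack([col, np.full(3, 2.0)])
        prof = ap.position_correlation(mat(v), reference=0)
        assert np.isnan(prof.corr_value[1])

    def test_constant_reference_rejected(self):
        v = np.column_stack([np.full(3, 2.0), [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            ap.position_correlation(mat(v), reference=0)


class TestRFProfile:
    def test_examples(self):
        v = np.column_stack([[0.0, 0.0], [3.0, 4.0]])
        prof = ap.rf_profile(mat(v))
        assert prof.rf_value[0] == 0.0
        assert prof.rf_value[1] == pytest.approx(5.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((20, 3))
        a = ap.rf_profile(mat(v)).rf_value
        b = ap.rf_profile(mat(2 * v)).rf_value
        assert np.allclose(b, 2 * a)


class TestTIMetric:
    def test_separable_matrix_gives_one(self):
        T = np.array([0.1, 1.0, 0.4, 2.0, 0.3])
        G = np.array([0.2, 1.0, 0.5])
        assert ap.ti_metric(mat(np.outer(T, G))) == pytest.approx(1.0)

    def test_hand_computed_three_column_case(self):
        # covariances (2, -1, -2), SD products (2, 1, 2) -> TI = -1/5
        v = np.column_stack([[1, 2, 3], [2, 4, 6], [3, 2, 1]])
        assert ap.ti_metric(mat(v)) == pytest.approx(-0.2)

    def test_uncorrelated_columns_near_zero(self):
        rng = np.random.default_rng(1)
        tis = [ap.ti_metric(mat(rng.standard_normal((362, 5))))
               for _ in range(20)]
        assert abs(np.mean(tis)) < 0.05

    def test_estimator_convention_agrees_with_population_oracle(self):
        # TI is invariant to n vs n-1 denominators used consistently
        rng = np.random.default_rng(5)
        v = rng.standard_normal((30, 4))
        vc = v - v.mean(axis=0)
        cov = vc.T @ vc / len(v)          # population estimators
        sd = np.sqrt(np.diag(cov))
        off = ~np.eye(4, dtype=bool)
        oracle = cov[off].sum() / np.outer(sd, sd)[off].sum()
        assert ap.ti_metric(mat(v)) == pytest.approx(oracle, rel=1e-12)

    def test_one_iff_positively_proportional_columns(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        good = np.column_stack([base, 0.5 * base, 2.0 * base])
        assert ap.ti_metric(mat(good)) == pytest.approx(1.0)
        # negative proportionality or distinct tuning must fall below 1
        bad1 = np.column_stack([base, -base])
        bad2 = np.column_stack([base, base[::-1]])
        assert ap.ti_metric(mat(bad1)) < 1.0 - 1e-9
        assert ap.ti_metric(mat(bad2)) < 1.0 - 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 20), st.integers(2, 6))
    def test_bounded_on_random_matrices(self, seed, n_stim, n_pos):
        v = np.random.default_rng(seed).standard_normal((n_stim, n_pos))
        if (v.std(axis=0) == 0).any():
            return
        assert abs(ap.ti_metric(mat(v))) <= 1.0 + 1e-12

    def test_zero_variance_columns_dropped_with_warning(self):
        v = np.column_stack([[1, 2, 3], [2, 4, 6], [5, 5, 5]])
        with pytest.warns(RuntimeWarning):
            ti = ap.ti_metric(mat(v))
        assert ti == pytest.approx(1.0)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            ap.ti_metric(mat(np.ones((5, 1))))


class TestSeparabilityIndex:
    def test_separable_matrix_gives_one(self):
        v = np.outer([1.0, 2.0, 3.0], [0.5, 1.0])
        assert ap.separability_index(mat(v)) == pytest.approx(1.0)

    def test_equal_singular_values_give_reciprocal_rank(self):
        assert ap.separability_index(mat(np.eye(3))) == pytest.approx(1 / 3)

    def test_known_singular_values(self):
        v = np.diag([2.0, 1.0])
        assert ap.separability_index(mat(v)) == pytest.approx(0.8)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ap.separability_index(mat(np.zeros((3, 2))))

    def test_si_overstates_invariance_for_confined_profiles(self, bank):
        """With identical shape tuning plus additive noise, narrowing the RF
        profile collapses TI (weak positions become noise-dominated) while
        the SVD index stays near 1 — the bias TI was designed to avoid."""
        pars = ap.APCParams(0.5, 0.3, 90.0, 45.0)
        T = np.array([ap.apc_predict(pars, s) for s in bank])
        noise = 0.03 * np.random.default_rng(0).standard_normal((len(T), 5))
        broad = mat(np.outer(T, [0.9, 1.0, 1.0, 1.0, 0.9]) + noise)
        narrow = mat(np.outer(T, [0.05, 0.3, 1.0, 0.3, 0.05]) + noise)
        assert ap.ti_metric(narrow) < ap.ti_metric(broad) - 0.3
        assert ap.separability_index(narrow) > 0.99
        assert ap.separability_index(broad) > 0.99


class TestCRF:
    @staticmethod
    def box_unit(lo, hi):
        def unit(img):
            return float(img[:, lo:hi + 1].sum())
        return unit

    def test_saturated_unit_spans_whole_sweep(self, bank):
        rendered = ap.render_bank(bank[:2])
        crf = ap.estimate_crf(lambda im: float(im.sum()), rendered)
        max_w = crf.max_width
        assert crf.extent == (SWEEP_CENTERS[-1] - SWEEP_CENTERS[0]) - max_w + 1
        assert crf.saturated

    def test_box_rf_width_recovered_by_overlap_geometry(self):
        # 40 px box RF (cols 94..133) probed with a single 10 px wide bar:
        # responsive span ~ W + width, extent = span - width + 1 ~ W + 1
        img = np.zeros((227, 227))
        img[100:127, 108:118] = 255.0  # 10 px wide bar centered at col 113
        bar = ap.StimulusImage(img, 255.0, (113, 113), 10)
        crf = ap.estimate_crf(self.box_unit(94, 133), [bar])
        assert not crf.saturated
        assert abs(crf.extent - 41) <= 2

    def test_unresponsive_unit_excluded(self, bank):
        rendered = ap.render_bank([bank[1]])
        crf = ap.estimate_crf(lambda im: 0.0, rendered)
        assert crf.extent == 0.0 and not crf.eligible

    def test_narrow_rf_not_eligible(self, bank):
        rendered = ap.render_bank([bank[1]])
        crf = ap.estimate_crf(self.box_unit(110, 116), rendered)
        assert not crf.eligible


class TestTIWindow:
    def test_interval_shrinks_by_half_width(self):
        centers = np.arange(64, 165, 2)
        m = mat(np.random.default_rng(0).standard_normal((10, len(centers))),
                positions=centers)
        win = ap.ti_window(m, (90.0, 140.0), stimulus_width=32)
        assert win.positions.min() >= 106 and win.positions.max() <= 124
        assert win.n_positions == len([c for c in centers if 106 <= c <= 124])

    def test_crf_narrower_than_stimulus_gives_empty_window(self):
        centers = np.arange(64, 165, 2)
        m = mat(np.ones((5, len(centers))), positions=centers)
        win = ap.ti_window(m, (100.0, 110.0), stimulus_width=32)
        assert win.n_positions == 0

    def test_full_span_crf_keeps_all_but_margin(self):
        centers = np.arange(64, 165, 2)
        m = mat(np.ones((5, len(centers))), positions=centers)
        win = ap.ti_window(m, (float(centers[0]), float(centers[-1])),
                           stimulus_width=32)
        assert win.positions.min() == 80 and win.positions.max() == 148
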