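"""Statistical kernel: oracle checks and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from somshunt import stats


# ---------------------------------------------------------------------------
# Nadaraya-Watson smoothing
# ---------------------------------------------------------------------------

class TestNwSmooth:
    def test_constant_preserved(self):
        out = stats.nw_smooth([0, 3, 7, 11], [3.7] * 4, 2.5, [0, 5, 10])
        assert np.allclose(out, 3.7)

    def test_symmetry_about_eval_point(self):
        out = stats.nw_smooth([0, 5, 10], [0, 1, 2], 5.0, [5.0])
        assert out[0] == pytest.approx(1.0)

    def test_weighted_sum_oracle(self):
        # direct Gaussian-weight computation at the boundary point
        x = np.array([0.0, 5.0, 10.0])
        y = np.array([0.0, 1.0, 2.0])
        w = np.exp(-0.5 * (x / 5.0) ** 2)
        expected = float(np.sum(w * y) / np.sum(w))
        out = stats.nw_smooth(x, y, 5.0, [0.0])
        assert out[0] == pytest.approx(expected, abs=1e-12)
        assert out[0] == pytest.approx(0.5036, abs=2e-4)

    def test_missing_values_dropped(self):
        out = stats.nw_smooth([0, 5, 10], [1.0, np.nan, 1.0], 5.0, [5.0])
        assert out[0] == pytest.approx(1.0)

    def test_linearity_in_y(self, rng):
        x = rng.uniform(0, 20, 15)
        y1 = rng.standard_normal(15)
        y2 = rng.standard_normal(15)
        ev = np.linspace(0, 20, 7)
        lhs = stats.nw_smooth(x, 2 * y1 + 3 * y2, 4.0, ev)
        rhs = 2 * stats.nw_smooth(x, y1, 4.0, ev) + 3 * stats.nw_smooth(x, y2, 4.0, ev)
        assert np.allclose(lhs, rhs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stats.nw_smooth([], [], 5.0, [0.0])


# ---------------------------------------------------------------------------
# detrending and the calibration fit
# ---------------------------------------------------------------------------

class TestDetrendAndOls:
    def test_exact_line_removed(self):
        t = np.arange(10.0)
        assert np.allclose(stats.linear_detrend(t, 2 + 3 * t), 0.0)

    def test_output_orthogonal_to_time(self, rng):
        t = np.arange(30.0)
        y = np.sin(t / 3) + 0.5 * t + rng.standard_normal(30)
        d = stats.linear_detrend(t, y)
        assert abs(np.corrcoef(t, d)[0, 1]) < 1e-10
        assert abs(d.mean()) < 1e-10

    def test_normal_equations_oracle(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.5, 2.0, 4.0, 3.5])
        X = np.column_stack([np.ones(5), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(stats.linear_detrend(t, y), y - X @ beta)

    def test_constant_time_rejected(self):
        with pytest.raises(ValueError):
            stats.linear_detrend([2.0] * 5, [1, 2, 3, 4, 5])

    def test_ols_recovers_calibration_line(self):
        # the optode/Winkler correspondence line, noiseless
        x = np.linspace(150, 250, 20)
        fit = stats.ols_fit(x, 7.85 + 0.964 * x)
        assert fit.intercept == pytest.approx(7.85)
        assert fit.slope == pytest.approx(0.964)
        assert fit.adj_r_squared == pytest.approx(1.0)

    def test_constant_y_zero_slope(self):
        fit = stats.ols_fit([1, 2, 3, 4], [5.0] * 4)
        assert fit.slope == pytest.approx(0.0)

    def test_outlier_studentized_residual(self):
        x = np.arange(6.0)
        y = x.copy()
        y[3] += 50.0
        fit = stats.ols_fit(x, y)
        # independent hand computation: e / (s * sqrt(1 - h))
        X = np.column_stack([np.ones(6), x])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        e = y - H @ y
        s2 = (e @ e) / (6 - 2)
        stud = e / np.sqrt(s2 * (1 - np.diag(H)))
        assert np.allclose(fit.standardized_residuals, stud)
        assert abs(fit.standardized_residuals[3]) >= 1.5
        assert np.argmax(np.abs(fit.standardized_residuals)) == 3

    def test_studentized_residuals_unit_scale(self, rng):
        x = rng.uniform(0, 10, 50)
        fit = stats.ols_fit(x, 2 + x + rng.standard_normal(50))
        assert fit.standardized_residuals.std() == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# seasonal sinusoid
# ---------------------------------------------------------------------------

class TestSinusoidFit:
    def test_recovers_seasonal_constants(self):
        # noiseless recovery of the documented sub-MLD saturation law
        t = np.linspace(0, 1, 100, endpoint=False)
        y = 102.0 + (-2.993) * np.sin(2 * np.pi * (0.5924 + t))
        fit = stats.nls_sinusoid_fit(t, y)
        assert fit.a == pytest.approx(102.0, abs=1e-6)
        assert fit.b == pytest.approx(-2.993, abs=1e-6)
        assert fit.c == pytest.approx(0.5924, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.993, abs=1e-6)

    def test_constant_series(self):
        fit = stats.nls_sinusoid_fit(np.linspace(0, 1, 12, endpoint=False), [5.0] * 12)
        assert fit.a == pytest.approx(5.0)
        assert abs(fit.b) < 1e-8
        assert not fit.phase_identifiable

    def test_parameterization_equivalence(self):
        # (b, c) and (-b, c+0.5) describe the same curve; output is unique
        t = np.linspace(0, 1, 60, endpoint=False)
        y1 = 10 + 2.0 * np.sin(2 * np.pi * (0.2 + t))
        y2 = 10 + (-2.0) * np.sin(2 * np.pi * (0.7 + t))
        assert np.allclose(y1, y2)
        f1 = stats.nls_sinusoid_fit(t, y1)
        f2 = stats.nls_sinusoid_fit(t, y2)
        assert f1.b == pytest.approx(f2.b)
        assert f1.c == pytest.approx(f2.c)
        assert 0.5 <= f1.c < 1.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(a=st.floats(50, 150), bmag=st.floats(0.5, 10),
           bsign=st.sampled_from([-1.0, 1.0]), c=st.floats(0.505, 0.995))
    def test_noiseless_recovery_property(self, a, bmag, bsign, c):
        t = np.linspace(0, 1, 48, endpoint=False)
        b = bsign * bmag
        y = a + b * np.sin(2 * np.pi * (c + t))
        fit = stats.nls_sinusoid_fit(t, y)
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)

    def test_extrema_half_year_apart(self, rng):
        t = rng.uniform(0, 1, 200)
        y = 100 + 3 * np.sin(2 * np.pi * (0.3 + t)) + 0.5 * rng.standard_normal(200)
        fit = stats.nls_sinusoid_fit(t, y)
        assert fit.phase_identifiable
        assert abs(fit.t_min - fit.t_max) % 1.0 == pytest.approx(0.5, abs=1e-9)
        curve = fit.a + fit.b * np.sin(2 * np.pi * (fit.c + np.array([fit.t_min, fit.t_max])))
        assert curve[1] > curve[0]

    def test_se_calibration(self, rng):
        """Delta-method SEs agree with the empirical spread over replicates."""
        bs, ses = [], []
        for _ in range(150):
            t = rng.uniform(0, 1, 400)
            y = 102.0 - 2.993 * np.sin(2 * np.pi * (0.5924 + t)) \
                + 1.5 * rng.standard_normal(400)
            f = stats.nls_sinusoid_fit(t, y)
            bs.append(f.b)
            ses.append(f.se_b)
        assert np.mean(bs) == pytest.approx(-2.993, abs=0.06)
        assert np.std(bs) == pytest.approx(np.mean(ses), rel=0.25)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            stats.nls_sinusoid_fit([0.1, 0.5, 0.9], [1, 2, 3])


# ---------------------------------------------------------------------------
# rank tests and multiplicity
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = stats.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_rank_oracle(self):
        # ranks 1..6, rank sums 6 and 15:
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
        h, _ = stats.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27.0 / 7.0)

    def test_all_identical_defined(self):
        h, p = stats.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_monotone_invariance(self, rng):
        groups = [rng.standard_normal(8), rng.standard_normal(6) + 1]
        h1, p1 = stats.kruskal_wallis(groups)
        h2, p2 = stats.kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis([[1, 2], []])


class TestDunn:
    def test_identical_groups(self):
        gc = stats.dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert gc.pairs[0].dunn_z == pytest.approx(0.0)
        assert gc.pairs[0].dunn_p_raw == pytest.approx(1.0)

    def test_hand_rank_oracle(self):
        # three separated triples: mean ranks 2, 5, 8; no ties, so the
        # pair variance is N(N+1)/12 * (1/3 + 1/3) = 5
        gc = stats.dunn_posthoc([[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        z = {(p.group_i, p.group_j): p.dunn_z for p in gc.pairs}
        assert z[(0, 1)] == pytest.approx(-3 / np.sqrt(5))
        assert z[(0, 2)] == pytest.approx(-6 / np.sqrt(5))
        assert z[(1, 2)] == pytest.approx(-3 / np.sqrt(5))

    def test_sign_antisymmetry(self, rng):
        a, b = rng.standard_normal(7), rng.standard_normal(9) + 0.5
        z_ab = stats.dunn_posthoc([a, b]).pairs[0].dunn_z
        z_ba = stats.dunn_posthoc([b, a]).pairs[0].dunn_z
        assert z_ab == pytest.approx(-z_ba)

    def test_adjusted_at_least_raw(self, rng):
        groups = [rng.standard_normal(6) + d for d in (0, 0.5, 1.0, 2.0)]
        gc = stats.dunn_posthoc(groups)
        for p in gc.pairs:
            assert p.dunn_p_adj >= p.dunn_p_raw - 1e-12


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_oracle(self):
        adj = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert np.allclose(stats.bh_adjust(p)[perm], stats.bh_adjust(p[perm]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_reference_and_rejection_sets(self, ps):
        p = np.array(ps)
        adj = stats.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref)
        assert (adj >= p - 1e-12).all()
        for q in (0.05, 0.1, 0.2):
            # classical step-up rule
            order = np.argsort(p)
            k = 0
            for i, idx in enumerate(order, start=1):
                if p[idx] <= q * i / len(p):
                    k = i
            classical = np.zeros(len(p), bool)
            classical[order[:k]] = True
            assert ((adj <= q) == classical).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# major axis regression
# ---------------------------------------------------------------------------

class TestMajorAxis:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        fit = stats.major_axis_fit(x, 2 * x, n_perm=99, seed=0)
        assert fit.slope == pytest.approx(2.0)

    def test_reciprocal_symmetry(self, rng):
        x = rng.uniform(0, 1, 20)
        y = 1.5 * x + 0.1 * rng.standard_normal(20)
        m_xy = stats.major_axis_fit(x, y, n_perm=9, seed=0).slope
        m_yx = stats.major_axis_fit(y, x, n_perm=9, seed=0).slope
        assert m_xy == pytest.approx(1.0 / m_yx)

    def test_eigenvector_oracle(self):
        # independent route: principal eigenvector of the covariance matrix
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 2.0, 3.9, 6.1])
        cov = np.cov(np.vstack([x, y]))
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        assert stats.major_axis_fit(x, y, n_perm=9, seed=0).slope == \
            pytest.approx(v[1] / v[0])

    def test_slope_sign_and_collinear_limit(self, rng):
        x = rng.uniform(0, 1, 30)
        y = -2 * x + 0.05 * rng.standard_normal(30)
        fit = stats.major_axis_fit(x, y, n_perm=9, seed=0)
        assert np.sign(fit.slope) == np.sign(np.cov(x, y)[0, 1])
        x2 = np.array([0.0, 1, 2, 3, 4])
        fit2 = stats.major_axis_fit(x2, 3 * x2 + 1, n_perm=9, seed=0)
        assert fit2.slope == pytest.approx(np.polyfit(x2, 3 * x2 + 1, 1)[0])

    def test_perm_p_bounds_and_reproducibility(self, rng):
        x = rng.uniform(0, 1, 12)
        y = 2 * x + 0.2 * rng.standard_normal(12)
        f1 = stats.major_axis_fit(x, y, n_perm=500, seed=42)
        f2 = stats.major_axis_fit(x, y, n_perm=500, seed=42)
        assert f1.perm_p == f2.perm_p
        assert 1 / 501 <= f1.perm_p <= 1
        assert f1.perm_p < 0.05

    def test_zero_covariance_flagged(self):
        fit = stats.major_axis_fit([-1, 0, 1], [1.0, 1.0, 1.0], n_perm=9, seed=0)
        assert not fit.slope_defined
        assert fit.perm_p == 1.0


# ---------------------------------------------------------------------------
# umbrella rhythm test
# ---------------------------------------------------------------------------

class TestRhythm:
    def _sinusoid(self, rng, amp=1.0, noise=0.3, days=6, peak_hour=12.0):
        t = np.arange(0, days * 24.0, 4.0)
        y = amp * np.cos(2 * np.pi * (t - peak_hour) / 24.0) \
            + noise * rng.standard_normal(t.size)
        return t, y

    def test_detects_planted_cycle(self, rng):
        t, y = self._sinusoid(rng)
        res = stats.rank_rhythm_test(t, y)
        assert res.p_value < 0.01
        assert res.best_peak_phase == 3  # 12:00 is phase class 12/4 = 3

    def test_permutation_null_oracle_confirms(self, rng):
        """The analytic p agrees with a direct permutation null."""
        t, y = self._sinusoid(rng)
        obs = stats.rank_rhythm_test(t, y)

        def min_p(yy):
            return stats.rank_rhythm_test(t, yy).p_value

        count = 0
        yp = y.copy()
        for _ in range(500):
            rng.shuffle(yp)
            if min_p(yp) <= obs.p_value:
                count += 1
        assert (1 + count) / 501 < 0.01

    def test_null_uniformity(self, rng):
        t = np.arange(0, 144.0, 4.0)
        ps = [stats.rank_rhythm_test(t, rng.standard_normal(t.size)).p_value
              for _ in range(300)]
        assert np.mean(np.array(ps) <= 0.05) <= 0.05 + 0.03

    def test_monotone_invariance(self, rng):
        t, y = self._sinusoid(rng)
        r1 = stats.rank_rhythm_test(t, y)
        r2 = stats.rank_rhythm_test(t, np.exp(y))
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.best_peak_phase == r2.best_peak_phase

    def test_preconditions(self):
        t = np.arange(0, 144.0, 4.0)
        with pytest.raises(ValueError):
            stats.rank_rhythm_test(t, np.zeros(t.size), period_hours=22.0)
        with pytest.raises(ValueError):
            stats.rank_rhythm_test(t[:8], np.zeros(8))

    def test_constant_series_not_significant(self):
        t = np.arange(0, 144.0, 4.0)
        res = stats.rank_rhythm_test(t, np.ones(t.size))
        assert res.p_value == 1.0
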