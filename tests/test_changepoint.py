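"""Penalised segmentation: costs, PELT vs brute force, CROPS, knee."""

import numpy as np
import pytest

import vistrack as vt
from vistrack.changepoint import _Prefix


def random_piecewise(rng, n_max=20, k_max=3, sd=1.0):
    n = int(rng.integers(6, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False)) if k > 1 else []
    lengths = np.diff([0, *cuts, n])
    means = rng.normal(0, 3, k)
    y = np.repeat(means, lengths) + rng.normal(0, sd, n)
    return y


class TestSegmentCost:
    def test_constant_segment_is_free(self):
        assert vt.segment_cost(np.full(10, 4.2), 0, 9) == pytest.approx(0.0)

    def test_two_point_segment_hand_value(self):
        # values {0, 10}: mean 5, squared deviations 25 + 25
        assert vt.segment_cost(np.array([0.0, 10.0]), 0, 1) == pytest.approx(50.0)

    def test_matches_naive_two_pass(self, rng):
        y = rng.normal(0, 5, 40)
        for _ in range(25):
            i = int(rng.integers(0, 39))
            j = int(rng.integers(i, 40))
            naive = float(((y[i : j + 1] - y[i : j + 1].mean()) ** 2).sum())
            assert vt.segment_cost(y, i, j) == pytest.approx(naive, abs=1e-9)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            vt.segment_cost(np.ones(5), 3, 2)


class TestPelt:
    def test_constant_series_no_changepoints(self):
        seg = vt.pelt_segment(np.full(20, 2.0), beta=1.0)
        assert seg.changepoints == ()
        assert seg.total_cost == pytest.approx(0.0)

    def test_perfect_step(self):
        seg = vt.pelt_segment(np.array([0.0, 0, 0, 10, 10, 10]), beta=0.1)
        assert seg.changepoints == (2,)
        assert seg.total_cost == pytest.approx(0.1)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 5.0])
    def test_matches_exhaustive_oracle(self, rng, beta):
        for _ in range(25):
            y = random_piecewise(rng)
            a = vt.pelt_segment(y, beta)
            b = vt.exhaustive_segment(y, beta)
            assert a.changepoints == b.changepoints
            assert a.total_cost == pytest.approx(b.total_cost, abs=1e-9)

    def test_min_seg_respected(self, rng):
        y = random_piecewise(rng, sd=0.5)
        for min_seg in (2, 3):
            seg = vt.pelt_segment(y, 0.5, min_seg=min_seg)
            bounds = [0, *[c + 1 for c in seg.changepoints], seg.n]
            assert min(np.diff(bounds)) >= min_seg
            orc = vt.exhaustive_segment(y, 0.5, min_seg=min_seg)
            assert seg.total_cost == pytest.approx(orc.total_cost, abs=1e-9)

    def test_total_cost_reevaluates_from_tau(self, rng):
        y = rng.normal(0, 1, 80) + np.repeat([0, 4.0], 40)
        seg = vt.pelt_segment(y, 2.0)
        recomputed = sum(vt.segment_cost(y, a, b - 1) for a, b in seg.segments())
        assert seg.total_cost == pytest.approx(recomputed + 2.0 * seg.m, abs=1e-9)

    def test_shift_invariance(self, rng):
        y = random_piecewise(rng, n_max=18)
        s0 = vt.pelt_segment(y, 1.0)
        s1 = vt.pelt_segment(y + 100.0, 1.0)
        assert s0.changepoints == s1.changepoints

    def test_scale_covariance(self, rng):
        """Scaling the series by c and the penalty by c^2 keeps tau."""
        y = random_piecewise(rng, n_max=18)
        c = 3.7
        s0 = vt.pelt_segment(y, 1.0)
        s1 = vt.pelt_segment(c * y, c**2 * 1.0)
        assert s0.changepoints == s1.changepoints
        assert s1.unpenalised_cost == pytest.approx(c**2 * s0.unpenalised_cost, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            vt.pelt_segment(np.ones(1), 1.0)
        with pytest.raises(ValueError):
            vt.pelt_segment(np.array([1.0, np.nan, 2.0]), 1.0)
        with pytest.raises(ValueError):
            vt.pelt_segment(np.ones(10), -1.0)


class TestExhaustive:
    def test_constant_series(self):
        assert vt.exhaustive_segment(np.ones(8), 1.0).changepoints == ()

    def test_zero_penalty_prefers_fewest_among_zero_cost(self):
        # at beta = 0 every refinement of the true step also costs zero;
        # the declared tie-break picks the fewest changepoints
        y = np.array([0.0, 0, 0, 1, 1, 1])
        seg = vt.exhaustive_segment(y, 0.0)
        assert seg.total_cost == pytest.approx(0.0)
        assert seg.changepoints == (2,)

    def test_refuses_large_n(self):
        with pytest.raises(ValueError):
            vt.exhaustive_segment(np.ones(30), 1.0)


class TestCrops:
    def test_constant_series_flat_path(self):
        path = vt.crops_path(np.full(30, 1.5), 0.01, 100.0)
        assert len(path.intervals) == 1
        assert path.intervals[0][2].m == 0

    def test_step_series_transition_penalty(self):
        y = np.concatenate([np.zeros(10), np.full(10, 10.0)])
        path = vt.crops_path(y, 0.01, 1000.0)
        ms = [seg.m for _, _, seg in path.intervals]
        assert 1 in ms and 0 in ms
        # the m=1 -> m=0 boundary sits at the unpenalised cost difference
        cost_unsplit = vt.segment_cost(y, 0, 19)
        b_at = [b0 for (b0, b1, seg) in path.intervals if seg.m == 0][0]
        assert b_at == pytest.approx(cost_unsplit - 0.0, rel=1e-9)

    def test_grid_agrees_with_path(self, rng):
        y = np.repeat(rng.normal(0, 3, 3), [15, 20, 15]) + rng.normal(0, 1, 50)
        path = vt.crops_path(y, 0.1, 100.0)
        for beta in np.linspace(0.1, 100.0, 60):
            direct = vt.pelt_segment(y, beta)
            via = path.segmentation_at(beta)
            assert direct.changepoints == via.changepoints

    def test_m_nonincreasing_along_path(self, rng):
        y = rng.normal(0, 1, 60)
        path = vt.crops_path(y, 0.05, 50.0)
        ms = [seg.m for _, _, seg in path.intervals]
        assert all(a > b for a, b in zip(ms, ms[1:]))
        # intervals tile the range
        assert path.intervals[0][0] == pytest.approx(0.05)
        assert path.intervals[-1][1] == pytest.approx(50.0)
        for (_, hi, _), (lo, _, _) in zip(path.intervals, path.intervals[1:]):
            assert hi == pytest.approx(lo)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            vt.crops_path(np.ones(10), 5.0, 1.0)


class TestKnee:
    def test_exact_two_line_data_recovered(self):
        beta = np.linspace(0.5, 12, 50)
        m = -2.0 * beta + 1.9 * np.maximum(beta - 5.0, 0) + 40.0
        fit = vt.fit_knee((beta, m))
        assert fit.converged and not fit.degenerate
        assert fit.psi == pytest.approx(5.0, abs=1e-6)
        assert fit.a == pytest.approx(-2.0, abs=1e-6)
        assert fit.b == pytest.approx(1.9, abs=1e-6)
        assert fit.c == pytest.approx(40.0, abs=1e-6)

    def test_pure_line_flagged_degenerate(self):
        beta = np.linspace(0, 10, 30)
        fit = vt.fit_knee((beta, -3.0 * beta + 7.0))
        assert fit.degenerate
        assert fit.b == 0.0

    def test_noisy_recovery_vs_grid_oracle(self, rng):
        def grid_psi(beta, m):
            best, best_sse = None, np.inf
            for psi in np.linspace(beta.min(), beta.max(), 400):
                X = np.column_stack(
                    [np.ones_like(beta), beta, np.maximum(beta - psi, 0)]
                )
                r = m - X @ np.linalg.lstsq(X, m, rcond=None)[0]
                sse = float(r @ r)
                if sse < best_sse:
                    best, best_sse = psi, sse
            return best

        errs, oracle_gap = [], []
        for _ in range(30):
            beta = np.linspace(0.5, 12, 50)
            m = -10.0 * beta + 9.5 * np.maximum(beta - 5.0, 0) + 80.0
            m = m + rng.normal(0, 2.0, m.size)
            fit = vt.fit_knee((beta, m))
            if fit.converged and not fit.degenerate:
                errs.append(abs(fit.psi - 5.0))
                oracle_gap.append(abs(fit.psi - grid_psi(beta, m)))
        assert np.median(errs) <= 0.25
        assert np.median(oracle_gap) <= 0.1

    def test_too_few_support_points_rejected(self):
        with pytest.raises(ValueError):
            vt.fit_knee((np.array([1.0, 2, 3]), np.array([5.0, 4, 3])))


class TestPenaltyChoice:
    @pytest.mark.parametrize(
        "knees,expect",
        [([5.0], 5.0), ([2.0, 4.0, 9.0], 4.0), ([3, 3, 3, 3, 50], 3.0)],
    )
    def test_median_of_knees(self, knees, expect):
        assert vt.choose_penalty(knees) == expect

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vt.choose_penalty([])


class TestPooling:
    def test_no_changepoints_zero_vector(self):
        pooled = vt.pool_changepoints([], 50)
        assert pooled.counts.sum() == 0

    def test_coherent_event_counts(self):
        segs = [vt.pelt_segment(np.repeat([0.0, 9.0], [91, 29]), 1.0) for _ in range(10)]
        pooled = vt.pool_changepoints(segs, 120)
        assert pooled.counts[90] == 10
        assert pooled.total == 10

    def test_count_conservation(self, rng):
        segs = [vt.pelt_segment(random_piecewise(rng, sd=0.3), 0.5) for _ in range(8)]
        pooled = vt.pool_changepoints(segs, 20)
        assert pooled.total == sum(s.m for s in segs)

    def test_out_of_range_rejected(self):
        seg = vt.pelt_segment(np.repeat([0.0, 9.0], [5, 5]), 0.5)
        with pytest.raises(ValueError):
            vt.pool_changepoints([seg], 3)


class TestDefaultBetaRange:
    def test_ordered_and_positive(self, rng):
        y = rng.normal(0, 1, 100)
        lo, hi = vt.default_beta_range(y)
        assert 0 < lo < hi


def test_prefix_cost_nonnegative(rng):
    pre = _Prefix(rng.normal(0, 1, 30))
    for i in range(0, 30, 5):
        for j in range(i + 1, 31, 7):
            assert pre.cost(i, j) >= 0
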