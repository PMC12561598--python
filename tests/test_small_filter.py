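"""Area-profile (small-breasts) filter: segmented fit oracle and indicators."""

import itertools

import numpy as np
import pytest

from scanqc import AreaTrendThresholds, apply_small_tool
from scanqc.geometry import AreaProfile
from scanqc.small_filter import breakpoint_detect, piecewise_fit, steep_decrease_detect

from conftest import circular_stack


def profile(areas, z0=24.5, step=5.0):
    z = z0 + step * np.arange(len(areas))
    return AreaProfile(z=z, area=np.asarray(areas, dtype=float))


def exhaustive_best_sse(z, a, k):
    """Oracle: enumerate every breakpoint placement (segments >= 2 samples)."""
    n = len(z)

    def seg_sse(i, j):
        coef = np.polyfit(z[i : j + 1], a[i : j + 1], 1)
        r = a[i : j + 1] - np.polyval(coef, z[i : j + 1])
        return float(r @ r)

    best = np.inf
    # choose k-1 cut positions; segment s covers cuts[s-1]+1 .. cuts[s]
    for cuts in itertools.combinations(range(1, n - 1), k - 1):
        bounds = [-1, *[c for c in cuts], n - 1]
        if any(bounds[s + 1] - bounds[s] < 2 for s in range(k)):
            continue
        sse = sum(seg_sse(bounds[s] + 1, bounds[s + 1]) for s in range(k))
        best = min(best, sse)
    return best


class TestPiecewiseFit:
    def test_exactly_linear_single_segment(self):
        p = profile(5000.0 - 40.0 * np.arange(10) * 5.0)
        fit = piecewise_fit(p)
        assert len(fit) == 1
        assert fit.sse == pytest.approx(0.0, abs=1e-6)

    def test_planted_two_segment_recovered_exactly(self):
        # flat 6 samples then slope -200 mm²/mm, no noise
        flat = np.full(6, 8000.0)
        dec = 8000.0 - 200.0 * 5.0 * np.arange(1, 7)
        p = profile(np.concatenate([flat, dec]))
        fit = piecewise_fit(p)
        assert len(fit) == 2
        assert fit.sse == pytest.approx(0.0, abs=1e-6)
        # the boundary sample lies on both lines, so either side of the tie
        # is an exact optimum
        assert fit.segments[0].i_end in (4, 5)
        assert fit.segments[0].slope == pytest.approx(0.0, abs=1e-9)
        assert fit.segments[1].slope == pytest.approx(-200.0, rel=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_fixed_k_matches_exhaustive_enumeration(self, k):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(8, 15))
            a = 6000.0 + rng.normal(0, 400.0, n).cumsum()
            z = 24.5 + 5.0 * np.arange(n)
            p = AreaProfile(z=z, area=np.abs(a) + 100.0)
            fit = piecewise_fit(p, n_segments=k)
            assert len(fit) == k
            assert fit.sse == pytest.approx(exhaustive_best_sse(p.z, p.area, k), rel=1e-9, abs=1e-9)

    def test_forced_k_with_too_few_samples_rejected(self):
        p = profile([100.0, 90.0, 80.0, 70.0, 60.0])
        with pytest.raises(ValueError):
            piecewise_fit(p, n_segments=3)

    def test_noisy_breakpoint_within_one_sample(self):
        # planted boundary after sample 7; sigma = 1% of max area
        rng = np.random.default_rng(7)
        hits = 0
        reps = 200
        for _ in range(reps):
            flat = np.full(8, 9000.0)
            dec = 9000.0 - 200.0 * 5.0 * np.arange(1, 9)
            a = np.concatenate([flat, dec]) + rng.normal(0, 90.0, 16)
            fit = piecewise_fit(profile(a), n_segments=2)
            if abs(fit.segments[0].i_end - 7) <= 1:
                hits += 1
        assert hits / reps >= 0.95

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            piecewise_fit(profile([100.0, 90.0, 80.0]))

    def test_segments_partition_samples(self):
        rng = np.random.default_rng(3)
        p = profile(np.abs(rng.normal(5000, 500, 20)) + 100)
        fit = piecewise_fit(p)
        idx = [(s.i_start, s.i_end) for s in fit.segments]
        assert idx[0][0] == 0 and idx[-1][1] == len(p) - 1
        for (a0, a1), (b0, b1) in zip(idx, idx[1:]):
            assert b0 == a1 + 1
        assert all(s.i_end - s.i_start >= 1 for s in fit.segments)


class TestSteepDecrease:
    def test_single_big_drop(self):
        # 40% drop between slices 2 and 3
        p = profile([8000, 7800, 7600, 4560, 4400, 4300, 4200])
        d = steep_decrease_detect(p)
        assert d.triggered and d.criterion == "area-steep-decrease"
        assert d.z_cut == pytest.approx(39.5)
        assert d.delta_height == pytest.approx(15.0)

    def test_smooth_profile_not_triggered(self):
        areas = 8000.0 * np.cos(np.linspace(0.0, 1.4, 25)) ** 1.4
        assert not steep_decrease_detect(profile(areas)).triggered

    def test_monotone_increasing_not_triggered(self):
        assert not steep_decrease_detect(profile(np.linspace(4000, 9000, 12))).triggered

    def test_drop_below_window_ignored(self):
        areas = [8000.0] * 8 + [4000.0] + [3900.0] * 4  # drop at 35+ mm below top
        assert not steep_decrease_detect(profile(areas)).triggered

    def test_contiguous_run_cut_at_deepest_pair(self):
        p = profile([9000, 6000, 3900, 3800, 3700, 3600])
        d = steep_decrease_detect(p)
        assert d.z_cut == pytest.approx(34.5)  # two consecutive steep pairs

    @pytest.mark.parametrize("r1,r2", [(0.1, 0.25), (0.25, 0.45)])
    def test_delta_monotone_decreasing_in_r_steep(self, r1, r2):
        p = profile([9000, 7000, 5000, 4000, 3800, 3700, 3600])
        d1 = steep_decrease_detect(p, AreaTrendThresholds(r_steep=r1))
        d2 = steep_decrease_detect(p, AreaTrendThresholds(r_steep=r2))
        assert d2.delta_height <= d1.delta_height


class TestBreakpoint:
    def test_flat_plateau_then_decrease(self):
        # flat plateau spanning ~14 mm, then a steady decrease
        plateau = np.full(4, 7000.0)  # samples at 24.5..39.5 with step 5
        dec = 7000.0 - 200.0 * 5.0 * np.arange(1, 7)
        p = profile(np.concatenate([plateau, dec]))
        fit = piecewise_fit(p)
        d = breakpoint_detect(p, fit)
        assert d.triggered and d.criterion == "area-breakpoint"
        assert d.delta_height == pytest.approx(15.0, abs=5.0)

    def test_monotone_decreasing_not_triggered(self):
        p = profile(np.linspace(9000, 2000, 15))
        d = breakpoint_detect(p, piecewise_fit(p))
        assert not d.triggered

    def test_flat_then_flat_not_triggered(self):
        a = np.concatenate([np.full(6, 7000.0), np.full(6, 6950.0)])
        p = profile(a)
        d = breakpoint_detect(p, piecewise_fit(p))
        assert not d.triggered

    def test_short_decrease_not_triggered(self):
        thr = AreaTrendThresholds(l_dec_min=30.0)
        plateau = np.full(5, 7000.0)
        dec = 7000.0 - 300.0 * 5.0 * np.arange(1, 4)
        p = profile(np.concatenate([plateau, dec]))
        d = breakpoint_detect(p, piecewise_fit(p), thr)
        assert not d.triggered


class TestApplySmallTool:
    def _stack(self, radii):
        return circular_stack({24.5 + 5.0 * i: r for i, r in enumerate(radii)})

    def test_abrupt_drop_routes_to_steep_decrease(self):
        radii = [50, 50, 38, 37, 36, 35, 33, 30, 26, 20, 12]
        d = apply_small_tool(self._stack(radii))
        assert d.criterion == "area-steep-decrease"
        assert d.delta_height == pytest.approx(10.0, abs=5.0)

    def test_plateau_routes_to_breakpoint(self):
        # no adjacent drop over 20%, but a flat top then a consistent decrease
        radii = [50, 50, 50, 46, 42, 38, 34, 30, 26, 22, 18, 14, 10]
        d = apply_small_tool(self._stack(radii))
        assert d.criterion == "area-breakpoint"

    def test_artifact_free_not_triggered(self):
        radii = 45.0 * np.cos(np.linspace(0.0, 1.45, 20)) ** 0.7
        d = apply_small_tool(self._stack([r for r in radii if r > 2]))
        assert not d.triggered

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            apply_small_tool(self._stack([50, 40, 30]))

    def test_delta_never_exceeds_extent(self):
        radii = [60, 40, 30, 22, 18, 14, 10, 8]
        stack = self._stack(radii)
        d = apply_small_tool(stack)
        assert 0.0 <= d.delta_height <= stack.extent
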