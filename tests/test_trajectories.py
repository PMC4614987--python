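"""Growth analytics on the published ammonite/Nautilus series and synthetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phragmovol.trajectories import (
    covariation_index,
    cumulative,
    detect_countdown,
    find_breakpoint,
    fit_logistic,
    largest_drop,
)

from conftest import make_series


class TestCumulative:
    def test_first_two_nm1_chambers(self, nm1):
        cum = cumulative(nm1)
        assert cum[25] == pytest.approx(0.9)
        assert cum[26] == pytest.approx(0.9 + 1.3)

    def test_total_is_sum_of_present(self, nm1):
        assert cumulative(nm1).iloc[-1] == pytest.approx(np.nansum(nm1.volumes))

    def test_nm1_total_exceeds_nm2_total(self, nm1, nm2):
        assert cumulative(nm1).iloc[-1] > cumulative(nm2).iloc[-1]

    def test_missing_chambers_skipped_with_warning(self):
        s = make_series([1, 2, 3], [1.0, np.nan, 2.0])
        with pytest.warns(UserWarning, match="missing"):
            cum = cumulative(s)
        assert list(cum.index) == [1, 3]
        assert cum.iloc[-1] == pytest.approx(3.0)

    def test_all_missing_rejected(self):
        s = make_series([1, 2], [np.nan, np.nan])
        with pytest.raises(ValueError):
            cumulative(s)


class TestFindBreakpoint:
    def test_exact_two_segment_recovery(self):
        # noiseless piecewise-log-linear data: zero-residual construction
        x = np.arange(1, 16)
        y = np.where(x <= 6, 2.0 + 1.5 * x, 2.0 + 1.5 * 6 + 0.3 * (x - 6))
        s = make_series(x, np.exp(y))
        bp = find_breakpoint(s)
        assert bp.knot == 6 and bp.breakpoint == 7
        assert bp.found
        assert bp.rss_two_segment < 1e-20

    def test_single_slope_line_not_found(self):
        x = np.arange(1, 16)
        s = make_series(x, np.exp(0.8 + 0.4 * x))
        bp = find_breakpoint(s)
        assert not bp.found

    def test_nm1_breakpoint_in_28_29(self, nm1):
        onset = detect_countdown(nm1).onset
        bp = find_breakpoint(nm1, fit_range=(int(nm1.chambers[0]), onset - 1))
        assert bp.breakpoint in (28, 29)

    def test_nautilus_early_breakpoints_within_4_9(self, nautilus_series):
        hits = {
            sid: find_breakpoint(s, fit_range=(1, 15)).breakpoint
            for sid, s in nautilus_series.items()
        }
        outside = {sid: b for sid, b in hits.items() if not 4 <= b <= 9}
        assert not outside, outside

    def test_matches_closed_form_segment_oracle(self):
        # brute force: per-candidate hinge fits via explicit normal equations
        rng = np.random.default_rng(42)
        x = np.arange(1.0, 21.0)
        y = np.where(x <= 9, 0.1 + 0.9 * x, 0.1 + 0.9 * 9 + 0.2 * (x - 9))
        y = y + 0.05 * rng.standard_normal(len(x))
        s = make_series(x.astype(int), np.exp(y))
        bp = find_breakpoint(s)

        def hinge_rss(c):
            X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)

        cands = [c for c in x if (x <= c).sum() >= 3 and (x > c).sum() >= 3]
        oracle = {c: hinge_rss(c) for c in cands}
        best = min(oracle, key=oracle.get)
        assert bp.knot == int(best)
        assert bp.rss_two_segment == pytest.approx(oracle[best], abs=1e-10)

    def test_too_few_points_rejected(self):
        s = make_series([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="at least"):
            find_breakpoint(s)


class TestDetectCountdown:
    def test_nm1_onset_56_length_5(self, nm1):
        cd = detect_countdown(nm1)
        assert (cd.onset, cd.length, cd.found) == (56, 5, True)

    def test_nm2_onset_53_length_7(self, nm2):
        cd = detect_countdown(nm2)
        assert (cd.onset, cd.length, cd.found) == (53, 7, True)

    def test_strictly_increasing_series_not_found(self):
        s = make_series(np.arange(1, 11), np.arange(1.0, 11.0))
        cd = detect_countdown(s)
        assert not cd.found and cd.length == 0

    def test_ties_break_to_earliest_chamber(self):
        v = [1.0, 5.0, 5.0, 5.0, 5.0, 5.0, 2.0]
        cd = detect_countdown(make_series(np.arange(1, 8), v))
        assert cd.onset == 3  # first centre of the tied maximal windows

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, nm2, scale):
        scaled = make_series(nm2.chambers, nm2.volumes * scale, unit="mm3")
        cd0, cd1 = detect_countdown(nm2), detect_countdown(scaled)
        assert (cd0.onset, cd0.length, cd0.found) == (cd1.onset, cd1.length, cd1.found)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_countdown(make_series([1, 2, 3], [1, 2, 3]))


class TestLargestDrop:
    def test_nm2_drop_at_45(self, nm2):
        drop = largest_drop(nm2)
        assert drop.chamber == 45
        assert drop.fraction == pytest.approx((78.6 - 54.0) / 78.6)

    def test_toy_series(self):
        drop = largest_drop(make_series([1, 2, 3], [10.0, 5.0, 20.0]))
        assert drop.chamber == 2 and drop.fraction == pytest.approx(0.5)

    def test_monotone_series_has_no_drop(self):
        assert largest_drop(make_series([1, 2, 3], [1.0, 2.0, 3.0])) is None

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, nm2, scale):
        scaled = make_series(nm2.chambers, nm2.volumes * scale, unit="mm3")
        a, b = largest_drop(nm2), largest_drop(scaled)
        assert a.chamber == b.chamber
        assert a.fraction == pytest.approx(b.fraction)

    def test_nonconsecutive_chambers_ignored(self):
        # the decrease 9 -> 2 spans a gap and must not count
        s = make_series([1, 2, 4, 5], [5.0, 9.0, 2.0, 1.0])
        assert largest_drop(s).chamber == 5


class TestFitLogistic:
    def test_noiseless_recovery(self):
        x = np.arange(1, 31)
        v = 20.0 / (1.0 + np.exp(-0.3 * (x - 15.0)))
        fit = fit_logistic(make_series(x, v))
        assert fit.K == pytest.approx(20.0, rel=1e-6)
        assert fit.r == pytest.approx(0.3, rel=1e-6)
        assert fit.m == pytest.approx(15.0, rel=1e-6)
        assert fit.rss < 1e-10 * 20.0**2

    def test_reindexing_shifts_midpoint_only(self):
        x = np.arange(1, 31)
        rng = np.random.default_rng(5)
        v = 20.0 / (1.0 + np.exp(-0.3 * (x - 15.0))) * np.exp(
            0.05 * rng.standard_normal(len(x))
        )
        fit0 = fit_logistic(make_series(x, v))
        fit1 = fit_logistic(make_series(x + 7, v))
        assert fit1.K == pytest.approx(fit0.K, rel=1e-6)
        assert fit1.r == pytest.approx(fit0.r, rel=1e-6)
        assert fit1.m == pytest.approx(fit0.m + 7, rel=1e-6)
        assert fit1.rss == pytest.approx(fit0.rss, rel=1e-6)

    def test_median_bias_of_K_under_lognormal_noise(self):
        # 200 seeded replicates at sigma 0.15, n = 30
        from phragmovol.synth import SeriesParams, simulate_series

        true_K = 20.0
        rel_errors = []
        for seed in range(200):
            p = SeriesParams(
                K=true_K, r=0.3, m=15.0, embryo_break=0, countdown_k=0,
                noise_sigma=0.15, n_chambers=30, seed=seed,
            )
            fit = fit_logistic(simulate_series(p))
            rel_errors.append((fit.K - true_K) / true_K)
        assert abs(np.median(rel_errors)) < 0.05

    def test_log_scale_option(self):
        x = np.arange(1, 31)
        v = 20.0 / (1.0 + np.exp(-0.3 * (x - 15.0)))
        fit = fit_logistic(make_series(x, v), scale="log")
        assert fit.K == pytest.approx(20.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(make_series([1, 2, 3], [1.0, 2.0, 3.0]))


class TestCovariationIndex:
    def test_identical_series_gives_unit_correlation(self):
        x = np.arange(1, 11)
        v = np.exp(0.3 * x)
        r = covariation_index(make_series(x, v, widths=v))
        assert r == pytest.approx(1.0)

    def test_constant_widths_undefined(self):
        x = np.arange(1, 11)
        r = covariation_index(make_series(x, np.exp(0.3 * x), widths=np.full(10, 2.0)))
        assert r is None

    def test_ammonite_covaries_more_than_nautilus(self, nm1):
        from phragmovol.fixtures import load_series

        r_ammonite = covariation_index(nm1)
        r_nautilus = covariation_index(load_series("7"))
        assert r_ammonite > r_nautilus

    def test_too_few_complete_chambers_rejected(self):
        s = make_series([1, 2, 3, 4], [1, 2, 3, 4], widths=[1, 2, 3, 4])
        with pytest.raises(ValueError):
            covariation_index(s)
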