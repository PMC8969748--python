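import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hafit.ha_sim import TimeConstants
from hafit.objective import OracleScorer, ScoreResult
from hafit.optimizer import (
    SearchSpec,
    accept,
    run_search,
    run_thread,
    sample_candidate,
    shrink_range,
)


def small_spec(**kw) -> SearchSpec:
    defaults = dict(n_iterations=100, n_threads=1, seeds=(7,), n_channels=1)
    defaults.update(kw)
    return SearchSpec(**defaults)


class TestSearchSpec:
    def test_defaults(self):
        spec = SearchSpec()
        assert spec.at_bounds_ms == (10.0, 500.0)
        assert spec.rt_bounds_ms == (300.0, 2000.0)
        assert spec.stepsize_ms == 10.0
        assert spec.n_iterations == 1000
        assert spec.n_threads == 4

    def test_seed_count_mismatch(self):
        with pytest.raises(ValueError, match="one seed per thread"):
            SearchSpec(n_threads=2, seeds=(1,))

    def test_indivisible_range(self):
        with pytest.raises(ValueError, match="divisible"):
            SearchSpec(at_bounds_ms=(10.0, 505.0))

    def test_bad_bounds(self):
        with pytest.raises(ValueError, match="lower < upper"):
            SearchSpec(at_bounds_ms=(500.0, 10.0))


class TestShrinkRange:
    def test_printed_decrement(self):
        # width 490, step 10, N=1000: decrement (490-20)/1000 = 0.47
        assert shrink_range(490.0, 490.0, 10.0, 1000) == pytest.approx(489.53)

    def test_fixed_point_at_two_steps(self):
        assert shrink_range(20.0, 20.0, 10.0, 1000) == pytest.approx(20.0)

    @pytest.mark.parametrize("initial,step,n", [(490.0, 10.0, 1000), (1700.0, 10.0, 1000),
                                                (490.0, 10.0, 200), (1700.0, 50.0, 17)])
    def test_telescoping_to_two_steps(self, initial, step, n):
        width = initial
        for _ in range(n):
            width = shrink_range(width, initial, step, n)
        assert width == pytest.approx(2 * step, abs=1e-9)

    @given(i=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_closed_form_width(self, i):
        initial, step, n = 490.0, 10.0, 1000
        width = initial
        for _ in range(i):
            width = shrink_range(width, initial, step, n)
        expected = initial - i * (initial - 2 * step) / n
        assert width == pytest.approx(expected, abs=1e-9)


class TestSampleCandidate:
    def test_values_on_grid_within_bounds(self):
        spec = SearchSpec(n_channels=5)
        rng = np.random.default_rng(0)
        baseline = TimeConstants((250.0,) * 5, (1150.0,) * 5)
        for _ in range(200):
            tc = sample_candidate(baseline, 490.0, 1700.0, spec, rng)
            for v in tc.attack_ms:
                assert 10.0 <= v <= 500.0 and v % 10 == 0
            for v in tc.release_ms:
                assert 300.0 <= v <= 2000.0 and v % 10 == 0

    def test_minimal_range_neighbourhood(self):
        spec = small_spec()
        rng = np.random.default_rng(1)
        baseline = TimeConstants((250.0,), (1000.0,))
        seen = set()
        for _ in range(300):
            tc = sample_candidate(baseline, 20.0, 20.0, spec, rng)
            seen.add(tc.attack_ms[0])
            assert tc.attack_ms[0] in (240.0, 250.0, 260.0)
            assert tc.release_ms[0] in (990.0, 1000.0, 1010.0)
        assert seen == {240.0, 250.0, 260.0}

    def test_boundary_baseline_intersection(self):
        spec = small_spec()
        rng = np.random.default_rng(2)
        baseline = TimeConstants((10.0,), (2000.0,))
        for _ in range(200):
            tc = sample_candidate(baseline, 20.0, 20.0, spec, rng)
            assert tc.attack_ms[0] in (10.0, 20.0)
            assert tc.release_ms[0] in (1990.0, 2000.0)

    def test_full_range_uniformity_chi_square(self):
        # chi-square over the attack grid at full range
        spec = small_spec()
        rng = np.random.default_rng(3)
        baseline = TimeConstants((250.0,), (1150.0,))
        n_draws = 10000
        counts = {}
        for _ in range(n_draws):
            tc = sample_candidate(baseline, 480.0, 1700.0, spec, rng)
            counts[tc.attack_ms[0]] = counts.get(tc.attack_ms[0], 0) + 1
        k = 49  # grid points in [10, 490]
        assert len(counts) == k
        expected = n_draws / k
        chi2 = sum((c - expected) ** 2 / expected for c in counts.values())
        # 3-sigma-ish bound for chi-square with k-1=48 dof: mean 48, sd sqrt(96)
        assert chi2 < 48 + 4 * np.sqrt(96)


class TestAccept:
    def test_higher_score_wins(self):
        assert accept(ScoreResult(92.0, -5.0), ScoreResult(88.0, -4.0))

    def test_tie_broken_by_loglik(self):
        assert accept(ScoreResult(88.0, -3.0), ScoreResult(88.0, -4.0))

    def test_exact_tie_keeps_incumbent(self):
        assert not accept(ScoreResult(88.0, -4.0), ScoreResult(88.0, -4.0))

    def test_lower_score_rejected_despite_loglik(self):
        assert not accept(ScoreResult(87.0, 0.0), ScoreResult(88.0, -4.0))


class TestRunThread:
    def test_trace_monotone_incumbent(self):
        oracle = OracleScorer(TimeConstants((200.0,), (1200.0,)))
        for seed in range(5):
            res = run_thread(small_spec(), oracle.score_for, seed)
            best = -np.inf
            for rec in res.trace:
                if rec.accepted:
                    assert rec.score_pct >= best
                    best = rec.score_pct

    def test_trace_length_and_grid(self):
        oracle = OracleScorer(TimeConstants((200.0,), (1200.0,)))
        res = run_thread(small_spec(n_iterations=150), oracle.score_for, 3)
        assert len(res.trace) == 150
        for rec in res.trace:
            assert rec.tc.attack_ms[0] % 10 == 0
            assert 10 <= rec.tc.attack_ms[0] <= 500
            assert 300 <= rec.tc.release_ms[0] <= 2000

    def test_deterministic_traces(self):
        oracle = OracleScorer(TimeConstants((200.0,), (1200.0,)))
        a = run_thread(small_spec(), oracle.score_for, 11)
        b = run_thread(small_spec(), oracle.score_for, 11)
        assert a == b

    def test_width_schedule_in_trace(self):
        spec = small_spec(n_iterations=50)
        oracle = OracleScorer(TimeConstants((200.0,), (1200.0,)))
        res = run_thread(spec, oracle.score_for, 0)
        n = spec.n_iterations
        for rec in res.trace:
            i = rec.iteration - 1  # widths recorded before the i-th shrink
            expected_at = 490.0 - i * (490.0 - 20.0) / n
            expected_rt = 1700.0 - i * (1700.0 - 20.0) / n
            assert rec.width_at_ms == pytest.approx(expected_at, abs=1e-9)
            assert rec.width_rt_ms == pytest.approx(expected_rt, abs=1e-9)

    def test_scorer_failure_preserves_trace(self):
        calls = {"n": 0}

        def flaky(tc):
            calls["n"] += 1
            if calls["n"] > 3:
                raise RuntimeError("scorer died")
            return ScoreResult(50.0, -1.0)

        with pytest.raises(RuntimeError) as excinfo:
            run_thread(small_spec(), flaky, 0)
        assert len(excinfo.value.partial_trace) == 3

    def test_oracle_recovery(self):
        # certified unique grid peak; RS with 200 iterations must land nearby
        peak = TimeConstants((140.0,), (980.0,))
        oracle = OracleScorer(peak, w_at=10.0, w_rt=100.0)
        hits = 0
        for seed in range(20):
            res = run_thread(small_spec(n_iterations=200, seeds=(seed,)),
                             oracle.score_for, seed)
            if (abs(res.best_tc.attack_ms[0] - 140.0) <= 20.0
                    and abs(res.best_tc.release_ms[0] - 980.0) <= 50.0):
                hits += 1
        assert hits >= 18


class TestRunSearch:
    def test_best_of_threads_tie_break(self):
        # scripted scorer: thread results (90,-4), (94,-3), (94,-5), (88,-2)
        outcomes = {0: (90.0, -4.0), 1: (94.0, -3.0), 2: (94.0, -5.0), 3: (88.0, -2.0)}
        spec = SearchSpec(n_iterations=1, n_threads=4, seeds=(0, 1, 2, 3), n_channels=1)
        calls = {"i": -1}

        def scripted(tc):
            calls["i"] += 1
            s, ll = outcomes[calls["i"]]
            return ScoreResult(s, ll)

        res = run_search(spec, scripted)
        assert res.best_thread_index == 1
        assert res.best_result.score_pct == 94.0
        assert res.best_result.mean_loglik == -3.0

    def test_defaults_retained_when_better(self):
        peak = TimeConstants((140.0,), (980.0,))
        oracle = OracleScorer(peak, w_at=0.5, w_rt=5.0)  # steep: search rarely hits 100
        spec = SearchSpec(n_iterations=5, n_threads=2, seeds=(1, 2), n_channels=1)
        res = run_search(spec, oracle.score_for, default_tc=peak)
        assert res.default_retained
        assert res.best_tc == peak
        assert res.best_thread_index is None

    def test_single_thread_equals_run_thread(self):
        oracle = OracleScorer(TimeConstants((200.0,), (1200.0,)))
        spec = small_spec(seeds=(5,))
        search = run_search(spec, oracle.score_for)
        thread = run_thread(spec, oracle.score_for, 5)
        assert search.best_tc == thread.best_tc
        assert search.best_result == thread.best_result

    def test_exhaustive_agreement_on_coarse_grid(self):
        # 1 channel, stepsize coarsened so the grid has <= 200 points;
        # exhaustive search certifies the maximizer, RS must agree for >= 90% of seeds
        # 10 x 17 = 170 grid points
        peak = TimeConstants((250.0,), (1300.0,))
        oracle = OracleScorer(peak, w_at=10.0, w_rt=100.0)
        grid_best, grid_key = None, (-np.inf, -np.inf)
        for at in range(50, 501, 50):
            for rt in range(300, 1901, 100):
                r = oracle.score_for(TimeConstants((float(at),), (float(rt),)))
                if (r.score_pct, r.mean_loglik) > grid_key:
                    grid_best = (float(at), float(rt))
                    grid_key = (r.score_pct, r.mean_loglik)
        agree = 0
        for seed in range(20):
            res = run_thread(
                SearchSpec(at_bounds_ms=(50.0, 500.0), rt_bounds_ms=(300.0, 1900.0),
                           stepsize_ms=50.0, n_iterations=150, n_threads=1,
                           seeds=(seed,), n_channels=1),
                oracle.score_for, seed,
            )
            if (res.best_tc.attack_ms[0], res.best_tc.release_ms[0]) == grid_best:
                agree += 1
        assert agree >= 18
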