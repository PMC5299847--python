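"""M1/M2 representative-cell statistics against brute-force oracles."""

import math

import numpy as np
import pytest

from osmotrace import (
    ChamberCohort,
    PopulationProfile,
    compute_m1,
    compute_m2,
    default_time_grid,
    make_default_panel,
    rank_m2,
    representative_analysis,
    select_representative,
    simulate_trajectories,
)

from conftest import make_traj


def m1_naive(S):
    """Double-loop scalar transcription of the M1 similarity statistic."""
    N, T = len(S), len(S[0])
    mean_t = [sum(S[j][t] for j in range(N)) / N for t in range(T)]
    scores = []
    for i in range(N):
        total = 0.0
        for j in range(N):
            if j == i:
                continue
            acc = 0.0
            for t in range(T):
                acc += ((S[i][t] - S[j][t]) / mean_t[t]) ** 2
            total += math.sqrt(acc / T)
        scores.append(total / (N - 1))
    return scores


def m2_naive(rep, pop_mean):
    """Scalar transcription of the M2 divergence statistic."""
    T = len(rep)
    acc = 0.0
    for t in range(T):
        acc += ((rep[t] - pop_mean[t]) / pop_mean[t]) ** 2
    return math.sqrt(acc / T)


def trajs_from_matrix(S, times=None):
    S = np.asarray(S, dtype=float)
    if times is None:
        times = 5.0 * np.arange(S.shape[1]) - 10.0
    return [make_traj(row, cell_id=i, times=times) for i, row in enumerate(S)]


def pop_profile(mean, times=None):
    mean = np.asarray(mean, dtype=float)
    if times is None:
        times = 5.0 * np.arange(len(mean)) - 10.0
    n = len(mean)
    return PopulationProfile("S", "0.4M", times, mean, np.full(n, 5), np.zeros(n, bool))


class TestComputeM1:
    def test_identical_trajectories_all_scores_equal_zero(self):
        trajs = trajs_from_matrix([[5.0, 6.0, 7.0]] * 4)
        ids, scores = compute_m1(trajs)
        np.testing.assert_allclose(scores, 0.0, atol=1e-15)
        assert select_representative(ids, scores) == 0  # lowest id wins the tie

    def test_two_cells_get_identical_scores(self):
        trajs = trajs_from_matrix([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0]])
        _, scores = compute_m1(trajs)
        assert scores[0] == pytest.approx(scores[1], rel=1e-15)

    def test_small_integer_fixture_matches_double_loop_oracle(self):
        S = [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 5.0], [3.0, 1.0, 4.0, 3.0]]
        _, scores = compute_m1(trajs_from_matrix(S))
        np.testing.assert_allclose(scores, m1_naive(S), rtol=1e-14)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            N = int(rng.integers(2, 11))
            T = int(rng.integers(2, 21))
            S = rng.uniform(10.0, 200.0, (N, T))
            _, scores = compute_m1(trajs_from_matrix(S))
            np.testing.assert_allclose(scores, m1_naive(S.tolist()), atol=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        S = rng.uniform(10.0, 100.0, (6, 8))
        _, scores = compute_m1(trajs_from_matrix(S))
        perm = rng.permutation(6)
        trajs_perm = [
            make_traj(S[p], cell_id=i) for i, p in enumerate(perm)
        ]
        _, scores_perm = compute_m1(trajs_perm)
        np.testing.assert_allclose(scores_perm, scores[perm], rtol=1e-14)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        S = rng.uniform(10.0, 100.0, (5, 12))
        _, scores = compute_m1(trajs_from_matrix(S))
        _, scores_scaled = compute_m1(trajs_from_matrix(7.3 * S))
        np.testing.assert_allclose(scores_scaled, scores, rtol=1e-12)

    def test_partial_trajectories_are_excluded(self):
        full = trajs_from_matrix([[5.0, 5.0, 5.0], [6.0, 6.0, 6.0]])
        partial = make_traj([7.0, 7.0, np.nan], cell_id=9, valid=[1, 1, 0])
        ids, scores = compute_m1(full + [partial])
        assert 9 not in ids and len(ids) == 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_m1(trajs_from_matrix([[1.0, 2.0]]))  # N < 2
        with pytest.raises(ValueError):
            compute_m1(
                [make_traj([1.0], cell_id=0), make_traj([1.0], cell_id=1)]
            )  # T < 2
        with pytest.raises(ValueError):
            compute_m1(trajs_from_matrix([[1.0, -5.0], [1.0, 3.0]]))  # mean <= 0


class TestSelectRepresentative:
    def test_minimum_wins(self):
        assert select_representative(np.array([0, 1, 2]), np.array([3.0, 1.0, 2.0])) == 1

    def test_tie_breaks_to_lowest_id(self):
        assert select_representative(np.array([0, 1, 2]), np.array([1.0, 1.0, 5.0])) == 0

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(1, 12))
            ids = rng.permutation(n) + 100
            scores = rng.uniform(0, 1, n).round(1)  # coarse grid forces ties
            got = select_representative(ids, scores)
            best = min(zip(scores, ids))
            assert got == best[1]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_representative(np.array([]), np.array([]))


class TestComputeM2:
    def test_rep_equal_to_population_gives_zero(self):
        rep = make_traj([4.0, 5.0, 6.0])
        assert compute_m2(rep, pop_profile([4.0, 5.0, 6.0])) == 0.0

    def test_single_cell_cohort_gives_zero(self):
        traj = make_traj([3.0, 8.0, 2.0])
        res_pop = pop_profile(traj.values)
        assert compute_m2(traj, res_pop) == 0.0

    def test_single_point_delta_matches_hand_oracle(self):
        pop = [10.0, 10.0, 10.0, 10.0]
        rep_vals = [10.0, 12.0, 10.0, 10.0]
        # hand evaluation: sqrt((1/4) * (2/10)^2) = 0.1
        assert compute_m2(make_traj(rep_vals), pop_profile(pop)) == pytest.approx(0.1)
        assert m2_naive(rep_vals, pop) == pytest.approx(0.1)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            T = int(rng.integers(2, 21))
            pop = rng.uniform(10.0, 100.0, T)
            rep = pop + rng.normal(0, 5.0, T)
            got = compute_m2(make_traj(rep), pop_profile(pop))
            assert got == pytest.approx(m2_naive(rep.tolist(), pop.tolist()), abs=1e-12)

    def test_grid_mismatch_is_error(self):
        rep = make_traj([1.0, 2.0], times=np.array([0.0, 5.0]))
        pop = pop_profile([1.0, 2.0], times=np.array([0.0, 10.0]))
        with pytest.raises(ValueError):
            compute_m2(rep, pop)


class TestRepresentativeProperty:
    def test_pinned_mean_cell_attains_minimum_m1(self):
        # one cell pinned at the cohort-mean dynamics, others jittered
        # symmetrically around it: the pinned cell must win as jitter shrinks
        rng = np.random.default_rng(11)
        base = 100.0 + 50.0 * np.sin(np.linspace(0, 3, 20))
        for eps in (0.01, 0.1):
            rows = [base]
            for i in range(4):
                delta = rng.normal(0, eps, 20)
                rows.append(base + delta)
                rows.append(base - delta)  # symmetric: mean stays at base
            ids, scores = compute_m1(trajs_from_matrix(np.stack(rows)))
            assert select_representative(ids, scores) == 0


class TestRankM2:
    def test_identical_dynamics_rank_alphabetically_with_zero_m2(self):
        results = []
        for name in ("B", "A", "C"):
            trajs = trajs_from_matrix([[5.0, 6.0, 7.0]] * 3)
            for t in trajs:
                t.strain = name
            results.append(representative_analysis(trajs))
        df = rank_m2(results)
        assert list(df["strain"]) == ["A", "B", "C"]
        np.testing.assert_allclose(df["m2"], 0.0, atol=1e-15)

    def test_heterogeneous_strain_ranks_above_homogeneous(self):
        rng = np.random.default_rng(12)
        base = np.full(15, 100.0)
        quiet = trajs_from_matrix([base + rng.normal(0, 0.5, 15) for _ in range(8)])
        noisy = trajs_from_matrix([base + rng.normal(0, 15.0, 15) for _ in range(8)])
        for t in quiet:
            t.strain = "QUIET"
        for t in noisy:
            t.strain = "NOISY"
        df = rank_m2([representative_analysis(quiet), representative_analysis(noisy)])
        assert list(df["strain"]) == ["NOISY", "QUIET"]

    def test_bursty_strain_ranks_first_in_simulated_panel(self):
        # asynchronous per-cell bursts average out in the population mean but
        # persist in the representative cell, inflating M2 for that strain
        panel = make_default_panel(n_per_archetype=1, bursty_strains=("RAPID_UP_ADAPT_0",))
        cohort = ChamberCohort(times=default_time_grid(), initial_cells=25)
        wins = 0
        for seed in range(5):
            trajs, _ = simulate_trajectories(panel, cohort, seed=seed)
            by_strain = {}
            for t in trajs:
                by_strain.setdefault(t.strain, []).append(t)
            df = rank_m2(
                [representative_analysis(ts) for ts in by_strain.values()]
            )
            wins += df.iloc[0]["strain"] == "RAPID_UP_ADAPT_0"
        assert wins >= 4
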