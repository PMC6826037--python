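import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import mucocensus as mc
from mucocensus.census import (
    PerturbationPlan,
    base_cluster,
    build_stability_matrix,
    consensus_partition,
    derive_seed,
    label_unassigned,
    run_perturbations,
    select_k,
    stability_scores,
)


def brute_force_stability(runs, n_cells):
    """Independent pair-counting oracle: iterate over every pair and run."""
    co_cluster = np.zeros((n_cells, n_cells))
    co_present = np.zeros((n_cells, n_cells))
    for i in range(n_cells):
        for j in range(n_cells):
            for present, labels in runs:
                present = list(present)
                if i in present and j in present:
                    co_present[i, j] += 1
                    if labels[present.index(i)] == labels[present.index(j)]:
                        co_cluster[i, j] += 1
    with np.errstate(invalid="ignore"):
        S = np.where(co_present > 0, co_cluster / co_present, 0.5)
    np.fill_diagonal(S, 1.0)
    return S


def naive_average_linkage(dist, k):
    """O(n^3) agglomerative average linkage, cut at k clusters."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean(
                [dist[i, j] for i in clusters[a] for j in clusters[b]]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c
    return labels


WORKED_RUNS = [
    (np.array([0, 1, 2, 3, 4]), np.array(list("AABBA"))),
    (np.arange(6), np.array(list("AABBBA"))),
    (np.arange(6), np.array(list("AAABBA"))),
]


class TestBaseCluster:
    def test_separable_blobs(self, rng):
        expr = np.zeros((20, 40))
        expr[:10, :20] = rng.normal(10, 0.1, (10, 20))
        expr[10:, 20:] = rng.normal(10, 0.1, (10, 20))
        labels = base_cluster(expr, 2, seed=0)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_rejected(self, rng):
        with pytest.raises(ValueError):
            base_cluster(rng.random((5, 10)), 1, seed=0)

    def test_k_exceeding_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            base_cluster(rng.random((5, 10)), 11, seed=0)

    def test_planted_types_recovered(self, standard_ds):
        _, truth, norm = standard_ds
        labels = base_cluster(norm.values, 6, seed=0)
        assert adjusted_rand_score(truth.cell_type, labels) >= 0.9


class TestRunPerturbations:
    def test_drop_fraction_exact(self, rng):
        expr = rng.random((10, 100))
        plan = PerturbationPlan(n_subsets=2, runs_per_subset=2, seed=1)
        runs = run_perturbations(expr, plan, k=2)
        assert len(runs) == 4
        for present, labels in runs:
            assert len(present) == 90
            assert len(labels) == 90

    def test_single_run(self, rng):
        expr = rng.random((10, 60))
        plan = PerturbationPlan(n_subsets=1, runs_per_subset=1, seed=1)
        assert len(run_perturbations(expr, plan, k=2)) == 1

    def test_reproducible_from_plan_seed(self, rng):
        expr = rng.random((10, 60))
        plan = PerturbationPlan(n_subsets=2, runs_per_subset=2, seed=9)
        a = run_perturbations(expr, plan, k=3)
        b = run_perturbations(expr, plan, k=3)
        for (pa, la), (pb, lb) in zip(a, b):
            assert np.array_equal(pa, pb) and np.array_equal(la, lb)

    def test_derived_seeds_distinct(self):
        seeds = {derive_seed(0, k, s, r)
                 for k in range(2, 5) for s in range(3) for r in range(3)}
        assert len(seeds) == 27


class TestStabilityMatrix:
    def test_perfect_agreement(self):
        runs = [(np.arange(4), np.array([0, 0, 1, 1]))] * 3
        S = build_stability_matrix(runs, 4).S
        expect = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            dtype=float,
        )
        assert np.array_equal(S, expect)

    def test_worked_example(self):
        stab = build_stability_matrix(WORKED_RUNS, 6)
        assert stab.S[0, 1] == pytest.approx(1.0)
        assert stab.S[2, 3] == pytest.approx(2 / 3)
        assert stab.S[0, 5] == pytest.approx(1.0)  # cell 5 absent in run 1

    def test_never_copresent_pair_gets_prior(self):
        runs = [
            (np.array([0, 1]), np.array([0, 0])),
            (np.array([1, 2]), np.array([0, 0])),
        ]
        stab = build_stability_matrix(runs, 3)
        assert stab.S[0, 2] == 0.5
        assert stab.never_copresent[0, 2]

    def test_matches_brute_force_exhaustively(self, rng):
        """Exact agreement with pair-counting for n <= 12, runs <= 5."""
        for trial in range(20):
            n = int(rng.integers(3, 13))
            n_runs = int(rng.integers(1, 6))
            runs = []
            for _ in range(n_runs):
                present = np.sort(
                    rng.choice(n, size=int(rng.integers(2, n + 1)),
                               replace=False)
                )
                labels = rng.integers(0, 3, size=len(present))
                runs.append((present, labels))
            stab = build_stability_matrix(runs, n)
            assert np.allclose(stab.S, brute_force_stability(runs, n))

    def test_symmetry_and_range(self, rng):
        runs = [
            (np.sort(rng.choice(20, 15, replace=False)),
             rng.integers(0, 4, 15))
            for _ in range(6)
        ]
        stab = build_stability_matrix(runs, 20)
        assert np.array_equal(stab.S, stab.S.T)
        assert stab.S.min() >= 0 and stab.S.max() <= 1
        assert (stab.co_cluster <= stab.co_present).all()
        assert np.all(np.diag(stab.S) == 1)


class TestConsensusPartition:
    def test_block_diagonal_recovered(self):
        runs = [(np.arange(6), np.array([0, 0, 0, 1, 1, 1]))] * 2
        stab = build_stability_matrix(runs, 6)
        labels = consensus_partition(stab, 2)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], labels) == 1.0

    def test_k_equals_n_singletons(self):
        runs = [(np.arange(5), np.array([0, 0, 1, 1, 1]))]
        stab = build_stability_matrix(runs, 5)
        assert len(set(consensus_partition(stab, 5))) == 5

    def test_matches_naive_average_linkage(self, rng):
        from scipy.spatial.distance import squareform, pdist

        for _ in range(5):
            S = rng.random((10, 10))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            stab = mc.StabilityMatrix(
                np.zeros((10, 10)), np.zeros((10, 10)), S,
                np.zeros((10, 10), bool),
            )
            dist = squareform(pdist(S))
            for k in (2, 3, 4):
                ours = consensus_partition(stab, k)
                ref = naive_average_linkage(dist, k)
                assert adjusted_rand_score(ours, ref) == 1.0


class TestStabilityScores:
    def test_perfect_blocks(self):
        runs = [(np.arange(6), np.array([0, 0, 0, 1, 1, 1]))] * 2
        stab = build_stability_matrix(runs, 6)
        per_cell, intra, inter = stability_scores(
            stab, np.array([0, 0, 0, 1, 1, 1])
        )
        assert np.allclose(per_cell, 1.0)
        assert intra["average"] == 1.0
        assert inter == 0.0

    def test_worked_example_cell0(self):
        stab = build_stability_matrix(WORKED_RUNS, 6)
        per_cell, _, _ = stability_scores(
            stab, np.array([0, 0, 1, 1, 1, 0])
        )
        assert per_cell[0] == pytest.approx(1.0)

    def test_random_labels_blur_intra_inter(self, rng):
        runs = [(np.arange(20), np.repeat([0, 1], 10))] * 3
        stab = build_stability_matrix(runs, 20)
        perm = rng.permutation(np.repeat([0, 1], 10))
        _, intra, inter = stability_scores(stab, perm)
        assert abs(intra["average"] - inter) < 0.25

    def test_singleton_cluster_convention(self):
        runs = [(np.arange(3), np.array([0, 0, 1]))]
        stab = build_stability_matrix(runs, 3)
        per_cell, intra, _ = stability_scores(stab, np.array([0, 0, 1]))
        assert per_cell[2] == 1.0
        assert intra[1] == 1.0


class TestSelectK:
    def test_peaked_curve_selects_peak(self):
        curve = {2: 0.99, 3: 0.95, 4: 0.97, 5: 0.99, 6: 0.87, 7: 0.80}
        assert select_k(curve)[0] == 5

    def test_flat_curve_warns_and_picks_smallest_interior(self):
        with pytest.warns(UserWarning, match="no elbow"):
            k, note = select_k({2: 0.9, 3: 0.9, 4: 0.9, 5: 0.9})
        assert k == 3 and note is not None

    def test_monotone_linear_curve_warns(self):
        with pytest.warns(UserWarning, match="no elbow"):
            k, _ = select_k({2: 0.9, 3: 0.8, 4: 0.7, 5: 0.6})
        assert k == 3

    def test_too_few_k_values(self):
        with pytest.raises(ValueError, match="manual"):
            select_k({2: 0.9, 3: 0.8})


class TestLabelUnassigned:
    def test_threshold_is_strict(self):
        flags = label_unassigned(np.array([0.70, 0.69, 0.71]))
        assert flags.tolist() == [False, True, False]

    def test_score_range_checked(self):
        with pytest.raises(ValueError):
            label_unassigned(np.array([1.2]))


class TestCensusModel:
    def test_census_reproducible(self, rng):
        expr = np.exp(rng.normal(0, 1, (50, 80)))
        plan = PerturbationPlan(
            k_range=(2, 3, 4), n_subsets=2, runs_per_subset=2, seed=4
        )
        a = mc.ClusterStabilityCensus(expr, plan).fit()
        b = mc.ClusterStabilityCensus(expr, plan).fit()
        assert a.selected_k == b.selected_k
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(
            a.per_cell_stability, b.per_cell_stability
        )
        assert np.array_equal(
            a.stability_matrix.S, b.stability_matrix.S
        )

    def test_raw_layer_rejected(self, standard_ds):
        matrix, _, _ = standard_ds
        with pytest.raises(ValueError, match="normalized"):
            mc.ClusterStabilityCensus(matrix)

    def test_summary_mentions_selection(self, rng):
        expr = np.exp(rng.normal(0, 1, (40, 60)))
        plan = PerturbationPlan(
            k_range=(2, 3, 4), n_subsets=2, runs_per_subset=2, seed=4
        )
        res = mc.ClusterStabilityCensus(expr, plan).fit()
        text = res.summary()
        assert f"selected k: {res.selected_k}" in text
        assert "intra" in text

    def test_noise_does_not_raise_stability(self, lineage6):
        """Mean per-cell stability does not increase as planted noise
        (NB dispersion) grows."""
        means = []
        for disp in (0.3, 1.0, 3.0):
            prog = mc.ExpressionProgram.build(
                lineage6, n_genes=400, nb_dispersion=disp, seed=7
            )
            matrix, _ = mc.generate_counts(
                lineage6, prog, 200, 0.0, seed=31
            )
            plan = PerturbationPlan(
                k_range=(6,), n_subsets=4, runs_per_subset=4, seed=5
            )
            res = mc.ClusterStabilityCensus(
                mc.normalize(matrix), plan
            ).fit(k=6)
            means.append(res.mean_stability)
        assert means[0] >= means[1] >= means[2] - 0.02
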