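import itertools

import numpy as np
import pytest

from coherence_screen.aco_seriation import (
    ACOParams,
    DistanceMatrix,
    FrequencyTable,
    GeneSequence,
    aco_order,
    brute_force_order,
    distance_matrix,
    neighbor_frequency,
    path_length,
    repeated_ordering,
    screen_candidates,
)
from coherence_screen.dataio import DataIOError, ExpressionMatrix


def _dist_from_profiles(profiles: np.ndarray, genes=None) -> DistanceMatrix:
    genes = genes or [f"g{i}" for i in range(profiles.shape[0])]
    d = ((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix(genes, d)


def _random_dist(rng, n, n_dim=5) -> DistanceMatrix:
    return _dist_from_profiles(rng.uniform(0, 1, size=(n, n_dim)))


FAST = ACOParams(n_iterations=50)


class TestDistanceMatrix:
    def test_hand_computed_pair(self):
        expr = ExpressionMatrix(
            ["x", "y", "z"], ["s1", "s2"],
            np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]]),
        )
        dm = distance_matrix(expr, standardize=False)
        assert dm.d[0, 1] == pytest.approx(2.0)  # (0-1)^2 + (0-1)^2

    def test_self_distance_zero(self, random_matrix):
        dm = distance_matrix(random_matrix, standardize=False)
        np.testing.assert_allclose(np.diag(dm.d), 0.0)

    def test_brute_force_elementwise_oracle(self, random_matrix):
        dm = distance_matrix(random_matrix, standardize=False)
        x = random_matrix.values
        for i in range(x.shape[0]):
            for j in range(x.shape[0]):
                expected = float(sum((x[i, s] - x[j, s]) ** 2
                                     for s in range(x.shape[1])))
                assert abs(dm.d[i, j] - expected) < 1e-9

    def test_standardized_distance_is_scale_free(self, random_matrix):
        dm1 = distance_matrix(random_matrix)
        scaled = ExpressionMatrix(
            random_matrix.gene_ids, random_matrix.sample_ids,
            random_matrix.values * 7.0 + 3.0,
        )
        dm2 = distance_matrix(scaled)
        np.testing.assert_allclose(dm1.d, dm2.d, atol=1e-8)

    def test_too_few_genes_rejected(self, random_matrix):
        with pytest.raises(DataIOError, match=">=3"):
            distance_matrix(random_matrix, genes=random_matrix.gene_ids[:2])

    def test_absent_gene_rejected(self, random_matrix):
        with pytest.raises(DataIOError, match="NOPE"):
            distance_matrix(random_matrix, genes=["NOPE", "G0", "G1"])

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(DataIOError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPathLength:
    def test_single_pair(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        assert path_length(["a", "b"], dm) == 5.0

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        dm = _random_dist(rng, 6)
        order = list(dm.gene_ids)
        rng.shuffle(order)
        assert path_length(order, dm) == pytest.approx(
            path_length(order[::-1], dm)
        )

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(1)
        dm = _random_dist(rng, 7)
        idx = {g: i for i, g in enumerate(dm.gene_ids)}
        for _ in range(20):
            order = list(dm.gene_ids)
            rng.shuffle(order)
            expected = sum(
                dm.d[idx[a], idx[b]] for a, b in zip(order, order[1:])
            )
            assert path_length(order, dm) == pytest.approx(expected)

    def test_cycle_adds_closing_edge(self):
        rng = np.random.default_rng(2)
        dm = _random_dist(rng, 5)
        order = list(dm.gene_ids)
        idx = {g: i for i, g in enumerate(dm.gene_ids)}
        open_len = path_length(order, dm, "open_path")
        cyc_len = path_length(order, dm, "cycle")
        assert cyc_len == pytest.approx(open_len + dm.d[idx[order[-1]], idx[order[0]]])

    def test_non_permutation_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(DataIOError, match="permutation"):
            path_length(["a", "a"], dm)


class TestBruteForce:
    def test_three_gene_enumeration(self):
        # d(1,2)=1, d(2,3)=1, d(1,3)=4 -> open path (1,2,3), length 2
        d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 1.0], [4.0, 1.0, 0.0]])
        dm = DistanceMatrix(["g1", "g2", "g3"], d)
        seq = brute_force_order(dm)
        assert seq.length == pytest.approx(2.0)
        assert seq.order in (("g1", "g2", "g3"), ("g3", "g2", "g1"))

    def test_beats_random_permutations(self):
        rng = np.random.default_rng(3)
        dm = _random_dist(rng, 7)
        best = brute_force_order(dm).length
        for _ in range(100):
            order = list(dm.gene_ids)
            rng.shuffle(order)
            assert best <= path_length(order, dm) + 1e-12

    def test_cycle_rotation_invariance(self):
        rng = np.random.default_rng(4)
        dm = _random_dist(rng, 6)
        seq = brute_force_order(dm, objective="cycle")
        order = list(seq.order)
        for k in range(1, len(order)):
            rotated = order[k:] + order[:k]
            assert path_length(rotated, dm, "cycle") == pytest.approx(seq.length)

    def test_refuses_large_n(self):
        dm = DistanceMatrix([f"g{i}" for i in range(11)], np.zeros((11, 11)))
        with pytest.raises(DataIOError, match="refuses"):
            brute_force_order(dm)


class TestAcoOrder:
    def test_collinear_instance_recovers_line(self):
        # 1-D profiles 0,1,2,3: squared distances force the order 0,1,2,3
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        dm = _dist_from_profiles(x, genes=["a", "b", "c", "d"])
        seq = aco_order(dm, ACOParams(seed=0))
        assert seq.length == pytest.approx(3.0)
        assert seq.order in (("a", "b", "c", "d"), ("d", "c", "b", "a"))

    def test_three_gene_minimum(self):
        d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 1.0], [4.0, 1.0, 0.0]])
        dm = DistanceMatrix(["g1", "g2", "g3"], d)
        seq = aco_order(dm, ACOParams(seed=1, n_iterations=50))
        assert seq.length == pytest.approx(2.0)

    def test_output_is_permutation(self):
        rng = np.random.default_rng(5)
        dm = _random_dist(rng, 9)
        seq = aco_order(dm, FAST)
        assert sorted(seq.order) == sorted(dm.gene_ids)

    def test_length_matches_recomputation(self):
        rng = np.random.default_rng(6)
        dm = _random_dist(rng, 8)
        seq = aco_order(dm, FAST)
        assert seq.length == pytest.approx(path_length(seq.order, dm))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        dm = _random_dist(rng, 8)
        s1 = aco_order(dm, ACOParams(seed=99, n_iterations=30))
        s2 = aco_order(dm, ACOParams(seed=99, n_iterations=30))
        assert s1.order == s2.order and s1.length == s2.length

    def test_more_iterations_never_worse_same_seed(self):
        # identical RNG stream prefix: best-so-far can only improve
        rng = np.random.default_rng(8)
        dm = _random_dist(rng, 10)
        short = aco_order(dm, ACOParams(seed=3, n_iterations=20))
        long = aco_order(dm, ACOParams(seed=3, n_iterations=120))
        assert long.length <= short.length + 1e-12

    def test_never_undercuts_brute_force(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            dm = _random_dist(rng, 6)
            opt = brute_force_order(dm).length
            seq = aco_order(dm, ACOParams(seed=trial, n_iterations=50))
            assert seq.length >= opt - 1e-12

    def test_matches_oracle_usually(self):
        # scaled-down version of the acceptance check
        rng = np.random.default_rng(10)
        hits = 0
        for trial in range(10):
            dm = _random_dist(rng, 7)
            opt = brute_force_order(dm).length
            seq = aco_order(dm, ACOParams(seed=trial))
            assert seq.length >= opt - 1e-12
            hits += seq.length <= opt + 1e-9
        assert hits >= 9

    def test_cycle_objective(self):
        rng = np.random.default_rng(11)
        dm = _random_dist(rng, 6)
        opt = brute_force_order(dm, objective="cycle").length
        seq = aco_order(dm, ACOParams(seed=0, objective="cycle"))
        assert seq.length >= opt - 1e-12
        assert seq.length == pytest.approx(path_length(seq.order, dm, "cycle"))

    def test_non_finite_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(DataIOError, match="non-finite"):
            DistanceMatrix(["a", "b", "c"], d)

    @pytest.mark.parametrize(
        "kwargs", [dict(rho=0.0), dict(rho=1.0), dict(n_iterations=0),
                   dict(n_ants=0), dict(objective="loop")],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ACOParams(**kwargs)


class TestRepeatedOrdering:
    def test_ten_runs_all_permutations(self):
        rng = np.random.default_rng(12)
        dm = _random_dist(rng, 8)
        seqs = repeated_ordering(dm, FAST, n_runs=10)
        assert len(seqs) == 10
        for seq in seqs:
            assert sorted(seq.order) == sorted(dm.gene_ids)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        dm = _random_dist(rng, 7)
        a = repeated_ordering(dm, FAST, n_runs=4)
        b = repeated_ordering(dm, FAST, n_runs=4)
        assert [s.order for s in a] == [s.order for s in b]

    def test_derived_seeds_differ(self):
        rng = np.random.default_rng(14)
        dm = _random_dist(rng, 7)
        seqs = repeated_ordering(dm, FAST, n_runs=6)
        assert [s.seed for s in seqs] == [FAST.seed + r for r in range(6)]

    def test_runs_not_all_identical_on_rugged_instance(self):
        # near-uniform random distances leave many near-ties; with one
        # iteration runs amount to randomized greedy and diverge
        rng = np.random.default_rng(15)
        dm = _random_dist(rng, 12, n_dim=2)
        seqs = repeated_ordering(dm, ACOParams(n_iterations=1), n_runs=10)
        assert len({s.order for s in seqs}) > 1


class TestNeighborFrequency:
    def _seq(self, order, seed=0):
        return GeneSequence(order=tuple(order), length=0.0, seed=seed)

    def test_always_adjacent_counts_every_run(self):
        seqs = [self._seq(["X", "ANCH", "G", "Y"], seed=i) for i in range(10)]
        freq = neighbor_frequency(seqs, "ANCH", window=1)
        assert freq.counts["G"] == 10
        assert freq.counts["X"] == 10
        assert freq.counts["Y"] == 0

    def test_never_near_counts_zero(self):
        seqs = [self._seq(["ANCH", "A", "B", "C", "FAR"]) for _ in range(5)]
        freq = neighbor_frequency(seqs, "ANCH", window=2)
        assert freq.counts["FAR"] == 0

    def test_brute_force_positional_scan_oracle(self):
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(12)] + ["ANCH"]
        seqs = []
        for i in range(8):
            order = list(genes)
            rng.shuffle(order)
            seqs.append(self._seq(order, seed=i))
        window = 3
        freq = neighbor_frequency(seqs, "ANCH", window=window)
        for g in genes:
            if g == "ANCH":
                continue
            expected = sum(
                abs(list(s.order).index(g) - list(s.order).index("ANCH")) <= window
                for s in seqs
            )
            assert freq.counts[g] == expected

    def test_reversal_invariance(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(9)] + ["ANCH"]
        seqs = []
        for i in range(6):
            order = list(genes)
            rng.shuffle(order)
            seqs.append(self._seq(order, seed=i))
        fwd = neighbor_frequency(seqs, "ANCH", window=2)
        rev = neighbor_frequency(
            [self._seq(list(s.order)[::-1], s.seed) for s in seqs], "ANCH", window=2
        )
        assert fwd.counts == rev.counts

    def test_anchor_absent_rejected(self):
        with pytest.raises(DataIOError, match="ANCH"):
            neighbor_frequency([self._seq(["a", "b", "c"])], "ANCH")

    def test_anchor_excluded_from_table(self):
        freq = neighbor_frequency([self._seq(["ANCH", "a", "b"])], "ANCH")
        assert "ANCH" not in freq.counts


class TestScreenCandidates:
    def test_table_semantics(self):
        freq = FrequencyTable("ANCH", 5, 10, {"A": 10, "B": 5, "C": 4})
        assert screen_candidates(freq, min_count=5) == ["A", "B"]

    def test_strict_gt_mode(self):
        freq = FrequencyTable("ANCH", 5, 10, {"A": 10, "B": 5, "C": 4})
        assert screen_candidates(freq, min_count=5, strict_gt=True) == ["A"]

    def test_all_zero_counts_empty(self):
        freq = FrequencyTable("ANCH", 5, 10, {"A": 0, "B": 0})
        assert screen_candidates(freq, min_count=5) == []

    def test_sorted_by_count_then_id(self):
        freq = FrequencyTable("ANCH", 5, 10, {"B": 7, "A": 7, "C": 9})
        assert screen_candidates(freq, min_count=5) == ["C", "A", "B"]

    def test_monotone_in_min_count(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            counts = {f"g{i}": int(rng.integers(0, 11)) for i in range(15)}
            freq = FrequencyTable("ANCH", 5, 10, counts)
            prev = None
            for mc in range(1, 11):
                kept = set(screen_candidates(freq, min_count=mc))
                if prev is not None:
                    assert kept <= prev
                prev = kept

    def test_min_count_range_enforced(self):
        freq = FrequencyTable("ANCH", 5, 10, {"A": 10})
        with pytest.raises(ValueError):
            screen_candidates(freq, min_count=11)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTable("ANCH", 5, 10, {"A": 12})
        with pytest.raises(ValueError):
            FrequencyTable("ANCH", 5, 10, {"ANCH": 3})
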