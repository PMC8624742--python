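import itertools

import numpy as np
import pytest

from moses import (
    AnnotationDatabase,
    BinaryProfileMatrix,
    ClusterSelection,
    HammingKMeans,
    Interactome,
    MosesPhaseError,
    RunConfig,
    build_profile_matrix,
    hamming_kmeans,
    intersect_clusters,
    run_moses,
    select_k,
)
from moses.synthetic import generate_benchmark, BenchmarkSpec


def exhaustive_partition_objective(X, k):
    """Oracle: minimum total within-cluster Hamming distance over every
    partition of the rows into at most k nonempty clusters, with
    majority-vote binary centers."""
    n, d = X.shape

    def cost(rows):
        sub = X[list(rows)]
        center = (sub.mean(axis=0) >= 0.5).astype(int)
        return np.abs(sub - center).sum() / d

    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        best = min(best, sum(cost(rows) for rows in groups.values()))
    return best


class TestHammingKMeans:
    def test_separable_data_perfect_split(self):
        X = np.array([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3)
        est = HammingKMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert est.inertia_ == pytest.approx(0.0)
        assert len(set(est.labels_[:3])) == 1 and len(set(est.labels_[3:])) == 1
        assert est.labels_[0] != est.labels_[3]

    def test_k1_center_is_columnwise_majority(self):
        X = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0]])
        est = HammingKMeans(n_clusters=1, n_init=3, random_state=0).fit(X)
        assert est.cluster_centers_.tolist() == [[1, 0, 0]]

    def test_majority_tie_resolves_to_one(self):
        X = np.array([[1, 0], [0, 1]])
        est = HammingKMeans(n_clusters=1, n_init=1, random_state=0).fit(X)
        assert est.cluster_centers_.tolist() == [[1, 1]]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(6, 4)).astype(np.uint8)
        est = HammingKMeans(n_clusters=2, n_init=50, random_state=seed).fit(X)
        assert est.inertia_ == pytest.approx(exhaustive_partition_objective(X, 2))

    def test_4x3_against_oracle(self):
        X = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 1]], dtype=np.uint8)
        est = HammingKMeans(n_clusters=2, n_init=50, random_state=1).fit(X)
        assert est.inertia_ == pytest.approx(exhaustive_partition_objective(X, 2))

    def test_objective_non_increasing_within_replicate(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(40, 8)).astype(np.uint8)
        est = HammingKMeans(n_clusters=3, n_init=20, random_state=3).fit(X)
        if not est.reseeded_:
            path = est.objective_path_
            assert all(a >= b - 1e-12 for a, b in zip(path, path[1:]))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(30, 6)).astype(np.uint8)
        a = HammingKMeans(n_clusters=4, n_init=10, random_state=42).fit(X)
        b = HammingKMeans(n_clusters=4, n_init=10, random_state=42).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert a.inertia_ == b.inertia_

    def test_k_exceeding_rows_errors(self):
        with pytest.raises(ValueError):
            HammingKMeans(n_clusters=5).fit(np.eye(3, dtype=int))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            HammingKMeans(n_clusters=2).fit(np.array([[0, 2], [1, 0]]))

    def test_functional_wrapper(self):
        X = np.array([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3)
        labels, centers, obj = hamming_kmeans(X, 2, replicates=5, rng_seed=0)
        assert obj == pytest.approx(0.0)
        assert sorted(centers.tolist()) == [[0, 0, 1, 1], [1, 1, 0, 0]]

    def test_sklearn_params_round_trip(self):
        est = HammingKMeans(n_clusters=3, n_init=7)
        assert est.get_params()["n_clusters"] == 3
        est.set_params(n_clusters=2)
        assert est.n_clusters == 2


class TestBuildProfileMatrix:
    def net(self):
        return Interactome([("A", "B"), ("B", "C"), ("C", "D")])

    def test_rows_and_entries(self):
        db = AnnotationDatabase("X", {"T1": frozenset("AB"), "T2": frozenset("BC")})
        m = build_profile_matrix(["T1", "T2"], db, self.net())
        assert m.genes == ["A", "B", "C"]
        assert m.X[m.genes.index("B")].tolist() == [1, 1]

    def test_unannotated_gene_absent(self):
        db = AnnotationDatabase("X", {"T1": frozenset("AB"), "T2": frozenset("BC")})
        m = build_profile_matrix(["T1", "T2"], db, self.net())
        assert "D" not in m.genes

    def test_missing_term_errors(self):
        db = AnnotationDatabase("X", {"T1": frozenset("AB")})
        with pytest.raises(ValueError, match="missing"):
            build_profile_matrix(["T1", "T9"], db, self.net())

    def test_every_row_nonzero_enforced(self):
        with pytest.raises(ValueError, match="nonzero|annotated"):
            BinaryProfileMatrix(["g1"], ["t1"], np.zeros((1, 1)))


def stub_clusterer(fracs_by_k, n_disease, n_rows):
    """Build a clusterer whose max disease-gene cluster fraction at each k
    reproduces a prescribed trace; disease genes occupy the first rows."""

    def cluster(X, k, rng):
        labels = np.zeros(len(X), dtype=int)
        # spilled disease genes stay in cluster 0; filler rows cycle over all
        # labels so every cluster is nonempty
        for j, row in enumerate(range(n_disease, n_rows)):
            labels[row] = j % k
        n_in = round(fracs_by_k[k] * n_disease)
        labels[:n_in] = k - 1
        return labels

    return cluster


def make_matrix(n_disease, n_rows):
    genes = [f"D{i:03d}" for i in range(n_disease)] + [
        f"O{i:03d}" for i in range(n_rows - n_disease)
    ]
    X = np.ones((n_rows, 2), dtype=np.uint8)
    return BinaryProfileMatrix(genes, ["W1", "C1"], X), {f"D{i:03d}" for i in range(n_disease)}


class TestSelectK:
    def run(self, fracs_by_k, n_disease=32, n_rows=100, **cfg_kw):
        matrix, disease = make_matrix(n_disease, n_rows)
        cfg = RunConfig(rng_seed=0, **cfg_kw)
        return select_k(
            matrix, disease, cfg, clusterer=stub_clusterer(fracs_by_k, n_disease, n_rows)
        )

    def test_band_entry_after_full_cluster(self):
        sel = self.run({2: 1.0, 3: 27 / 32})
        assert sel.success and sel.k_max == 3
        assert sel.q == pytest.approx(27 / 32)

    def test_low_split_at_k2_fails(self):
        sel = self.run({2: 0.57, 3: 0.5}, n_disease=100, n_rows=200)
        assert not sel.success
        assert "failed" in sel.reason

    def test_k2_band_low_closed_acceptance(self):
        sel = self.run({2: 0.6}, n_disease=30, n_rows=60)
        assert sel.success and sel.k_max == 2 and sel.q == pytest.approx(0.6)

    def test_late_band_entry(self):
        sel = self.run({2: 1.0, 3: 0.931, 4: 0.931, 5: 25 / 29}, n_disease=29, n_rows=120)
        assert sel.success and sel.k_max == 5
        assert sel.q == pytest.approx(25 / 29)

    def test_drop_below_band_fails_without_search(self):
        sel = self.run({2: 1.0, 3: 0.5, 4: 0.8})
        assert not sel.success
        assert sel.trace == [(2, 1.0), (3, pytest.approx(0.5))]

    def test_k_cap_exhaustion_fails(self):
        sel = self.run({k: 1.0 for k in range(2, 25)}, k_cap=6)
        assert not sel.success and "no k" in sel.reason

    def test_selected_members_exclude_spilled_disease_genes(self):
        sel = self.run({2: 1.0, 3: 27 / 32})
        spilled = 32 - 27
        assert len(sel.members & {f"D{i:03d}" for i in range(32)}) == 27


class TestIntersectClusters:
    def sel(self, members, db="D1"):
        return ClusterSelection(db, True, k_max=2, q=0.8, members=frozenset(members))

    def test_basic_intersection(self):
        res = intersect_clusters(
            {"D1": self.sel("ABC"), "D2": self.sel("BCD", "D2")}, warm={"B"}
        )
        assert res.intersection == frozenset("BC")
        assert res.known == frozenset("B")
        assert res.putative == frozenset("C")

    def test_disjoint_clusters_valid_empty(self):
        res = intersect_clusters(
            {"D1": self.sel("AB"), "D2": self.sel("CD", "D2")}, warm=set()
        )
        assert res.putative == frozenset()

    def test_min_databases_gate(self):
        fail = ClusterSelection("D2", False, reason="clustering phase failed")
        with pytest.raises(MosesPhaseError, match="requires >= 2 databases"):
            intersect_clusters({"D1": self.sel("AB"), "D2": fail}, warm=set())


class TestRunMoses:
    def test_database_order_invariance(self, small_benchmark):
        net, dbs, disease, _ = small_benchmark
        cfg = RunConfig(rng_seed=7)
        a = run_moses(disease, net, dbs, cfg)
        b = run_moses(disease, net, list(reversed(dbs)), cfg)
        assert a.putative == b.putative

    def test_putative_never_contains_warm_seeds(self, small_benchmark):
        net, dbs, disease, _ = small_benchmark
        res = run_moses(disease, net, dbs, RunConfig(rng_seed=7))
        assert not res.putative & disease.genes

    def test_warm_and_cold_share_no_terms(self, small_benchmark):
        net, dbs, disease, _ = small_benchmark
        res = run_moses(disease, net, dbs, RunConfig(rng_seed=7))
        for name in res.ws_terms_by_db:
            assert not set(res.ws_terms_by_db[name]) & set(res.cold_terms_by_db[name])

    def test_selected_cluster_never_mixes_seed_types(self, small_benchmark):
        net, dbs, disease, _ = small_benchmark
        res = run_moses(disease, net, dbs, RunConfig(rng_seed=7))
        cold = res.cold_result.cold
        for sel in res.selections.values():
            if sel.success:
                has_warm = bool(sel.members & disease.genes)
                has_cold = bool(sel.members & cold)
                assert not (has_warm and has_cold)

    def test_min_databases_gate_with_single_database(self, small_benchmark):
        net, dbs, disease, _ = small_benchmark
        with pytest.raises(MosesPhaseError, match="requires >= 2"):
            run_moses(disease, net, dbs[:1], RunConfig(rng_seed=7))

    def test_duplicate_database_names_rejected(self, small_benchmark):
        net, dbs, disease, _ = small_benchmark
        with pytest.raises(ValueError, match="unique"):
            run_moses(disease, net, [dbs[0], dbs[0]], RunConfig(rng_seed=7))
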