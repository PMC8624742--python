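"""Binary-profile clustering and the three-phase pipeline driver.

Per database, the 2M selected terms (M warm + M cold) define the set J.
Every interactome gene annotated to at least one J term becomes a row of a
binary G_J x 2M membership matrix, which is clustered by k-means under the
Hamming (per-column mismatch fraction) distance.  k grows from 2 until the
largest disease-gene fraction first falls inside the acceptance band; the
per-database optimal clusters are then intersected into the putative gene
set PG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .cold_seeds import ColdSeedResult, characterize_cold, cold_seeds, peripheral_genes
from .enrichment import EnrichmentTable, enrich, significant_terms
from .io_model import (
    AnnotationDatabase,
    DiseaseGeneSet,
    Interactome,
    RunConfig,
    restrict_to_interactome,
)

__all__ = [
    "BinaryProfileMatrix",
    "HammingKMeans",
    "ClusterSelection",
    "MosesResult",
    "MosesPhaseError",
    "build_profile_matrix",
    "hamming_kmeans",
    "select_k",
    "intersect_clusters",
    "run_moses",
]


class MosesPhaseError(RuntimeError):
    """A pipeline phase could not produce its output for this disease."""

    def __init__(self, phase: str, reason: str) -> None:
        super().__init__(f"[{phase}] {reason}")
        self.phase = phase
        self.reason = reason


@dataclass
class BinaryProfileMatrix:
    """G_J genes (rows) x 2M terms (columns) membership indicators.

    Rows are exactly the interactome genes annotated to >= 1 term of J, in
    sorted order, so every row has at least one nonzero entry.
    """

    genes: list[str]
    terms: list[str]
    X: np.ndarray  # shape (len(genes), len(terms)), dtype uint8
    database: str = ""

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.uint8)
        if self.X.shape != (len(self.genes), len(self.terms)):
            raise ValueError("matrix shape does not match gene/term lists")
        if len(self.genes) and not (self.X.sum(axis=1) >= 1).all():
            raise ValueError("every G_J row must be annotated to >= 1 term of J")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_triplets(self, path: str | Path) -> None:
        """Write the nonzero entries as sparse (gene, term, 1) triplets."""
        with Path(path).open("w") as fh:
            fh.write("gene\tterm\tvalue\n")
            for i, j in zip(*np.nonzero(self.X)):
                fh.write(f"{self.genes[i]}\t{self.terms[j]}\t1\n")


def build_profile_matrix(
    terms_J: Sequence[str], db: AnnotationDatabase, net: Interactome
) -> BinaryProfileMatrix:
    """Build the G_J-by-2M matrix for one database's term set J."""
    missing = [t for t in terms_J if t not in db.terms]
    if missing:
        raise ValueError(f"terms missing from database {db.name!r}: {missing}")
    nodes = net.nodes
    members = [db.terms[t] & nodes for t in terms_J]
    g_j = sorted(set().union(*members)) if members else []
    idx = {g: i for i, g in enumerate(g_j)}
    X = np.zeros((len(g_j), len(terms_J)), dtype=np.uint8)
    for j, genes in enumerate(members):
        for g in genes:
            X[idx[g], j] = 1
    return BinaryProfileMatrix(g_j, list(terms_J), X, database=db.name)


# ---------------------------------------------------------------------------
# Hamming-distance k-means
# ---------------------------------------------------------------------------

def _hamming_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise per-column mismatch fraction, shape (n_rows, n_centers)."""
    Xf = X.astype(np.float64)
    Cf = centers.astype(np.float64)
    d = X.shape[1]
    # mismatches = x·(1-c) + (1-x)·c
    return (Xf @ (1.0 - Cf.T) + (1.0 - Xf) @ Cf.T) / d


class HammingKMeans(ClusterMixin, BaseEstimator):
    """k-means for binary data under the Hamming distance.

    Distance between a row and a center is the fraction of mismatching
    columns.  Centers are binary and updated by per-column majority vote
    over cluster members (exact ties resolve to 1, a fixed rule for
    bit-exact reruns).  Initialization is k-means++-style seeding adapted
    to the Hamming distance (squared-distance weighting); ``n_init``
    replicates are run to convergence and the one with the lowest total
    within-cluster distance wins, ties going to the lowest replicate index.
    Empty clusters are re-seeded with the row farthest from its center.

    Parameters
    ----------
    n_clusters : int, number of clusters k (k = 1 is permitted).
    n_init : int, number of random restarts (replicates).
    max_iter : int, iteration cap per replicate.
    random_state : int or numpy Generator, drives all randomness.

    Attributes
    ----------
    labels_ : (n_rows,) cluster assignment of the winning replicate.
    cluster_centers_ : (k, n_cols) binary centers.
    inertia_ : total within-cluster Hamming distance.
    n_iter_ : iterations used by the winning replicate.
    objective_path_ : per-iteration objective of the winning replicate
        (non-increasing unless an empty-cluster re-seed occurred).
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 50, max_iter: int = 100,
                 random_state: int | np.random.Generator | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _majority_center(rows: np.ndarray) -> np.ndarray:
        # ties (mean exactly 0.5) resolve to 1
        return (rows.mean(axis=0) >= 0.5).astype(np.uint8)

    def _plusplus_init(self, X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        n = X.shape[0]
        centers = np.empty((k, X.shape[1]), dtype=np.uint8)
        centers[0] = X[rng.integers(n)]
        d2 = _hamming_distances(X, centers[:1]).min(axis=1) ** 2
        for j in range(1, k):
            total = d2.sum()
            if total <= 0:
                centers[j] = X[rng.integers(n)]
            else:
                centers[j] = X[rng.choice(n, p=d2 / total)]
            d2 = np.minimum(d2, _hamming_distances(X, centers[j : j + 1])[:, 0] ** 2)
        return centers

    def _lloyd(self, X: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float, int, list[float], bool]:
        k = self.n_clusters
        centers = self._plusplus_init(X, k, rng)
        labels = np.full(X.shape[0], -1, dtype=np.int64)
        path: list[float] = []
        reseeded = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            D = _hamming_distances(X, centers)
            new_labels = D.argmin(axis=1)  # argmin takes the lowest label on ties
            mind = D[np.arange(X.shape[0]), new_labels]
            for c in range(k):  # re-seed empty clusters with the farthest row
                if not (new_labels == c).any():
                    reseeded = True
                    far = int(mind.argmax())
                    new_labels[far] = c
                    mind[far] = 0.0
            path.append(float(mind.sum()))
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = X[labels == c]
                if len(members):  # a re-seed can orphan a singleton cluster
                    centers[c] = self._majority_center(members)
        D = _hamming_distances(X, centers)
        inertia = float(D[np.arange(X.shape[0]), labels].sum())
        return labels, centers, inertia, n_iter, path, reseeded

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a nonempty 2-D array")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary (0/1)")
        X = X.astype(np.uint8)
        if not 1 <= self.n_clusters <= X.shape[0]:
            raise ValueError(f"n_clusters={self.n_clusters} not in [1, n_rows={X.shape[0]}]")
        if isinstance(self.random_state, np.random.Generator):
            rng = self.random_state
        else:
            rng = np.random.default_rng(self.random_state)
        best = None
        for rep in range(self.n_init):
            labels, centers, inertia, n_iter, path, reseeded = self._lloyd(X, rng)
            if best is None or inertia < best[2]:  # strict: ties keep lowest index
                best = (labels, centers, inertia, n_iter, path, reseeded)
        self.labels_, self.cluster_centers_, self.inertia_, self.n_iter_, self.objective_path_, self.reseeded_ = best
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=np.uint8)
        return _hamming_distances(X, self.cluster_centers_).argmin(axis=1)


def hamming_kmeans(
    matrix: BinaryProfileMatrix | np.ndarray,
    k: int,
    replicates: int = 50,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Replicated Hamming k-means; returns (labels, centers, objective)."""
    X = matrix.X if isinstance(matrix, BinaryProfileMatrix) else np.asarray(matrix)
    est = HammingKMeans(n_clusters=k, n_init=replicates, random_state=rng_seed).fit(X)
    return est.labels_, est.cluster_centers_, est.inertia_


# ---------------------------------------------------------------------------
# adaptive k selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterSelection:
    """Outcome of the adaptive-k loop for one database."""

    database: str
    success: bool
    k_max: int | None = None
    q: float | None = None
    cluster_label: int | None = None
    members: frozenset[str] = frozenset()
    labels: np.ndarray | None = None
    trace: list[tuple[int, float]] = field(default_factory=list)
    reason: str = ""


Clusterer = Callable[[np.ndarray, int, np.random.Generator], np.ndarray]


def _default_clusterer(cfg: RunConfig) -> Clusterer:
    def cluster(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        return HammingKMeans(
            n_clusters=k, n_init=cfg.replicates, max_iter=cfg.kmeans_max_iter,
            random_state=rng,
        ).fit(X).labels_
    return cluster


def _best_cluster(labels: np.ndarray, disease_idx: np.ndarray, k: int) -> tuple[int, float]:
    """Cluster with the largest disease-gene fraction.

    Ties by (more disease genes is equivalent), then smaller cluster size,
    then lowest label.
    """
    n_dis = len(disease_idx)
    best_label, best_frac, best_size = -1, -1.0, -1
    for c in range(k):
        cnt = int((labels[disease_idx] == c).sum())
        frac = cnt / n_dis
        size = int((labels == c).sum())
        if frac > best_frac or (frac == best_frac and size < best_size):
            best_label, best_frac, best_size = c, frac, size
    return best_label, best_frac


def select_k(
    matrix: BinaryProfileMatrix,
    disease_in_matrix: set[str],
    cfg: RunConfig,
    clusterer: Clusterer | None = None,
) -> ClusterSelection:
    """Grow k from 2 until the largest disease-gene fraction f(k) first
    falls inside the acceptance band (band_low, band_high).

    While f(k) >= band_high the loop continues; the first k with
    band_low < f(k) < band_high is accepted with q = f(k).  At k = 2 a
    fraction below band_high is accepted whenever f(2) >= band_low; for
    k > 2 a fraction at or below band_low is a failure (the loop does not
    search past the first drop), as is exceeding k_cap.  Failures are
    returned as a diagnosed no-cluster outcome, not raised.
    """
    if not disease_in_matrix:
        raise ValueError("no disease genes fall in the profile matrix")
    idx = matrix.row_index()
    missing = set(disease_in_matrix) - set(idx)
    if missing:
        raise ValueError(f"disease genes not in the matrix: {sorted(missing)}")
    disease_idx = np.array(sorted(idx[g] for g in disease_in_matrix), dtype=np.int64)
    if clusterer is None:
        clusterer = _default_clusterer(cfg)
    trace: list[tuple[int, float]] = []
    for k in range(2, min(cfg.k_cap, len(matrix.genes)) + 1):
        rng = np.random.default_rng([cfg.rng_seed, k])
        labels = np.asarray(clusterer(matrix.X, k, rng))
        label, f = _best_cluster(labels, disease_idx, k)
        trace.append((k, f))
        if f >= cfg.band_high:
            continue
        accept = f >= cfg.band_low if k == 2 else f > cfg.band_low
        if accept:
            members = frozenset(g for g, i in idx.items() if labels[i] == label)
            return ClusterSelection(
                matrix.database, True, k_max=k, q=f, cluster_label=int(label),
                members=members, labels=labels, trace=trace,
            )
        return ClusterSelection(
            matrix.database, False, trace=trace,
            reason=f"clustering phase failed: f({k}) = {f:.3f} outside the band "
                   f"({cfg.band_low:g}, {cfg.band_high:g})",
        )
    return ClusterSelection(
        matrix.database, False, trace=trace,
        reason=f"clustering phase failed: no k <= {cfg.k_cap} entered the band",
    )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class MosesResult:
    """Per-disease output: the optimal clusters, their intersection, and PG."""

    disease_id: str
    selections: dict[str, ClusterSelection]
    intersection: frozenset[str]
    known: frozenset[str]
    putative: frozenset[str]
    m_by_db: dict[str, int] = field(default_factory=dict)
    ws_terms_by_db: dict[str, list[str]] = field(default_factory=dict)
    cold_terms_by_db: dict[str, list[str]] = field(default_factory=dict)
    cold_result: ColdSeedResult | None = None
    warm_in_network: frozenset[str] = frozenset()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "putative_genes.txt").write_text("".join(f"{g}\n" for g in sorted(self.putative)))
        (outdir / "known_in_module.txt").write_text("".join(f"{g}\n" for g in sorted(self.known)))
        with (outdir / "provenance.tsv").open("w") as fh:
            fh.write("database\tM\tk_max\tq\tcluster_size\twarm_terms\tcold_terms\n")
            for name, sel in sorted(self.selections.items()):
                fh.write(
                    f"{name}\t{self.m_by_db.get(name, '')}\t{sel.k_max}\t"
                    f"{'' if sel.q is None else f'{sel.q:.4f}'}\t{len(sel.members)}\t"
                    f"{','.join(self.ws_terms_by_db.get(name, []))}\t"
                    f"{','.join(self.cold_terms_by_db.get(name, []))}\n"
                )
        if self.cold_result is not None:
            self.cold_result.trace.to_tsv(outdir / "expansion_trace.tsv")
            (outdir / "cold_seeds.txt").write_text(
                "".join(f"{g}\n" for g in sorted(self.cold_result.cold))
            )


def intersect_clusters(
    selections: Mapping[str, ClusterSelection],
    warm: set[str],
    min_databases: int = 2,
    disease_id: str = "",
) -> MosesResult:
    """Intersect the per-database optimal clusters into known + putative genes."""
    ok = {name: sel for name, sel in selections.items() if sel.success}
    if len(ok) < min_databases:
        raise MosesPhaseError(
            "integration",
            f"data integration requires >= {min_databases} databases; "
            f"{len(ok)} successful cluster selections available",
        )
    inter: frozenset[str] = frozenset.intersection(*(sel.members for sel in ok.values()))
    warm = set(warm)
    return MosesResult(
        disease_id=disease_id,
        selections=dict(selections),
        intersection=inter,
        known=frozenset(inter & warm),
        putative=frozenset(inter - warm),
    )


def _assert_no_seed_mixing(
    matrix: BinaryProfileMatrix, sel: ClusterSelection, warm: set[str], cold: set[str], M: int
) -> None:
    """Warm and cold seeds share no term of J by construction, so whenever
    the block-zero profile structure holds (warm rows zero on cold columns
    and vice versa) the optimal cluster cannot contain both seed types."""
    idx = matrix.row_index()
    warm_rows = [idx[g] for g in warm if g in idx]
    cold_rows = [idx[g] for g in cold if g in idx]
    if not warm_rows or not cold_rows:
        return
    block_zero = (
        not matrix.X[warm_rows, M:].any() and not matrix.X[cold_rows, :M].any()
    )
    if block_zero and (sel.members & set(warm)) and (sel.members & set(cold)):
        raise RuntimeError(
            f"optimal cluster of {sel.database or 'database'} mixes warm and cold "
            "seeds despite block-zero profiles"
        )


def run_moses(
    disease: DiseaseGeneSet,
    net: Interactome,
    dbs: Sequence[AnnotationDatabase],
    cfg: RunConfig = RunConfig(),
) -> MosesResult:
    """The full three-phase pipeline for one disease.

    Phase 1: warm-seed enrichment per database; keep databases with M >= 2
    significant terms.  Phase 2: peripheral genes by neighbour absorption,
    cold seeds by functional exclusion, cold top-M terms per retained
    database.  Phase 3: per-database profile matrix and adaptive-k
    clustering, then intersection into the putative gene set.
    """
    names = [db.name for db in dbs]
    if len(set(names)) != len(names):
        raise ValueError("database names must be unique")
    dbs = sorted(dbs, key=lambda d: d.name)  # PG invariant to input order

    warm_all = set(disease.genes)
    warm_net = warm_all & net.nodes
    if not warm_net:
        raise MosesPhaseError("input", "no warm seed is present in the interactome")

    # phase 1 -- warm-seed functional characterization, M >= 2 gate
    restricted = [  # keep G_J inside the interactome
        d for d in (restrict_to_interactome(db, net) for db in dbs) if len(d)
    ]
    backgrounds = {db.name: db.genes() for db in restricted}
    ws_terms: dict[str, list[str]] = {}
    warm_tables: dict[str, EnrichmentTable] = {}
    retained: list[AnnotationDatabase] = []
    for db in restricted:
        query = warm_all & backgrounds[db.name]
        if not query:
            continue
        table = enrich(query, db, backgrounds[db.name])
        terms = significant_terms(table, cfg.alpha, cfg.use_adjusted)
        if len(terms) >= 2:
            ws_terms[db.name] = terms
            warm_tables[db.name] = table
            retained.append(db)
    if len(retained) < cfg.min_databases:
        raise MosesPhaseError(
            "warm enrichment",
            f"data integration requires >= {cfg.min_databases} databases with M >= 2; "
            f"{len(retained)} retained",
        )

    # phase 2 -- peripheral genes, cold seeds, cold characterization
    trace = peripheral_genes(net, warm_net, cfg.stop_ratio)
    peripheral = trace.peripheral
    cold = cold_seeds(peripheral, ws_terms, retained)
    if not cold:
        raise MosesPhaseError("cold seeds", "functional exclusion left no cold seeds")
    cold_terms: dict[str, list[str]] = {}
    for db in retained:
        try:
            terms, _ = characterize_cold(cold, db, len(ws_terms[db.name]), backgrounds[db.name])
        except ValueError as exc:
            raise MosesPhaseError("cold enrichment", str(exc)) from exc
        cold_terms[db.name] = terms
    cold_result = ColdSeedResult(
        peripheral=peripheral,
        cold=cold,
        excluded_by_function=len(peripheral) - len(cold),
        trace=trace,
        cold_terms_by_db=cold_terms,
    )

    # phase 3 -- per-database clustering and integration
    selections: dict[str, ClusterSelection] = {}
    for db in retained:
        J = ws_terms[db.name] + cold_terms[db.name]
        matrix = build_profile_matrix(J, db, net)
        disease_in_matrix = warm_all & set(matrix.genes)
        if not disease_in_matrix:
            selections[db.name] = ClusterSelection(
                db.name, False, reason="no disease genes in the profile matrix"
            )
            continue
        sel = select_k(matrix, disease_in_matrix, cfg)
        if sel.success:
            _assert_no_seed_mixing(matrix, sel, warm_all, cold, len(ws_terms[db.name]))
        selections[db.name] = sel

    result = intersect_clusters(selections, warm_all, cfg.min_databases, disease.disease_id)
    result.m_by_db = {name: len(ts) for name, ts in ws_terms.items()}
    result.ws_terms_by_db = ws_terms
    result.cold_terms_by_db = cold_terms
    result.cold_result = cold_result
    result.warm_in_network = frozenset(warm_net)
    return result
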