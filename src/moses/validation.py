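"""Validation machinery: cross-validation against a random-walk baseline
and disease-module connectivity against a random-gene null.

The 10-fold cross-validation hides one tenth of the warm seeds, runs the
pipeline on the rest, and scores the fraction of hidden seeds recovered
among the putative genes; the same training seeds drive a random walk with
restart whose top-|PG| ranked genes give the baseline recovery.  Module
significance compares the largest connected component of warm + putative
genes with the 95th percentile of LCC sizes over random same-size modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import t as t_dist

from .clustering import MosesPhaseError, run_moses
from .io_model import AnnotationDatabase, DiseaseGeneSet, Interactome, RunConfig

__all__ = [
    "CVRecord",
    "CVResult",
    "ModuleStats",
    "kfold_split",
    "rwr",
    "rwr_topn",
    "paired_t",
    "cross_validate",
    "module_lcc",
    "random_module_null",
    "module_stats",
]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVRecord:
    disease_id: str
    fold: int
    train: frozenset[str]
    probe: frozenset[str]
    n_putative: int | None
    moses_recovery: float | None  # percent, None when the pipeline failed
    rwr_recovery: float | None
    failure_reason: str = ""


@dataclass
class CVResult:
    records: list[CVRecord]
    t_stat: float
    p_value: float
    n_pairs: int
    n_failed_folds: int
    degenerate: bool = False  # zero variance of the paired differences

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "disease": r.disease_id,
                    "fold": r.fold,
                    "train_size": len(r.train),
                    "probe_size": len(r.probe),
                    "n_putative": r.n_putative,
                    "moses_recovery_pct": r.moses_recovery,
                    "rwr_recovery_pct": r.rwr_recovery,
                    "failure": r.failure_reason,
                }
                for r in self.records
            ]
        )


def kfold_split(
    genes: set[str], folds: int = 10, rng_seed: int = 0
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Random partition into ``folds`` probe sets of near-equal size
    (differing by at most one); returns (train, probe) pairs."""
    genes = sorted(genes)
    if folds > len(genes):
        raise ValueError(f"folds={folds} exceeds the number of genes ({len(genes)})")
    rng = np.random.default_rng(rng_seed)
    order = np.array(genes, dtype=object)
    rng.shuffle(order)
    out = []
    for chunk in np.array_split(order, folds):
        probe = frozenset(chunk.tolist())
        out.append((frozenset(genes) - probe, probe))
    return out


def rwr(
    net: Interactome,
    seeds: set[str],
    r: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> pd.Series:
    """Random walk with restart: iterate p <- (1-r)·W·p + r·p0 to its
    stationary distribution.

    W is the column-normalized adjacency matrix and p0 is uniform over the
    seeds.  Mass on dangling (degree-zero) nodes is redistributed to the
    restart vector so the scores keep summing to one.
    """
    if not seeds:
        raise ValueError("empty seed set")
    if not 0 < r <= 1:
        raise ValueError("restart probability must be in (0, 1]")
    missing = set(seeds) - net.nodes
    if missing:
        raise ValueError(f"seeds not in the interactome: {sorted(missing)}")
    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    A = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, dtype=float, format="csc")
    deg = np.asarray(A.sum(axis=0)).ravel()
    dangling = deg == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    W = A @ sparse.diags(inv)
    p0 = np.zeros(len(nodes))
    for g in seeds:
        p0[index[g]] = 1.0 / len(seeds)
    p = p0.copy()
    for _ in range(max_iter):
        lost = p[dangling].sum()
        p_new = (1.0 - r) * (W @ p + lost * p0) + r * p0
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return pd.Series(p, index=nodes, name="rwr_score")


def rwr_topn(scores: pd.Series, exclude: set[str], n: int) -> frozenset[str]:
    """Top-n genes by descending score, ties broken by gene id, with the
    excluded set (typically the training seeds) removed first."""
    if n < 0:
        raise ValueError("n must be >= 0")
    candidates = scores.drop(labels=[g for g in exclude if g in scores.index])
    ordered = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    return frozenset(g for g, _ in ordered[:n])


def paired_t(differences: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided paired t-test from per-pair differences.

    t = mean(d) / (sd(d)/sqrt(n)), d.f. = n - 1.  Zero variance is
    degenerate: t = 0, p = 1 when the mean is also zero, otherwise t is
    signed infinite with p = 0, both flagged.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, mean), 0.0, True
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t), n - 1))
    return float(t), p, False


def cross_validate(
    disease: DiseaseGeneSet,
    net: Interactome,
    dbs: Sequence[AnnotationDatabase],
    cfg: RunConfig = RunConfig(),
    folds: int = 10,
) -> CVResult:
    """k-fold recovery of held-out warm seeds, pipeline vs RWR baseline.

    Per fold the pipeline runs on the training seeds; the baseline ranks
    genes by RWR from the same training seeds (training seeds excluded from
    the ranking) and is cut at that fold's |PG|.  Both are scored as the
    percentage of probe genes recovered.  Folds where the pipeline fails
    are recorded with a missing recovery and excluded from the pairing.
    """
    splits = kfold_split(set(disease.genes), folds, cfg.rng_seed)
    records: list[CVRecord] = []
    diffs: list[float] = []
    n_failed = 0
    for i, (train, probe) in enumerate(splits, start=1):
        train_net = train & net.nodes
        rec = CVRecord(disease.disease_id, i, train, probe, None, None, None)
        try:
            result = run_moses(DiseaseGeneSet(disease.disease_id, train), net, dbs, cfg)
        except MosesPhaseError as exc:
            n_failed += 1
            rec.failure_reason = str(exc)
            records.append(rec)
            continue
        pg = result.putative
        rec.n_putative = len(pg)
        rec.moses_recovery = 100.0 * len(pg & probe) / len(probe)
        scores = rwr(net, train_net, cfg.rwr_restart, cfg.rwr_tol, cfg.rwr_max_iter)
        baseline = rwr_topn(scores, train, len(pg))
        rec.rwr_recovery = 100.0 * len(baseline & probe) / len(probe)
        diffs.append(rec.moses_recovery - rec.rwr_recovery)
        records.append(rec)
    if len(diffs) >= 2:
        t, p, degenerate = paired_t(diffs)
    else:
        t, p, degenerate = math.nan, math.nan, True
    return CVResult(records, t, p, len(diffs), n_failed, degenerate)


# ---------------------------------------------------------------------------
# disease-module topology
# ---------------------------------------------------------------------------

def module_lcc(net: Interactome, genes: set[str]) -> tuple[int, frozenset[str]]:
    """Size and members of the largest connected component of the subgraph
    induced by ``genes``.

    Genes absent from the interactome count as isolated singletons.  Ties
    between equal-size components go to the one containing the lowest gene
    id.
    """
    genes = set(genes)
    if not genes:
        return 0, frozenset()
    present = genes & net.nodes
    components = [set(c) for c in nx.connected_components(net.graph.subgraph(present))]
    components.extend({g} for g in genes - net.nodes)
    # deterministic tie-break: largest size, then lowest minimum member
    best = sorted(components, key=lambda c: (-len(c), min(c)))[0]
    return len(best), frozenset(best)


def _lcc_size(adj: dict[str, set[str]], genes: set[str]) -> int:
    """Union-find LCC size over an induced node subset (absent genes are
    singletons); fast path for the permutation null."""
    idx = {g: i for i, g in enumerate(genes)}
    parent = list(range(len(idx)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g, i in idx.items():
        for nb in adj.get(g, ()):  # absent genes have no adjacency entry
            j = idx.get(nb)
            if j is not None and j > i:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    sizes: dict[int, int] = {}
    for i in range(len(idx)):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) if sizes else 0


@dataclass
class ModuleStats:
    """LCC of the predicted disease module against the random-gene null."""

    lcc_ws: int
    lcc_ws_pg: int
    ws_in_lcc: int
    null_sizes: np.ndarray
    threshold: int
    significant: bool
    fewer_warm_in_extended: bool = False  # warm seeds in extended LCC < |LCC_WS|

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lcc_ws": self.lcc_ws,
                    "lcc_ws_pg": self.lcc_ws_pg,
                    "ws_in_lcc_ws_pg": self.ws_in_lcc,
                    "null_p95": self.threshold,
                    "significant": self.significant,
                }
            ]
        )


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values))
    rank = max(1, math.ceil(pct / 100.0 * v.size))
    return v[rank - 1]


def random_module_null(
    net: Interactome,
    warm: set[str],
    n_random: int,
    reps: int = 1000,
    rng_seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null distribution of |LCC(warm ∪ RG)| over ``reps`` uniform draws of
    n_random genes from the interactome excluding the warm seeds; returns
    the sizes and their 95th percentile (nearest rank)."""
    warm = set(warm)
    candidates = np.array(sorted(net.nodes - warm), dtype=object)
    if n_random > candidates.size:
        raise ValueError(
            f"n_random={n_random} exceeds the {candidates.size} non-seed interactome genes"
        )
    rng = np.random.default_rng(rng_seed)
    adj = net.adjacency()
    sizes = np.empty(reps, dtype=np.int64)
    for rep in range(reps):
        draw = rng.choice(candidates, size=n_random, replace=False)
        sizes[rep] = _lcc_size(adj, warm | set(draw.tolist()))
    return sizes, nearest_rank_percentile(sizes, 95.0)


def module_stats(
    net: Interactome,
    warm: set[str],
    putative: set[str],
    reps: int = 1000,
    rng_seed: int = 0,
) -> ModuleStats:
    """Compare the warm+putative module LCC with the random-gene null.

    Significance is strict: |LCC_WS+PG| must exceed the 95th-percentile
    threshold of the null sizes.
    """
    warm = set(warm)
    putative = set(putative) - warm
    lcc_ws, _ = module_lcc(net, warm)
    lcc_ws_pg, members = module_lcc(net, warm | putative)
    assert lcc_ws_pg >= lcc_ws, "LCC cannot shrink under a superset"
    ws_in = len(members & warm)
    null_sizes, threshold = random_module_null(net, warm, len(putative), reps, rng_seed)
    return ModuleStats(
        lcc_ws=lcc_ws,
        lcc_ws_pg=lcc_ws_pg,
        ws_in_lcc=ws_in,
        null_sizes=null_sizes,
        threshold=int(threshold),
        significant=bool(lcc_ws_pg > threshold),
        fewer_warm_in_extended=ws_in < lcc_ws,
    )
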