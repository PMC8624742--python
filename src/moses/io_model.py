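"""Core domain types and readers/writers.

The tool works on four plain-text formats: a two-column edge list for the
interactome, GMT files for annotation databases, an optional GAF-like TSV
(gene, term, evidence, qualifier) and one-symbol-per-line disease gene
lists.  Gene identity is the symbol string after case normalization
(uppercase by default); no identifier mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "AnnotationDatabase",
    "DiseaseGeneSet",
    "RunConfig",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gaf_tsv",
    "filter_gaf_annotations",
    "read_disease_genes",
    "restrict_to_interactome",
    "filter_disease_size",
    "load_config",
]


def normalize_symbol(symbol: str, symbol_case: str = "upper") -> str:
    s = symbol.strip()
    if symbol_case == "upper":
        return s.upper()
    if symbol_case == "asis":
        return s
    raise ValueError(f"unknown symbol_case {symbol_case!r} (expected 'upper' or 'asis')")


class Interactome:
    """Undirected simple graph over gene symbols.

    Self-loops and duplicate (unordered) edges are dropped at construction,
    with counts kept for the load summary.  The node set is the union of
    edge endpoints plus any explicitly declared isolated nodes.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        symbol_case: str = "upper",
    ) -> None:
        g = nx.Graph()
        self.n_self_loops_dropped = 0
        self.n_duplicates_dropped = 0
        for a, b in edges:
            a = normalize_symbol(a, symbol_case)
            b = normalize_symbol(b, symbol_case)
            if a == b:
                self.n_self_loops_dropped += 1
                continue
            if g.has_edge(a, b):
                self.n_duplicates_dropped += 1
                continue
            g.add_edge(a, b)
        for n in nodes:
            g.add_node(normalize_symbol(n, symbol_case))
        if g.number_of_nodes() == 0:
            raise ValueError("interactome has no genes")
        self.graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_genes(self) -> int:
        """N, the number of genes in the interactome."""
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def adjacency(self) -> dict[str, set[str]]:
        """Plain adjacency-set map, handy for tight inner loops."""
        return {n: set(nbrs) for n, nbrs in self.graph.adjacency()}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __repr__(self) -> str:
        return f"Interactome(N={self.n_genes}, edges={self.n_edges})"


@dataclass
class AnnotationDatabase:
    """Named map term-id -> (description, gene set); e.g. GO-BP or KEGG."""

    name: str
    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} in database {self.name!r} has an empty gene set")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs
        return out

    def description(self, term: str) -> str:
        return self.descriptions.get(term, "")

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:
        return f"AnnotationDatabase({self.name!r}, terms={len(self.terms)})"


@dataclass(frozen=True)
class DiseaseGeneSet:
    """A disease and its known disease genes (warm seeds, S0; P = |S0|)."""

    disease_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease {self.disease_id!r} has no genes")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the pipeline.

    alpha            significance threshold on the enrichment q-values
    use_adjusted     test FDR-adjusted values (default) or raw p-values
    stop_ratio       peripheral search stops once P/|NS| >= stop_ratio
    band_low/high    acceptance band for the disease-gene cluster fraction
    replicates       k-means restarts per k
    kmeans_max_iter  iteration cap per k-means replicate
    k_cap            largest k tried by the adaptive loop
    min_databases    databases (with M >= 2) required for integration
    rwr_restart      restart probability r of the random walk baseline
    """

    alpha: float = 0.05
    use_adjusted: bool = True
    stop_ratio: float = 0.1
    band_low: float = 0.6
    band_high: float = 0.9
    replicates: int = 50
    kmeans_max_iter: int = 100
    k_cap: int = 20
    min_databases: int = 2
    rwr_restart: float = 0.7
    rwr_tol: float = 1e-6
    rwr_max_iter: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.stop_ratio <= 0:
            raise ValueError("stop_ratio must be positive")
        if not 0 <= self.band_low < self.band_high <= 1:
            raise ValueError("need 0 <= band_low < band_high <= 1")
        if self.replicates < 1 or self.k_cap < 2 or self.min_databases < 1:
            raise ValueError("replicates >= 1, k_cap >= 2, min_databases >= 1 required")
        if not 0 < self.rwr_restart <= 1:
            raise ValueError("rwr_restart must be in (0, 1]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    symbol_case: str = "upper",
    node_list: str | Path | None = None,
) -> Interactome:
    """Load an interactome from a whitespace/tab-delimited two-column file.

    Lines must carry at least two symbol columns (extra columns are
    ignored).  Self-loops and duplicate unordered pairs are dropped and
    counted.  ``node_list`` optionally declares isolated nodes, one symbol
    per line.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    isolated: list[str] = []
    if node_list is not None:
        isolated = [
            ln.strip() for ln in Path(node_list).read_text().splitlines() if ln.strip()
        ]
    net = Interactome(edges, nodes=isolated, symbol_case=symbol_case)
    logger.info(
        "loaded %s: N=%d genes, %d edges (%d self-loops, %d duplicates dropped)",
        path, net.n_genes, net.n_edges,
        net.n_self_loops_dropped, net.n_duplicates_dropped,
    )
    return net


def write_edge_list(net: Interactome, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in sorted(tuple(sorted(edge)) for edge in net.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


def read_gmt(path: str | Path, name: str | None = None, symbol_case: str = "upper") -> AnnotationDatabase:
    """Read an MSigDB-dialect GMT file: term <TAB> description <TAB> genes...

    Terms with no genes are dropped with a warning; a duplicated term id is
    an error.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected term and description columns")
            term, desc = parts[0], parts[1]
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            genes = frozenset(
                normalize_symbol(g, symbol_case) for g in parts[2:] if g.strip()
            )
            if not genes:
                logger.warning("%s:%d: term %r has no genes, dropped", path, lineno, term)
                continue
            terms[term] = genes
            descriptions[term] = desc
    return AnnotationDatabase(name or path.stem, terms, descriptions)


def write_gmt(db: AnnotationDatabase, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(db.terms):
            genes = "\t".join(sorted(db.terms[term]))
            fh.write(f"{term}\t{db.description(term)}\t{genes}\n")


def filter_gaf_annotations(
    records: Iterable[tuple[str, str, str, str]],
    name: str = "GAF",
    symbol_case: str = "upper",
) -> AnnotationDatabase:
    """Aggregate (gene, term, evidence, qualifier) records into a database.

    Records with evidence code IPI (inferred from physical interaction,
    excluded to avoid circularity with the interactome) and records whose
    qualifier contains NOT are removed.  No upward propagation over any
    ontology graph is performed.
    """
    terms: dict[str, set[str]] = {}
    for gene, term, evidence, qualifier in records:
        if evidence.strip().upper() == "IPI":
            continue
        if "NOT" in qualifier.strip().upper().split("|"):
            continue
        terms.setdefault(term, set()).add(normalize_symbol(gene, symbol_case))
    if not terms:
        logger.warning("GAF filtering left no annotations")
    return AnnotationDatabase(name, {t: frozenset(g) for t, g in terms.items()})


def read_gaf_tsv(path: str | Path, name: str | None = None, symbol_case: str = "upper") -> AnnotationDatabase:
    """Read a GAF-like TSV with columns gene, term, evidence, qualifier."""
    path = Path(path)

    def records() -> Iterator[tuple[str, str, str, str]]:
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected gene, term, evidence[, qualifier]")
                qualifier = parts[3] if len(parts) > 3 else ""
                yield parts[0], parts[1], parts[2], qualifier

    return filter_gaf_annotations(records(), name=name or path.stem, symbol_case=symbol_case)


def read_disease_genes(
    path: str | Path, disease_id: str | None = None, symbol_case: str = "upper"
) -> DiseaseGeneSet:
    path = Path(path)
    genes = frozenset(
        normalize_symbol(ln, symbol_case)
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    )
    return DiseaseGeneSet(disease_id or path.stem, genes)


def restrict_to_interactome(db: AnnotationDatabase, net: Interactome) -> AnnotationDatabase:
    """Intersect every term's gene set with the interactome; drop emptied terms."""
    nodes = net.nodes
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for term, genes in db.terms.items():
        kept = genes & nodes
        if kept:
            terms[term] = frozenset(kept)
            descriptions[term] = db.description(term)
    return AnnotationDatabase(db.name, terms, descriptions)


def filter_disease_size(
    diseases: Sequence[DiseaseGeneSet], low: int = 25, high: int = 150
) -> list[DiseaseGeneSet]:
    """Keep diseases with low < P < high (open interval on both ends)."""
    if low >= high:
        raise ValueError("low must be < high")
    return [d for d in diseases if low < d.size < high]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML file whose keys mirror RunConfig fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of config fields")
    valid = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    return RunConfig(**data)
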