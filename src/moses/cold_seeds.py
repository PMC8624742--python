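"""Cold-seed identification.

Cold seeds are genes doubly distant from the known disease genes: far on
the interactome (they survive the iterative first-neighbour absorption
until the stopping ratio is reached) and functionally unrelated (annotated
to none of the warm seeds' significant terms in any retained database).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .enrichment import EnrichmentTable, enrich, top_m_terms
from .io_model import AnnotationDatabase, Interactome

__all__ = [
    "ExpansionTrace",
    "ColdSeedResult",
    "peripheral_genes",
    "cold_seeds",
    "characterize_cold",
]


@dataclass
class ExpansionTrace:
    """Record of the iterative neighbour-absorption search.

    ``rows`` holds one (iteration, |S_i|, |NS_i|, |FN_i|, ratio) tuple per
    iteration, where ratio = P/|NS_i| is checked before absorbing the
    first-neighbour layer FN_i.  ``disconnected_remainder`` flags the case
    where expansion exhausted the warm seeds' component before the ratio
    was reached.
    """

    rows: list[tuple[int, int, int, int, float]]
    peripheral: frozenset[str]
    disconnected_remainder: bool = False

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("iteration\tS\tNS\tFN\tratio\n")
            for i, s, ns, fn, ratio in self.rows:
                fh.write(f"{i}\t{s}\t{ns}\t{fn}\t{ratio:.6g}\n")


@dataclass
class ColdSeedResult:
    peripheral: frozenset[str]
    cold: frozenset[str]
    excluded_by_function: int
    trace: ExpansionTrace
    cold_terms_by_db: dict[str, list[str]] = field(default_factory=dict)


def peripheral_genes(net: Interactome, warm: set[str], stop_ratio: float = 0.1) -> ExpansionTrace:
    """Absorb whole first-neighbour layers of the warm seeds until the
    ratio P/|NS| reaches ``stop_ratio``; the remaining non-seed set is the
    peripheral gene set.

    The ratio is checked before each absorption.  If the expansion runs out
    of reachable neighbours while the ratio is still below the threshold
    (warm seeds confined to a small component), the remaining NS is
    returned with ``disconnected_remainder`` set.
    """
    warm = set(warm)
    if not warm:
        raise ValueError("warm seed set is empty")
    missing = warm - net.nodes
    if missing:
        raise ValueError(f"warm seeds not in the interactome: {sorted(missing)}")
    P = len(warm)
    adj = net.adjacency()
    S = set(warm)
    NS = net.nodes - S
    frontier = set(S)  # nodes whose neighbours have not been scanned yet
    rows: list[tuple[int, int, int, int, float]] = []
    disconnected = False
    i = 0
    while True:
        i += 1
        ratio = P / len(NS) if NS else float("inf")
        if ratio >= stop_ratio:
            rows.append((i, len(S), len(NS), 0, ratio))
            break
        FN = set()
        for g in frontier:
            FN |= adj[g]
        FN &= NS
        rows.append((i, len(S), len(NS), len(FN), ratio))
        if not FN:
            disconnected = True
            break
        S |= FN
        NS -= FN
        frontier = FN
    return ExpansionTrace(rows, frozenset(NS), disconnected)


def cold_seeds(
    peripheral: set[str],
    ws_terms_by_db: Mapping[str, Sequence[str]],
    dbs: Sequence[AnnotationDatabase],
) -> frozenset[str]:
    """Peripheral genes annotated to none of the warm seeds' significant
    terms, pooled across all retained databases.  Unannotated peripheral
    genes are kept."""
    by_name = {db.name: db for db in dbs}
    excluded: set[str] = set()
    for db_name, terms in ws_terms_by_db.items():
        db = by_name[db_name]
        for term in terms:
            excluded |= db.terms.get(term, frozenset())
    return frozenset(set(peripheral) - excluded)


def characterize_cold(
    cold: set[str],
    db: AnnotationDatabase,
    M: int,
    background: set[str],
) -> tuple[list[str], EnrichmentTable]:
    """Top-M enrichment terms of the cold seeds in one database.

    M matches the warm-seed characterization of the same database, so each
    database contributes a 2M-term set J.  Warm-seed significant terms can
    never be returned: cold seeds have zero overlap with them by
    construction and zero-overlap rows are excluded from top-M selection.
    """
    query = set(cold) & set(background)
    if not query:
        raise ValueError(f"no cold seeds are annotated in database {db.name!r}")
    table = enrich(query, db, background)
    return top_m_terms(table, M), table
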