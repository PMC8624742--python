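"""Hypergeometric over-representation analysis with FDR control.

A query gene set (warm or cold seeds) is tested against every term of an
annotation database by the exact hypergeometric upper tail, adjusted across
the database's terms by the Benjamini-Hochberg step-up procedure.  The M
terms selected per database (significant ones for warm seeds, the top-M
for cold seeds) feed the clustering phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import AnnotationDatabase

__all__ = [
    "EnrichmentTable",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "significant_terms",
    "top_m_terms",
]

#: columns of the serialized table, in order
TABLE_COLUMNS = ["term", "description", "k", "K", "n", "Nbg", "p", "q"]


@dataclass
class EnrichmentTable:
    """Per-term enrichment results for one database.

    Rows are sorted by ascending p, ties broken by ascending q then by term
    id, so that top-M selection is total and deterministic.
    """

    database: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hypergeom_upper_tail(k: int, K: int, n: int, Nbg: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(Nbg, K, n).

    k: observed overlap, K: term size, n: query size, Nbg: background size.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > Nbg or n > Nbg:
        raise ValueError(f"need K <= Nbg and n <= Nbg; got K={K}, n={n}, Nbg={Nbg}")
    return float(hypergeom.sf(k - 1, Nbg, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query: set[str], db: AnnotationDatabase, background: set[str]) -> EnrichmentTable:
    """Over-representation of ``query`` in every term of ``db``.

    The background is the gene universe the draw is taken from (by default
    in the pipeline: all interactome genes annotated in the database).  The
    q-values are adjusted over all tested terms of the database.
    """
    if not query:
        raise ValueError("empty query gene set")
    query = set(query)
    background = set(background)
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise ValueError(f"query is not a subset of the background (e.g. {missing})")
    nbg = len(background)
    nq = len(query)
    rows = []
    for term, genes in db.terms.items():
        genes = genes & background
        if not genes:
            continue
        k = len(genes & query)
        K = len(genes)
        rows.append((term, db.description(term), k, K, nq, nbg, hypergeom_upper_tail(k, K, nq, nbg)))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS[:-1])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df = df.sort_values(["p", "q", "term"], kind="mergesort").reset_index(drop=True)
    return EnrichmentTable(db.name, df)


def significant_terms(
    table: EnrichmentTable, alpha: float, use_adjusted: bool = True
) -> list[str]:
    """Terms below the significance threshold, in table order.

    The caller applies the M >= 2 gate: a database contributes to the
    downstream integration only when it yields at least two such terms.
    """
    col = "q" if use_adjusted else "p"
    mask = table.table[col] < alpha
    return table.table.loc[mask, "term"].tolist()


def top_m_terms(table: EnrichmentTable, M: int) -> list[str]:
    """First M terms by the table's sort order among rows with overlap >= 1."""
    hit = table.table[table.table["k"] >= 1]
    if len(hit) < M:
        raise ValueError(
            f"insufficient cold-seed annotations in {table.database!r}: "
            f"{len(hit)} terms with overlap >= 1, need {M}"
        )
    return hit["term"].head(M).tolist()
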