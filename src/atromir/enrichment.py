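"""Over-representation analysis of a gene list against a gene-set collection.

A local replacement for web-based annotation tools: for each term, the overlap
between the query list and the term's members (both intersected with the
expression universe) is scored with the exact hypergeometric upper-tail
probability, adjusted across terms with Benjamini-Hochberg, and the top terms
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentRow", "hypergeom_tail", "enrich"]


@dataclass
class EnrichmentRow:
    term: str
    term_name: str
    K: int          # annotated genes in universe
    n: int          # query size (in universe)
    k: int          # overlap
    p_hyper: float
    p_bh: float
    overlap: tuple[str, ...]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    top: int = 10,
) -> tuple[list[EnrichmentRow], list[EnrichmentRow]]:
    """Hypergeometric over-representation with BH adjustment.

    Gene symbols are matched case-insensitively (uppercased).  Terms with no
    annotated gene in the universe, or no overlap with the query, are not
    tested.  Returns (top rows, all tested rows), both sorted by raw p
    ascending with ties broken by term id.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {g.upper() for g in query} & universe
    N, n = len(universe), len(query)
    rows: list[EnrichmentRow] = []
    for term, (name, members) in sorted(collection.items()):
        members_u = members & universe
        K = len(members_u)
        if K == 0:
            continue
        overlap = tuple(sorted(query & members_u))
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        rows.append(EnrichmentRow(term, name, K, n, k, p, 1.0, overlap))
    if rows:
        _, p_bh, _, _ = multipletests([r.p_hyper for r in rows], method="fdr_bh")
        for r, q in zip(rows, p_bh):
            r.p_bh = float(q)
    rows.sort(key=lambda r: (r.p_hyper, r.term))
    return rows[:top], rows
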