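"""Local Fisher-exact gene-set enrichment with BH adjustment.

The background universe is the set of all interactome/network genes, and the
2x2 table for each term counts query membership against term membership
within that background. Terms with no gene in the background are skipped.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io_formats import GeneSetCollection
from .stats import bh_adjust, fisher_enrichment_p

logger = logging.getLogger(__name__)


def fisher_enrichment(
    query: list[str],
    background: set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a gene list against a gene-set library.

    Returns a table ranked by (adjusted_p, p_value, term_id) with columns
    term_id, term_name, overlap, p_value, adjusted_p, rank. Query genes
    outside the background are dropped with a warning.
    """
    if not background:
        raise ValueError("background is empty")
    q = {g.upper() for g in query}
    outside = q - background
    if outside:
        logger.warning("%d query genes outside background dropped", len(outside))
        q &= background
    if not q:
        raise ValueError("query is empty after background filtering")
    rows = []
    for term_id in sorted(sets.terms):
        name, genes = sets.terms[term_id]
        term_bg = genes & background
        if not term_bg:
            continue
        overlap = sorted(q & term_bg)
        a = len(overlap)
        b = len(q) - a
        c = len(term_bg) - a
        d = len(background) - a - b - c
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "overlap": tuple(overlap),
                "p_value": fisher_enrichment_p(a, b, c, d),
            }
        )
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "overlap", "p_value"])
    if table.empty:
        table["adjusted_p"] = []
        table["rank"] = []
        return table
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        ["adjusted_p", "p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    return table


def top_terms(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """First k rows of a ranked enrichment table."""
    if k <= 0:
        raise ValueError("k must be >= 1")
    return table.head(k).copy()
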