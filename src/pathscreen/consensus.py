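"""Cross-screen consensus: harmonized favorability, aggregate coefficients,
and shared gene / shared term reports.

Screens disagree on which coefficient sign is "favorable" (negative only for
the in silico phagocytosis screen), so consensus first maps each screen's
coefficients onto favorable/unfavorable gene sets via its sign convention,
then aggregates per-gene effect magnitudes as the mean of absolute
coefficients across screens, rounded half-to-even to 4 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .regression import CoefficientTable

logger = logging.getLogger(__name__)


@dataclass
class SharedGeneReport:
    favorable_shared: set[str]
    unfavorable_shared: set[str]
    reference_favorable: set[str] | None
    reference_unfavorable: set[str] | None
    venn_counts: dict[str, dict[tuple[str, ...], int]]


def harmonize_favorability(
    coeff_tables: dict[str, CoefficientTable],
    conventions: dict[str, int],
) -> dict[str, dict[str, set[str]]]:
    """Per-screen favorable/unfavorable gene sets by coefficient sign.

    favorable(screen) = genes whose coefficient sign equals that screen's
    favorable_sign; zero coefficients belong to neither set.
    """
    unknown = set(conventions) - set(coeff_tables)
    if unknown:
        raise ValueError(f"conventions name unknown screens: {sorted(unknown)}")
    missing = set(coeff_tables) - set(conventions)
    if missing:
        raise ValueError(f"conventions missing screens: {sorted(missing)}")
    out: dict[str, dict[str, set[str]]] = {}
    for screen, table in coeff_tables.items():
        sign = conventions[screen]
        if sign not in (1, -1):
            raise ValueError(f"favorable_sign for {screen!r} must be +1 or -1")
        c = table.coefficients
        fav = set(c.index[np.sign(c.to_numpy()) == sign])
        unfav = set(c.index[np.sign(c.to_numpy()) == -sign])
        out[screen] = {"favorable": fav, "unfavorable": unfav}
    return out


def aggregate_coefficient(per_screen_coefficients) -> float:
    """Mean of absolute per-screen coefficients, rounded half-to-even to 4 dp."""
    values = np.asarray(list(per_screen_coefficients), dtype=float)
    if values.size == 0:
        raise ValueError("no coefficients to aggregate")
    # np.round rounds half to even, the convention all printed averages follow
    return float(np.round(np.mean(np.abs(values)), 4))


def consensus_table(
    coeff_tables: dict[str, CoefficientTable],
    conventions: dict[str, int],
) -> pd.DataFrame:
    """Per-gene per-screen coefficients with favorability flags and aggregate.

    Only genes present in every compared screen are aggregated; genes missing
    from any screen are excluded (absence from a design matrix is lack of
    evidence, not a zero effect) and logged.
    """
    favorability = harmonize_favorability(coeff_tables, conventions)
    screens = sorted(coeff_tables)
    common = set.intersection(*(set(coeff_tables[s].coefficients.index) for s in screens))
    all_genes = set.union(*(set(coeff_tables[s].coefficients.index) for s in screens))
    excluded = all_genes - common
    if excluded:
        logger.info("%d genes missing from >=1 screen excluded from consensus", len(excluded))
    rows = []
    for gene in sorted(common):
        row: dict = {"gene": gene}
        coeffs = []
        for s in screens:
            c = float(coeff_tables[s].coefficients[gene])
            coeffs.append(c)
            row[f"coeff_{s}"] = c
            row[f"favorable_{s}"] = gene in favorability[s]["favorable"]
        row["aggregate"] = aggregate_coefficient(coeffs)
        rows.append(row)
    return pd.DataFrame(rows)


def _venn_counts(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for a 2- or 3-set Venn diagram."""
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            counts[combo] = len(inside - outside)
    return counts


def shared_genes(
    favorability: dict[str, dict[str, set[str]]],
    reference: set[str] | None = None,
) -> SharedGeneReport:
    """Genes favorable (or unfavorable) in every compared screen.

    The optional reference set (e.g. genes behind the psychiatric pathway
    predictions) is intersected with each shared set; Venn region counts are
    reported for the per-screen sets.
    """
    if len(favorability) < 2:
        raise ValueError("need at least 2 screens for a shared-gene report")
    fav_sets = {s: v["favorable"] for s, v in favorability.items()}
    unfav_sets = {s: v["unfavorable"] for s, v in favorability.items()}
    fav_shared = set.intersection(*fav_sets.values())
    unfav_shared = set.intersection(*unfav_sets.values())
    return SharedGeneReport(
        favorable_shared=fav_shared,
        unfavorable_shared=unfav_shared,
        reference_favorable=(fav_shared & reference) if reference is not None else None,
        reference_unfavorable=(unfav_shared & reference) if reference is not None else None,
        venn_counts={"favorable": _venn_counts(fav_sets), "unfavorable": _venn_counts(unfav_sets)},
    )


def shared_terms(
    enrichment_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tiered report of gene-set terms shared across screens.

    Tiers (nested): ``all_significant`` — adjusted_p <= alpha in every
    screen's table; ``two_plus_significant`` — in at least two;
    ``shared_regardless`` — present in at least two tables, significance
    aside. Terms absent from a screen's table are non-significant there.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    screens = sorted(enrichment_tables)
    adj: dict[str, dict[str, float]] = {
        s: dict(zip(t["term_id"], t["adjusted_p"])) for s, t in enrichment_tables.items()
    }
    names: dict[str, str] = {}
    for t in enrichment_tables.values():
        names.update(dict(zip(t["term_id"], t["term_name"])))
    all_terms = sorted(names)
    rows = []
    for term in all_terms:
        present = [s for s in screens if term in adj[s]]
        if len(present) < 2:
            continue
        sig = [s for s in screens if adj[s].get(term, 1.0) <= alpha]
        row = {"term_id": term, "term_name": names[term]}
        for s in screens:
            row[f"adjusted_p_{s}"] = adj[s].get(term, np.nan)
            row[f"significant_{s}"] = term in adj[s] and adj[s][term] <= alpha
        row["n_screens_present"] = len(present)
        row["n_screens_significant"] = len(sig)
        if len(sig) == len(screens):
            row["tier"] = "all_significant"
        elif len(sig) >= 2:
            row["tier"] = "two_plus_significant"
        else:
            row["tier"] = "shared_regardless"
        rows.append(row)
    return pd.DataFrame(rows)
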