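"""Shared statistical primitives: one-sided Fisher enrichment and BH adjustment.

Both the drug-network phenotype association stage and the gene-set enrichment
stage call these same two functions, so the multiple-testing behaviour is a
single source of truth.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    a: in-selection and annotated; b: in-selection, not annotated;
    c: annotated, not in selection; d: neither. Equals the hypergeometric
    upper tail P(X >= a) with population a+b+c+d, a+c annotated draws of
    size a+b.
    """
    for name, x in (("a", a), ("b", b), ("c", c), ("d", d)):
        if x < 0:
            raise ValueError(f"count {name}={x} is negative")
    total = a + b + c + d
    annotated = a + c
    drawn = a + b
    return float(hypergeom.sf(a - 1, total, annotated, drawn))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted
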