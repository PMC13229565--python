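"""Screen-outcome regression on drug-network membership.

Each screen is modeled as outcome ~ binary membership of genes in each
drug's predicted network, fit with L2 regularization (ridge by default;
logistic with an L2 penalty by flag). Coefficient magnitudes are calibrated
against a permutation null that refits after shuffling the outcome column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import mean_squared_error, r2_score

from .io_formats import ScreenTable
from .pathfx import DrugNetwork

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Regression configuration.

    ``split_fraction`` = 1 fits on all rows; below 1 a seeded shuffle
    partitions drugs into train/test and holdout MSE and R² are reported,
    but the returned coefficients always come from a full-matrix refit (the
    exploratory fit used by every downstream stage).
    """

    kind: Literal["linear_ridge", "logistic_l2"] = "linear_ridge"
    alpha: float = 1.0
    fit_intercept: bool = True
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("penalty strength alpha must be > 0")
        if not 0 < self.split_fraction <= 1:
            raise ValueError("split_fraction must lie in (0, 1]")


@dataclass
class CoefficientTable:
    """Per-gene coefficients from one screen's fit."""

    screen_name: str
    coefficients: pd.Series  # index: gene, sorted
    intercept: float
    mse: float | None = None
    r2: float | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients.index)


@dataclass
class NullCoefficientSummary:
    """Per-gene min/max/mean/median coefficients over shuffled refits."""

    screen_name: str
    summary: pd.DataFrame  # index: gene; columns: min, max, mean, median
    n_shuffles: int
    seed: int


@dataclass
class SelectionRule:
    """How extreme-coefficient genes are picked for enrichment.

    threshold: favorable = coeff strictly beyond ``favorable_bound``,
    unfavorable strictly beyond ``unfavorable_bound`` (signed bounds).
    top_k: k largest / k smallest with lexicographic tie-break.
    quantile: top/bottom fraction of genes by coefficient.
    """

    mode: Literal["threshold", "top_k", "quantile"] = "threshold"
    favorable_bound: float | None = None
    unfavorable_bound: float | None = None
    k: int | None = None
    fraction: float | None = None


@dataclass
class GeneSelection:
    favorable: list[str]
    unfavorable: list[str]
    rule: SelectionRule = field(repr=False, default=None)


def build_design_matrix(networks: list[DrugNetwork]) -> pd.DataFrame:
    """Drugs x genes binary membership matrix.

    Columns are the lexicographically sorted union of all network genes;
    cell (d, g) is 1 iff gene g is in drug d's network (target or retained
    downstream).
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 drug networks to build a design matrix")
    ids = [n.drug_id for n in networks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate drug_id among networks")
    genes = sorted(set().union(*(n.genes for n in networks)))
    data = np.zeros((len(networks), len(genes)), dtype=np.int8)
    col = {g: j for j, g in enumerate(genes)}
    for i, n in enumerate(networks):
        for g in n.genes:
            data[i, col[g]] = 1
    return pd.DataFrame(data, index=ids, columns=genes)


def _align(X: pd.DataFrame, y: ScreenTable) -> tuple[pd.DataFrame, pd.Series]:
    common = [d for d in X.index if d in y.outcomes.index]  # order-stable inner join
    if not common:
        raise ValueError("no drugs shared between design matrix and screen table")
    return X.loc[common], y.outcomes.loc[common]


def _fit_once(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, float]:
    if spec.kind == "linear_ridge":
        model = Ridge(alpha=spec.alpha, fit_intercept=spec.fit_intercept)
        model.fit(X, y)
        return model.coef_.ravel(), float(model.intercept_)
    if spec.kind == "logistic_l2":
        if len(np.unique(y)) < 2:
            # degenerate response: no signal, all coefficients zero
            return np.zeros(X.shape[1]), 0.0
        # default penalty is L2; C is the inverse regularization strength
        model = LogisticRegression(C=1.0 / spec.alpha, fit_intercept=spec.fit_intercept, max_iter=2000)
        model.fit(X, y.astype(int))
        return model.coef_.ravel(), float(model.intercept_[0])
    raise ValueError(f"unknown model kind {spec.kind!r}")


def fit_l2(X: pd.DataFrame, y: ScreenTable, spec: ModelSpec) -> CoefficientTable:
    """L2-regularized fit of screen outcomes on network membership.

    With ``split_fraction`` < 1 the drugs are shuffled with ``spec.seed``,
    the model is fit on the training fraction, and holdout MSE/R² are
    reported; the coefficients returned are from a refit on all rows.
    """
    Xa, ya = _align(X, y)
    Xm, ym = Xa.to_numpy(dtype=float), ya.to_numpy(dtype=float)
    mse = r2 = None
    if spec.split_fraction < 1:
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(len(ym))
        n_train = max(1, int(round(spec.split_fraction * len(ym))))
        if n_train >= len(ym):
            n_train = len(ym) - 1
        tr, te = order[:n_train], order[n_train:]
        coef_tr, b_tr = _fit_once(Xm[tr], ym[tr], spec)
        pred = Xm[te] @ coef_tr + b_tr
        if spec.kind == "logistic_l2":
            pred = 1.0 / (1.0 + np.exp(-pred))
        mse = float(mean_squared_error(ym[te], pred))
        r2 = float(r2_score(ym[te], pred)) if len(te) > 1 else None
    coef, intercept = _fit_once(Xm, ym, spec)
    return CoefficientTable(
        screen_name=y.screen_name,
        coefficients=pd.Series(coef, index=Xa.columns),
        intercept=intercept,
        mse=mse,
        r2=r2,
    )


def permutation_null(
    X: pd.DataFrame,
    y: ScreenTable,
    spec: ModelSpec,
    n_shuffles: int = 100,
    seed: int = 0,
) -> NullCoefficientSummary:
    """Refit after shuffling the outcome column ``n_shuffles`` times.

    Each refit uses the full matrix (no split); shuffle i uses seed
    ``seed + i``. Reports per-gene min, max, mean, and median coefficients.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    Xa, ya = _align(X, y)
    Xm, ym = Xa.to_numpy(dtype=float), ya.to_numpy(dtype=float)
    full_spec = ModelSpec(
        kind=spec.kind, alpha=spec.alpha, fit_intercept=spec.fit_intercept, split_fraction=1.0, seed=spec.seed
    )
    coefs = np.empty((n_shuffles, Xm.shape[1]))
    for i in range(n_shuffles):
        rng = np.random.default_rng((seed + i) % (2**31))
        shuffled = rng.permutation(ym)
        coefs[i], _ = _fit_once(Xm, shuffled, full_spec)
    summary = pd.DataFrame(
        {
            "min": coefs.min(axis=0),
            "max": coefs.max(axis=0),
            "mean": coefs.mean(axis=0),
            "median": np.median(coefs, axis=0),
        },
        index=Xa.columns,
    )
    return NullCoefficientSummary(
        screen_name=y.screen_name, summary=summary, n_shuffles=n_shuffles, seed=seed
    )


def select_genes(coeffs: CoefficientTable, rule: SelectionRule) -> GeneSelection:
    """Pick favorable/unfavorable gene lists from a coefficient table."""
    c = coeffs.coefficients
    if rule.mode == "threshold":
        if rule.favorable_bound is None or rule.unfavorable_bound is None:
            raise ValueError("threshold mode needs favorable_bound and unfavorable_bound")
        if rule.favorable_bound >= 0:
            fav = c[c > rule.favorable_bound]
        else:
            fav = c[c < rule.favorable_bound]
        if rule.unfavorable_bound >= 0:
            unfav = c[c > rule.unfavorable_bound]
        else:
            unfav = c[c < rule.unfavorable_bound]
        return GeneSelection(sorted(fav.index), sorted(unfav.index), rule)
    if rule.mode == "top_k":
        if rule.k is None or rule.k <= 0:
            raise ValueError("top_k mode needs k >= 1")
        k = rule.k
        if k > len(c):
            logger.warning("k=%d exceeds %d genes; returning all", k, len(c))
            k = len(c)
        # sort by (-coeff, gene) for top, (coeff, gene) for bottom: lexicographic tie-break
        top = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        bottom = sorted(c.items(), key=lambda kv: (kv[1], kv[0]))[:k]
        return GeneSelection(sorted(g for g, _ in top), sorted(g for g, _ in bottom), rule)
    if rule.mode == "quantile":
        if rule.fraction is None or not 0 < rule.fraction <= 1:
            raise ValueError("quantile mode needs fraction in (0, 1]")
        k = max(1, int(round(rule.fraction * len(c))))
        return select_genes(coeffs, SelectionRule(mode="top_k", k=k))
    raise ValueError(f"unknown selection mode {rule.mode!r}")


def write_coefficients(
    coeffs: CoefficientTable, null: NullCoefficientSummary | None, path
) -> None:
    """Write gene, coefficient, and null summary columns as TSV."""
    df = coeffs.coefficients.rename("coefficient").to_frame()
    if null is not None:
        df = df.join(null.summary.add_prefix("null_"))
    df.rename_axis("gene").to_csv(path, sep="\t")


def read_coefficients(path, screen_name: str) -> CoefficientTable:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return CoefficientTable(
        screen_name=screen_name, coefficients=df["coefficient"], intercept=float("nan")
    )
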