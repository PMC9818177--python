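"""Dependency-expression correlation screen (functional substitution).

Given a panel of cell lines with a gene x line expression matrix and a
target gene's CRISPR gene-effect vector (more negative = more depended
upon), the screen selects genes whose expression correlates POSITIVELY with
the target's gene effect: lines expressing them highly tolerate losing the
target, so they are candidate functional substitutes.  The screen runs once
per scoring algorithm (e.g. two different gene-effect estimators) and the
hit sets are intersected for robustness before gene-set enrichment.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import DependencyPanel

logger = logging.getLogger(__name__)

ALGORITHM_A = "A"
ALGORITHM_B = "B"


def _pearson_with_p(matrix: np.ndarray, vector: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``matrix`` against ``vector`` with two-sided p.

    Rows with zero variance (or a constant vector) get r = 0, p = 1.
    """
    n = vector.size
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    yc = vector - vector.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    constant = denom == 0
    denom = np.where(constant, 1.0, denom)
    r = (xc @ yc) / denom
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(constant, 1.0, p)
    return r, p


def correlate_dependency(panel: DependencyPanel, which: str = ALGORITHM_A,
                         method: str = "pearson") -> pd.DataFrame:
    """Correlate every gene's expression with the chosen effect vector.

    Returns one row per gene with ``gene``, ``r``, ``p_value`` and
    ``selected`` (left False; filled in by `select_positive`).  Genes with
    constant expression across the panel get r = 0, p = 1 and a logged
    count.  ``method`` is Pearson (default; dependence is modelled as
    linear) or Spearman.
    """
    if which == ALGORITHM_A:
        effect = panel.effect_a
    elif which == ALGORITHM_B:
        effect = panel.effect_b
    else:
        raise ValueError(f"unknown algorithm {which!r}")
    expr = panel.expr.to_numpy()
    if method == "pearson":
        r, p = _pearson_with_p(expr, effect.to_numpy())
    elif method == "spearman":
        ranks = stats.rankdata(expr, axis=1)
        r, p = _pearson_with_p(ranks, stats.rankdata(effect.to_numpy()))
    else:
        raise ValueError(f"unknown method {method!r}")
    n_constant = int((panel.expr.std(axis=1) == 0).sum())
    if n_constant:
        logger.info("%d gene(s) with constant expression: r set to 0, p to 1", n_constant)
    return pd.DataFrame(
        {"gene": panel.expr.index, "r": r, "p_value": p, "selected": False}
    ).reset_index(drop=True)


def select_positive(records: pd.DataFrame, alpha: float = 0.05, r_min: float = 0.0
                    ) -> frozenset:
    """Genes with r > r_min and p < alpha (the positive-correlation hits).

    Also marks ``selected`` in-place on the records table.
    """
    mask = (records["r"] > r_min) & (records["p_value"] < alpha)
    records["selected"] = mask.to_numpy()
    return frozenset(records.loc[mask, "gene"])


def intersect_screens(set_a: Iterable[str], set_b: Iterable[str]) -> list[str]:
    """Sorted intersection of the two algorithms' hit sets."""
    return sorted(frozenset(set_a) & frozenset(set_b))


def lineage_dependency_summary(effects: pd.DataFrame, lineage: pd.Series) -> pd.DataFrame:
    """Mean dependency score per (gene, lineage).

    ``effects`` is a gene x cell-line matrix of gene-effect scores and
    ``lineage`` maps each cell line to a tissue label.  Returns a gene x
    lineage table of arithmetic means; the most negative entry in a gene's
    row is its most-dependent lineage.
    """
    missing = [c for c in effects.columns if c not in lineage.index]
    if missing:
        raise ValueError(f"cell line(s) without lineage label: {missing}")
    groups = lineage.reindex(effects.columns)
    out = effects.T.groupby(groups).mean().T
    out = out[sorted(out.columns)]
    out.index.name = "gene"
    out.columns.name = "lineage"
    return out


def most_dependent_lineage(summary: pd.DataFrame, gene: str) -> str:
    """Lineage with the most negative mean effect for ``gene``."""
    return str(summary.loc[gene].idxmin())
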