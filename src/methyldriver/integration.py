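"""Integration of methylation and expression screens into driver candidates.

A methylation-driven candidate is a gene whose expression change is
sign-consistent with its methylation change: promoter-hypomethylated and
over-expressed (HYPO_UP) or hypermethylated and under-expressed
(HYPER_DOWN).  Because region screens yield several (gene, region) records
per gene, a reduction policy first collapses them to one methylation call
per gene; the default prefers promoter-window regions, reflecting the
canonical promoter-methylation/expression coupling.

Also houses the single-gene biomarker evaluator: an empirical ROC with the
AUC computed as the Mann-Whitney U statistic over n_case * n_control (i.e.
the probability that a random case scores above a random control, ties
counted half), and the operating point chosen by the Youden index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PROMOTER_REGIONS

HYPO_UP = "HYPO_UP"
HYPER_DOWN = "HYPER_DOWN"

PROMOTER_FIRST = "promoter_first"
MAX_ABS = "max_abs"


def resolve_gene_methylation(
    dmrs: pd.DataFrame,
    policy: str = PROMOTER_FIRST,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collapse a full region table to one methylation record per gene.

    ``promoter_first`` prefers significant regions (p < alpha), promoter
    classes (TSS1500/TSS200/5'UTR/1st exon) within them, then the largest
    |delta-beta| — falling back to non-promoter or non-significant regions
    when a gene has nothing better.  ``max_abs`` simply takes the largest
    |delta-beta| over all the gene's regions.  Ties break on region class
    name for determinism.

    Returns columns ``gene``, ``delta_beta``, ``p_value``, ``region_used``.
    """
    if policy not in (PROMOTER_FIRST, MAX_ABS):
        raise ValueError(f"unknown policy {policy!r}")
    if not len(dmrs):
        return pd.DataFrame(columns=["gene", "delta_beta", "p_value", "region_used"])
    work = dmrs[["gene", "region_class", "delta_beta", "p_value"]].copy()
    work["abs_db"] = work["delta_beta"].abs()
    if policy == PROMOTER_FIRST:
        work["rank_sig"] = (work["p_value"] < alpha).astype(int)
        work["rank_prom"] = work["region_class"].isin(PROMOTER_REGIONS).astype(int)
        order = ["rank_sig", "rank_prom", "abs_db"]
    else:
        order = ["abs_db"]
    work = work.sort_values(
        order + ["region_class"],
        ascending=[False] * len(order) + [True],
        kind="mergesort",
    )
    best = work.groupby("gene", sort=True).head(1)
    out = best[["gene", "delta_beta", "p_value", "region_class"]].rename(
        columns={"region_class": "region_used"}
    )
    return out.sort_values("gene", kind="mergesort").reset_index(drop=True)


def select_driver_genes(
    meth_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    dbeta_min: float = 0.1,
    log2fc_min: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Join gene-level methylation and expression into driver candidates.

    Inner-joins on gene symbol, then keeps genes where both screens are
    individually significant (p < alpha), the methylation effect clears
    ``dbeta_min`` and the expression effect clears ``log2fc_min``, and the
    two signs are consistent: HYPO_UP (delta-beta < -dbeta_min, log2FC >
    log2fc_min) or HYPER_DOWN (delta-beta > dbeta_min, log2FC < -log2fc_min).
    Sign-discordant genes that pass both magnitude/significance gates are
    excluded and counted in the returned report.

    Returns ``(drivers, report)`` where report carries the join size and
    class/discordant counts.
    """
    for name, tab in (("meth_table", meth_table), ("deg_table", deg_table)):
        if tab["gene"].duplicated().any():
            dup = tab.loc[tab["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene key in {name}: {dup!r}")
    meth = meth_table.rename(
        columns={"delta_beta": "meth_delta_beta", "p_value": "p_meth",
                 "region_used": "meth_region_used"}
    )
    deg = deg_table.rename(columns={"p_value": "p_expr"})[["gene", "log2_fc", "p_expr"]]
    joined = meth.merge(deg, on="gene", how="inner")

    sig = (joined["p_meth"] < alpha) & (joined["p_expr"] < alpha)
    meth_eff = joined["meth_delta_beta"].abs() > dbeta_min
    expr_eff = joined["log2_fc"].abs() > log2fc_min
    passing = sig & meth_eff & expr_eff
    hypo_up = passing & (joined["meth_delta_beta"] < 0) & (joined["log2_fc"] > 0)
    hyper_down = passing & (joined["meth_delta_beta"] > 0) & (joined["log2_fc"] < 0)
    discordant = passing & ~hypo_up & ~hyper_down

    drivers = joined[hypo_up | hyper_down].copy()
    drivers["klass"] = np.where(drivers["meth_delta_beta"] < 0, HYPO_UP, HYPER_DOWN)
    cols = ["gene", "meth_delta_beta", "meth_region_used", "log2_fc", "p_meth", "p_expr", "klass"]
    cols = [c for c in cols if c in drivers.columns]
    drivers = drivers[cols].sort_values("gene", kind="mergesort").reset_index(drop=True)
    report = {
        "n_joined": int(len(joined)),
        "n_hypo_up": int(hypo_up.sum()),
        "n_hyper_down": int(hyper_down.sum()),
        "n_discordant": int(discordant.sum()),
    }
    return drivers, report


def intersect_gene_lists(candidates: Iterable[str], reference: Iterable[str]) -> list[str]:
    """Sorted intersection of two gene collections."""
    return sorted(frozenset(candidates) & frozenset(reference))


@dataclass(frozen=True)
class BiomarkerEval:
    """ROC summary for a single-gene expression biomarker."""

    gene: str
    auc: float
    sensitivity_at_youden: float
    specificity_at_youden: float
    threshold: float


def evaluate_biomarker(
    values: np.ndarray | pd.Series,
    is_case: np.ndarray,
    gene: str = "",
) -> BiomarkerEval:
    """Empirical ROC evaluation of one expression vector against labels.

    AUC is the Mann-Whitney U statistic divided by n_case * n_control (the
    fraction of concordant case/control pairs, ties counted 0.5), the
    convention under which cases are expected to score HIGH.  The operating
    threshold maximizes the Youden index (sensitivity + specificity - 1)
    over the observed values, predicting case when value >= threshold; ties
    resolve to the lowest threshold.
    """
    x = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if x.shape != is_case.shape:
        raise ValueError("values and labels differ in length")
    case = x[is_case]
    control = x[~is_case]
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(x)
    u = ranks[is_case].sum() - case.size * (case.size + 1) / 2.0
    auc = float(u / (case.size * control.size))

    thresholds = np.unique(x)
    sens = (case[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (control[None, :] < thresholds[:, None]).mean(axis=1)
    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])  # lowest threshold on ties
    return BiomarkerEval(
        gene=gene,
        auc=auc,
        sensitivity_at_youden=float(sens[best]),
        specificity_at_youden=float(spec[best]),
        threshold=float(thresholds[best]),
    )
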