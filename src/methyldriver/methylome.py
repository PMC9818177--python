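"""Beta-value computation and differential methylation screens.

The beta value of a probe is the clamped methylated intensity over the
clamped total intensity plus a stabilizing offset:

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + offset)

with offset 100 by default, so beta lies in [0, 1) for any finite input.
Group comparison uses a pooled-variance (Student) two-sample t-test; probes
are flagged when |delta-beta| exceeds an effect gate (default 0.1) at raw
p < 0.05, regions (probe groups sharing a gene and annotation class,
averaged per sample) at a stricter default gate of 0.5.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CPG_REGIONS, GENE_REGIONS, ProbeAnnotation, SampleSheet

HYPO = "HYPO"
HYPER = "HYPER"

GENE_REGION = "gene_region"
CPG_REGION = "cpg_region"


def compute_beta(
    methylated: pd.DataFrame | np.ndarray,
    unmethylated: pd.DataFrame | np.ndarray,
    offset: float = 100.0,
) -> pd.DataFrame | np.ndarray:
    """Elementwise beta values from the two intensity channels.

    Negative channel intensities are clamped to zero before the ratio; the
    positive ``offset`` in the denominator keeps the value strictly below 1.
    Raises on non-finite input, naming the offending probe/sample when the
    inputs are DataFrames.
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if m.shape != u.shape:
        raise ValueError("channel matrices differ in shape")
    bad = ~(np.isfinite(m) & np.isfinite(u))
    if bad.any():
        where = np.argwhere(bad)[0]
        if isinstance(methylated, pd.DataFrame):
            raise ValueError(
                "non-finite intensity at probe "
                f"{methylated.index[where[0]]!r}, sample {methylated.columns[where[1]]!r}"
            )
        raise ValueError(f"non-finite intensity at position {tuple(where)}")
    mc = np.maximum(m, 0.0)
    uc = np.maximum(u, 0.0)
    beta = mc / (mc + uc + offset)
    if isinstance(methylated, pd.DataFrame):
        return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)
    return beta


def pooled_t_test(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance (Student) two-sample t-test.

    Returns ``(t, p)`` arrays.  Degenerate rows where both groups have zero
    variance follow an explicit convention: p = 1 when the means are equal
    (no evidence), p = 0 when they differ (beta truncation can produce
    constant groups, and a constant separation is then unambiguous).
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    m1 = case.mean(axis=1)
    m2 = control.mean(axis=1)
    ss1 = ((case - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((control - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    # A group is constant when every value equals its first; detecting this
    # on the raw values (not on sp2) sidesteps catastrophic cancellation.
    const = (case == case[:, :1]).all(axis=1) & (control == control[:, :1]).all(axis=1)
    degenerate = const | (se == 0.0)
    safe_se = np.where(degenerate, 1.0, se)
    t = (m1 - m2) / safe_se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if degenerate.any():
        diff0 = case[:, 0] - control[:, 0]
        deg_t = np.where(diff0 > 0, np.inf, np.where(diff0 < 0, -np.inf, 0.0))
        t = np.where(degenerate, deg_t, t)
        p = np.where(degenerate, np.where(diff0 == 0, 1.0, 0.0), p)
    return t, p


def _group_split(matrix: pd.DataFrame, sheet: SampleSheet) -> tuple[np.ndarray, np.ndarray]:
    missing = [s for s in sheet.sample_ids if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing}")
    return matrix[sheet.case_ids].to_numpy(), matrix[sheet.control_ids].to_numpy()


def test_probes(
    beta: pd.DataFrame,
    sheet: SampleSheet,
    dbeta_min: float = 0.1,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-probe differential methylation: delta-beta plus pooled t-test.

    Returns the full table (one row per probe) with columns ``probe_id``,
    ``delta_beta`` (mean CASE - mean CONTROL), ``p_value``, ``direction``
    (HYPO when delta-beta < 0, else HYPER) and ``flagged``
    (|delta-beta| > dbeta_min and p < alpha).  With ``bh=True`` a
    Benjamini-Hochberg ``q_value`` column is added (informational; flagging
    stays on the raw p, matching the screen's definition).
    """
    case, control = _group_split(beta, sheet)
    delta = case.mean(axis=1) - control.mean(axis=1)
    _, p = pooled_t_test(case, control)
    out = pd.DataFrame(
        {
            "probe_id": beta.index,
            "delta_beta": delta,
            "p_value": p,
            "direction": np.where(delta < 0, HYPO, HYPER),
            "flagged": (np.abs(delta) > dbeta_min) & (p < alpha),
        }
    )
    if bh:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def aggregate_regions(
    beta: pd.DataFrame,
    annot: ProbeAnnotation,
    scheme: str = GENE_REGION,
) -> pd.DataFrame:
    """Average probe betas into (gene, annotation-class) regions per sample.

    ``scheme`` selects the gene-annotation or CpG-island classification.
    Intergenic probes (empty gene) are excluded; a probe absent from the
    manifest is an error.  Returns a region x sample matrix indexed by
    (gene, region_class); regions with no probes simply do not appear.
    """
    if scheme not in (GENE_REGION, CPG_REGION):
        raise ValueError(f"unknown scheme {scheme!r}")
    missing = beta.index.difference(annot.probe_ids)
    if len(missing):
        raise ValueError(f"probe missing from manifest: {missing[0]!r}")
    ann = annot.table.loc[beta.index]
    keep = ann["gene"] != ""
    grouped = beta.loc[keep].groupby(
        [ann.loc[keep, "gene"], ann.loc[keep, scheme]], sort=True
    )
    region = grouped.mean()
    region.index.names = ["gene", "region_class"]
    return region


def region_sizes(beta: pd.DataFrame, annot: ProbeAnnotation, scheme: str = GENE_REGION) -> pd.Series:
    """Number of probes per (gene, region_class) region, matching `aggregate_regions`."""
    ann = annot.table.loc[beta.index]
    keep = ann["gene"] != ""
    sizes = ann.loc[keep].groupby(["gene", scheme], sort=True).size()
    sizes.index.names = ["gene", "region_class"]
    return sizes


def test_regions(
    regions: pd.DataFrame,
    sheet: SampleSheet,
    dbeta_min: float = 0.5,
    alpha: float = 0.05,
    n_probes: pd.Series | None = None,
) -> pd.DataFrame:
    """Region-level differential methylation on the aggregated matrix.

    Same statistic and conventions as `test_probes`; the default effect gate
    is the stricter region-screen threshold of 0.5 (the integration stage
    re-screens gene-level results at 0.1).
    """
    case, control = _group_split(regions, sheet)
    delta = case.mean(axis=1) - control.mean(axis=1)
    _, p = pooled_t_test(case, control)
    idx = regions.index
    out = pd.DataFrame(
        {
            "gene": idx.get_level_values("gene"),
            "region_class": idx.get_level_values("region_class"),
            "delta_beta": delta,
            "p_value": p,
            "direction": np.where(delta < 0, HYPO, HYPER),
            "flagged": (np.abs(delta) > dbeta_min) & (p < alpha),
        }
    )
    if n_probes is not None:
        out["n_probes"] = n_probes.reindex(idx).to_numpy()
    else:
        out["n_probes"] = 1
    return out


def summarize_region_distribution(
    dmrs: pd.DataFrame, classes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Contingency counts of DMR calls: direction (HYPO/HYPER) x annotation class.

    ``classes`` fixes the column enumeration (defaults to the union of the
    gene and CpG classes); absent cells are zero, so totals always equal the
    number of input records.
    """
    if classes is None:
        classes = tuple(GENE_REGIONS) + tuple(CPG_REGIONS)
    counts = pd.DataFrame(0, index=[HYPO, HYPER], columns=list(classes), dtype=int)
    if len(dmrs):
        tab = dmrs.groupby(["direction", "region_class"]).size()
        for (direction, klass), n in tab.items():
            if klass not in counts.columns:
                raise ValueError(f"region class {klass!r} not in enumeration")
            counts.loc[direction, klass] = int(n)
    counts.index.name = "direction"
    return counts
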