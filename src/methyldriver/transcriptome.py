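"""Differential expression by anti-logged fold change plus t-test.

The fold change convention here is the ratio of arithmetic means of the
anti-logged (2^x) group signals — NOT the anti-log of the mean log2
difference.  The significance test, by contrast, runs on the log2-scale
signals (variance-stabilized), with the same pooled-variance Student t and
zero-variance conventions as the methylation screens.  A gene is called UP
when fold change > 2 and p < 0.05, DOWN when fold change < 0.5 and p < 0.05
(defaults; both gates configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import SampleSheet
from .methylome import pooled_t_test

UP = "UP"
DOWN = "DOWN"


def compute_fold_change(log2_case: np.ndarray, log2_control: np.ndarray) -> float:
    """Linear-scale case/control fold change from log2 signals.

    mean(2^case) / mean(2^control): the groups are anti-logged first, then
    averaged, so a single high-signal sample pulls the ratio more than it
    would under the geometric-mean (mean-of-logs) convention.
    """
    log2_case = np.asarray(log2_case, dtype=float)
    log2_control = np.asarray(log2_control, dtype=float)
    if log2_case.size == 0 or log2_control.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.mean(np.exp2(log2_case)) / np.mean(np.exp2(log2_control)))


def test_genes(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression over a log2 gene x sample matrix.

    Returns the full table with columns ``gene``, ``fold_change``,
    ``log2_fc``, ``p_value``, ``direction`` and ``flagged``.  ``direction``
    is UP when fold change > 1 else DOWN; ``flagged`` applies the effect
    gates (FC > fc_up or FC < fc_down) together with p < alpha.
    """
    missing = [s for s in sheet.sample_ids if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing}")
    case = expr[sheet.case_ids].to_numpy()
    control = expr[sheet.control_ids].to_numpy()
    fc = np.exp2(case).mean(axis=1) / np.exp2(control).mean(axis=1)
    _, p = pooled_t_test(case, control)
    flagged = ((fc > fc_up) | (fc < fc_down)) & (p < alpha)
    return pd.DataFrame(
        {
            "gene": expr.index,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": p,
            "direction": np.where(fc > 1.0, UP, DOWN),
            "flagged": flagged,
        }
    )
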