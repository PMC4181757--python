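"""Classifier-style evaluation of fitted pair models: AUC, sens/spec, PAF."""

from __future__ import annotations

import numpy as np

from .pair_tables import PairExposureTable


def auc_from_counts(cases: np.ndarray, controls: np.ndarray) -> float:
    """Concordance AUC of a categorical risk score defined by cell odds.

    Categories are scored by their case:control odds; the AUC is the
    probability that a random case sits in a strictly higher-scored category
    than a random control, with ties contributing 1/2 (the grouped-data
    Mann-Whitney statistic).  Categories empty in both strata are dropped.
    """
    c = np.asarray(cases, dtype=float)
    k = np.asarray(controls, dtype=float)
    keep = (c + k) > 0
    c, k = c[keep], k[keep]
    if c.sum() == 0 or k.sum() == 0:
        raise ValueError("need at least one case and one control")
    p = c / c.sum()
    q = k / k.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = c / k  # inf for zero-control cells: highest risk
    gt = score[:, None] > score[None, :]
    eq = score[:, None] == score[None, :]
    return float(np.sum(p[:, None] * q[None, :] * (gt + 0.5 * eq)))


def auc_from_table(t: PairExposureTable) -> float:
    """AUC of the four joint-exposure categories of a pair (see above)."""
    if t.degenerate:
        raise ValueError(f"degenerate table for pair {t.pair}")
    return auc_from_counts(t.cases, t.controls)


def sens_spec(cases: np.ndarray, controls: np.ndarray,
              high_risk: np.ndarray) -> tuple[float, float]:
    """Sensitivity and specificity of a binary high/low risk rule.

    ``high_risk`` is a boolean mask over the categories; sensitivity is the
    case mass in high-risk categories, specificity the control mass in
    low-risk ones.
    """
    c = np.asarray(cases, dtype=float)
    k = np.asarray(controls, dtype=float)
    h = np.asarray(high_risk, dtype=bool)
    if c.sum() == 0 or k.sum() == 0:
        raise ValueError("need at least one case and one control")
    return float(c[h].sum() / c.sum()), float(k[~h].sum() / k.sum())


def paf(t: PairExposureTable, baseline: int = 0) -> float:
    """Population attributable fraction, Miettinen case-load form.

    PAF = sum over non-baseline categories of pc_i * (OR_i - 1) / OR_i, with
    pc_i the proportion of cases in category i and OR_i its odds ratio versus
    the baseline category.  Equivalent to 1 - sum_i pc_i / OR_i (with
    OR_baseline = 1).  Categories with OR_i < 1 contribute negatively.  A
    zero cell in the baseline category triggers a 0.5 continuity correction
    on all cells.
    """
    if t.degenerate:
        raise ValueError(f"degenerate table for pair {t.pair}")
    c = t.cases.astype(float)
    k = t.controls.astype(float)
    if c[baseline] == 0 or k[baseline] == 0:
        c, k = c + 0.5, k + 0.5
    pc = c / c.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = c / k
        ors = odds / odds[baseline]
    total = 0.0
    for i in range(len(c)):
        if i == baseline or pc[i] == 0:
            continue
        if np.isinf(ors[i]):  # zero-control category: (OR-1)/OR -> 1
            total += pc[i]
        else:
            total += pc[i] * (ors[i] - 1.0) / ors[i]
    return float(total)
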