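"""Additive-scale interaction: RERI and attributable proportion (AP).

For a 2x2 joint-exposure table with odds ratios OR01, OR10, OR11 relative to
the doubly-unexposed cell,

    RERI = OR11 - OR01 - OR10 + 1        (excess relative risk due to interaction)
    AP   = RERI / OR11                   (attributable proportion, <= 1)

The odds ratios are the MLEs of the saturated logistic model for the grouped
2x2x2 table, so they are computed in closed form as cross-product ratios; the
AP variance follows the Hosmer-Lemeshow delta method on the three log-OR
coefficients, whose covariance is assembled from the independent cell
log-odds variances 1/cases + 1/controls.

AP can be negative, and on sparse tables far below -1; such values are
reported as-is (never truncated), and :func:`ap_diagnostics` summarizes the
pathology: strongly negative AP concentrates where an exposure cell is nearly
empty or one single-exposure OR is large, because the denominator OR11 can be
small for negatively interacting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pair_tables import PairExposureTable

Z95 = stats.norm.ppf(0.975)


@dataclass
class AdditiveResult:
    pair: tuple[str, str]
    or01: float
    or10: float
    or11: float
    reri: float
    ap: float
    ap_se: float
    ap_ci: tuple[float, float]
    p_value: float
    recoding: str = "identity"
    small_cell: bool = False       # some cell < 5 (or zero, continuity-corrected)
    continuity_corrected: bool = False

    @property
    def ap_below_minus_one(self) -> bool:
        return self.ap < -1.0


def _ap_variance(cases: np.ndarray, controls: np.ndarray,
                 or01: float, or10: float, or11: float) -> float:
    """Delta-method variance of AP from independent cell log-odds.

    beta1 = log OR10, beta2 = log OR01, beta3 = interaction coefficient.
    """
    v = 1.0 / cases + 1.0 / controls  # var of each cell log-odds
    cov = np.array(
        [
            [v[2] + v[0], v[0], -(v[2] + v[0])],
            [v[0], v[1] + v[0], -(v[1] + v[0])],
            [-(v[2] + v[0]), -(v[1] + v[0]), v.sum()],
        ]
    )
    grad = np.array(
        [(or01 - 1.0) / or11, (or10 - 1.0) / or11, (or10 + or01 - 1.0) / or11]
    )
    return float(grad @ cov @ grad)


def additive_fit(t: PairExposureTable) -> AdditiveResult:
    """RERI/AP with delta-method CI and two-sided z test for one pair.

    Expects a (recoded) non-degenerate table.  Point estimates use the raw
    counts; when any cell is zero, a 0.5 continuity correction is applied to
    all eight cells for the variance (and for point estimates that would
    otherwise be undefined), and the result is flagged.
    """
    if t.degenerate:
        raise ValueError(f"degenerate table for pair {t.pair}")
    c = t.cases.astype(float)
    k = t.controls.astype(float)
    zero = (c == 0).any() or (k == 0).any()
    cc, kc = (c + 0.5, k + 0.5) if zero else (c, k)

    odds = cc / kc
    or01, or10, or11 = odds[1] / odds[0], odds[2] / odds[0], odds[3] / odds[0]
    reri = or11 - or01 - or10 + 1.0
    ap = reri / or11
    var = _ap_variance(cc, kc, or01, or10, or11)
    se = float(np.sqrt(var))
    z = ap / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    return AdditiveResult(
        pair=t.pair,
        or01=float(or01),
        or10=float(or10),
        or11=float(or11),
        reri=float(reri),
        ap=float(ap),
        ap_se=se,
        ap_ci=(float(ap - Z95 * se), float(ap + Z95 * se)),
        p_value=p,
        recoding=t.recoding,
        small_cell=bool(min(c.min(), k.min()) < 5),
        continuity_corrected=zero,
    )


def ap_diagnostics(results: list[AdditiveResult],
                   tables: list[PairExposureTable]) -> tuple[pd.DataFrame, dict]:
    """Per-pair AP pathology table plus summary correlations.

    For each pair: AP, the minimum count over the eight exposure cells, and
    the smaller/larger of the two single-exposure ORs.  The summary reports
    Pearson correlations of AP with each quantity restricted to AP < 0, and
    the fractions of negative and below--1 AP values.
    """
    if not results:
        raise ValueError("need at least one result")
    rows = []
    for r, t in zip(results, tables):
        rows.append(
            {
                "marker_1": r.pair[0],
                "marker_2": r.pair[1],
                "ap": r.ap,
                "min_cell": int(min(t.cases.min(), t.controls.min())),
                "or_single_min": min(r.or01, r.or10),
                "or_single_max": max(r.or01, r.or10),
            }
        )
    df = pd.DataFrame(rows)
    neg = df[np.isfinite(df["ap"]) & (df["ap"] < 0)]

    def _corr(col: str) -> float:
        sub = neg[np.isfinite(neg[col])]
        if len(sub) < 3 or sub["ap"].nunique() < 2 or sub[col].nunique() < 2:
            return float("nan")
        return float(stats.pearsonr(sub["ap"], sub[col])[0])

    summary = {
        "n_pairs": len(df),
        "frac_ap_negative": float((df["ap"] < 0).mean()),
        "frac_ap_below_minus1": float((df["ap"] < -1).mean()),
        "corr_ap_min_cell_neg": _corr("min_cell"),
        "corr_ap_or_min_neg": _corr("or_single_min"),
        "corr_ap_or_max_neg": _corr("or_single_max"),
    }
    return df, summary
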