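"""Multiplicative-scale interaction: the product-term of a logistic model.

With two binary exposures A and B, the saturated logistic model

    logit P(case) = beta0 + beta1*A + beta2*B + beta3*A*B

has closed-form MLEs on a grouped 2x2x2 table: each beta is a contrast of
cell log-odds, so exp(beta3) = OR11 / (OR01 * OR10).  The Wald SE of beta3 is
the square root of the sum of reciprocals of the eight cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pair_tables import PairExposureTable

Z95 = stats.norm.ppf(0.975)


@dataclass
class MultiplicativeResult:
    pair: tuple[str, str]
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    or3: float                      # exp(beta3)
    or3_ci: tuple[float, float]
    se_beta3: float
    p_value: float                  # two-sided Wald
    converged: bool = True
    continuity_corrected: bool = False


def multiplicative_fit(t: PairExposureTable) -> MultiplicativeResult:
    """Saturated logistic interaction fit for one pair (closed form).

    Zero cells get a 0.5 continuity correction on all eight cells and are
    flagged; the closed-form coefficients then play the role of the
    non-convergent iterative fit's fallback.
    """
    if t.degenerate:
        raise ValueError(f"degenerate table for pair {t.pair}")
    c = t.cases.astype(float)
    k = t.controls.astype(float)
    zero = (c == 0).any() or (k == 0).any()
    if zero:
        c, k = c + 0.5, k + 0.5
    logodds = np.log(c / k)  # cells 00, 01, 10, 11
    beta0 = logodds[0]
    beta1 = logodds[2] - logodds[0]          # marker-1 exposure
    beta2 = logodds[1] - logodds[0]          # marker-2 exposure
    beta3 = logodds[3] - logodds[2] - logodds[1] + logodds[0]
    se = float(np.sqrt((1.0 / c + 1.0 / k).sum()))
    z = beta3 / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    or3 = float(np.exp(beta3))
    return MultiplicativeResult(
        pair=t.pair,
        beta0=float(beta0),
        beta1=float(beta1),
        beta2=float(beta2),
        beta3=float(beta3),
        or3=or3,
        or3_ci=(float(np.exp(beta3 - Z95 * se)), float(np.exp(beta3 + Z95 * se))),
        se_beta3=se,
        p_value=p,
        converged=not zero,
        continuity_corrected=zero,
    )
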