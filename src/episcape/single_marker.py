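"""Per-marker association (Cochran-Armitage trend test) and two-cohort
meta-analysis (Mantel-Haenszel fixed / DerSimonian-Laird random effects after
Woolf's heterogeneity test).

The trend test assumes an additive genetic model (scores 0, 1, 2 on the
minor-allele dosage) and is computed complete-case.  No covariate adjustment
is performed: the synthetic populations this package analyses carry no
population structure, so principal-component covariates would be fitted to
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .datamodel import MISSING, GenotypeMatrix, Phenotype

Z95 = stats.norm.ppf(0.975)


@dataclass
class MarkerAssocResult:
    marker_id: str
    statistic: float            # signed trend z (nan when undefined)
    p_value: float
    allelic_or: float
    allelic_or_ci: tuple[float, float]
    counts: np.ndarray          # 2 x 3 genotype-by-status table (cases row 0)
    undefined: bool = False


def trend_test(g: GenotypeMatrix, p: Phenotype, marker_id: str) -> MarkerAssocResult:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    A marker with a single observed genotype has no trend to test: the
    statistic is reported as nan with P = 1 and ``undefined`` set.
    """
    d = g.dosage(marker_id)
    ok = d != MISSING
    dd, case = d[ok], p.is_case[ok]
    r = np.bincount(dd[case], minlength=3).astype(float)    # cases per genotype
    s = np.bincount(dd[~case], minlength=3).astype(float)   # controls
    counts = np.vstack([r, s])
    n = r + s
    N, R = n.sum(), r.sum()
    x = np.array([0.0, 1.0, 2.0])
    num = N * (x * r).sum() - R * (x * n).sum()
    den = R * (N - R) * (N * (x * x * n).sum() - (x * n).sum() ** 2)
    if den <= 0:
        return MarkerAssocResult(marker_id, float("nan"), 1.0, *_allelic_or(r, s),
                                 counts, undefined=True)
    z = num * np.sqrt(N / den)  # z^2 = N * num^2 / den (large-sample variance)
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return MarkerAssocResult(marker_id, float(z), pval, *_allelic_or(r, s), counts)


def _allelic_or(r: np.ndarray, s: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Allele-count odds ratio (minor vs major) with a Wald CI."""
    a = 2 * r[2] + r[1]          # minor alleles in cases
    b = 2 * r[0] + r[1]
    c = 2 * s[2] + s[1]
    d = 2 * s[0] + s[1]
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    lor = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(lor)), (float(np.exp(lor - Z95 * se)),
                                float(np.exp(lor + Z95 * se)))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test significance threshold alpha / n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class MetaAnalysisResult:
    pooled_or: float
    pooled_p: float
    study_ors: list[float]
    q_statistic: float          # Woolf heterogeneity Q
    q_p: float
    method: str                 # "fixed" (Mantel-Haenszel) or "random" (DL)
    continuity_corrected: bool = False


def meta_analyze(tables: list[np.ndarray], het_alpha: float = 0.05
                 ) -> MetaAnalysisResult:
    """Pool per-study 2x2 allele-count tables into one odds ratio.

    Each table is ``[[case_minor, case_major], [control_minor,
    control_major]]``.  Woolf's Q (inverse-variance weighted dispersion of
    study log-ORs around the fixed-effect pool) decides the branch: below
    ``het_alpha`` the DerSimonian-Laird random-effects pool is used,
    otherwise the Mantel-Haenszel fixed-effect pool.  The pooled P is a Wald
    test on the pooled log-OR.  Zero cells receive a 0.5 continuity
    correction (flagged).
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    arr = [np.asarray(t, dtype=float) for t in tables]
    corrected = False
    fixed = []
    for t in arr:
        if t.shape != (2, 2):
            raise ValueError("each study must be a 2x2 allele-count table")
        if (t == 0).any():
            t = t + 0.5
            corrected = True
        fixed.append(t)
    lors = np.array([np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])) for t in fixed])
    variances = np.array([(1.0 / t).sum() for t in fixed])
    w = 1.0 / variances

    pooled_iv = float((w * lors).sum() / w.sum())
    q = float((w * (lors - pooled_iv) ** 2).sum())
    q_p = float(stats.chi2.sf(q, len(fixed) - 1))

    if q_p < het_alpha:
        # DerSimonian-Laird: tau^2 truncated at zero
        tau2 = max(0.0, (q - (len(fixed) - 1)) / (w.sum() - (w * w).sum() / w.sum()))
        wr = 1.0 / (variances + tau2)
        lor = float((wr * lors).sum() / wr.sum())
        se = float(1.0 / np.sqrt(wr.sum()))
        method = "random"
    else:
        strat = StratifiedTable(np.dstack(fixed))
        lor = float(np.log(strat.oddsratio_pooled))
        lo, hi = strat.oddsratio_pooled_confint(alpha=0.05)
        se = float((np.log(hi) - np.log(lo)) / (2 * Z95))
        method = "fixed"
    z = lor / se
    return MetaAnalysisResult(
        pooled_or=float(np.exp(lor)),
        pooled_p=float(2.0 * stats.norm.sf(abs(z))),
        study_ors=[float(np.exp(v)) for v in lors],
        q_statistic=q,
        q_p=q_p,
        method=method,
        continuity_corrected=corrected,
    )
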