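"""Multifactor dimensionality reduction (MDR) for 2-way and 3-way models.

Each multi-locus genotype cell (missing genotype is its own fourth category
per marker, so a pair spans a 4x4 grid) is labelled high-risk when its
training case:control ratio reaches the sample-wide ratio T; the pair then
collapses to one binary attribute whose quality is scored by balanced
accuracy.  Reported table metrics (balanced accuracy, OR, chi-square P,
TPR/FPR) are computed on the full data from the high/low classification
counts; stratified k-fold cross-validation yields the testing balanced
accuracy and the cross-validation consistency (CVC) bookkeeping.

Labelling conventions for sparse cells: a non-empty cell with zero training
controls has an infinite ratio and is labelled high; a fully empty cell is
labelled low.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datamodel import MISSING, GenotypeMatrix, Phenotype

Z95 = stats.norm.ppf(0.975)
N_CAT = 4  # genotype categories per marker: 0, 1, 2, missing


@dataclass
class MDRModel:
    combo: tuple[str, ...]
    labels: np.ndarray              # high (True) / low per genotype cell
    threshold: float                # T = training cases / training controls
    ba_full: float
    ba_cv: float
    cvc: int
    k_folds: int
    high_cases: int
    high_controls: int
    low_cases: int
    low_controls: int
    odds_ratio: float
    or_ci: tuple[float, float]
    p_value: float                  # Pearson chi-square on the 2x2 table
    tpr: float
    fpr: float
    continuity_corrected: bool = False


def cell_index(g: GenotypeMatrix, combo: tuple[str, ...]) -> np.ndarray:
    """Flattened genotype-cell index per sample (missing -> category 3)."""
    idx = np.zeros(g.n_samples, dtype=np.int64)
    for mid in combo:
        d = g.dosage(mid).astype(np.int64)
        d = np.where(d == MISSING, N_CAT - 1, d)
        idx = idx * N_CAT + d
    return idx


def _cell_counts(idx: np.ndarray, is_case: np.ndarray, n_cells: int,
                 mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    if mask is not None:
        idx, is_case = idx[mask], is_case[mask]
    cases = np.bincount(idx[is_case], minlength=n_cells)
    controls = np.bincount(idx[~is_case], minlength=n_cells)
    return cases, controls


def label_cells(case_counts: np.ndarray, ctrl_counts: np.ndarray,
                threshold: float) -> np.ndarray:
    """High/low risk labels from per-cell training counts.

    high iff cases/controls >= T; zero-control non-empty cells are high,
    fully empty cells low.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = case_counts / ctrl_counts.astype(float)
    labels = np.zeros(case_counts.shape, dtype=bool)
    finite = ctrl_counts > 0
    labels[finite] = ratio[finite] >= threshold
    labels[(ctrl_counts == 0) & (case_counts > 0)] = True
    return labels


def mdr_label(g: GenotypeMatrix, p: Phenotype, combo: tuple[str, ...],
              training_mask: np.ndarray | None = None) -> np.ndarray:
    """Risk labels over the genotype grid from (training) data."""
    is_case = p.is_case
    if training_mask is None:
        training_mask = np.ones(g.n_samples, dtype=bool)
    if not (is_case[training_mask].any() and (~is_case[training_mask]).any()):
        raise ValueError("training mask needs at least one case and one control")
    idx = cell_index(g, combo)
    n_cells = N_CAT ** len(combo)
    cases, controls = _cell_counts(idx, is_case, n_cells, training_mask)
    threshold = cases.sum() / controls.sum()
    return label_cells(cases, controls, threshold)


def _balanced_accuracy(cases: np.ndarray, controls: np.ndarray,
                       labels: np.ndarray) -> float:
    tpr = cases[labels].sum() / cases.sum()
    fpr = controls[labels].sum() / controls.sum()
    return float((tpr + 1.0 - fpr) / 2.0)


def classification_metrics(high_cases: int, high_controls: int,
                           low_cases: int, low_controls: int) -> dict:
    """BA/OR/CI/chi-square P/TPR/FPR from high-low classification counts.

    This is the arithmetic behind a published MDR result row, applicable to
    any 2x2 classification-by-status table.
    """
    hc, hn, lc, ln = (float(high_cases), float(high_controls),
                      float(low_cases), float(low_controls))
    tpr = hc / (hc + lc)
    fpr = hn / (hn + ln)
    ba = (tpr + 1.0 - fpr) / 2.0
    corrected = 0.0 in (hc, hn, lc, ln)
    a, b, c, d = (hc, hn, lc, ln) if not corrected else \
        (hc + 0.5, hn + 0.5, lc + 0.5, ln + 0.5)
    lor = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    table = np.array([[hc, hn], [lc, ln]])
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, pval = stats.chi2_contingency(table, correction=False)[:2]
    else:
        pval = 1.0
    return {
        "ba_full": float(ba),
        "tpr": float(tpr),
        "fpr": float(fpr),
        "odds_ratio": float(np.exp(lor)),
        "or_ci": (float(np.exp(lor - Z95 * se)), float(np.exp(lor + Z95 * se))),
        "p_value": float(pval),
        "continuity_corrected": corrected,
    }


def _folds(p: Phenotype, k_folds: int, seed: int) -> list[np.ndarray]:
    """Stratified fold membership masks (True = training) with a fixed seed."""
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    masks = []
    dummy = np.zeros(p.status.size)
    for train_idx, _ in skf.split(dummy, p.status):
        m = np.zeros(p.status.size, dtype=bool)
        m[train_idx] = True
        masks.append(m)
    return masks


def mdr_evaluate(g: GenotypeMatrix, p: Phenotype, combo: tuple[str, ...],
                 k_folds: int = 10, seed: int = 0,
                 fold_masks: list[np.ndarray] | None = None) -> MDRModel:
    """Full-data MDR metrics plus cross-validated testing balanced accuracy."""
    combo = tuple(combo)
    idx = cell_index(g, combo)
    n_cells = N_CAT ** len(combo)
    is_case = p.is_case
    cases, controls = _cell_counts(idx, is_case, n_cells)
    threshold = cases.sum() / controls.sum()
    labels = label_cells(cases, controls, threshold)
    hc = int(cases[labels].sum())
    hn = int(controls[labels].sum())
    lc = int(cases[~labels].sum())
    ln = int(controls[~labels].sum())
    m = classification_metrics(hc, hn, lc, ln)

    if fold_masks is None:
        fold_masks = _folds(p, k_folds, seed)
    ba_tests = []
    for train in fold_masks:
        tc, tn = _cell_counts(idx, is_case, n_cells, train)
        t = tc.sum() / tn.sum()
        fold_labels = label_cells(tc, tn, t)
        vc, vn = _cell_counts(idx, is_case, n_cells, ~train)
        ba_tests.append(_balanced_accuracy(vc, vn, fold_labels))
    return MDRModel(
        combo=combo,
        labels=labels,
        threshold=float(threshold),
        ba_full=m["ba_full"],
        ba_cv=float(np.mean(ba_tests)),
        cvc=len(fold_masks),      # uncontested; mdr_scan overwrites
        k_folds=len(fold_masks),
        high_cases=hc, high_controls=hn, low_cases=lc, low_controls=ln,
        odds_ratio=m["odds_ratio"], or_ci=m["or_ci"], p_value=m["p_value"],
        tpr=m["tpr"], fpr=m["fpr"],
        continuity_corrected=m["continuity_corrected"],
    )


def mdr_scan(g: GenotypeMatrix, p: Phenotype, order: int = 2,
             k_folds: int = 10, seed: int = 0,
             marker_ids: list[str] | None = None) -> list[MDRModel]:
    """Exhaustive MDR over all marker combinations of the given order.

    Returns models ranked by testing balanced accuracy (ties broken by
    full-data balanced accuracy, then lexicographic combo).  CVC of a combo
    is the number of folds in which it attains the best training balanced
    accuracy (one winner per fold, same tie-break).
    """
    ids = marker_ids if marker_ids is not None else g.marker_ids
    if len(ids) < order:
        raise ValueError(f"need at least {order} markers")
    fold_masks = _folds(p, k_folds, seed)
    is_case = p.is_case
    n_cells = N_CAT ** order

    models: list[MDRModel] = []
    train_bas = np.zeros((0, k_folds))
    rows = []
    for combo in combinations(ids, order):
        idx = cell_index(g, combo)
        model = mdr_evaluate(g, p, combo, fold_masks=fold_masks)
        per_fold = []
        for train in fold_masks:
            tc, tn = _cell_counts(idx, is_case, n_cells, train)
            t = tc.sum() / tn.sum()
            per_fold.append(
                _balanced_accuracy(tc, tn, label_cells(tc, tn, t))
            )
        rows.append(per_fold)
        models.append(model)
    train_bas = np.array(rows)  # (n_models, k_folds)

    # one CVC winner per fold: best training BA, ties by full BA then combo
    order_key = [(-m.ba_full, m.combo) for m in models]
    cvc = np.zeros(len(models), dtype=int)
    for f in range(k_folds):
        col = train_bas[:, f]
        best = np.flatnonzero(col == col.max())
        winner = min(best, key=lambda i: order_key[i])
        cvc[winner] += 1
    for m_i, model in enumerate(models):
        model.cvc = int(cvc[m_i])

    models.sort(key=lambda m: (-m.ba_cv, -m.ba_full, m.combo))
    return models
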