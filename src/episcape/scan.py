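"""Scan orchestration: marker prioritization, pairwise scans, permutation
family-wise correction, top-fraction extraction and cross-method correlation.

Regression scans (additive and multiplicative) run on a vectorized path:
joint-exposure categories are computed once per pair and case/control cell
counts for any phenotype relabelling reduce to one indicator-matrix product,
which makes the permutation engine (re-scanning under B phenotype
permutations and recording the best statistic of each) affordable.  A test
guarantees the vectorized statistics agree with the per-table fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, Coding, GenotypeMatrix, Phenotype, code_exposure
from .mdr import mdr_scan
from .pair_tables import RECODING_SCHEMES, SCHEME_ORDER

Method = Literal["additive", "multiplicative", "mdr"]


# ---------------------------------------------------------------------------
# Marker prioritization


@dataclass
class SeedMarkerSet:
    """Scan seeds: main-effect markers plus filter-selected ones (disjoint)."""

    main_effect: list[str]
    filter_selected: list[str]

    @property
    def seeds(self) -> list[str]:
        return list(self.main_effect) + list(self.filter_selected)

    def __len__(self) -> int:
        return len(self.main_effect) + len(self.filter_selected)


def relieff_scores(g: GenotypeMatrix, p: Phenotype, n_neighbors: int = 10,
                   n_probes: int | None = 300, seed: int = 0) -> np.ndarray:
    """ReliefF relevance score per marker.

    Standard ReliefF for discrete genotype attributes: for each probe sample,
    the k nearest hits (same status) and k nearest misses (other status)
    under a normalized Manhattan dosage distance pull each marker's weight
    down (hits differing) or up (misses differing).  Missing dosages
    contribute a neutral half-difference.  Probes are subsampled for large n.
    """
    rng = np.random.default_rng(seed)
    D = g.dosages.astype(float)
    D[D == MISSING] = np.nan
    n, m = D.shape
    probes = np.arange(n)
    if n_probes is not None and n_probes < n:
        probes = rng.choice(n, size=n_probes, replace=False)
    status = p.status
    w = np.zeros(m)
    half = 0.5
    for i in probes:
        diff = np.abs(D - D[i]) / 2.0          # per-marker difference in [0,1]
        diff = np.where(np.isnan(diff), half, diff)
        dist = diff.sum(axis=1)
        dist[i] = np.inf
        same = status == status[i]
        same[i] = False
        hits = np.flatnonzero(same)
        misses = np.flatnonzero(~same & (np.arange(n) != i))
        kh = min(n_neighbors, hits.size)
        km = min(n_neighbors, misses.size)
        nh = hits[np.argsort(dist[hits], kind="stable")[:kh]]
        nm = misses[np.argsort(dist[misses], kind="stable")[:km]]
        if kh:
            w -= diff[nh].mean(axis=0)
        if km:
            w += diff[nm].mean(axis=0)
    return w / probes.size


def prioritize(g: GenotypeMatrix, p: Phenotype, p_threshold: float = 0.05,
               n_filter: int = 49, trend_pvalues: dict[str, float] | None = None,
               seed: int = 0, **relieff_kwargs) -> SeedMarkerSet:
    """Seed markers = {trend P < threshold} union {top ReliefF among the rest}.

    ``trend_pvalues`` may carry precomputed single-marker P values; otherwise
    the trend test is run here.
    """
    if trend_pvalues is None:
        from .single_marker import trend_test

        trend_pvalues = {
            mid: trend_test(g, p, mid).p_value for mid in g.marker_ids
        }
    main = [mid for mid in g.marker_ids if trend_pvalues[mid] < p_threshold]
    rest = [mid for mid in g.marker_ids if mid not in set(main)]
    if n_filter > len(rest):
        n_filter = len(rest)
    filt: list[str] = []
    if n_filter > 0 and rest:
        scores = relieff_scores(g, p, seed=seed, **relieff_kwargs)
        by_id = dict(zip(g.marker_ids, scores))
        rest_sorted = sorted(rest, key=lambda mid: (-by_id[mid], mid))
        filt = rest_sorted[:n_filter]
    return SeedMarkerSet(main_effect=main, filter_selected=filt)


# ---------------------------------------------------------------------------
# Pair enumeration


@dataclass
class PairEnumeration:
    pairs: list[tuple[str, str]]    # unique unordered pairs (sorted keys)
    n_evaluations: int              # raw count: seeds x all keeps self/dup pairs
    mode: str = "exhaustive"


def enumerate_pairs(seeds: Sequence[str] | None, markers: Sequence[str],
                    mode: str = "exhaustive") -> PairEnumeration:
    """Enumerate marker pairs for a scan.

    ``seeds_x_all``: every (seed, marker) ordered pair counts as one
    evaluation (|seeds| x |markers|, the bookkeeping used when a seed set is
    screened against a full panel); the unique unordered non-self pairs are
    what the scan actually tests.  ``exhaustive``: all C(n, 2) pairs.
    """
    if mode == "exhaustive":
        ms = list(markers)
        pairs = [
            tuple(sorted((ms[i], ms[j])))
            for i in range(len(ms))
            for j in range(i + 1, len(ms))
        ]
        return PairEnumeration(pairs, len(pairs), mode)
    if mode == "seeds_x_all":
        if seeds is None:
            raise ValueError("seeds_x_all mode requires a seed list")
        uniq = sorted(
            {tuple(sorted((s, m))) for s in seeds for m in markers if s != m}
        )
        return PairEnumeration(list(uniq), len(seeds) * len(markers), mode)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Vectorized regression statistics over many pairs


def _exposure_matrix(g: GenotypeMatrix, marker_ids: Sequence[str],
                     coding: Coding) -> np.ndarray:
    cols = [code_exposure(g, mid, coding) for mid in marker_ids]
    return np.stack(cols, axis=1)  # (n_samples, n_markers) in {0,1,-1}


def _category_indicators(E: np.ndarray, pair_idx: np.ndarray) -> np.ndarray:
    """(n_pairs, 4, n_samples) float indicators of joint-exposure cells.

    Samples missing either exposure have all-zero indicators (complete-case
    per pair).
    """
    ea = E[:, pair_idx[:, 0]].T  # (n_pairs, n)
    eb = E[:, pair_idx[:, 1]].T
    ok = (ea != MISSING) & (eb != MISSING)
    cat = (2 * ea + eb).astype(np.int8)
    ind = np.zeros((pair_idx.shape[0], 4, E.shape[0]), dtype=np.float64)
    for c in range(4):
        ind[:, c, :] = ok & (cat == c)
    return ind


def _pair_counts(ind: np.ndarray, is_case: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    case = is_case.astype(np.float64)
    cases = ind @ case                 # (n_pairs, 4)
    controls = ind @ (1.0 - case)
    return cases, controls


def _mult_stats(cases: np.ndarray, controls: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form multiplicative interaction fit.

    Returns (beta3, z, p).  Zero cells get the 0.5 correction per pair.
    """
    zero = (cases == 0).any(axis=1) | (controls == 0).any(axis=1)
    c = cases + 0.5 * zero[:, None]
    k = controls + 0.5 * zero[:, None]
    lo = np.log(c / k)
    beta3 = lo[:, 3] - lo[:, 2] - lo[:, 1] + lo[:, 0]
    se = np.sqrt((1.0 / c + 1.0 / k).sum(axis=1))
    z = beta3 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta3, z, p


def _recode_counts(cases: np.ndarray, controls: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized preventive-factor recoding (same rule as recode_preventive)."""
    n = cases.shape[0]
    perms = np.array([RECODING_SCHEMES[s] for s in SCHEME_ORDER])  # (4 schemes, 4)
    cc = cases[:, perms]        # (n_pairs, 4 schemes, 4 cells)
    kk = controls[:, perms]
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = cc / kk
        or01 = odds[:, :, 1] / odds[:, :, 0]
        or10 = odds[:, :, 2] / odds[:, :, 0]
        min_or = np.where(
            np.isnan(or01) | np.isnan(or10), -np.inf, np.minimum(or01, or10)
        )
    ok = min_or >= 1.0
    first_ok = np.argmax(ok, axis=1)
    chosen = np.where(ok.any(axis=1), first_ok, np.argmax(min_or, axis=1))
    rows = np.arange(n)
    return cc[rows, chosen], kk[rows, chosen], chosen


def _additive_stats(cases: np.ndarray, controls: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized RERI/AP fit on (already recoded) counts: (ap, z, p)."""
    zero = (cases == 0).any(axis=1) | (controls == 0).any(axis=1)
    c = cases + 0.5 * zero[:, None]
    k = controls + 0.5 * zero[:, None]
    odds = c / k
    or01 = odds[:, 1] / odds[:, 0]
    or10 = odds[:, 2] / odds[:, 0]
    or11 = odds[:, 3] / odds[:, 0]
    reri = or11 - or01 - or10 + 1.0
    ap = reri / or11
    # expanded form of additive._ap_variance, vectorized over pairs
    v = 1.0 / c + 1.0 / k
    g1 = (or01 - 1.0) / or11
    g2 = (or10 - 1.0) / or11
    g3 = (or10 + or01 - 1.0) / or11
    var = (
        g1 * g1 * (v[:, 2] + v[:, 0])
        + g2 * g2 * (v[:, 1] + v[:, 0])
        + g3 * g3 * v.sum(axis=1)
        + 2 * g1 * g2 * v[:, 0]
        - 2 * g1 * g3 * (v[:, 2] + v[:, 0])
        - 2 * g2 * g3 * (v[:, 1] + v[:, 0])
    )
    se = np.sqrt(var)
    z = ap / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ap, z, p


# ---------------------------------------------------------------------------
# Scans


@dataclass
class ScanResult:
    method: str                      # additive_dom, mult_rec, mdr, ...
    table: pd.DataFrame              # ranked records; 'stat' = ranking statistic
    n_tests: int                     # raw evaluation count
    n_unique: int                    # unique unordered pairs

    def pair_keys(self) -> pd.Series:
        return self.table["marker_1"] + "|" + self.table["marker_2"]


def _method_name(method: Method, coding: Coding | None) -> str:
    if method == "mdr":
        return "mdr"
    prefix = {"additive": "additive", "multiplicative": "mult"}[method]
    return f"{prefix}_{'dom' if coding == 'dominant' else 'rec'}"


def scan_regression(g: GenotypeMatrix, p: Phenotype,
                    enumeration: PairEnumeration, method: Method,
                    coding: Coding) -> ScanResult:
    """Additive or multiplicative scan over an enumerated pair list."""
    pairs = enumeration.pairs
    ids = sorted({m for ab in pairs for m in ab})
    col = {m: j for j, m in enumerate(ids)}
    E = _exposure_matrix(g, ids, coding)
    pair_idx = np.array([[col[a], col[b]] for a, b in pairs], dtype=np.int64)
    ind = _category_indicators(E, pair_idx)
    cases, controls = _pair_counts(ind, p.is_case)
    degenerate = (cases.sum(axis=1) == 0) | (controls.sum(axis=1) == 0)

    if method == "multiplicative":
        beta3, z, pv = _mult_stats(cases, controls)
        extra = {"beta3": beta3, "or3": np.exp(beta3)}
        recoding = np.zeros(len(pairs), dtype=int)
    else:
        rc, rk, recoding = _recode_counts(cases, controls)
        ap, z, pv = _additive_stats(rc, rk)
        extra = {"ap": ap}
    pv = np.where(degenerate, 1.0, pv)
    df = pd.DataFrame(
        {
            "marker_1": [a for a, _ in pairs],
            "marker_2": [b for _, b in pairs],
            **extra,
            "p_value": pv,
            "recoding": [SCHEME_ORDER[i] for i in recoding],
            "degenerate": degenerate,
        }
    )
    with np.errstate(divide="ignore"):
        df["stat"] = -np.log10(df["p_value"].clip(lower=1e-300))
    df = df.sort_values(
        ["stat", "marker_1", "marker_2"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return ScanResult(
        _method_name(method, coding), df, enumeration.n_evaluations, len(pairs)
    )


def scan_mdr(g: GenotypeMatrix, p: Phenotype,
             marker_ids: Sequence[str] | None = None, order: int = 2,
             k_folds: int = 10, seed: int = 0) -> ScanResult:
    """Exhaustive MDR scan wrapped into the common ScanResult shape."""
    models = mdr_scan(g, p, order=order, k_folds=k_folds, seed=seed,
                      marker_ids=list(marker_ids) if marker_ids else None)
    rows = []
    for m in models:
        key = sorted(m.combo)  # lexicographic keys shared with regression scans
        rows.append(
            {
                "marker_1": key[0],
                "marker_2": key[-1] if order == 2 else "|".join(key[1:]),
                "ba_cv": m.ba_cv,
                "ba_full": m.ba_full,
                "cvc": m.cvc,
                "odds_ratio": m.odds_ratio,
                "p_value": m.p_value,
                "stat": m.ba_cv,
            }
        )
    df = pd.DataFrame(rows)
    return ScanResult("mdr", df, len(models), len(models))


# ---------------------------------------------------------------------------
# Permutation-based family-wise error control


@dataclass
class PermutationResult:
    permuted_p: np.ndarray       # aligned with the observed ScanResult table
    fwer_threshold: float        # 95th percentile of the permutation-best stat
    best_stats: np.ndarray       # (B,) best statistic per permutation
    b: int


def permute_fwer(g: GenotypeMatrix, p: Phenotype, observed: ScanResult,
                 method: Method, coding: Coding | None, b: int, seed: int,
                 enumeration: PairEnumeration | None = None,
                 mdr_marker_ids: Sequence[str] | None = None
                 ) -> PermutationResult:
    """Max-statistic permutation correction for one scan.

    Phenotype labels are permuted ``b`` times; each permutation is re-scanned
    and its best ranking statistic recorded.  The permuted P of an observed
    record is (1 + #{permutation best >= observed}) / (b + 1) (add-one
    estimator), and the FWER threshold is the 95th percentile of the
    permutation-best distribution.  For regressions the statistic is
    -log10 P; for MDR the full-data balanced accuracy.
    """
    if b < 1:
        raise ValueError("permutation count must be >= 1")
    rng = np.random.default_rng(seed)
    status = p.status
    best = np.empty(b)

    if method in ("additive", "multiplicative"):
        if enumeration is None:
            raise ValueError("regression permutation needs the pair enumeration")
        pairs = enumeration.pairs
        ids = sorted({m for ab in pairs for m in ab})
        col = {m: j for j, m in enumerate(ids)}
        E = _exposure_matrix(g, ids, coding)
        pair_idx = np.array([[col[a], col[b_]] for a, b_ in pairs])
        ind = _category_indicators(E, pair_idx)

        def best_stat(is_case: np.ndarray) -> float:
            cases, controls = _pair_counts(ind, is_case)
            degen = (cases.sum(axis=1) == 0) | (controls.sum(axis=1) == 0)
            if method == "multiplicative":
                _, _, pv = _mult_stats(cases, controls)
            else:
                rc, rk, _ = _recode_counts(cases, controls)
                _, _, pv = _additive_stats(rc, rk)
            pv = np.where(degen, 1.0, pv)
            return float(-np.log10(max(pv.min(), 1e-300)))

        for i in range(b):
            best[i] = best_stat(rng.permutation(status) == 1)
    elif method == "mdr":
        from .mdr import N_CAT, _cell_counts, cell_index, label_cells

        ids = list(mdr_marker_ids) if mdr_marker_ids else g.marker_ids
        enum = enumerate_pairs(None, ids, "exhaustive")
        idx_list = [cell_index(g, pair) for pair in enum.pairs]
        n_cells = N_CAT ** 2

        def best_ba(is_case: np.ndarray) -> float:
            out = 0.0
            for idx in idx_list:
                cases, controls = _cell_counts(idx, is_case, n_cells)
                t = cases.sum() / controls.sum()
                labels = label_cells(cases, controls, t)
                tpr = cases[labels].sum() / cases.sum()
                fpr = controls[labels].sum() / controls.sum()
                out = max(out, (tpr + 1.0 - fpr) / 2.0)
            return out

        for i in range(b):
            best[i] = best_ba(rng.permutation(status) == 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    obs = observed.table["stat"].to_numpy()
    exceed = (best[None, :] >= obs[:, None]).sum(axis=1)
    permuted_p = (1.0 + exceed) / (b + 1.0)
    return PermutationResult(
        permuted_p=permuted_p,
        fwer_threshold=float(np.quantile(best, 0.95)),
        best_stats=best,
        b=b,
    )


# ---------------------------------------------------------------------------
# Top fraction and cross-method correlation


def top_fraction(result: ScanResult, q: float) -> pd.DataFrame:
    """Best ceil(q * n) records by the method's ranking statistic."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    n = int(np.ceil(q * result.n_tests))
    n = max(1, min(n, len(result.table)))
    return result.table.head(n)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_joined: int
    joined: pd.DataFrame


def correlate_methods(a: ScanResult, b: ScanResult, q: float = 0.005
                      ) -> CorrelationResult:
    """Pearson correlation of ranking statistics: top q of ``a`` joined
    against the full table of ``b`` on unordered pair keys."""
    top = top_fraction(a, q).copy()
    top["key"] = top["marker_1"] + "|" + top["marker_2"]
    bt = b.table.copy()
    bt["key"] = bt["marker_1"] + "|" + bt["marker_2"]
    joined = top.merge(
        bt[["key", "stat"]], on="key", suffixes=("_a", "_b")
    )
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} shared pairs between {a.method} and "
            f"{b.method}; correlation undefined"
        )
    if joined["stat_a"].nunique() < 2 or joined["stat_b"].nunique() < 2:
        raise ValueError("constant statistics; correlation undefined")
    r, pv = stats.pearsonr(joined["stat_a"], joined["stat_b"])
    return CorrelationResult(float(r), float(pv), len(joined), joined)
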