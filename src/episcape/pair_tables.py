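"""Joint-exposure tables for marker pairs and preventive-factor recoding.

A marker pair under a dominant/recessive coding collapses to four joint
binary-exposure cells 00/01/10/11 (marker-1 exposure first).  Before additive
interaction statistics are computed, cell labels are permuted so that both
single-exposure odds ratios (vs the relabelled 00 cell) are risk-conferring
(>= 1); the three non-identity relabelling schemes mirror the ones used in
published top-10 interaction tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import MISSING, Coding, GenotypeMatrix, Phenotype, code_exposure

CELL_LABELS = ("00", "01", "10", "11")

# scheme name -> new_counts = old_counts[perm]
# flipA:     exposure of marker 1 is inverted                (00->10, 01->11, 10->00, 11->01)
# swap_flip: markers swapped, then new marker-2 exposure inverted
#                                                            (00->01, 01->11, 10->00, 11->10)
# flip_both: both exposures inverted                         (00->11, 01->10, 10->01, 11->00)
RECODING_SCHEMES: dict[str, tuple[int, int, int, int]] = {
    "identity": (0, 1, 2, 3),
    "flipA": (2, 3, 0, 1),
    "swap_flip": (2, 0, 3, 1),
    "flip_both": (3, 2, 1, 0),
}
SCHEME_ORDER = ("identity", "flipA", "swap_flip", "flip_both")


@dataclass
class PairExposureTable:
    """Case/control counts in the four joint-exposure cells of a marker pair."""

    cases: np.ndarray        # counts in cells 00, 01, 10, 11
    controls: np.ndarray
    pair: tuple[str, str]
    coding: tuple[Coding, Coding]
    recoding: str = "identity"
    recoding_forced: bool = False  # no scheme achieved both ORs >= 1

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=np.int64)
        self.controls = np.asarray(self.controls, dtype=np.int64)
        if self.cases.shape != (4,) or self.controls.shape != (4,):
            raise ValueError("expected four case and four control cell counts")
        if (self.cases < 0).any() or (self.controls < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def n_complete(self) -> int:
        return int(self.cases.sum() + self.controls.sum())

    @property
    def degenerate(self) -> bool:
        """True when either status stratum is empty."""
        return self.cases.sum() == 0 or self.controls.sum() == 0

    def odds_ratios(self) -> np.ndarray:
        """(OR00=1, OR01, OR10, OR11) vs the 00 cell; nan where undefined."""
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = self.cases / self.controls.astype(float)
            return np.asarray(odds / odds[0])

    def to_dict(self) -> dict:
        d = {"marker_1": self.pair[0], "marker_2": self.pair[1],
             "coding_1": self.coding[0], "coding_2": self.coding[1],
             "recoding": self.recoding, "n_complete": self.n_complete}
        for i, lab in enumerate(CELL_LABELS):
            d[f"cases_{lab}"] = int(self.cases[i])
            d[f"controls_{lab}"] = int(self.controls[i])
        return d


def build_table(g: GenotypeMatrix, p: Phenotype, pair: tuple[str, str],
                coding: Coding | tuple[Coding, Coding]) -> PairExposureTable:
    """Complete-case cross-tabulation of two binary exposures by status.

    Samples missing either genotype are dropped (per-pair complete case).
    """
    if isinstance(coding, str):
        coding = (coding, coding)
    ea = code_exposure(g, pair[0], coding[0])
    eb = code_exposure(g, pair[1], coding[1])
    ok = (ea != MISSING) & (eb != MISSING)
    cell = 2 * ea[ok].astype(np.int64) + eb[ok]
    case = p.is_case[ok]
    cases = np.bincount(cell[case], minlength=4)
    controls = np.bincount(cell[~case], minlength=4)
    return PairExposureTable(cases, controls, tuple(pair), coding)


def apply_scheme(t: PairExposureTable, scheme: str) -> PairExposureTable:
    """Relabel cells by one named scheme; counts move with their labels."""
    perm = list(RECODING_SCHEMES[scheme])
    return replace(
        t, cases=t.cases[perm], controls=t.controls[perm], recoding=scheme
    )


def _min_single_or(t: PairExposureTable) -> float:
    ors = t.odds_ratios()
    vals = ors[[1, 2]]
    if np.isnan(vals).any():
        return float("-inf")
    return float(vals.min())


def recode_preventive(t: PairExposureTable) -> PairExposureTable:
    """Permute cell labels so both single exposures confer risk.

    Tries the four schemes in the fixed order identity, flipA, swap_flip,
    flip_both and returns the first under which OR01 >= 1 and OR10 >= 1
    (odds ratios relative to the relabelled 00 cell).  If no scheme succeeds,
    the scheme maximizing min(OR01, OR10) is applied and
    ``recoding_forced`` is set.
    """
    if t.degenerate:
        raise ValueError("cannot recode a degenerate table")
    candidates = [apply_scheme(t, s) for s in SCHEME_ORDER]
    for cand in candidates:
        if _min_single_or(cand) >= 1.0:
            return cand
    best = max(candidates, key=_min_single_or)
    return replace(best, recoding_forced=True)
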