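"""Genotype/phenotype containers, file I/O, genetic codings and LD utilities.

Genotypes are stored as minor-allele dosages (0, 1, 2) with ``MISSING`` (-1)
for untyped or unparseable entries.  For PLINK-style ``.ped`` input the minor
allele is determined per marker from the pooled allele frequency; the TSV
dialect is already dosage-coded and is read verbatim, which makes a
write-then-read round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

MISSING = -1

Coding = Literal["dominant", "recessive"]
CODINGS: tuple[Coding, ...] = ("dominant", "recessive")


class FormatError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


class MarkerLookupError(KeyError):
    """Raised when a marker_id is not present in a GenotypeMatrix."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic autosomal marker."""

    marker_id: str
    chromosome: int = 1
    position: int = 0
    gene: str = ""

    def __post_init__(self) -> None:
        if not 1 <= int(self.chromosome) <= 22:
            raise ValueError(
                f"marker {self.marker_id}: chromosome must be autosomal (1-22), "
                f"got {self.chromosome}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage grid with aligned marker metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_markers)
        Minor-allele counts in {0, 1, 2} with -1 for missing.
    markers : sequence of MarkerInfo
    sample_ids : sequence of str
    """

    dosages: np.ndarray
    markers: list[MarkerInfo]
    sample_ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.markers = list(self.markers)
        self.sample_ids = list(self.sample_ids)
        if self.dosages.ndim != 2 or self.dosages.shape != (
            len(self.sample_ids),
            len(self.markers),
        ):
            raise ValueError(
                f"dosage grid shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1 (missing)}")
        ids = [m.marker_id for m in self.markers]
        self._index = {mid: j for j, mid in enumerate(ids)}
        if len(self._index) != len(ids):
            raise ValueError("marker_ids must be unique within a dataset")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise MarkerLookupError(f"unknown marker_id {marker_id!r}") from None

    def dosage(self, marker_id: str) -> np.ndarray:
        """Dosage column for one marker (int8, -1 missing)."""
        return self.dosages[:, self.index(marker_id)]

    def monomorphic(self) -> np.ndarray:
        """Boolean flag per marker: no dosage variation among typed samples."""
        out = np.empty(self.n_markers, dtype=bool)
        for j in range(self.n_markers):
            col = self.dosages[:, j]
            obs = col[col != MISSING]
            out[j] = obs.size == 0 or (obs == obs[0]).all()
        return out

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.index(m) for m in marker_ids]
        return GenotypeMatrix(
            self.dosages[:, idx], [self.markers[j] for j in idx], self.sample_ids
        )


@dataclass
class Phenotype:
    """Binary disease status aligned with a GenotypeMatrix (1 = case)."""

    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (control) or 1 (case)")
        if self.status.sum() == 0 or self.status.sum() == self.status.size:
            raise ValueError("need at least one case and one control")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(self.status.size - self.status.sum())

    @property
    def is_case(self) -> np.ndarray:
        return self.status == 1


def code_exposure(g: GenotypeMatrix, marker_id: str, coding: Coding) -> np.ndarray:
    """Collapse a 3-level dosage to a binary exposure.

    dominant: carriers of the minor allele ({1,2}) are exposed;
    recessive: only minor-allele homozygotes ({2}) are exposed.
    Missing dosages stay missing (-1).
    """
    d = g.dosage(marker_id)
    out = np.full(d.shape, MISSING, dtype=np.int8)
    if coding == "dominant":
        out[d == 0] = 0
        out[(d == 1) | (d == 2)] = 1
    elif coding == "recessive":
        out[(d == 0) | (d == 1)] = 0
        out[d == 2] = 1
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return out


def ld_r2(g: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Composite (dosage-correlation) LD r-squared between two markers.

    Squared Pearson correlation of the dosage vectors over pairwise-complete
    samples.  Returns ``nan`` (undefined, distinct from 0) when fewer than two
    complete samples remain or either marker is constant among them.
    """
    da, db = g.dosage(marker_a), g.dosage(marker_b)
    ok = (da != MISSING) & (db != MISSING)
    x, y = da[ok].astype(float), db[ok].astype(float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _pair_markers(item) -> tuple[str, str]:
    if hasattr(item, "pair"):
        return tuple(item.pair)  # type: ignore[return-value]
    a, b = item[0], item[1]
    return str(a), str(b)


def prune_top_list(results: Iterable, g: GenotypeMatrix, r2_max: float = 0.2,
                   k: int = 10) -> list:
    """Greedy LD pruning of a significance-ranked pair list.

    Scanning from the best rank, a candidate pair is dropped when it is
    redundant with an already-kept pair: both of its markers are in LD
    (r-squared > ``r2_max``, identical markers counting as r-squared 1) with
    the kept pair's markers under either alignment of the two slots.  A pair
    that merely shares one marker with a kept pair is retained, matching how
    published top-10 tables keep one marker paired with several uncorrelated
    partners.  Stops once ``k`` pairs are kept.
    """

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        v = ld_r2(g, a, b)
        return 0.0 if np.isnan(v) else v

    kept: list = []
    for item in results:
        if len(kept) >= k:
            break
        a, b = _pair_markers(item)
        redundant = False
        for prev in kept:
            p, q = _pair_markers(prev)
            if (r2(a, p) > r2_max and r2(b, q) > r2_max) or (
                r2(a, q) > r2_max and r2(b, p) > r2_max
            ):
                redundant = True
                break
        if not redundant:
            kept.append(item)
    return kept


# ---------------------------------------------------------------------------
# File I/O


def read_genotypes(path, format: str | None = None, markers_path=None
                   ) -> tuple[GenotypeMatrix, Phenotype]:
    """Read genotype + phenotype data from a ``.ped/.map`` pair or a TSV.

    TSV dialect: header row; first two columns ``sample_id`` and ``status``
    (``case``/``control`` or 1/0), remaining columns are marker_ids holding
    dosage tokens 0/1/2; anything else (NA, blanks, stray strings) becomes
    missing.  ``markers_path`` may point to a tab-separated marker metadata
    table (marker_id, chromosome, position, gene).
    """
    path = Path(path)
    if format is None:
        format = "ped" if path.suffix == ".ped" else "tsv"
    if format == "ped":
        return _read_ped(path)
    if format == "tsv":
        return _read_tsv(path, markers_path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path, markers_path=None) -> tuple[GenotypeMatrix, Phenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "status"]:
        raise FormatError(
            f"{path}: TSV dialect requires 'sample_id' and 'status' as the "
            "first two columns followed by marker columns"
        )
    sample_ids = df["sample_id"].astype(str).tolist()
    status_map = {"case": 1, "1": 1, "control": 0, "0": 0}
    try:
        status = np.array([status_map[str(s).strip().lower()] for s in df["status"]])
    except KeyError as exc:
        raise FormatError(f"{path}: unrecognized status token {exc}") from None
    marker_ids = list(df.columns[2:])
    dos = df.iloc[:, 2:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    dos[~np.isin(dos, (0.0, 1.0, 2.0))] = MISSING
    dos = np.nan_to_num(dos, nan=MISSING).astype(np.int8)

    meta = {m: MarkerInfo(m, 1, j + 1) for j, m in enumerate(marker_ids)}
    if markers_path is not None:
        mdf = pd.read_csv(markers_path, sep="\t", dtype=str)
        for _, row in mdf.iterrows():
            mid = str(row["marker_id"])
            if mid in meta:
                meta[mid] = MarkerInfo(
                    mid,
                    int(row.get("chromosome", 1)),
                    int(row.get("position", 0)),
                    str(row.get("gene", "") or ""),
                )
    g = GenotypeMatrix(dos, [meta[m] for m in marker_ids], sample_ids)
    return g, Phenotype(status)


def _read_ped(ped_path: Path) -> tuple[GenotypeMatrix, Phenotype]:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FormatError(f"companion .map file not found for {ped_path}")
    mdf = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mdf.shape[1] == 3:  # chrom, id, pos (no genetic distance column)
        mdf.columns = ["chrom", "marker_id", "position"]
    elif mdf.shape[1] >= 4:
        mdf = mdf.iloc[:, :4]
        mdf.columns = ["chrom", "marker_id", "cm", "position"]
    else:
        raise FormatError(f"{map_path}: expected 3 or 4 columns")
    markers = [
        MarkerInfo(str(r.marker_id), int(r.chrom), int(r.position))
        for r in mdf.itertuples()
    ]
    m = len(markers)

    rows: list[list[str]] = []
    for line in ped_path.read_text().splitlines():
        tok = line.split()
        if not tok:
            continue
        if len(tok) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}: line with {len(tok)} fields does not match "
                f"{m} markers from {map_path}"
            )
        rows.append(tok)
    sample_ids, status_list, allele_rows = [], [], []
    for tok in rows:
        st = {"1": 0, "2": 1}.get(tok[5])
        if st is None:  # unknown phenotype: sample dropped
            continue
        sample_ids.append(tok[1])
        status_list.append(st)
        allele_rows.append(tok[6:])
    if not sample_ids:
        raise FormatError(f"{ped_path}: no samples with a 1/2 phenotype code")

    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)
    dos = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        a = alleles[:, j, :]
        flat = a.ravel()
        obs = flat[flat != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size > 2:
            raise FormatError(
                f"marker {markers[j].marker_id}: more than two alleles observed"
            )
        typed = (a != "0").all(axis=1)
        if uniq.size == 0:
            continue  # fully missing marker
        if uniq.size == 1:
            # monomorphic: the minor allele is the unobserved one
            dos[typed, j] = 0
            continue
        # minor = least frequent allele; tie broken to the lexicographically
        # later allele for determinism
        minor = uniq[np.argmin(counts)] if counts[0] != counts[1] \
            else sorted(uniq)[-1]
        dos[typed, j] = (a[typed] == minor).sum(axis=1)
    g = GenotypeMatrix(dos, markers, sample_ids)
    return g, Phenotype(np.array(status_list))


def write_genotypes(g: GenotypeMatrix, p: Phenotype, path,
                    markers_path=None) -> None:
    """Write the TSV dialect (and optionally a marker metadata table)."""
    df = pd.DataFrame(
        g.dosages.astype(object), columns=g.marker_ids
    )
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "status", np.where(p.is_case, "case", "control"))
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    if markers_path is not None:
        pd.DataFrame(
            [
                {
                    "marker_id": m.marker_id,
                    "chromosome": m.chromosome,
                    "position": m.position,
                    "gene": m.gene,
                }
                for m in g.markers
            ]
        ).to_csv(markers_path, sep="\t", index=False)
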