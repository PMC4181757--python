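"""Case-control genotype simulator with known interaction structure.

The generator emulates the structure of a candidate-gene case-control study:
biallelic autosomal markers drawn under Hardy-Weinberg equilibrium with
per-marker MAF uniform on a configurable range, a common-disease baseline
prevalence (default 15%), and optional planted effects:

* ``main`` — a single-marker log-odds effect,
* ``multiplicative_pair`` — a logistic model with two binary exposures and a
  product term (interaction OR = exp(beta3)),
* ``additive_pair`` — exposure-category risks specified on the risk-ratio
  scale, R(xa, xb) = R00 * [1 + (ORa-1)xa + (ORb-1)xb + RERI*xa*xb], the
  generative counterpart of the RERI/AP statistics,
* ``epistatic_grid`` — an arbitrary 3x3 penetrance grid over the two
  genotypes (purely epistatic patterns such as XOR grids live here).

Disease status is assigned per individual from the risk model and cases and
controls are accumulated by rejection sampling to the exact configured group
sizes (the case-control design fixes group sizes by construction, so
prevalence-weighted sampling would be the wrong generative model).  Missing
genotypes are inserted independently at a configurable rate afterwards.  The
truth record stores every generating parameter together with derived
estimands (e.g. the odds-scale AP implied by an additive pair under the
configured baseline prevalence, which is what a case-control estimator
converges to).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .datamodel import MISSING, Coding, GenotypeMatrix, MarkerInfo, Phenotype


class SimulationError(RuntimeError):
    """Raised when the requested case/control quota cannot be reached."""


@dataclass
class EffectSpec:
    """One planted genetic effect.

    ``markers`` are column indices into the simulated matrix.  ``coding``
    applies to the binary-exposure kinds.  Effect sizes: ``or_main`` for
    ``main``; ``or_a``/``or_b`` plus ``or_interaction`` (odds scale) for
    ``multiplicative_pair``; ``or_a``/``or_b`` (risk-ratio scale) plus
    ``reri`` for ``additive_pair``; ``penetrance`` (3x3, rows = genotype of
    the first marker) for ``epistatic_grid``.  ``mafs`` optionally pins the
    MAF of the effect markers (e.g. 0.5 for an XOR grid with equal
    marginals).
    """

    kind: str
    markers: tuple[int, ...]
    coding: Coding = "dominant"
    or_main: float = 1.0
    or_a: float = 1.0
    or_b: float = 1.0
    or_interaction: float = 1.0
    reri: float = 0.0
    penetrance: Optional[Sequence[Sequence[float]]] = None
    mafs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.markers = tuple(int(m) for m in self.markers)
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("effect marker indices must be distinct")
        n_expected = 1 if self.kind == "main" else 2
        if len(self.markers) != n_expected:
            raise ValueError(f"{self.kind} effect needs {n_expected} marker(s)")
        if self.kind not in ("main", "multiplicative_pair", "additive_pair",
                             "epistatic_grid"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "epistatic_grid":
            pen = np.asarray(self.penetrance, dtype=float)
            if pen.shape != (3, 3) or (pen < 0).any() or (pen > 1).any():
                raise ValueError("penetrance must be a 3x3 grid of values in [0,1]")
            self.penetrance = pen


@dataclass
class SimConfig:
    """Study-scale defaults mirror the modelled cohort: 1,732 cases, 1,783
    controls, 3,704 markers, 15% baseline prevalence."""

    n_cases: int = 1732
    n_controls: int = 1783
    n_markers: int = 3704
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    baseline_prevalence: float = 0.15
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0
    n_genes: int = 63            # markers are grouped into this many gene labels

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        for e in self.effects:
            for m in e.markers:
                if not 0 <= m < self.n_markers:
                    raise ValueError(f"effect marker index {m} out of range")


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    phenotype: Phenotype
    truth: dict


def _exposure(geno: np.ndarray, coding: Coding) -> np.ndarray:
    return (geno >= 1) if coding == "dominant" else (geno == 2)


def _risk(config: SimConfig, G: np.ndarray) -> np.ndarray:
    """Per-individual disease probability under the configured effects.

    main/multiplicative effects act on the logit of the baseline prevalence;
    additive_pair and epistatic_grid effects multiply the resulting
    probability on the risk-ratio scale.
    """
    eta = np.full(G.shape[0], logit(config.baseline_prevalence))
    rr = np.ones(G.shape[0])
    for e in config.effects:
        if e.kind == "main":
            x = _exposure(G[:, e.markers[0]], e.coding)
            eta = eta + np.log(e.or_main) * x
        elif e.kind == "multiplicative_pair":
            xa = _exposure(G[:, e.markers[0]], e.coding)
            xb = _exposure(G[:, e.markers[1]], e.coding)
            eta = eta + np.log(e.or_a) * xa + np.log(e.or_b) * xb \
                + np.log(e.or_interaction) * (xa & xb)
        elif e.kind == "additive_pair":
            xa = _exposure(G[:, e.markers[0]], e.coding)
            xb = _exposure(G[:, e.markers[1]], e.coding)
            rr = rr * (1.0 + (e.or_a - 1.0) * xa + (e.or_b - 1.0) * xb
                       + e.reri * (xa & xb))
        else:  # epistatic_grid
            pen = np.asarray(e.penetrance)
            rr = rr * pen[G[:, e.markers[0]], G[:, e.markers[1]]] \
                / config.baseline_prevalence
    p = expit(eta) * rr
    if (p > 1.0 + 1e-12).any():
        raise ValueError(
            "configured effects imply a disease risk above 1; reduce effect "
            "sizes or the baseline prevalence"
        )
    return np.clip(p, 0.0, 1.0)


def _additive_truth(e: EffectSpec, baseline: float) -> dict:
    """Risk-scale targets and the implied odds-scale (case-control) estimands."""
    risks = {
        "00": baseline,
        "01": baseline * e.or_b,
        "10": baseline * e.or_a,
        "11": baseline * (1.0 + (e.or_a - 1.0) + (e.or_b - 1.0) + e.reri),
    }
    odds = {k: v / (1.0 - v) for k, v in risks.items()}
    or01 = odds["01"] / odds["00"]
    or10 = odds["10"] / odds["00"]
    or11 = odds["11"] / odds["00"]
    reri_or = or11 - or01 - or10 + 1.0
    rr11 = e.or_a + e.or_b - 1.0 + e.reri
    return {
        "risks": risks,
        "ap_risk": e.reri / rr11,
        "or01": or01,
        "or10": or10,
        "or11": or11,
        "reri_or": reri_or,
        "ap_or": reri_or / or11,
    }


def simulate(config: SimConfig) -> SimResult:
    """Draw a case-control dataset with exact group sizes.

    Deterministic for a fixed ``config.seed``.  Raises
    :class:`SimulationError` if the quota is unreachable within a bounded
    number of rejection-sampling batches.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.n_markers)
    for e in config.effects:
        if e.mafs is not None:
            for m, q in zip(e.markers, e.mafs):
                mafs[m] = q

    n_total = config.n_cases + config.n_controls
    batch = max(2048, 2 * n_total)
    max_batches = 400
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    n_case = n_ctrl = 0
    for _ in range(max_batches):
        G = rng.binomial(2, mafs, size=(batch, config.n_markers)).astype(np.int8)
        p = _risk(config, G)
        y = rng.random(batch) < p
        if n_case < config.n_cases:
            take = G[y][: config.n_cases - n_case]
            if take.size:
                case_rows.append(take)
                n_case += take.shape[0]
        if n_ctrl < config.n_controls:
            take = G[~y][: config.n_controls - n_ctrl]
            if take.size:
                ctrl_rows.append(take)
                n_ctrl += take.shape[0]
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
    else:
        raise SimulationError(
            f"could not reach {config.n_cases} cases / {config.n_controls} "
            f"controls after {max_batches} sampling batches"
        )

    G = np.vstack(case_rows + ctrl_rows)
    status = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8),
         np.zeros(config.n_controls, dtype=np.int8)]
    )
    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G[miss] = MISSING

    per_gene = max(1, config.n_markers // max(1, config.n_genes))
    markers = [
        MarkerInfo(
            marker_id=f"sim{j + 1}",
            chromosome=(j // per_gene) % 22 + 1,
            position=(j % per_gene + 1) * 1000,
            gene=f"GENE{j // per_gene + 1}",
        )
        for j in range(config.n_markers)
    ]
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]
    g = GenotypeMatrix(G, markers, sample_ids)
    pheno = Phenotype(status)

    truth: dict = {
        "seed": config.seed,
        "baseline_prevalence": config.baseline_prevalence,
        "mafs": mafs.tolist(),
        "effects": [],
    }
    for e in config.effects:
        rec = asdict(e)
        if isinstance(e.penetrance, np.ndarray):
            rec["penetrance"] = e.penetrance.tolist()
        if e.kind == "additive_pair":
            rec.update(_additive_truth(e, config.baseline_prevalence))
        if e.kind == "multiplicative_pair":
            rec["beta3"] = float(np.log(e.or_interaction))
        rec["marker_ids"] = [markers[m].marker_id for m in e.markers]
        truth["effects"].append(rec)
    return SimResult(g, pheno, truth)


def xor_grid(low: float, high: float) -> np.ndarray:
    """XOR-style penetrance grid: risk is high when exactly one genotype
    carries an odd dosage.  With MAF 0.5 both marginal penetrances are equal,
    so neither marker shows a main effect."""
    pen = np.full((3, 3), low)
    for a in range(3):
        for b in range(3):
            if (a % 2) != (b % 2):
                pen[a, b] = high
    return pen
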