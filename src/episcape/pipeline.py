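"""End-to-end pipeline: data -> single-marker -> seeds -> scans ->
permutation -> metrics -> LD-pruned top-10 report tables -> cross-method
correlations -> AP diagnostics.

Every output is a pure function of (input data, configuration, seed); two
runs with the same configuration produce byte-identical TSVs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import report
from .additive import additive_fit, ap_diagnostics
from .datamodel import (Coding, GenotypeMatrix, Phenotype, prune_top_list,
                        read_genotypes)
from .metrics import auc_from_table, paf
from .multiplicative import multiplicative_fit
from .pair_tables import build_table, recode_preventive
from .scan import (PairEnumeration, ScanResult, correlate_methods,
                   enumerate_pairs, permute_fwer, prioritize, scan_mdr,
                   scan_regression, top_fraction)
from .simulate import SimConfig, simulate
from .single_marker import trend_test


@dataclass
class RunConfig:
    input_path: str | None = None        # TSV/PED input; None -> simulate
    markers_path: str | None = None
    sim: SimConfig | None = None
    methods: list[str] = field(default_factory=lambda: ["additive",
                                                        "multiplicative", "mdr"])
    codings: list[Coding] = field(default_factory=lambda: ["dominant",
                                                           "recessive"])
    pair_mode: str = "seeds_x_all"       # or "exhaustive"
    p_threshold: float = 0.05
    n_filter: int = 49
    q: float = 0.005
    r2_max: float = 0.2
    k_top: int = 10
    k_folds: int = 10
    b_permutations: int = 0              # 0 disables the permutation stage
    mdr_max_markers: int = 150           # cap for the exhaustive MDR scan
    seed: int = 0
    out_dir: str = "episcape_out"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")


def _load(config: RunConfig) -> tuple[GenotypeMatrix, Phenotype, dict | None]:
    if config.input_path is not None:
        g, p = read_genotypes(config.input_path,
                              markers_path=config.markers_path)
        return g, p, None
    sim = config.sim or SimConfig(seed=config.seed)
    res = simulate(sim)
    return res.genotypes, res.phenotype, res.truth


def _regression_records(g, p, coding, sr: ScanResult) -> pd.DataFrame:
    """Attach per-pair tables, metrics and Table-1-style columns to the
    ranked records of one regression scan."""
    rows = []
    for _, rec in sr.table.iterrows():
        pair = (rec["marker_1"], rec["marker_2"])
        t = build_table(g, p, pair, coding)
        if t.degenerate:
            continue
        rows.append(
            {
                **rec.to_dict(),
                "paf": paf(t),
                "auc": auc_from_table(t),
                **{k: v for k, v in t.to_dict().items()
                   if k.startswith(("cases_", "controls_"))},
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes TSV/JSON outputs and returns a bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, p, truth = _load(config)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1))

    # --- single-marker stage -------------------------------------------------
    assoc = [trend_test(g, p, mid) for mid in g.marker_ids]
    assoc_df = pd.DataFrame(
        {
            "marker_id": [a.marker_id for a in assoc],
            "trend_z": [a.statistic for a in assoc],
            "p_value": [a.p_value for a in assoc],
            "allelic_or": [a.allelic_or for a in assoc],
            "undefined": [a.undefined for a in assoc],
        }
    )
    report.write_tsv(assoc_df, out / "single_marker.tsv")
    trend_ps = dict(zip(assoc_df["marker_id"], assoc_df["p_value"]))

    # --- marker prioritization ----------------------------------------------
    seeds = prioritize(g, p, config.p_threshold, config.n_filter,
                       trend_pvalues=trend_ps, seed=config.seed)
    (out / "seeds.json").write_text(
        json.dumps(
            {
                "main_effect": seeds.main_effect,
                "filter_selected": seeds.filter_selected,
                "n_seeds": len(seeds),
            },
            indent=1,
        )
    )

    # --- scans ---------------------------------------------------------------
    scans: dict[str, ScanResult] = {}
    enums: dict[str, PairEnumeration] = {}
    counts_log = {"n_markers": g.n_markers, "n_cases": p.n_cases,
                  "n_controls": p.n_controls, "n_seeds": len(seeds)}
    for method in config.methods:
        if method == "mdr":
            ids = g.marker_ids[: config.mdr_max_markers]
            sr = scan_mdr(g, p, marker_ids=ids, k_folds=config.k_folds,
                          seed=config.seed)
            scans[sr.method] = sr
            report.write_tsv(sr.table, out / f"scan_{sr.method}.tsv")
            counts_log[f"n_tests_{sr.method}"] = sr.n_tests
            continue
        for coding in config.codings:
            if config.pair_mode == "seeds_x_all" and len(seeds):
                enum = enumerate_pairs(seeds.seeds, g.marker_ids, "seeds_x_all")
            else:
                enum = enumerate_pairs(None, g.marker_ids, "exhaustive")
            sr = scan_regression(g, p, enum, method, coding)
            scans[sr.method] = sr
            enums[sr.method] = enum
            report.write_tsv(sr.table, out / f"scan_{sr.method}.tsv")
            counts_log[f"n_tests_{sr.method}"] = sr.n_tests
            counts_log[f"n_unique_{sr.method}"] = sr.n_unique

    # --- permutation correction ---------------------------------------------
    if config.b_permutations > 0:
        perm_summary = {}
        for name, sr in scans.items():
            method = ("mdr" if name == "mdr"
                      else "additive" if name.startswith("additive")
                      else "multiplicative")
            coding = ("dominant" if name.endswith("dom")
                      else "recessive" if name.endswith("rec") else None)
            pr = permute_fwer(
                g, p, sr, method, coding, config.b_permutations, config.seed,
                enumeration=enums.get(name),
                mdr_marker_ids=g.marker_ids[: config.mdr_max_markers]
                if name == "mdr" else None,
            )
            sr.table["permuted_p"] = pr.permuted_p
            perm_summary[name] = {"fwer_threshold": pr.fwer_threshold,
                                  "b": pr.b}
            report.write_tsv(sr.table, out / f"scan_{name}.tsv")
        (out / "permutation.json").write_text(json.dumps(perm_summary, indent=1))

    # --- top-10 Table-1-style reports + AP diagnostics ------------------------
    add_results, add_tables = [], []
    for name, sr in scans.items():
        if name == "mdr":
            pruned = prune_top_list(
                list(sr.table[["marker_1", "marker_2"]].itertuples(index=False,
                                                                   name=None)),
                g, config.r2_max, config.k_top,
            )
            top_df = report.mdr_top_table(g, p, pruned, config.k_folds,
                                          config.seed)
            report.write_tsv(top_df, out / "top10_mdr.tsv")
            continue
        coding: Coding = "dominant" if name.endswith("dom") else "recessive"
        records = _regression_records(g, p, coding, sr)
        pruned_pairs = prune_top_list(
            list(records[["marker_1", "marker_2"]].itertuples(index=False,
                                                              name=None)),
            g, config.r2_max, config.k_top,
        )
        keys = {tuple(pr) for pr in pruned_pairs}
        mask = [
            (a, b) in keys
            for a, b in records[["marker_1", "marker_2"]].itertuples(index=False,
                                                                     name=None)
        ]
        top_df = report.table1_style(g, records[mask].head(config.k_top), name)
        report.write_tsv(top_df, out / f"top10_{name}.tsv")

        if name.startswith("additive"):
            for _, rec in records.iterrows():
                t = build_table(g, p, (rec["marker_1"], rec["marker_2"]),
                                coding)
                if t.degenerate:
                    continue
                rt = recode_preventive(t)
                add_results.append(additive_fit(rt))
                add_tables.append(rt)
    if add_results:
        diag_df, diag_summary = ap_diagnostics(add_results, add_tables)
        report.write_tsv(diag_df, out / "ap_diagnostics.tsv")
        (out / "ap_diagnostics.json").write_text(
            json.dumps(diag_summary, indent=1)
        )

    # --- cross-method correlations -------------------------------------------
    corr_rows = []
    names = list(scans)
    for na in names:
        for nb in names:
            if na == nb:
                continue
            try:
                cr = correlate_methods(scans[na], scans[nb], config.q)
                corr_rows.append({"top_method": na, "other_method": nb,
                                  "r": cr.r, "p_value": cr.p_value,
                                  "n_joined": cr.n_joined})
            except ValueError:
                corr_rows.append({"top_method": na, "other_method": nb,
                                  "r": float("nan"), "p_value": float("nan"),
                                  "n_joined": 0})
    if corr_rows:
        report.write_tsv(pd.DataFrame(corr_rows), out / "correlations.tsv")

    cfg = asdict(config)
    if config.sim is not None:
        cfg["sim"] = {k: v for k, v in asdict(config.sim).items()
                      if k != "effects"}
    (out / "run_config.json").write_text(json.dumps(cfg, indent=1, default=str))
    (out / "counts.json").write_text(json.dumps(counts_log, indent=1))
    return {"scans": scans, "seeds": seeds, "counts": counts_log,
            "out_dir": str(out)}
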