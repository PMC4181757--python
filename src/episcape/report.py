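"""Fixed-format TSV report writers.

Rounding conventions follow the published top-10 interaction tables: AP and
OR to 2 decimals with the CI in parentheses, balanced accuracy and AUC to 4
decimals, P values in scientific notation with 3 significant figures.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .additive import additive_fit
from .datamodel import Coding, GenotypeMatrix, Phenotype
from .metrics import auc_from_table, paf
from .multiplicative import multiplicative_fit
from .pair_tables import build_table, recode_preventive


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def fmt_ci(est: float, lo: float, hi: float, nd: int = 2) -> str:
    return f"{est:.{nd}f} ({lo:.{nd}f}:{hi:.{nd}f})"


def fmt_p(p: float) -> str:
    return f"{p:.2E}"


def _marker_cols(g: GenotypeMatrix, mid: str, slot: int) -> dict:
    info = g.markers[g.index(mid)]
    return {f"chr_{slot}": info.chromosome, f"gene_{slot}": info.gene,
            f"rs_{slot}": info.marker_id}


def table1_style(g: GenotypeMatrix, records: pd.DataFrame,
                 method_name: str) -> pd.DataFrame:
    """Regression top-list in the layout of a published top-10 panel."""
    rows = []
    additive = method_name.startswith("additive")
    for _, rec in records.iterrows():
        row = {}
        row.update(_marker_cols(g, rec["marker_1"], 1))
        row.update(_marker_cols(g, rec["marker_2"], 2))
        if additive:
            row["ap"] = f"{rec['ap']:.2f}"
        else:
            row["or"] = f"{rec['or3']:.2f}"
        row["p"] = fmt_p(rec["p_value"])
        if "permuted_p" in rec:
            row["permuted_p"] = f"{rec['permuted_p']:.3f}"
        row["paf"] = f"{rec['paf']:.3f}"
        row["auc"] = f"{rec['auc']:.4f}"
        for lab in ("00", "01", "10", "11"):
            row[lab] = f"{int(rec[f'cases_{lab}'])}/{int(rec[f'controls_{lab}'])}"
        if additive:
            row["recoding"] = rec.get("recoding", "identity")
        rows.append(row)
    return pd.DataFrame(rows)


def mdr_top_table(g: GenotypeMatrix, p: Phenotype,
                  pairs: list[tuple[str, str]], k_folds: int,
                  seed: int) -> pd.DataFrame:
    """MDR top-list: BA, PAF, OR, CI, P, high/low counts, TPR, FPR."""
    from .mdr import mdr_evaluate

    rows = []
    for a, b in pairs:
        m = mdr_evaluate(g, p, (a, b), k_folds=k_folds, seed=seed)
        t = build_table(g, p, (a, b), "dominant")
        row = {}
        row.update(_marker_cols(g, a, 1))
        row.update(_marker_cols(g, b, 2))
        row.update(
            {
                "balanced_accuracy": f"{m.ba_full:.4f}",
                "ba_cv": f"{m.ba_cv:.4f}",
                "cvc": f"{m.cvc}/{m.k_folds}",
                "paf": f"{paf(t):.3f}" if not t.degenerate else "NA",
                "or": fmt_ci(m.odds_ratio, *m.or_ci),
                "p": fmt_p(m.p_value),
                "high_risk": f"{m.high_cases}/{m.high_controls}",
                "low_risk": f"{m.low_cases}/{m.low_controls}",
                "tpr": f"{m.tpr:.3f}",
                "fpr": f"{m.fpr:.3f}",
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pair_report(g: GenotypeMatrix, p: Phenotype, pair: tuple[str, str],
                coding: Coding) -> dict:
    """One pair under one coding: all three statistics plus metrics."""
    t = build_table(g, p, pair, coding)
    rt = recode_preventive(t)
    add = additive_fit(rt)
    mult = multiplicative_fit(t)
    return {
        "marker_1": pair[0],
        "marker_2": pair[1],
        "coding": coding,
        "ap": fmt_ci(add.ap, *add.ap_ci),
        "ap_p": fmt_p(add.p_value),
        "recoding": rt.recoding,
        "or3": fmt_ci(mult.or3, *mult.or3_ci),
        "or3_p": fmt_p(mult.p_value),
        "paf": f"{paf(t):.3f}",
        "auc": f"{auc_from_table(t):.4f}",
    }
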