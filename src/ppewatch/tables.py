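"""Shipped reference count tables and their statistical summaries.

Three small CSVs ride along with the package: the per-item
prediction-vs-truth confusion matrices (training and live splits), the
overall correct/incorrect counts under the two frame-correctness
definitions, and the correct/incorrect strata by confounder.  They are
the published evaluation counts of the monitoring study and serve as
fixed inputs for the statistics layer.

Note on the shipped numbers: the height confounder's correct/incorrect
columns total 6046/1022 while every other confounder totals 6097/1027,
and the chi-square recomputed from the height counts (46.40) does not
match the printed 46.51.  The discrepancy is preserved as shipped — the
``printed_chi2`` column records the published statistic so the mismatch
is visible rather than silently corrected.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import (
    ConfusionMatrix2x2,
    Strata2x2,
    accuracy,
    cohen_kappa,
    format_pvalue,
    mcnemar,
    pearson_chi2,
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("ppewatch.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_confusion_matrices() -> pd.DataFrame:
    """Per-item 2x2 counts: item, split, a (TP), b (FN), c (FP), d (TN)."""
    return _read("confusion_matrices.csv")


def load_overall_counts() -> pd.DataFrame:
    """Overall correct/incorrect counts per split and correctness definition."""
    return _read("overall_counts.csv")


def load_strata_counts() -> pd.DataFrame:
    """Correct/incorrect counts per confounder group, plus the published chi-square."""
    return _read("strata_counts.csv")


def summarize_confusions(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Accuracy, kappa, McNemar and p-value per (item, split) row."""
    df = load_confusion_matrices() if df is None else df
    rows = []
    for r in df.itertuples():
        cm = ConfusionMatrix2x2(r.a, r.b, r.c, r.d)
        mc = mcnemar(cm)
        rows.append(
            {
                "item": r.item,
                "split": r.split,
                "n": cm.n,
                "accuracy": accuracy(cm),
                "kappa": cohen_kappa(cm),
                "mcnemar": mc.statistic,
                "pvalue": mc.pvalue,
                "pvalue_str": format_pvalue(mc.pvalue),
            }
        )
    return pd.DataFrame(rows)


def summarize_overall(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Overall accuracies from the correct/incorrect counts."""
    df = load_overall_counts() if df is None else df
    out = df.copy()
    out["n"] = out["correct"] + out["incorrect"]
    out["accuracy"] = out["correct"] / out["n"]
    return out


def summarize_strata(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Chi-square of correctness vs group per confounder row."""
    df = load_strata_counts() if df is None else df
    rows = []
    for r in df.itertuples():
        st = Strata2x2(r.correct_a, r.correct_b, r.incorrect_a, r.incorrect_b)
        res = pearson_chi2(st)
        rows.append(
            {
                "confounder": r.confounder,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "n": st.n,
                "accuracy_a": st.correct_a / (st.correct_a + st.incorrect_a),
                "accuracy_b": st.correct_b / (st.correct_b + st.incorrect_b),
                "chi2": res.statistic,
                "pvalue": res.pvalue,
                "pvalue_str": format_pvalue(res.pvalue),
                "printed_chi2": getattr(r, "printed_chi2", float("nan")),
            }
        )
    return pd.DataFrame(rows)
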