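"""Delta-mass assignment of open-search PSM tables and class-level evidence.

An open search reports, for each peptide-spectrum match (PSM), the
difference between observed and sequence-predicted precursor mass.  This
stage assigns those delta masses to oligophosphate/metal-adduct classes,
aggregates PSM counts per class and replicate, applies the minimum-PSM
evidence filter, and compares conditions with per-class t-tests.

A *class* pools Fe and Al adducts of the same phosphorylation state: its
identity is (chain length, number of metals, number of oxidations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .masscalc import ModComposition, enumerate_hypotheses, match_delta

__all__ = [
    "assign_table",
    "summarize_classes",
    "compare_conditions",
    "class_label",
    "DELTA_WINDOW",
]

#: open-search precursor window (Da): deltas outside pass through unassigned
DELTA_WINDOW = (-50.0, 600.0)

REQUIRED_COLUMNS = ("spectrum", "peptide", "delta_mass", "replicate")


def class_label(comp: ModComposition) -> str:
    """Class label pooling Fe/Al: e.g. '3p+metal', '2p', 'unmodified'."""
    n_phos, n_metal, n_ox = comp.class_key()
    parts = []
    if n_phos:
        parts.append(f"{n_phos}p")
    if n_metal:
        parts.append("metal" if n_metal == 1 else f"{n_metal}metal")
    if n_ox:
        parts.append(f"{n_ox}ox")
    return "+".join(parts) if parts else "unmodified"


def assign_table(
    psms: pd.DataFrame,
    space: list[ModComposition] | None = None,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Annotate each PSM with the best-matching modification hypothesis.

    Adds columns ``assigned`` (class label or 'unassigned'), ``n_phos``,
    ``n_metal``, ``n_ox`` and ``assignment_error``.  Deltas outside the
    open-search window are left unassigned.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in psms.columns]
    if missing:
        raise ValueError(f"PSM table missing required column(s): {', '.join(missing)}")
    if space is None:
        space = enumerate_hypotheses()

    out = psms.copy()
    labels, n_phos, n_metal, n_ox, errors = [], [], [], [], []
    cache: dict[float, tuple] = {}
    for delta in out["delta_mass"].astype(float):
        key = round(delta, 6)
        if key in cache:
            row = cache[key]
        else:
            row = ("unassigned", -1, -1, -1, np.nan)
            if DELTA_WINDOW[0] <= delta <= DELTA_WINDOW[1]:
                m = match_delta(delta, space, tolerance=tol)
                if m.best is not None:
                    row = (
                        class_label(m.best),
                        m.best.n_phos,
                        m.best.n_metal,
                        m.best.n_ox,
                        m.best_error,
                    )
            cache[key] = row
        labels.append(row[0])
        n_phos.append(row[1])
        n_metal.append(row[2])
        n_ox.append(row[3])
        errors.append(row[4])
    out["assigned"] = labels
    out["n_phos"] = n_phos
    out["n_metal"] = n_metal
    out["n_ox"] = n_ox
    out["assignment_error"] = errors
    return out


def summarize_classes(psms: pd.DataFrame, min_psms: int = 5) -> pd.DataFrame:
    """Per-class PSM counts by replicate, with the minimum-evidence filter.

    A class passes when its total PSM count over all replicates is at
    least ``min_psms``.  Unassigned records are excluded.
    """
    if "assigned" not in psms.columns:
        raise ValueError("table must be assigned first (run assign_table)")
    assigned = psms[psms["assigned"] != "unassigned"]
    if assigned.empty:
        return pd.DataFrame(
            columns=["class", "total", "passes"]
        )
    counts = (
        assigned.groupby(["assigned", "replicate"]).size().unstack(fill_value=0)
    )
    counts.columns = [f"rep_{c}" for c in counts.columns]
    summary = counts.reset_index().rename(columns={"assigned": "class"})
    rep_cols = [c for c in summary.columns if c.startswith("rep_")]
    summary["total"] = summary[rep_cols].sum(axis=1)
    summary["passes"] = summary["total"] >= min_psms
    return summary.sort_values("class").reset_index(drop=True)


def compare_conditions(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    pseudo_count: float = 1.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-class count ratios and t-test p-values between two conditions.

    Log2 ratio of mean per-replicate counts (with a pseudo-count for
    classes absent on one side) and a two-sided t-test across replicates;
    Welch (unequal variance) by default.
    """
    def rep_cols(df):
        return [c for c in df.columns if c.startswith("rep_")]

    cols_a, cols_b = rep_cols(summary_a), rep_cols(summary_b)
    if len(cols_a) != len(cols_b):
        raise ValueError("conditions have different replicate structure")
    if len(cols_a) < 2:
        raise ValueError("need at least 2 replicates per condition")

    a = summary_a.set_index("class")[cols_a]
    b = summary_b.set_index("class")[cols_b]
    classes = sorted(set(a.index) | set(b.index))
    rows = []
    for cls in classes:
        ca = a.loc[cls].to_numpy(float) if cls in a.index else np.zeros(len(cols_a))
        cb = b.loc[cls].to_numpy(float) if cls in b.index else np.zeros(len(cols_b))
        log2_ratio = float(
            np.log2((cb.mean() + pseudo_count) / (ca.mean() + pseudo_count))
        )
        if np.allclose(ca, ca[0]) and np.allclose(cb, cb[0]) and ca[0] == cb[0]:
            p = 1.0  # identical constant counts: no evidence of difference
        else:
            p = float(stats.ttest_ind(ca, cb, equal_var=equal_var).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append(
            {
                "class": cls,
                "mean_a": ca.mean(),
                "mean_b": cb.mean(),
                "log2_ratio": log2_ratio,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
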