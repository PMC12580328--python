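"""Relative quantification: XIC areas, LFQ filtering/imputation, volcano stats.

Two quantification layers are covered.  First, normalized extracted-ion
chromatogram (XIC) areas: the precursor area of each species integrated
over its retention window, expressed relative to the full-chromatogram
area and to the most abundant species.  Second, interactome label-free
quantification (LFQ): row filtering by valid values, left-censored
imputation from a down-shifted narrowed normal (per sample: mean - 1.8*sd,
width 0.3*sd, on the log2 scale), and an unadjusted two-sample t-test
volcano with enrichment thresholds |log2 FC| > 1.5 and -log10 p > 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Chromatogram",
    "VolcanoRow",
    "xic_area",
    "normalized_xic_percent",
    "filter_rows",
    "impute_left_censored",
    "volcano",
]


@dataclass
class Chromatogram:
    """A retention-time trace (seconds, arbitrary intensity units)."""

    time: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity arrays differ in length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("retention time must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")


@dataclass
class VolcanoRow:
    protein: str
    log2_fc: float
    neg_log10_p: float
    category: str  # enriched-right | enriched-left | not-significant


def xic_area(chrom: Chromatogram, rt_window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of the trace over a retention window.

    An empty overlap integrates to zero.  Window edges are included by
    linear interpolation so the area is insensitive to sample placement.
    """
    t, y = chrom.time, chrom.intensity
    if rt_window is not None:
        lo, hi = rt_window
        if lo > hi:
            raise ValueError("rt_window lower bound exceeds upper bound")
        if hi <= t[0] or lo >= t[-1]:
            return 0.0
        lo, hi = max(lo, t[0]), min(hi, t[-1])
        grid = t[(t > lo) & (t < hi)]
        grid = np.concatenate([[lo], grid, [hi]])
        y = np.interp(grid, t, y)
        t = grid
    return float(np.trapezoid(y, t))


def normalized_xic_percent(
    species_areas: dict[str, float], total_area: float
) -> dict[str, tuple[float, float]]:
    """Percent of total chromatogram area and percent of the top species.

    Returns label -> (percent of total, percent normalized to the species
    with the highest contribution; that species reports 100).
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if not species_areas:
        return {}
    top = max(species_areas.values())
    if top <= 0:
        raise ValueError("all species areas are zero")
    return {
        label: (100.0 * a / total_area, 100.0 * a / top)
        for label, a in species_areas.items()
    }


def _group_columns(matrix: pd.DataFrame, groups: dict[str, str]) -> dict[str, list[str]]:
    by_group: dict[str, list[str]] = {}
    for col in matrix.columns:
        if col not in groups:
            raise ValueError(f"column {col!r} has no group label")
        by_group.setdefault(groups[col], []).append(col)
    return by_group


def filter_rows(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    min_valid: int = 2,
) -> pd.DataFrame:
    """Keep proteins with >= min_valid present values in at least one group.

    ``matrix`` is proteins x replicates with NaN for missing; ``groups``
    maps each column to its condition label.
    """
    by_group = _group_columns(matrix, groups)
    keep = pd.Series(False, index=matrix.index)
    for cols in by_group.values():
        keep |= matrix[cols].notna().sum(axis=1) >= min_valid
    return matrix.loc[keep]


def impute_left_censored(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Impute missing log-scale intensities from a down-shifted normal.

    Per column (sample), missing entries are drawn from
    ``Normal(mu - downshift*sigma, (width*sigma)^2)`` where mu and sigma
    are the mean and standard deviation of the column's present values —
    the Perseus convention for missing-not-at-random, left-censored LFQ
    data.  Observed entries are preserved bit-exactly; the draw is seeded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        present = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(present) < 2:
            raise ValueError(
                f"column {col!r} has fewer than 2 present values; "
                "sigma is undefined"
            )
        mu, sigma = float(present.mean()), float(present.std(ddof=1))
        draws = rng.normal(mu - downshift * sigma, width * sigma, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


def volcano(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    group_a: str | None = None,
    group_b: str | None = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 1.5,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test volcano on a complete log2 matrix.

    log2 FC is mean(group_b) - mean(group_a); p-values are unadjusted
    (Student's equal-variance test by default, Welch optional).  A protein
    is enriched-right/-left when |log2 FC| exceeds ``fc_threshold`` and
    -log10 p exceeds ``p_threshold``.
    """
    by_group = _group_columns(matrix, groups)
    if group_a is None or group_b is None:
        labels = sorted(by_group)
        if len(labels) != 2:
            raise ValueError("specify group_a and group_b when not exactly 2 groups")
        group_a, group_b = labels
    cols_a, cols_b = by_group[group_a], by_group[group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = matrix[cols_a].to_numpy(float)
    b = matrix[cols_b].to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix contains missing values; filter and impute first")

    log2_fc = b.mean(axis=1) - a.mean(axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    neg_log10_p = -np.log10(np.clip(pvals, np.finfo(float).tiny, 1.0))

    significant = neg_log10_p > p_threshold
    category = np.full(len(matrix), "not-significant", dtype=object)
    category[significant & (log2_fc > fc_threshold)] = "enriched-right"
    category[significant & (log2_fc < -fc_threshold)] = "enriched-left"

    return pd.DataFrame(
        {
            "protein": matrix.index,
            "log2_fc": log2_fc,
            "neg_log10_p": neg_log10_p,
            "p_value": pvals,
            "category": category,
        }
    ).set_index("protein")
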