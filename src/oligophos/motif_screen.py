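"""Positively charged stretches/motifs and interactor-vs-proteome statistics.

Oligophosphate chains carry a dense negative charge, and proteins that
preferentially bind the oligophosphorylated form are enriched in basic
(Lys/Arg/His) sequence features.  Two feature kinds are scanned:

* **stretch** — 3-7 consecutive repeats of the *same* basic residue
  (the default mode), or, in ``class`` mode, a run of >= ``min_run`` mixed
  K/R/H residues;
* **motif** — three basic residues with at most two interrupting residues
  between the first and the last (e.g. KxKK, KKxK), reported only when not
  already inside a reported stretch, so the combined stretch-or-motif
  count never double-counts a window.

Set-level comparison reports the percent of positively charged residues
per protein (box-plot statistics, type-7 quantiles) and an unadjusted
two-sample t-test between interactors and the proteome background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MotifHit",
    "find_stretches",
    "find_motifs",
    "percent_positive",
    "compare_sets",
    "POSITIVE_RESIDUES",
]

POSITIVE_RESIDUES = frozenset("KRH")


@dataclass(frozen=True)
class MotifHit:
    """A located basic stretch or interrupted motif (1-based start)."""

    kind: str  # stretch | motif
    start: int
    match: str
    protein: str = ""
    over_length: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.match) - 1


def find_stretches(
    sequence: str,
    mode: str = "same",
    min_run: int = 3,
    max_run: int = 7,
    residues=POSITIVE_RESIDUES,
    protein: str = "",
) -> list[MotifHit]:
    """Maximal runs of basic residues, reported once each.

    ``same`` mode requires a run of one repeated residue (K, R or H);
    ``class`` mode accepts any mix of the residue class.  A maximal run
    longer than ``max_run`` is reported whole and flagged ``over_length``.
    """
    if mode not in ("same", "class"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = []
    i, n = 0, len(sequence)
    while i < n:
        if sequence[i] not in residues:
            i += 1
            continue
        j = i + 1
        if mode == "same":
            while j < n and sequence[j] == sequence[i]:
                j += 1
        else:
            while j < n and sequence[j] in residues:
                j += 1
        run_len = j - i
        # in `same` mode a maximal same-residue run may sit inside a longer
        # class run; maximality is per definition of the mode
        if run_len >= min_run:
            hits.append(
                MotifHit(
                    kind="stretch",
                    start=i + 1,
                    match=sequence[i:j],
                    protein=protein,
                    over_length=run_len > max_run,
                )
            )
        i = j
    return hits


def find_motifs(
    sequence: str,
    residues=POSITIVE_RESIDUES,
    max_interruptions: int = 2,
    stretches: list[MotifHit] | None = None,
    protein: str = "",
) -> list[MotifHit]:
    """Interrupted basic triplets (e.g. KxKK) outside reported stretches.

    A motif window spans three class residues with at most
    ``max_interruptions`` other residues between the first and the last.
    Windows fully inside a stretch from :func:`find_stretches` (computed
    with defaults when not supplied) are suppressed; overlapping candidate
    windows are deduplicated leftmost-longest.
    """
    if stretches is None:
        stretches = find_stretches(sequence, protein=protein)
    spans = [(h.start, h.end) for h in stretches]

    positions = [i for i, aa in enumerate(sequence) if aa in residues]
    candidates = []
    for k in range(len(positions) - 2):
        i, j = positions[k], positions[k + 2]
        span = j - i + 1
        if span - 3 <= max_interruptions:
            start, end = i + 1, j + 1  # 1-based inclusive
            if any(start >= s and end <= e for s, e in spans):
                continue
            candidates.append((start, end))
    # leftmost-longest: sort by (start, -length); drop windows that start
    # inside an already accepted one
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    hits = []
    last_end = 0
    for start, end in candidates:
        if start <= last_end:
            continue
        hits.append(
            MotifHit(
                kind="motif",
                start=start,
                match=sequence[start - 1 : end],
                protein=protein,
            )
        )
        last_end = end
    return hits


def percent_positive(sequence: str, residues=POSITIVE_RESIDUES) -> float:
    """Percent of K/R/H residues over total protein length."""
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * sum(aa in residues for aa in sequence) / len(sequence)


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7 quantiles
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo) & (values <= hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inside.min()) if inside.size else float(med),
        "whisker_high": float(inside.max()) if inside.size else float(med),
        "n": int(values.size),
    }


def _set_summary(sequences: dict[str, str], stretch_mode: str) -> dict:
    pct = np.array([percent_positive(s) for s in sequences.values()])
    n_features = 0
    for name, seq in sequences.items():
        st = find_stretches(seq, mode=stretch_mode, protein=name)
        mo = find_motifs(seq, stretches=st, protein=name)
        n_features += len(st) + len(mo)
    out = _box_stats(pct)
    out["percent_positive"] = pct
    out["features_per_protein"] = n_features / len(sequences)
    return out


def compare_sets(
    interactors: dict[str, str],
    background: dict[str, str],
    stretch_mode: str = "same",
) -> dict:
    """Compare an interactor set against a proteome background.

    Returns per-set box-plot statistics of percent positively charged
    residues, the stretch-or-motif count per protein, and the unadjusted
    two-sample t-test p-value between the two percent distributions.
    """
    if not interactors or not background:
        raise ValueError("both sets must be non-empty")
    if len(interactors) < 2 or len(background) < 2:
        raise ValueError("need at least 2 sequences per set for the t-test")
    summary_i = _set_summary(interactors, stretch_mode)
    summary_b = _set_summary(background, stretch_mode)
    t = stats.ttest_ind(
        summary_i.pop("percent_positive"),
        summary_b.pop("percent_positive"),
        equal_var=True,
    )
    p = float(t.pvalue)
    return {
        "interactors": summary_i,
        "background": summary_b,
        "t_statistic": float(t.statistic) if np.isfinite(t.statistic) else 0.0,
        "p_value": p if np.isfinite(p) else 1.0,
    }
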