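"""Theoretical fragment ions, peak annotation and ion-couplet localization.

A phosphate chain shifts every fragment that spans its site; fragments on
either side of the site are unshifted.  A pair of matched fragments that
flank a candidate residue — one N-terminal-series ion (b/c) and one
C-terminal-series ion (y/z) whose masses discriminate that placement from
every alternative — is an *ion couplet* and pins the modification to the
site.  Localization here is couplet counting, not probabilistic scoring.

Conventions: b = prefix residues + proton; y = suffix residues + water +
proton; c = b + NH3; z is the z-dot radical ion (y − NH3 + H).  Metal
adducts are treated as non-dissociating: fragments spanning the modified
site carry the full composition delta, including the metal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masscalc import (
    ElementTable,
    InvalidHypothesisError,
    ModComposition,
    peptide_neutral_mass,
)

__all__ = [
    "SiteModification",
    "FragmentIon",
    "PeakList",
    "LocalizationResult",
    "generate_fragments",
    "annotate",
    "localize",
]

N_TERM_SERIES = frozenset("bc")
C_TERM_SERIES = frozenset("yz")

_PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class SiteModification:
    """A modification composition anchored to a 1-based residue index."""

    site: int
    comp: ModComposition

    def validate(self, sequence: str) -> None:
        if not (1 <= self.site <= len(sequence)):
            raise InvalidHypothesisError(
                f"site {self.site} outside sequence of length {len(sequence)}"
            )
        aa = sequence[self.site - 1]
        if self.comp.n_phos > 0 and aa not in _PHOSPHO_RESIDUES:
            raise InvalidHypothesisError(
                f"phosphate chain placed on {aa!r} at position {self.site}; "
                "only S/T/Y accepted"
            )
        if self.comp.n_phos == 0 and self.comp.n_ox > 0 and aa != "M":
            raise InvalidHypothesisError(
                f"oxidation placed on {aa!r} at position {self.site}; only M accepted"
            )


@dataclass(frozen=True)
class FragmentIon:
    series: str  # b, y, c or z (z-dot)
    index: int
    charge: int
    n_hpo3_loss: int = 0
    n_h3po4_loss: int = 0
    mz: float = 0.0

    @property
    def label(self) -> str:
        loss = ""
        if self.n_hpo3_loss:
            loss += f"-{self.n_hpo3_loss}xHPO3"
        if self.n_h3po4_loss:
            loss += f"-{self.n_h3po4_loss}xH3PO4"
        return f"{self.series}{self.index}{loss}({self.charge}+)"


@dataclass
class PeakList:
    """A centroided spectrum: parallel m/z and intensity arrays.

    Peaks are kept sorted by m/z; an unsorted input is re-sorted and
    flagged via ``resorted``.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    resorted: bool = False

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            self.resorted = True

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class LocalizationResult:
    """Outcome of couplet-based site localization.

    ``evidence`` maps candidate site -> dict with keys ``n_matched``
    (matched site-determining ions), ``nterm``/``cterm`` (flanking-series
    support) and ``couplet``.
    """

    best_site: int | None
    status: str  # unambiguous | ambiguous | unsupported
    evidence: dict = field(default_factory=dict)


def _series_neutral(series: str, running_mass: float, suffix: bool) -> float:
    t = ElementTable
    if series == "b":
        return running_mass
    if series == "c":
        return running_mass + t.NH3
    if series == "y":
        return running_mass + t.WATER
    if series == "z":
        # z-dot radical: y - NH3 + H
        return running_mass + t.WATER - t.NH3 + t.masses["H"]
    raise ValueError(f"unknown ion series {series!r}")


def generate_fragments(
    sequence: str,
    mods: tuple[SiteModification, ...] = (),
    series=("b", "y"),
    max_frag_charge: int = 1,
    losses: bool = False,
    max_loss_events: int = 2,
) -> list[FragmentIon]:
    """Enumerate theoretical fragment ions for a modified peptide.

    Every fragment spanning a modified site carries that site's full
    composition delta.  With ``losses`` enabled, fragments spanning a
    phosphorylated site additionally appear with up to ``max_loss_events``
    combined HPO3/H3PO4 neutral losses (never more losses than phosphates
    on the fragment).
    """
    peptide_neutral_mass(sequence)  # validates residues
    for m in mods:
        m.validate(sequence)
    series = [s for s in series]
    for s in series:
        if s not in "bycz":
            raise ValueError(f"unknown ion series {s!r}")

    n = len(sequence)
    t = ElementTable
    res = [t.residue_mass(aa) for aa in sequence]
    mod_at = {m.site: m.comp for m in mods}
    if len(mod_at) != len(mods):
        raise InvalidHypothesisError("multiple modifications on one site")

    # prefix_mass[i] = residues 1..i plus mods anchored within
    prefix_mass = [0.0] * (n + 1)
    prefix_phos = [0] * (n + 1)
    for i in range(1, n + 1):
        prefix_mass[i] = prefix_mass[i - 1] + res[i - 1]
        prefix_phos[i] = prefix_phos[i - 1]
        if i in mod_at:
            prefix_mass[i] += mod_at[i].delta_mass
            prefix_phos[i] += mod_at[i].n_phos
    total_mass = prefix_mass[n]
    total_phos = prefix_phos[n]

    ions = []
    for idx in range(1, n):  # fragment index < peptide length
        for s in series:
            if s in N_TERM_SERIES:
                frag_mass = prefix_mass[idx]
                frag_phos = prefix_phos[idx]
            else:
                frag_mass = total_mass - prefix_mass[n - idx]
                frag_phos = total_phos - prefix_phos[n - idx]
            neutral = _series_neutral(s, frag_mass, s in C_TERM_SERIES)
            loss_variants = [(0, 0)]
            if losses and frag_phos > 0:
                cap = min(max_loss_events, frag_phos)
                loss_variants += [
                    (a, b)
                    for a in range(cap + 1)
                    for b in range(cap + 1)
                    if 1 <= a + b <= cap
                ]
            for n1, n2 in loss_variants:
                m_neutral = neutral - n1 * t.PHOSPHO - n2 * t.PHOSPHORIC
                for z in range(1, max_frag_charge + 1):
                    ions.append(
                        FragmentIon(
                            series=s,
                            index=idx,
                            charge=z,
                            n_hpo3_loss=n1,
                            n_h3po4_loss=n2,
                            mz=(m_neutral + z * t.PROTON) / z,
                        )
                    )
    ions.sort(key=lambda f: (f.series, f.index, f.charge, f.n_hpo3_loss, f.n_h3po4_loss))
    return ions


def annotate(
    peaks: PeakList,
    theoretical: list[FragmentIon],
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Match theoretical ions to the nearest observed peak within tolerance.

    One peak may satisfy several isobaric ions; such matches are flagged
    ``shared``.  The matched fraction is stored in ``df.attrs['match_fraction']``.
    """
    rows = []
    mz = peaks.mz
    use_count: dict[int, int] = {}
    for ion in theoretical:
        row = {
            "ion": ion.label,
            "series": ion.series,
            "index": ion.index,
            "charge": ion.charge,
            "theo_mz": ion.mz,
            "matched": False,
            "obs_mz": np.nan,
            "intensity": np.nan,
            "ppm_error": np.nan,
            "peak_index": -1,
        }
        if len(mz):
            j = int(np.searchsorted(mz, ion.mz))
            best = None
            for k in (j - 1, j):
                if 0 <= k < len(mz):
                    d = abs(mz[k] - ion.mz)
                    if best is None or d < best[1]:
                        best = (k, d)
            if best is not None:
                k, d = best
                ppm = d / ion.mz * 1e6
                if ppm <= tol_ppm:
                    row.update(
                        matched=True,
                        obs_mz=mz[k],
                        intensity=peaks.intensity[k],
                        ppm_error=(mz[k] - ion.mz) / ion.mz * 1e6,
                        peak_index=k,
                    )
                    use_count[k] = use_count.get(k, 0) + 1
        rows.append(row)
    df = pd.DataFrame(rows)
    df["shared"] = df["peak_index"].map(lambda k: use_count.get(k, 0) > 1)
    df.attrs["match_fraction"] = float(df["matched"].mean()) if len(df) else 0.0
    return df


def _spans(ion_series: str, index: int, site: int, n: int) -> bool:
    """Does fragment (series, index) of an n-mer include residue `site`?"""
    if ion_series in N_TERM_SERIES:
        return site <= index
    return site > n - index


def localize(
    sequence: str,
    candidate_sites: list[int],
    comp: ModComposition,
    peaks: PeakList,
    tol_ppm: float = 10.0,
    series=("b", "y"),
    max_frag_charge: int = 1,
) -> LocalizationResult:
    """Place a phosphate-chain composition on one of the candidate S/T/Y sites.

    For every placement the matched *site-determining* ions are counted: a
    fragment whose m/z under this placement differs from its m/z under some
    alternative placement by more than the matching tolerance.  A placement
    is supported by a complete flanking couplet when at least one matched
    discriminating N-terminal-series and one C-terminal-series ion exist.
    Exactly one coupled site => unambiguous; ties or no couplet =>
    ambiguous.  A composition without phosphates is unsupported.
    """
    if not candidate_sites:
        raise ValueError("at least one candidate site is required")
    if comp.n_phos == 0:
        return LocalizationResult(None, "unsupported", {})

    n = len(sequence)
    placements = {
        s: generate_fragments(
            sequence,
            (SiteModification(s, comp),),
            series=series,
            max_frag_charge=max_frag_charge,
            losses=False,
        )
        for s in candidate_sites
    }
    annotations = {s: annotate(peaks, placements[s], tol_ppm) for s in candidate_sites}

    evidence = {}
    for s in candidate_sites:
        df = annotations[s]
        matched = df[df["matched"]]
        alternatives = [s2 for s2 in candidate_sites if s2 != s]
        if not alternatives:
            # single placement: the site-pinning ions are those carrying
            # the mass shift, i.e. fragments spanning the site
            spanning = matched[
                [
                    _spans(row["series"], row["index"], s, n)
                    for _, row in matched.iterrows()
                ]
            ]
            nterm = bool(spanning["series"].isin(list(N_TERM_SERIES)).any())
            cterm = bool(spanning["series"].isin(list(C_TERM_SERIES)).any())
            evidence[s] = {
                "n_matched": int(len(spanning)),
                "nterm": nterm,
                "cterm": cterm,
                "couplet": nterm and cterm,
            }
            continue
        # an ion discriminates placement s from s2 iff it spans exactly one
        # of the two sites: its m/z then differs between the placements.
        # The placement is pinned only when, against EVERY alternative, at
        # least one matched discriminating ion exists in the N-terminal
        # series and one in the C-terminal series (the flanking couplet).
        discriminating_ions = set()
        all_pairs_coupled = True
        for s2 in alternatives:
            pair_n = pair_c = False
            for _, row in matched.iterrows():
                if _spans(row["series"], row["index"], s, n) != _spans(
                    row["series"], row["index"], s2, n
                ):
                    discriminating_ions.add(row["ion"])
                    if row["series"] in N_TERM_SERIES:
                        pair_n = True
                    else:
                        pair_c = True
            if not (pair_n and pair_c):
                all_pairs_coupled = False
        evidence[s] = {
            "n_matched": len(discriminating_ions),
            "nterm": all(
                any(
                    _spans(row["series"], row["index"], s, n)
                    != _spans(row["series"], row["index"], s2, n)
                    and row["series"] in N_TERM_SERIES
                    for _, row in matched.iterrows()
                )
                for s2 in alternatives
            ),
            "cterm": all(
                any(
                    _spans(row["series"], row["index"], s, n)
                    != _spans(row["series"], row["index"], s2, n)
                    and row["series"] in C_TERM_SERIES
                    for _, row in matched.iterrows()
                )
                for s2 in alternatives
            ),
            "couplet": all_pairs_coupled,
        }

    coupled = [s for s in candidate_sites if evidence[s]["couplet"]]
    if len(coupled) == 1:
        return LocalizationResult(coupled[0], "unambiguous", evidence)
    return LocalizationResult(None, "ambiguous", evidence)
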