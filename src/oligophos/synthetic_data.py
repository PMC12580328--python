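"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the study's input classes — open-search PSM
tables, fragment spectra with planted modification sites, chromatographic
peaks, left-censored LFQ matrices, and proteomes with controlled basic-
residue content — together with machine-readable ground truth, so every
downstream stage can be tested without any external data.  All randomness
flows from the single ``SimConfig.seed``; identical seeds give bit-
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import PeakList, SiteModification, generate_fragments
from .masscalc import ModComposition, peptide_neutral_mass, precursor_mz
from .motif_screen import POSITIVE_RESIDUES, find_motifs, find_stretches
from .quantstats import Chromatogram

__all__ = [
    "SimConfig",
    "DEFAULT_CLASS_PROPORTIONS",
    "ENDOGENOUS_PEPTIDE",
    "SCAR_PEPTIDE",
    "make_proteome",
    "make_psm_table",
    "make_spectrum",
    "make_lfq_matrix",
    "make_chromatogram",
]

#: the endogenous tryptic peptide around the modification site, and the
#: single-conservative-amino-acid-replacement standard used for targeting
ENDOGENOUS_PEPTIDE = "VMLGETNPADSKPGTIR"
SCAR_PEPTIDE = "VMLGETNPADSKPATIR"

#: modification-class mixture of an ATP-treated pyrophosphoprotein digest:
#: oligophosphate chains are observed mostly as Fe/Al adducts once the
#: chain can chelate a trivalent metal
DEFAULT_CLASS_PROPORTIONS = {
    ModComposition(): 0.30,
    ModComposition(n_phos=1): 0.10,
    ModComposition(n_phos=2): 0.20,
    ModComposition(n_phos=2, n_fe=1): 0.10,
    ModComposition(n_phos=2, n_al=1): 0.05,
    ModComposition(n_phos=3, n_fe=1): 0.10,
    ModComposition(n_phos=4, n_fe=1): 0.05,
    ModComposition(n_phos=4, n_al=1): 0.05,
    ModComposition(n_phos=5, n_fe=1): 0.03,
    ModComposition(n_phos=6, n_fe=2): 0.02,
}

# background amino-acid frequencies, roughly human-proteome-like
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [
        0.070, 0.023, 0.047, 0.071, 0.037, 0.066, 0.026, 0.043, 0.057, 0.100,
        0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.054, 0.060, 0.012, 0.027,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    # proteome / motifs
    n_proteins: int = 200
    protein_length: int = 300
    motif_probability: float = 0.0  # per-protein chance of planted basic features
    max_planted_features: int = 3
    # PSM tables
    n_psms: int = 2000
    n_replicates: int = 4
    precursor_sigma_da: float = 0.003
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    # spectra
    fragment_ppm_sigma: float = 5.0
    fragment_efficiency: float = 0.7
    n_noise_peaks_mean: float = 10.0
    # LFQ matrices
    n_lfq_proteins: int = 1500
    n_enriched: int = 80
    effect_log2fc: float = 2.0
    lfq_noise_sigma: float = 0.5
    missing_frac: float = 0.25
    censor_strength: float = 0.8
    lfq_mean: float = 25.0
    lfq_between_protein_sigma: float = 2.0
    # chromatograms
    chrom_peak_sigma_s: float = 4.0
    chrom_dt_s: float = 0.25
    chrom_background: float = 0.0

    def __post_init__(self):
        for name in ("motif_probability", "fragment_efficiency", "missing_frac",
                     "censor_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("precursor_sigma_da", "fragment_ppm_sigma", "lfq_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent generator for one output stream of this seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


_STREAM_PROTEOME = 1
_STREAM_PSMS = 2
_STREAM_SPECTRUM = 3
_STREAM_LFQ = 4


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))


def make_proteome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random protein sequences with optionally planted basic features.

    With probability ``motif_probability`` a protein receives 1..``max_
    planted_features`` inserted stretches (same-residue runs of 3-7 K/R/H)
    or interrupted motifs.  The ground-truth table lists every stretch/
    motif found by the scanners with a ``planted`` flag: chance hits from
    the random background carry ``planted=False``.
    """
    rng = config.rng(_STREAM_PROTEOME)
    sequences: dict[str, str] = {}
    truth_rows = []
    for idx in range(config.n_proteins):
        name = f"SYN{idx:05d}"
        seq = _random_sequence(rng, config.protein_length)
        planted_spans = []
        if rng.random() < config.motif_probability:
            n_features = int(rng.integers(1, config.max_planted_features + 1))
            for _ in range(n_features):
                residue = rng.choice(list(POSITIVE_RESIDUES))
                if rng.random() < 0.5:  # stretch
                    run = int(rng.integers(3, 8))
                    insert = residue * run
                else:  # interrupted triplet, e.g. KxKK / KKxK
                    other = rng.choice([aa for aa in _AA if aa not in POSITIVE_RESIDUES])
                    pattern = rng.choice(["1011", "1101", "10101", "10011"])
                    insert = "".join(residue if c == "1" else other for c in pattern)
                pos = int(rng.integers(0, len(seq) - len(insert)))
                seq = seq[:pos] + insert + seq[pos + len(insert):]
                planted_spans.append((pos + 1, pos + len(insert)))
        sequences[name] = seq
        stretches = find_stretches(seq, protein=name)
        motifs = find_motifs(seq, stretches=stretches, protein=name)
        for hit in stretches + motifs:
            planted = any(
                hit.start <= e and hit.end >= s for s, e in planted_spans
            )
            truth_rows.append(
                {
                    "protein": name,
                    "kind": hit.kind,
                    "start": hit.start,
                    "match": hit.match,
                    "planted": planted,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["protein", "kind", "start", "match", "planted"])
    return sequences, truth


def make_psm_table(
    config: SimConfig, peptide: str = ENDOGENOUS_PEPTIDE
) -> pd.DataFrame:
    """Open-search PSM table with known modification classes.

    Each PSM's delta mass is its class offset plus Gaussian precursor mass
    error; replicates are assigned round-robin.  The ``true_class`` column
    is the ground truth (a :class:`ModComposition` label).
    """
    rng = config.rng(_STREAM_PSMS)
    comps = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in comps])
    choice = rng.choice(len(comps), size=config.n_psms, p=probs)
    noise = rng.normal(0.0, config.precursor_sigma_da, size=config.n_psms)
    rows = []
    for i, (ci, eps) in enumerate(zip(choice, noise)):
        comp = comps[ci]
        rows.append(
            {
                "spectrum": f"scan{i:06d}",
                "peptide": peptide,
                "delta_mass": comp.delta_mass + eps,
                "replicate": (i % config.n_replicates) + 1,
                "true_class": comp.label(),
                "true_n_phos": comp.n_phos,
                "true_n_metal": comp.n_metal,
                "true_n_ox": comp.n_ox,
            }
        )
    return pd.DataFrame(rows)


def make_spectrum(
    config: SimConfig,
    sequence: str = ENDOGENOUS_PEPTIDE,
    site: int = 15,
    comp: ModComposition = ModComposition(n_phos=3, n_fe=1),
    charge: int = 2,
    series=("b", "y"),
    spectrum_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[PeakList, dict]:
    """A centroided spectrum with a planted modification site.

    Theoretical fragments of the modified peptide are thinned by the
    fragment efficiency, jittered with ppm mass error, and mixed with
    Poisson-count uniform noise peaks.  Ground truth records the planted
    site and which fragments survived.
    """
    if rng is None:
        rng = config.rng(_STREAM_SPECTRUM)
    mods = (SiteModification(site, comp),) if comp.n_components else ()
    theo = generate_fragments(sequence, mods, series=series, max_frag_charge=1)
    keep = rng.random(len(theo)) < config.fragment_efficiency
    mz, intensity, kept_labels = [], [], []
    for ion, k in zip(theo, keep):
        if not k:
            continue
        jitter = rng.normal(0.0, config.fragment_ppm_sigma * 1e-6 * ion.mz)
        mz.append(ion.mz + jitter)
        intensity.append(float(rng.lognormal(10.0, 1.0)))
        kept_labels.append(ion.label)
    lo = 100.0
    hi = max([i.mz for i in theo]) + 100.0 if theo else 1500.0
    n_noise = int(rng.poisson(config.n_noise_peaks_mean))
    for _ in range(n_noise):
        mz.append(float(rng.uniform(lo, hi)))
        intensity.append(float(rng.lognormal(8.0, 1.0)))
    neutral = peptide_neutral_mass(sequence, (comp,) if comp.n_components else ())
    peaks = PeakList(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz(neutral, charge),
        precursor_charge=charge,
        mz=np.array(mz),
        intensity=np.array(intensity),
    )
    truth = {
        "sequence": sequence,
        "site": site,
        "composition": comp,
        "charge": charge,
        "kept_fragments": kept_labels,
        "n_noise_peaks": n_noise,
    }
    return peaks, truth


def make_lfq_matrix(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Left-censored LFQ matrix with planted enriched proteins.

    Log2 intensities: per-protein baselines are normal around
    ``lfq_mean``; replicate noise has sd ``lfq_noise_sigma``; the first
    ``n_enriched`` proteins gain ``effect_log2fc`` in the "bait" group.
    Missingness is missing-not-at-random: per sample, values in the lowest
    intensity band (the ``missing_frac/censor_strength`` quantile) are
    dropped with probability ``censor_strength``, giving ~``missing_frac``
    overall missingness concentrated at low abundance.

    Returns (matrix, column->group mapping, list of enriched protein ids).
    """
    rng = config.rng(_STREAM_LFQ)
    n, k = config.n_lfq_proteins, config.n_replicates
    proteins = [f"P{idx:05d}" for idx in range(n)]
    enriched = proteins[: config.n_enriched]
    baseline = rng.normal(config.lfq_mean, config.lfq_between_protein_sigma, size=n)
    a = baseline[:, None] + rng.normal(0, config.lfq_noise_sigma, size=(n, k))
    b = baseline[:, None] + rng.normal(0, config.lfq_noise_sigma, size=(n, k))
    b[: config.n_enriched] += config.effect_log2fc
    values = np.concatenate([a, b], axis=1)

    if config.missing_frac > 0:
        band = min(1.0, config.missing_frac / max(config.censor_strength, 1e-9))
        for j in range(values.shape[1]):
            col = values[:, j]
            threshold = np.quantile(col, band)
            drop = (col <= threshold) & (rng.random(n) < config.censor_strength)
            col[drop] = np.nan

    cols = [f"ctrl_{i+1}" for i in range(k)] + [f"bait_{i+1}" for i in range(k)]
    matrix = pd.DataFrame(values, index=proteins, columns=cols)
    groups = {c: ("ctrl" if c.startswith("ctrl") else "bait") for c in cols}
    return matrix, groups, enriched


def make_chromatogram(
    species_areas: dict[str, float],
    config: SimConfig,
) -> tuple[Chromatogram, dict[str, dict]]:
    """A chromatogram of Gaussian peaks with specified areas.

    Species elute as Gaussians of width ``chrom_peak_sigma_s`` spaced
    along the gradient on a flat ``chrom_background``.  Ground truth maps
    each label to its planted area and retention window (+-5 sigma).
    Zero-area species contribute no peak.
    """
    sigma = config.chrom_peak_sigma_s
    spacing = 20.0 * sigma
    labels = list(species_areas)
    centers = {lab: 100.0 + i * spacing for i, lab in enumerate(labels)}
    t_end = 100.0 + len(labels) * spacing + 100.0
    t = np.arange(0.0, t_end, config.chrom_dt_s)
    y = np.full_like(t, config.chrom_background)
    truth = {}
    for lab in labels:
        area = species_areas[lab]
        c = centers[lab]
        if area > 0:
            y = y + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((t - c) / sigma) ** 2
            )
        truth[lab] = {"area": area, "window": (c - 5 * sigma, c + 5 * sigma)}
    return Chromatogram(time=t, intensity=y, label="total"), truth
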