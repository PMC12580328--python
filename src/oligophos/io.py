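"""Shared format readers/writers, run configuration, and the full pipeline.

Canonical table dialect is TSV (tab-delimited, UTF-8, header row), the
dialect search-engine and LFQ exports use.  FASTA goes through Biopython,
MGF through pyteomics, structures through gemmi.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from . import motif_screen, psm_pipeline, quantstats, synthetic_data
from .fragments import PeakList
from .masscalc import ModComposition, enumerate_hypotheses
from .structmetrics import read_model  # noqa: F401  (re-exported reader)

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "read_table",
    "write_table",
    "read_model",
    "hypotheses_to_table",
    "table_to_hypotheses",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Pipeline-wide settings; defaults are the study's stated values."""

    precursor_tol_da: float = 0.01
    fragment_tol_ppm: float = 10.0
    max_phos: int = 6
    max_metal: int = 2
    max_ox: int = 3
    fc_threshold: float = 1.5
    p_threshold: float = 1.5
    min_psms: int = 5
    min_valid: int = 2
    imputation_width: float = 0.3
    imputation_downshift: float = 1.8
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        for name in ("precursor_tol_da", "fragment_tol_ppm", "fc_threshold",
                     "p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_psms < 0 or self.min_valid < 0:
            raise ValueError("count thresholds must be non-negative")


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_mgf(path) -> list[PeakList]:
    """Read an MGF peak-list file; unsorted spectra are re-sorted and flagged."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            pepmass = params.get("pepmass", (0.0,))[0]
            charge = int(params["charge"][0]) if "charge" in params else 1
            spectra.append(
                PeakList(
                    spectrum_id=str(params.get("title", f"index{len(spectra)}")),
                    precursor_mz=float(pepmass),
                    precursor_charge=charge,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                )
            )
    return spectra


def write_mgf(spectra: list[PeakList], path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": f"{s.precursor_charge}+",
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a TSV table, checking for required columns by name."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"table {path} is missing required column(s): {', '.join(missing)}"
        )
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def hypotheses_to_table(space: list[ModComposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_phos": c.n_phos,
                "n_fe": c.n_fe,
                "n_al": c.n_al,
                "n_na": c.n_na,
                "n_ox": c.n_ox,
                "delta_mass": c.delta_mass,
            }
            for c in space
        ]
    )


def table_to_hypotheses(df: pd.DataFrame) -> list[ModComposition]:
    return [
        ModComposition(
            int(r.n_phos), int(r.n_fe), int(r.n_al), int(r.n_na), int(r.n_ox)
        )
        for r in df.itertuples()
    ]


def run_pipeline(
    config: RunConfig = RunConfig(),
    sim: synthetic_data.SimConfig | None = None,
    psm_table: pd.DataFrame | None = None,
    lfq_matrix: pd.DataFrame | None = None,
    lfq_groups: dict[str, str] | None = None,
    interactors: dict[str, str] | None = None,
    background: dict[str, str] | None = None,
    out_json=None,
) -> dict:
    """Chain assign -> summarize -> LFQ filter/impute/volcano -> motifs.

    Inputs not supplied are generated from ``sim`` (defaulting to a
    synthetic bundle seeded from ``config.seed``) so the full pipeline is
    runnable end to end without external data.  Returns a JSON-ready
    report of stage parameters, record counts and headline statistics.
    """
    if sim is None:
        sim = synthetic_data.SimConfig(seed=config.seed)
    report: dict = {"parameters": asdict(config)}

    space = enumerate_hypotheses(config.max_phos, config.max_metal, config.max_ox)
    if psm_table is None:
        psm_table = synthetic_data.make_psm_table(sim)
    assigned = psm_pipeline.assign_table(psm_table, space, tol=config.precursor_tol_da)
    summary = psm_pipeline.summarize_classes(assigned, min_psms=config.min_psms)
    report["psms"] = {
        "n_records": int(len(assigned)),
        "n_assigned": int((assigned["assigned"] != "unassigned").sum()),
        "n_classes": int(len(summary)),
        "n_classes_passing": int(summary["passes"].sum()) if len(summary) else 0,
    }

    if lfq_matrix is None:
        lfq_matrix, lfq_groups, _ = synthetic_data.make_lfq_matrix(sim)
    if lfq_groups is None:
        raise ValueError("lfq_groups is required when lfq_matrix is supplied")
    filtered = quantstats.filter_rows(lfq_matrix, lfq_groups, min_valid=config.min_valid)
    imputed = quantstats.impute_left_censored(
        filtered,
        width=config.imputation_width,
        downshift=config.imputation_downshift,
        seed=config.seed,
    )
    vol = quantstats.volcano(
        imputed,
        lfq_groups,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
    )
    counts = vol["category"].value_counts()
    report["lfq"] = {
        "n_proteins": int(len(lfq_matrix)),
        "n_after_filter": int(len(filtered)),
        "n_enriched_right": int(counts.get("enriched-right", 0)),
        "n_enriched_left": int(counts.get("enriched-left", 0)),
    }

    if interactors is None or background is None:
        proteome_cfg = synthetic_data.SimConfig(
            seed=sim.seed, n_proteins=120, motif_probability=0.8
        )
        interactors_all, _ = synthetic_data.make_proteome(proteome_cfg)
        background_cfg = synthetic_data.SimConfig(seed=sim.seed + 1, n_proteins=200)
        background_all, _ = synthetic_data.make_proteome(background_cfg)
        interactors = interactors or interactors_all
        background = background or background_all
    motifs = motif_screen.compare_sets(interactors, background)
    report["motifs"] = {
        "interactor_median_percent_positive": motifs["interactors"]["median"],
        "background_median_percent_positive": motifs["background"]["median"],
        "features_per_protein_interactors": motifs["interactors"]["features_per_protein"],
        "features_per_protein_background": motifs["background"]["features_per_protein"],
        "p_value": motifs["p_value"],
    }

    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
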