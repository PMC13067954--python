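"""Shared study conditions for the numbered analysis scripts.

One place defines the sampling conditions (seed, ladder size, sweep count)
so every script analyzes the same ensembles.  Sampled 300 K trajectories
are cached as dihedral CSVs under scratch/ (they are bulky and fully
reproducible from the seed); small derived tables go to results/.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ppiikit import io as kio
from ppiikit.peptide import MODEL_PEPTIDE
from ppiikit.pipeline import sample_peptide

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "remd"
RESULTS = ROOT / "results"

SEED = 1
N_REPLICAS = 8
TOTAL_SWEEPS = 100_000
VARIANTS = ("nonglyco", "glyco")


def trajectory_path(variant: str) -> Path:
    return SCRATCH / f"dihedrals_300K_{variant}.csv"


def ensure_sampled(variant: str):
    """300 K dihedral series for one variant, sampling and caching if needed.

    Returns (series, run_info dict).  The cached CSV is bit-reproducible
    from the seed, so re-sampling and re-reading are interchangeable.
    """
    SCRATCH.mkdir(parents=True, exist_ok=True)
    info_path = SCRATCH / f"run_info_{variant}.json"
    path = trajectory_path(variant)
    if path.exists() and info_path.exists():
        series = kio.read_dihedral_csv(path, temperature=300.0)
        # CSV residue columns are 1-based positions; restore biological labels
        from ppiikit.analysis import DihedralSeries
        labels = tuple(f"{aa}{num}" for aa, num in
                       zip(MODEL_PEPTIDE.sequence,
                           MODEL_PEPTIDE.residue_numbers))
        series = DihedralSeries(angles=series.angles, residue_labels=labels,
                                temperature=300.0, source=str(path))
        info = json.loads(info_path.read_text())
        return series, info
    run = sample_peptide(MODEL_PEPTIDE, glycosylated=(variant == "glyco"),
                         n_replicas=N_REPLICAS, total_sweeps=TOTAL_SWEEPS,
                         seed=SEED)
    series = run.series_at(300.0)
    kio.write_dihedral_csv(series, path)
    info = {
        "variant": variant,
        "seed": SEED,
        "n_replicas": N_REPLICAS,
        "total_sweeps": TOTAL_SWEEPS,
        "exchange_rates": [float(r) for r in run.exchange_rates],
        "sweep_acceptance": float(run.sweep_acceptance),
        "n_frames_300K": int(series.n_frames),
    }
    info_path.write_text(json.dumps(info, indent=2))
    return series, info
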