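"""End-to-end studies: build -> sample -> analyze -> converge -> compare.

These functions are the programmatic backbone of the command-line
``full-run`` and of the numbered analysis scripts: each runs a complete
paired glycosylated / nonglycosylated study on the mucin-domain model
peptide (or the threonine tetrapeptide preset) and returns plain
dataclasses / DataFrames that the callers serialize.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as kio
from .analysis import (
    DEFAULT_REGIONS,
    compare_populations,
    free_energy_surface,
    population_ci,
    ramachandran_histogram,
    region_populations,
)
from .convergence import convergence_check, radius_of_gyration
from .peptide import (
    MODEL_PEPTIDE,
    TETRAPEPTIDE,
    build_backbone_batch,
    glycosylation_sites,
)
from .sampler import MCConfig, TorsionPotential, make_ladder, run_remd

#: Ladder presets: (T_min, T_max) as used for the reference simulations,
#: with desk-scale replica counts.
MODEL_LADDER = (300.0, 455.95)
TETRA_LADDER = (300.0, 452.32)


@dataclass
class StudyResult:
    """One peptide's sampled 300 K ensemble plus its analytics."""

    run: object
    series_300k: object
    populations: object
    surface: object
    rg_overlap: object


def sample_peptide(spec, glycosylated: bool, n_replicas: int = 8,
                   total_sweeps: int = 200_000, seed: int = 0,
                   t_range=MODEL_LADDER, step_deg: float = 180.0,
                   sweeps_per_segment: int = 10,
                   glyco_modifier: float = 0.05):
    """Run the toy replica-exchange sampler for one peptide variant."""
    if glycosylated:
        # the Thr401 exclusion only concerns peptides that contain it
        excluded = frozenset({401}) & set(int(n) for n in spec.residue_numbers)
        peptide = spec.with_glyco_sites(glycosylation_sites(spec, excluded))
    else:
        peptide = spec.with_glyco_sites(())
    potential = TorsionPotential.for_peptide(
        peptide, glyco_modifier=glyco_modifier)
    ladder = make_ladder(t_range[0], t_range[1], n_replicas)
    config = MCConfig(
        n_segments=total_sweeps // sweeps_per_segment,
        sweeps_per_segment=sweeps_per_segment,
        step_deg=step_deg, exchange_interval=sweeps_per_segment,
        seed=seed,
    )
    return run_remd(peptide, potential, ladder, config)


def analyze_run(run, bins_per_axis: int = 72, n_boot: int = 500,
                ci_seed: int = 0) -> StudyResult:
    """300 K analytics for a replica run: surface, populations, convergence."""
    series = run.series_at(300.0)
    hist = ramachandran_histogram(series, bins_per_axis=bins_per_axis)
    surface = free_energy_surface(hist, temperature=300.0)
    populations = population_ci(series, n_boot=n_boot, seed=ci_seed)
    coords = build_backbone_batch(series.angles)
    rg = radius_of_gyration(coords.reshape(series.n_frames, -1, 3))
    report = convergence_check(rg)
    return StudyResult(run=run, series_300k=series, populations=populations,
                       surface=surface, rg_overlap=report)


def rg_split_overlap(run) -> float:
    """Histogram-overlap (50 bins) of R_g over the two halves of the
    post-burn-in 300 K trajectory, as a fraction in [0, 1]."""
    series = run.series_at(300.0)
    coords = build_backbone_batch(series.angles)
    rg = radius_of_gyration(coords.reshape(series.n_frames, -1, 3))
    return convergence_check(rg).overlap


def full_run(out_dir, seed: int = 0, peptide: str = "model",
             n_replicas: int = 8, total_sweeps: int = 50_000,
             n_boot: int = 500, bins_per_axis: int = 72,
             alpha: float = 0.05, min_effect: float = 0.05) -> dict:
    """Paired glyco/nonglyco toy-REMD study with a full artifact manifest.

    Writes dihedral CSVs, population tables, gridded surfaces, a
    convergence report, comparison flags, the exact configuration used and
    a manifest into ``out_dir``; returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if peptide == "model":
        spec, t_range = MODEL_PEPTIDE, MODEL_LADDER
    elif peptide == "tetra":
        spec, t_range = TETRAPEPTIDE, TETRA_LADDER
    else:
        raise ValueError("peptide must be 'model' or 'tetra'")
    config = {
        "peptide": peptide, "sequence": spec.sequence,
        "first_residue_number": int(spec.first_residue_number),
        "n_replicas": n_replicas, "total_sweeps": total_sweeps,
        "t_min": t_range[0], "t_max": t_range[1],
        "bins_per_axis": bins_per_axis, "n_boot": n_boot,
        "alpha": alpha, "min_effect": min_effect, "seed": seed,
    }
    kio.save_config(config, out / "config.yaml")

    results = {}
    artifacts = {"config": "config.yaml"}
    for variant, glyc in (("nonglyco", False), ("glyco", True)):
        run = sample_peptide(spec, glyc, n_replicas=n_replicas,
                             total_sweeps=total_sweeps, seed=seed,
                             t_range=t_range)
        res = analyze_run(run, bins_per_axis=bins_per_axis,
                          n_boot=n_boot, ci_seed=seed)
        results[variant] = res
        kio.write_dihedral_csv(res.series_300k,
                               out / f"dihedrals_300K_{variant}.csv")
        res.populations.fractions.to_csv(
            out / f"populations_{variant}.csv")
        kio.write_surface_text(res.surface, out / f"surface_{variant}.txt")
        artifacts[f"dihedrals_{variant}"] = f"dihedrals_300K_{variant}.csv"
        artifacts[f"populations_{variant}"] = f"populations_{variant}.csv"
        artifacts[f"surface_{variant}"] = f"surface_{variant}.txt"

    comparison = compare_populations(results["nonglyco"].populations,
                                     results["glyco"].populations,
                                     alpha=alpha, min_effect=min_effect)
    comparison.to_csv(out / "comparison.csv", index=False)
    artifacts["comparison"] = "comparison.csv"

    manifest = {
        "config": config,
        "artifacts": artifacts,
        "summary": {
            variant: {
                "argmin_region": res.surface.argmin_region(),
                "rg_overlap": res.rg_overlap.overlap,
                "rg_converged": bool(res.rg_overlap.passed),
                "mean_ppii": float(res.populations.fractions["PPII"].mean()),
                "exchange_rate_mean":
                    float(np.nanmean(res.run.exchange_rates)),
            }
            for variant, res in results.items()
        },
        "significant_differences": comparison.loc[
            comparison["significant"], ["residue", "region"]
        ].to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
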