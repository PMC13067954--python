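# ppiikit

Conformational analysis of mucin-domain peptides: does a densely
O-glycosylated tandem-repeat sequence like lubricin's
KEPAPTTP mucin domain prefer the polyproline type II (PPII) helix, and
what do the glycans change?

`ppiikit` provides the full desk-scale pipeline for that question:

* **peptide geometry** — build idealized N/CA/C backbones from per-residue
  (φ, ψ) torsions, annotate tandem repeats and O-glycosylation sites, and
  fit helical parameters (residues per turn, rise, handedness);
* **torsional replica-exchange Monte Carlo** — Metropolis sampling of
  (φ, ψ) on a von Mises basin-mixture potential at a geometric temperature
  ladder with neighbour exchanges (a protocol-faithful, non-atomistic
  stand-in for replica-exchange MD);
* **ensemble analytics** — Ramachandran histograms, free-energy surfaces
  by Boltzmann inversion ΔG(φ, ψ) = −k_B T ln[P(φ, ψ)/P_max],
  dihedral-based secondary-structure populations
  (α_R / β / PPII / α_L / coil) with moving-block-bootstrap confidence
  intervals and a calibrated glyco/non-glyco difference test;
* **convergence diagnostics** — per-frame radius of gyration
  R_g = √[(1/M) Σ m_i (r_i − R)²], split-halves 50-bin histogram overlap
  against a ≥ 90 % criterion;
* **synthetic ensembles** — a sticky-Markov / von Mises generator with
  known basin occupancies, autocorrelation and glycosylation effect, so
  every statistic can be validated against ground truth.

It is aimed at structural bioinformaticians who want the analysis layer of
a glycopeptide conformational study — reusable, tested, and runnable in
minutes on a laptop — without the atomistic simulation itself.

## Worked example

```python
import numpy as np
from ppiikit import (build_backbone, helix_parameters, MODEL_PEPTIDE,
                     glycosylation_sites)
from ppiikit.pipeline import sample_peptide, rg_split_overlap
from ppiikit.analysis import (ramachandran_histogram, free_energy_surface,
                              region_populations)

# 1. the model peptide: lubricin residues 393-410
print(MODEL_PEPTIDE.sequence)           # PKEPAPTTTKEPAPTTPK
print(glycosylation_sites(MODEL_PEPTIDE))  # [399, 400, 407, 408]

# 2. ideal PPII geometry
conf = build_backbone(MODEL_PEPTIDE.sequence,
                      np.tile([-75.0, 145.0], (18, 1)))
print(helix_parameters(conf))
# HelixParameters(residues_per_turn=2.99, rise_per_residue=3.08,
#                 handedness='left', twist_deg=-120.5)

# 3. sample, check convergence, invert the 300 K histogram
run = sample_peptide(MODEL_PEPTIDE, glycosylated=False,
                     n_replicas=8, total_sweeps=100_000, seed=1)
print(f"Rg split-halves overlap: {100 * rg_split_overlap(run):.1f}%")
# Rg split-halves overlap: 90.9%
surface = free_energy_surface(
    ramachandran_histogram(run.series_at(300.0)), temperature=300.0)
print(surface.argmin_region(), surface.argmin_center())
# PPII (-77.5, 142.5)
```

The numbers read: an ideal (−75°, 145°) backbone is a left-handed helix
with 3 residues per turn (the PPII signature); the sampled run is
converged by the ≥ 90 % overlap criterion; and the 300 K free-energy
minimum of the PPII-dominant ensemble falls inside the PPII region bounds.
Running the glycosylated variant and comparing populations
(`analysis/05_populations.py`) shows each glycosylated threonine losing
essentially all α_R occupancy (≈ 0.13 → 0.001) and gaining PPII
(≈ +0.07), the modeled steric effect of the O-linked GalNAc–Gal glycans.

## Command line

```sh
ppiikit build --out ppii.pdb                 # ideal backbone -> PDB
ppiikit simulate --replicas 8 --sweeps 20000 --out dih.csv
ppiikit synth --residues 18 --frames 10000 --out synth.csv
ppiikit analyze --dihedrals dih.csv --out-dir out/
ppiikit converge --dihedrals dih.csv
ppiikit compare --dihedrals-a a.csv --dihedrals-b b.csv --out cmp.csv
ppiikit full-run --out-dir study/ --seed 1   # paired glyco/nonglyco study
```

## Analysis scripts

The numbered drivers under `analysis/` run the packaged study and write
small tables under `results/` (bulky trajectories are cached under
`scratch/`): `01_build_peptides.py` (repeats, glyco sites, ideal helices),
`02_sample_remd.py` (paired toy-REMD sampling), `03_convergence.py`
(R_g overlap check), `04_free_energy.py` (ΔG surfaces),
`05_populations.py` (per-residue populations, CIs, glyco comparison).

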