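# Methods

## Problem and scope

Lubricin (PRG4) owes its boundary-lubrication behaviour largely to a long,
densely O-glycosylated central mucin domain built from KEPAPTTP-type tandem
repeats.  The working hypothesis for such sequences is that they adopt the
polyproline type II (PPII) helix — a left-handed backbone helix near
(phi, psi) = (-75 deg, 145 deg) with ~3 residues per turn and no regular
backbone hydrogen bonding — and that threonine-linked GalNAc-Gal glycans
stabilize it further by destabilizing the compact right-handed alpha
(alpha_R) conformation.

This package implements the *analysis pipeline* for that question at desk
scale: an idealized backbone builder and helix fit, a torsional
replica-exchange Monte Carlo (MC) sampler on a basin-mixture potential, a
ground-truth synthetic ensemble generator, Ramachandran free-energy
surfaces by Boltzmann inversion, dihedral-based secondary-structure
populations with bootstrap confidence intervals, and a radius-of-gyration
(R_g) convergence diagnostic.  It does **not** perform atomistic
simulation: there is no force field, no solvent, and no claim of
thermodynamic equivalence to explicit-solvent replica-exchange MD.  The
sampler reproduces the *protocol structure* (geometric temperature ladder,
neighbour exchanges, production/analysis split) so that every downstream
analysis can be exercised and validated end to end.

## Model peptide

The modeled mucin subsection is lubricin residues 393-410,
PKEPAPTTTKEPAPTTPK, spanning one canonical KEPAPTTP repeat and the common
KEPAPTTT variant.  Threonines sit at residues 399, 400, 401, 407, 408;
Thr401 (the third) carries no glycan in vivo, so the glycosylated variant
has O-linked sites at {399, 400, 407, 408}.  A TTTT tetrapeptide preset
(glycans on every threonine, 32-replica ladder to 452.32 K) probes
threonine's intrinsic propensity.

## Backbone geometry

Backbones are built from per-residue (phi, psi) by sequential
natural-extension (NeRF-style) placement of N/CA/C atoms with fixed
standard internal coordinates (N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A,
angles 111.0/116.6/121.7 deg, trans omega = 180 deg; all configurable).
The first residue's phi and last residue's psi are undefined; they are
flagged NaN and excluded from analytics, never imputed.  Construction and
extraction round-trip to < 1e-6 deg (PDB files, which store coordinates at
1e-3 A, limit re-extracted torsions to ~0.1 deg).

Helical parameters of a uniform chain come from the screw transform
between consecutive N/CA/C triads (Kabsch superposition): residues per
turn = 360 / |twist|, rise = translation along the screw axis, handedness
by the right-hand rule about the axis of advance.  The ideal PPII chain
gives 2.99 residues/turn, left-handed, rise 3.08 A; the ideal alpha chain
3.62 residues/turn, right-handed, rise 1.56 A.

## Torsional potential and sampler

Each residue feels U(phi, psi) = -eps * ln sum_k w_k g(phi - phi_k; kappa)
g(psi - psi_k; kappa), a log-mixture of products of von Mises bells over
four basins centered at PPII (-75, 145), alpha_R (-60, -45),
beta (-135, 135) and alpha_L (60, 45).  Defaults: kappa = 8 (basin width
~20 deg), eps = 1 kcal/mol, weights PPII 0.5 / beta 0.2 / alpha_R 0.2 /
alpha_L 0.1 — a PPII-dominant mix consistent with the sequence-driven PPII
preference of mucin repeats.  Glycosylation multiplies the alpha_R weight
of the glycosylated residue by 0.05 (steric destabilization of the compact
conformation).  Residues are energetically independent by default; an
optional nearest-neighbour phi-coupling term J(1 - cos(dphi)) exists but
is off, since no coupling model is part of the study.

Sampling is single-angle Metropolis: each sweep proposes every phi and psi
once with a uniform +/-step kick and accepts with min(1, exp(-dU/kB T)).
The default step is 180 deg (a full-circle symmetric proposal).  This is a
deliberate equilibrium-sampling choice: the psi gap between the PPII and
alpha_R basins (~170 deg) crosses a barrier of several kcal/mol that
+/-30 deg local moves essentially never surmount at 300 K, whereas the
global proposal hops between basins directly while remaining exactly
Boltzmann-correct (acceptance ~0.22 at 300 K).  Smaller steps remain
available and are used where only within-basin mixing matters.

Replica exchange uses a geometric ladder T_i = T_min r^(i-1) (presets
300-455.95 K; 300-452.32 K for the tetrapeptide), neighbour swap attempts
every 10 sweeps with even/odd pair alternation, and the standard parallel
tempering criterion min(1, exp[(1/kB T_i - 1/kB T_j)(E_i - E_j)]).  Swaps
permute configurations only (verified by walker bookkeeping at every
recorded frame).  One frame is recorded per 10-sweep segment and the first
half of each run is discarded before analysis, mirroring the
analyze-the-last-half convention of production REMD protocols.  A single
seed drives one master generator, so runs are bit-reproducible.

kB = 0.0019872041 kcal/(mol K) throughout, so free energies are in
kcal/mol.

## Analytics

**Free-energy surfaces.**  All residues and frames are pooled into a
72 x 72 histogram over (-180, 180]^2 (5-deg bins; resolution
configurable), normalized, and inverted via dG = -kB T ln(P/Pmax).  Empty
bins are *undefined* (NaN), not infinite, keeping surfaces plottable; the
minimum over defined bins is exactly 0 at the most populated bin.
Surfaces scale linearly with T bin-by-bin.

**Region classification.**  Literature rectangle bounds: alpha_R
(-160 < phi < -20, -120 < psi < 50), beta (-180 < phi < -90,
50 < psi < 240), PPII (-90 < phi < 20, 50 < psi < 240), alpha_L
(30 < phi < 100, 0 < psi < 80), coil elsewhere.  Where an upper psi bound
exceeds 180, psi values below (bound - 360) are lifted by +360 before
testing (psi = -150 tests as 210).  Inequalities are strict, so exact
boundary values classify as coil — a zero-measure convention that keeps
the printed bounds authoritative.  The named regions tile the torus
disjointly (verified on a 1-deg grid).

**Populations and uncertainty.**  Per-residue region occupancies get
percentile confidence intervals from a moving-block bootstrap over frames
(block length ceil(n^(1/3)) by default), which preserves the temporal
autocorrelation that makes naive binomial intervals too narrow.  The
glyco/nonglyco comparison forms the bootstrap distribution of the
difference of fractions; its interval uses the *expanded-percentile*
calibration (the percentile level is widened via the t quantile on the
effective number of resampled blocks, after Hesterberg), because the plain
percentile interval is anticonservative at small frame counts (measured
type-I ~0.08-0.095 at 10 frames versus ~0.053 with the calibration; the
two coincide for long trajectories).  A difference is flagged significant
when the interval excludes zero at alpha = 0.05 *and* exceeds a practical
threshold (default 0.05 absolute occupancy, settable to 0), mirroring the
"practically and statistically significant" reading of population
differences.

**Convergence.**  Per-frame R_g = sqrt((1/M) sum m_i |r_i - R|^2) (equal
masses by default for backbone-only toy trajectories; per-atom masses
supported).  The post-burn-in window is split into two equal contiguous
halves (odd counts give the extra frame to the second half), both are
histogrammed on 50 shared bins spanning the pooled range, and the overlap
coefficient sum_bins min(p, q) is compared against 0.90; the boundary
counts as a pass.  The overlap statistic itself is a definition adopted
here (the convergence literature leaves it unnamed): 1 for identical
samples, 0 for disjoint ones, symmetric, and invariant under a common
affine rescaling.

## Synthetic generator

For validation with known truth, dihedral ensembles are generated from a
per-residue sticky Markov chain over basin labels (PPII, alpha_R, beta,
alpha_L, coil): P(next = j | cur = i) = rho [i = j] + (1 - rho) w_j, whose
stationary law is exactly the weight vector w and whose lag-1 label
autocorrelation is rho (default 0.9 — autocorrelation is present on
purpose, it is what the block bootstrap exists for).  Given the label,
angles are von Mises around the basin center with concentration kappa
(default 16, ~14-deg spread); coil draws uniformly on the torus.  The
glycosylation effect moves alpha_R weight to PPII (factor 0.02 by
default) at glycosylated threonines and, by default, also at threonines
adjacent to a glycosylated one (the cooperative-neighbour observation), so
the perturbed set of the model peptide is all five threonines.

Two caveats govern what generator-based tests can show.  First, basin
mass leaks across region boundaries at realistic kappa — the PPII center
sits 15 deg from the phi = -90 boundary, so at kappa = 8 roughly a fifth
of PPII-labelled mass classifies as beta.  Recovery tests therefore
compare measured populations against region probabilities obtained by
independent quadrature of the mixture density, not against raw weights.
Second, the generator emulates only label-level autocorrelation and
per-residue independence; real trajectories carry inter-residue coupling,
slow collective modes, and force-field-specific basin shapes.  Passing
tests validate the *analytics*, not any atomistic claim about lubricin.

## Study conditions and problem sizes

The packaged studies use an 8-replica ladder and 1-2 x 10^5 sweeps of the
18-residue model peptide (sweeps are vectorized across replicas and
residues, ~80 s for 2 x 10^5 sweeps), 72 x 72 surfaces, 200-500 bootstrap
replicates, and 200-replication calibration studies — sizes chosen so the
whole pipeline, including its statistical calibration checks, runs on one
CPU in minutes while leaving every estimate's Monte Carlo error well
inside the tolerances asserted in the tests.

At these conditions the sampled 300 K ensembles give: both variants'
free-energy minima inside the PPII bounds; split-halves R_g overlaps of
91-94% (pass at >= 90%); and, for the glycopeptide, threonine alpha_R
occupancy dropping from ~0.13 to ~0.001 with PPII rising by ~0.07-0.08 —
the modeled steric effect propagating through the full pipeline.

## Known limitations

* The basin-mixture potential is phenomenological; its weights set the
  answer's direction by construction.  Directional results (PPII-dominant
  minima, alpha_R suppression) validate the pipeline's plumbing, not
  lubricin's physics.
* Only N/CA/C atoms exist; glycans are annotations plus an energy
  modifier, so R_g values are backbone-only and not comparable to
  experimental radii.
* The exchange pairing scheme (even/odd alternation) and the overlap
  statistic are documented defaults; alternatives exist in the literature
  and are not implemented.
* Bootstrap intervals assume stationarity of the analyzed window; they do
  not diagnose unequilibrated input (that is the R_g overlap check's job,
  and it is a necessary, not sufficient, signal).
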