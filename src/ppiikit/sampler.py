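"""Replica-exchange Metropolis Monte Carlo over backbone torsions.

This is a desk-scale stand-in for explicit-solvent replica-exchange MD: the
configuration of a peptide is its vector of per-residue (phi, psi) torsions,
the energy is a smooth basin-mixture potential on the Ramachandran torus,
and sampling proceeds by single-angle Metropolis moves at a geometric ladder
of temperatures with periodic neighbor-swap attempts.  It reproduces the
*structure* of the REMD protocol (geometric 300-455.95 K ladder, exchange
attempts at fixed intervals, discarding the first half of each run before
analysis) without any atomistic force field, and makes no claim of
thermodynamic equivalence to molecular dynamics.

The potential for each residue is

    U(phi, psi) = -eps * ln sum_k w_k g(phi - phi_k; kappa) g(psi - psi_k; kappa)

with g a von Mises density, basins centered at PPII (-75, 145),
alpha_R (-60, -45), beta (-135, 135) and alpha_L (60, 45).  O-glycosylation
of a residue is modeled as a multiplicative suppression of its alpha_R basin
weight (the glycan sterically clashes with the compact alpha_R backbone),
which is the qualitative effect seen for glycosylated threonines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0, logsumexp

from .analysis import DihedralSeries
from .peptide import PeptideSpec
from .util import KB_KCAL_MOL_K, wrap_angle

#: Basin centers (phi, psi) in degrees, chosen inside the literature region
#: bounds so that basin occupancy is unambiguous.
BASIN_CENTERS = {
    "PPII": (-75.0, 145.0),
    "alpha_R": (-60.0, -45.0),
    "beta": (-135.0, 135.0),
    "alpha_L": (60.0, 45.0),
}

#: Default stationary basin mix: PPII-dominant, matching the sequence-driven
#: PPII preference of mucin repeats.
DEFAULT_BASIN_WEIGHTS = {
    "PPII": 0.5,
    "beta": 0.2,
    "alpha_R": 0.2,
    "alpha_L": 0.1,
}


@dataclass(frozen=True)
class TorsionPotential:
    """Basin-mixture torsional potential, independent across residues.

    ``weights`` has shape (n_residues, n_basins) and is positive; ``kappa``
    is the angular concentration (dimensionless), ``epsilon`` the depth
    scale in kcal/mol.  ``coupling`` optionally adds a nearest-neighbor
    term J * (1 - cos(phi_{i+1} - phi_i)) in kcal/mol (0 = independent
    residues, the default).
    """

    centers: np.ndarray
    kappa: float
    weights: np.ndarray
    epsilon: float = 1.0
    coupling: float = 0.0
    basin_names: tuple = tuple(BASIN_CENTERS)

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if np.any(w <= 0):
            raise ValueError("basin weights must be positive")
        if w.shape[1] != c.shape[0]:
            raise ValueError("weights do not match basin count")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "weights", w)

    @property
    def n_residues(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def for_peptide(cls, spec: PeptideSpec,
                    basin_weights=None,
                    kappa: float = 8.0,
                    epsilon: float = 1.0,
                    glyco_modifier: float = 0.05,
                    coupling: float = 0.0) -> "TorsionPotential":
        """Default potential for a peptide; glyco sites get alpha_R damped.

        ``glyco_modifier`` multiplies the alpha_R basin weight of every
        residue in ``spec.glyco_sites`` (values < 1 suppress the compact
        alpha_R conformation, the modeled steric effect of the glycan).
        """
        basin_weights = dict(basin_weights or DEFAULT_BASIN_WEIGHTS)
        names = tuple(BASIN_CENTERS)
        base = np.array([basin_weights[n] for n in names], dtype=float)
        w = np.tile(base, (spec.n_residues, 1))
        a_r = names.index("alpha_R")
        for number in spec.glyco_sites:
            w[spec.position_of(number) - 1, a_r] *= glyco_modifier
        centers = np.array([BASIN_CENTERS[n] for n in names])
        return cls(centers=centers, kappa=kappa, weights=w, epsilon=epsilon,
                   coupling=coupling, basin_names=names)

    def residue_energy(self, phi, psi) -> np.ndarray:
        """Per-residue mixture energy, kcal/mol; broadcasts leading dims.

        ``phi``/``psi`` are degrees with trailing axis of length
        ``n_residues``.
        """
        dphi = np.deg2rad(phi[..., None] - self.centers[:, 0])
        dpsi = np.deg2rad(psi[..., None] - self.centers[:, 1])
        log_norm = 2.0 * np.log(2.0 * np.pi * i0(self.kappa))
        log_mix = logsumexp(
            np.log(self.weights) + self.kappa * (np.cos(dphi) + np.cos(dpsi)),
            axis=-1,
        ) - log_norm
        return -self.epsilon * log_mix

    def coupling_energy(self, phi) -> np.ndarray:
        """Total nearest-neighbor phi coupling energy (0 when J = 0)."""
        if self.coupling == 0.0:
            return np.zeros(np.asarray(phi).shape[:-1])
        dphi = np.deg2rad(np.diff(phi, axis=-1))
        return self.coupling * np.sum(1.0 - np.cos(dphi), axis=-1)

    def total_energy(self, state) -> np.ndarray:
        """Total energy of (..., n_residues, 2) torsion states, kcal/mol."""
        state = np.asarray(state, dtype=float)
        res = self.residue_energy(state[..., 0], state[..., 1]).sum(axis=-1)
        return res + self.coupling_energy(state[..., 0])


@dataclass(frozen=True)
class ReplicaLadder:
    """Geometric temperature ladder T_i = T_min * r^(i-1)."""

    temperatures: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 1 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be positive and increasing")
        object.__setattr__(self, "temperatures", t)

    @property
    def n_replicas(self) -> int:
        return self.temperatures.size

    @property
    def ratio(self) -> float:
        if self.n_replicas < 2:
            return 1.0
        return float(self.temperatures[1] / self.temperatures[0])


def make_ladder(t_min: float, t_max: float, n_replicas: int) -> ReplicaLadder:
    """Geometric ladder with exact endpoints, e.g. 64 replicas 300-455.95 K."""
    if n_replicas < 2:
        raise ValueError("a replica ladder needs at least 2 replicas")
    if not t_max > t_min > 0:
        raise ValueError("require t_max > t_min > 0")
    return ReplicaLadder(np.geomspace(t_min, t_max, n_replicas))


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo schedule.

    A *sweep* proposes each angle once.  One frame is recorded per segment
    of ``sweeps_per_segment`` sweeps; exchange attempts occur every
    ``exchange_interval`` sweeps.  The first ``burn_in_fraction`` of the
    recorded frames is discarded before analysis (default one half,
    mirroring the analyze-the-last-half convention of the reference
    protocol).
    """

    n_segments: int = 1000
    sweeps_per_segment: int = 10
    # +/-180 spans the full circle: a symmetric proposal that can hop
    # directly between basins separated by large psi gaps (PPII <-> alpha_R)
    step_deg: float = 180.0
    exchange_interval: int = 10
    burn_in_fraction: float = 0.5
    seed: int = 0
    k_b: float = KB_KCAL_MOL_K

    def __post_init__(self):
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.n_segments < 1 or self.sweeps_per_segment < 1:
            raise ValueError("segments and sweeps must be positive")


def mc_sweep(state, potential: TorsionPotential, temperatures, rng,
             step_deg: float = 30.0, energies=None, k_b: float = KB_KCAL_MOL_K):
    """One Metropolis sweep: every angle proposed once with a +/-step kick.

    ``state`` has shape (n_replicas, n_residues, 2) degrees (a bare
    (n_residues, 2) state is treated as one replica); ``temperatures``
    broadcasts over replicas.  Moves are accepted with probability
    min(1, exp(-dU / kB T)).  Returns (state, per-residue energies,
    acceptance fraction); the input arrays are not modified.

    With zero coupling all residues are energetically independent, so the
    phi pass and psi pass are vectorized across replicas and residues; with
    coupling the phi pass runs checkerboard (even then odd residues), which
    is equivalent for a nearest-neighbor interaction.
    """
    state = np.array(state, dtype=float)
    squeeze = state.ndim == 2
    if squeeze:
        state = state[None]
    temps = np.broadcast_to(np.asarray(temperatures, dtype=float),
                            (state.shape[0],))
    if energies is None:
        energies = potential.residue_energy(state[..., 0], state[..., 1])
    else:
        energies = np.array(energies, dtype=float)
    beta = 1.0 / (k_b * temps)[:, None]
    accepted = 0
    total = 0

    def metropolis(delta, shape):
        if not np.isfinite(delta).all():
            raise FloatingPointError("non-finite energy change in MC sweep")
        return np.log(rng.random(shape)) < -beta * delta

    groups = [slice(None)]
    if potential.coupling != 0.0:
        groups = [slice(0, None, 2), slice(1, None, 2)]
    for axis in (0, 1):  # phi pass then psi pass
        for grp in groups:
            prop = state[..., axis].copy()
            kick = rng.uniform(-step_deg, step_deg,
                               size=prop[:, grp].shape)
            prop[:, grp] = wrap_angle(prop[:, grp] + kick)
            if axis == 0:
                new_e = potential.residue_energy(prop, state[..., 1])
            else:
                new_e = potential.residue_energy(state[..., 0], prop)
            delta = new_e - energies
            if potential.coupling != 0.0 and axis == 0:
                old_c = _phi_bond_terms(state[..., 0], potential)
                new_c = _phi_bond_terms(prop, potential)
                delta = delta + (new_c - old_c)
            accept = metropolis(delta[:, grp], delta[:, grp].shape)
            sel = state[..., axis]
            sel[:, grp] = np.where(accept, prop[:, grp], sel[:, grp])
            energies[:, grp] = np.where(accept, new_e[:, grp],
                                        energies[:, grp])
            accepted += int(accept.sum())
            total += accept.size
    if squeeze:
        return state[0], energies[0], accepted / total
    return state, energies, accepted / total


def _phi_bond_terms(phi, potential: TorsionPotential) -> np.ndarray:
    """Per-residue share of the phi coupling energy (residue i owns both
    bonds touching it, so a single-residue move sees the full local change)."""
    dphi = np.deg2rad(np.diff(phi, axis=-1))
    bond = potential.coupling * (1.0 - np.cos(dphi))
    out = np.zeros_like(phi)
    out[..., :-1] += bond
    out[..., 1:] += bond
    return out


def exchange_probability(e_i: float, t_i: float, e_j: float, t_j: float,
                         k_b: float = KB_KCAL_MOL_K) -> float:
    """Parallel-tempering swap probability for neighbor replicas.

    min(1, exp[(1/(kB T_i) - 1/(kB T_j)) * (E_i - E_j)]) — the standard
    Metropolis criterion that preserves the Boltzmann ensemble at every
    rung of the ladder.
    """
    delta = (1.0 / (k_b * t_i) - 1.0 / (k_b * t_j)) * (e_i - e_j)
    return float(min(1.0, np.exp(min(delta, 0.0)) if delta < 0 else 1.0))


def exchange_attempt(state_i, e_i, t_i, state_j, e_j, t_j, rng,
                     k_b: float = KB_KCAL_MOL_K):
    """Attempt one neighbor swap; returns (state_i, state_j, swapped)."""
    p = exchange_probability(e_i, t_i, e_j, t_j, k_b)
    if rng.random() < p:
        return state_j, state_i, True
    return state_i, state_j, False


@dataclass(frozen=True)
class ReplicaRun:
    """Output of a replica-exchange run.

    ``series_by_temperature`` holds one post-burn-in :class:`DihedralSeries`
    per ladder rung (configuration swaps already applied, so each series is
    at a fixed temperature).  ``walker_ids`` tracks which initial walker
    occupies each temperature slot at each recorded frame; its rows are
    permutations of 0..K-1, certifying that exchanges only permute
    configurations.
    """

    ladder: ReplicaLadder
    config: MCConfig
    series_by_temperature: list
    energies: np.ndarray  # (frames, n_replicas) post burn-in totals
    exchange_attempts: np.ndarray  # per neighbor pair
    exchange_accepts: np.ndarray
    walker_ids: np.ndarray  # (frames, n_replicas), post burn-in
    sweep_acceptance: float

    @property
    def exchange_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.exchange_accepts / self.exchange_attempts

    def series_at(self, temperature: float) -> DihedralSeries:
        i = int(np.argmin(np.abs(self.ladder.temperatures - temperature)))
        return self.series_by_temperature[i]


def run_remd(spec: PeptideSpec, potential: TorsionPotential,
             ladder: ReplicaLadder, config: MCConfig,
             initial_phi_psi=(-75.0, 145.0)) -> ReplicaRun:
    """Run replica-exchange torsional MC for a peptide.

    All replicas start from the same conformation (default the PPII point
    (-75, 145), the initialization used for the reference simulations).
    Neighbor-swap attempts alternate even/odd pairings every
    ``exchange_interval`` sweeps.  Fully reproducible from ``config.seed``.
    """
    if potential.n_residues != spec.n_residues:
        raise ValueError("potential sized for a different peptide")
    k = ladder.n_replicas
    n_res = spec.n_residues
    rng = np.random.default_rng(config.seed)
    init = np.asarray(initial_phi_psi, dtype=float)
    if init.shape == (2,):
        init = np.tile(init, (n_res, 1))
    state = np.tile(init[None], (k, 1, 1)).astype(float)
    energies = potential.residue_energy(state[..., 0], state[..., 1])
    walkers = np.arange(k)

    n_pairs = max(k - 1, 0)
    attempts = np.zeros(n_pairs)
    accepts = np.zeros(n_pairs)
    frames = np.empty((config.n_segments, k, n_res, 2))
    frame_energy = np.empty((config.n_segments, k))
    frame_walkers = np.empty((config.n_segments, k), dtype=int)
    beta = 1.0 / (config.k_b * ladder.temperatures)

    sweep_count = 0
    parity = 0
    acc_sum = 0.0
    for seg in range(config.n_segments):
        for _ in range(config.sweeps_per_segment):
            state, energies, acc = mc_sweep(
                state, potential, ladder.temperatures, rng,
                step_deg=config.step_deg, energies=energies, k_b=config.k_b)
            acc_sum += acc
            sweep_count += 1
            if k > 1 and sweep_count % config.exchange_interval == 0:
                totals = energies.sum(axis=1) + \
                    potential.coupling_energy(state[..., 0])
                for i in range(parity, k - 1, 2):
                    attempts[i] += 1
                    delta = (beta[i] - beta[i + 1]) * (totals[i] - totals[i + 1])
                    if np.log(rng.random()) < min(delta, 0.0):
                        state[[i, i + 1]] = state[[i + 1, i]]
                        energies[[i, i + 1]] = energies[[i + 1, i]]
                        totals[[i, i + 1]] = totals[[i + 1, i]]
                        walkers[[i, i + 1]] = walkers[[i + 1, i]]
                        accepts[i] += 1
                parity = 1 - parity
        frames[seg] = state
        frame_energy[seg] = energies.sum(axis=1) + \
            potential.coupling_energy(state[..., 0])
        frame_walkers[seg] = walkers
    burn = int(np.floor(config.n_segments * config.burn_in_fraction))
    labels = tuple(f"{aa}{num}" for aa, num in
                   zip(spec.sequence, spec.residue_numbers)) \
        if spec.sequence else ()
    series = [
        DihedralSeries(angles=frames[burn:, i],
                       residue_labels=labels,
                       temperature=float(ladder.temperatures[i]),
                       source=f"remd seed={config.seed}")
        for i in range(k)
    ]
    return ReplicaRun(
        ladder=ladder, config=config, series_by_temperature=series,
        energies=frame_energy[burn:], exchange_attempts=attempts,
        exchange_accepts=accepts, walker_ids=frame_walkers[burn:],
        sweep_acceptance=acc_sum / max(sweep_count, 1),
    )
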