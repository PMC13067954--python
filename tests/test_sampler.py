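"""Replica ladder, Metropolis sweeps, exchange criterion, REMD runs."""

import numpy as np
import pytest

from ppiikit.peptide import MODEL_PEPTIDE, PeptideSpec, glycosylation_sites
from ppiikit.sampler import (
    MCConfig,
    ReplicaLadder,
    TorsionPotential,
    exchange_attempt,
    exchange_probability,
    make_ladder,
    mc_sweep,
    run_remd,
)
from ppiikit.util import KB_KCAL_MOL_K as KB


def single_basin_potential(kappa=8.0, center=(-75.0, 145.0)):
    return TorsionPotential(centers=[center], kappa=kappa, weights=[[1.0]],
                            epsilon=1.0, basin_names=("PPII",))


class TestLadder:
    @pytest.mark.parametrize(
        "t_min, t_max, n",
        [(300.0, 455.95, 64), (300.0, 452.32, 32), (300.0, 330.0, 2)],
    )
    def test_geometric_with_exact_endpoints(self, t_min, t_max, n):
        ladder = make_ladder(t_min, t_max, n)
        temps = ladder.temperatures
        assert temps[0] == pytest.approx(t_min, abs=1e-12)
        assert temps[-1] == pytest.approx(t_max, abs=1e-12)
        ratios = temps[1:] / temps[:-1]
        assert np.ptp(ratios) < 1e-10

    def test_too_few_replicas_rejected(self):
        with pytest.raises(ValueError):
            make_ladder(300.0, 400.0, 1)
        with pytest.raises(ValueError):
            make_ladder(400.0, 300.0, 4)


class TestSweep:
    def test_zero_step_leaves_state_unchanged(self):
        pot = single_basin_potential()
        rng = np.random.default_rng(0)
        state = np.array([[[-75.0, 145.0], [10.0, -30.0]]])
        new, _, _ = mc_sweep(state, pot, [300.0], rng, step_deg=0.0)
        assert np.array_equal(new, state)

    def test_infinite_temperature_accepts_everything(self):
        pot = single_basin_potential()
        rng = np.random.default_rng(1)
        state = np.tile([-75.0, 145.0], (1, 20, 1))
        total = 0.0
        for _ in range(50):
            state, _, acc = mc_sweep(state, pot, [1e12], rng, step_deg=120.0)
            total += acc
        assert total / 50 == pytest.approx(1.0, abs=1e-3)

    def test_input_state_not_mutated(self):
        pot = single_basin_potential()
        state = np.tile([-75.0, 145.0], (2, 3, 1))
        before = state.copy()
        mc_sweep(state, pot, [300.0, 400.0], np.random.default_rng(2),
                 step_deg=40.0)
        assert np.array_equal(state, before)

    def test_boltzmann_recovery_short(self):
        # short-run version of the 5-degree-grid check (full run is in the
        # acceptance suite): TV to the quadrature law shrinks below 0.10
        pot = single_basin_potential()
        rng = np.random.default_rng(5)
        state = np.array([[[-75.0, 145.0]]])
        energies = None
        n = 20_000
        samples = np.empty((n, 2))
        for s in range(n):
            state, energies, _ = mc_sweep(state, pot, [300.0], rng,
                                          step_deg=60.0, energies=energies)
            samples[s] = state[0, 0]
        edges = np.linspace(-180, 180, 73)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ph, ps = np.meshgrid(centers, centers, indexing="ij")
        u = pot.residue_energy(ph[..., None], ps[..., None])[..., 0]
        p = np.exp(-u / (KB * 300.0))
        p /= p.sum()
        counts, _, _ = np.histogram2d(samples[:, 0], samples[:, 1],
                                      bins=[edges, edges])
        tv = 0.5 * np.abs(p - counts / counts.sum()).sum()
        assert tv < 0.10


class TestExchange:
    def test_equal_energies_always_swap(self):
        assert exchange_probability(2.0, 300.0, 2.0, 320.0) == 1.0

    def test_equal_temperatures_always_swap(self):
        assert exchange_probability(1.0, 300.0, 5.0, 300.0) == 1.0

    def test_unit_delta_gives_inverse_e(self):
        # construct (1/kT_i - 1/kT_j) * (E_i - E_j) = -1 exactly
        t_i, t_j = 300.0, 360.0
        dbeta = 1.0 / (KB * t_i) - 1.0 / (KB * t_j)
        e_i, e_j = 0.0, 1.0 / dbeta  # E_i - E_j = -1/dbeta
        p = exchange_probability(e_i, t_i, e_j, t_j)
        assert p == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_monte_carlo_frequency_matches_probability(self):
        t_i, t_j = 300.0, 360.0
        dbeta = 1.0 / (KB * t_i) - 1.0 / (KB * t_j)
        e_i, e_j = 0.0, 1.0 / dbeta
        rng = np.random.default_rng(17)
        n = 100_000
        swaps = sum(
            exchange_attempt(0, e_i, t_i, 1, e_j, t_j, rng)[2]
            for _ in range(n)
        )
        target = np.exp(-1.0)
        se = np.sqrt(target * (1 - target) / n)
        assert abs(swaps / n - target) < 3 * se


@pytest.fixture(scope="module")
def small_run():
    spec = MODEL_PEPTIDE.with_glyco_sites(glycosylation_sites(MODEL_PEPTIDE))
    pot = TorsionPotential.for_peptide(spec)
    ladder = make_ladder(300.0, 455.95, 4)
    config = MCConfig(n_segments=400, sweeps_per_segment=5,
                      exchange_interval=5, seed=42)
    return run_remd(spec, pot, ladder, config)


class TestRunRemd:
    def test_same_seed_identical_trajectories(self, small_run):
        spec = MODEL_PEPTIDE.with_glyco_sites(
            glycosylation_sites(MODEL_PEPTIDE))
        pot = TorsionPotential.for_peptide(spec)
        again = run_remd(spec, pot, small_run.ladder, small_run.config)
        for a, b in zip(small_run.series_by_temperature,
                        again.series_by_temperature):
            assert np.array_equal(a.angles, b.angles)

    def test_single_replica_reduces_to_plain_metropolis(self):
        spec = PeptideSpec("TT")
        pot = TorsionPotential.for_peptide(spec)
        ladder = ReplicaLadder(np.array([300.0]))
        config = MCConfig(n_segments=50, sweeps_per_segment=2,
                          step_deg=40.0, exchange_interval=2, seed=9,
                          burn_in_fraction=0.0)
        run = run_remd(spec, pot, ladder, config)
        # replay: same generator, same sweep order, no exchange consumption
        rng = np.random.default_rng(9)
        state = np.tile([-75.0, 145.0], (1, 2, 1))
        energies = None
        frames = []
        for _ in range(50):
            for _ in range(2):
                state, energies, _ = mc_sweep(state, pot, [300.0], rng,
                                              step_deg=40.0,
                                              energies=energies)
            frames.append(state[0].copy())
        assert np.array_equal(run.series_by_temperature[0].angles,
                              np.array(frames))

    def test_exchange_bookkeeping_is_a_permutation(self, small_run):
        k = small_run.ladder.n_replicas
        sorted_rows = np.sort(small_run.walker_ids, axis=1)
        assert np.array_equal(sorted_rows,
                              np.tile(np.arange(k), (len(sorted_rows), 1)))

    def test_exchange_rates_in_unit_interval(self, small_run):
        rates = small_run.exchange_rates
        assert np.all(rates > 0) and np.all(rates < 1)

    def test_wider_ladder_spacing_lowers_exchange_rates(self):
        spec = MODEL_PEPTIDE
        pot = TorsionPotential.for_peptide(spec)
        config = MCConfig(n_segments=300, sweeps_per_segment=5,
                          exchange_interval=5, seed=5)
        narrow = run_remd(spec, pot, make_ladder(300.0, 360.0, 4), config)
        wide = run_remd(spec, pot, make_ladder(300.0, 2000.0, 4), config)
        assert np.nanmean(wide.exchange_rates) < \
            np.nanmean(narrow.exchange_rates)

    def test_burn_in_discards_first_half(self, small_run):
        assert small_run.series_by_temperature[0].n_frames == 200

    def test_ppii_dominant_potential_ranks_ppii_first(self, small_run):
        from ppiikit.analysis import region_populations
        table = region_populations(small_run.series_at(300.0))
        means = table.fractions.mean(axis=0)
        assert means.idxmax() == "PPII"


class TestGlycoEffect:
    def test_glyco_modifier_suppresses_alpha_r_at_sites(self):
        from ppiikit.analysis import region_populations

        spec_plain = MODEL_PEPTIDE
        spec_glyco = MODEL_PEPTIDE.with_glyco_sites(
            glycosylation_sites(MODEL_PEPTIDE))
        ladder = make_ladder(300.0, 455.95, 4)
        config = MCConfig(n_segments=4000, sweeps_per_segment=5,
                          exchange_interval=5, seed=21)
        tables = {}
        for key, spec in (("plain", spec_plain), ("glyco", spec_glyco)):
            pot = TorsionPotential.for_peptide(spec)
            run = run_remd(spec, pot, ladder, config)
            tables[key] = region_populations(run.series_at(300.0)).fractions
        sites = glycosylation_sites(MODEL_PEPTIDE)
        labels = [f"T{n}" for n in sites]
        for label in labels:
            assert tables["glyco"].loc[label, "alpha_R"] < \
                tables["plain"].loc[label, "alpha_R"]
            assert tables["glyco"].loc[label, "PPII"] > \
                tables["plain"].loc[label, "PPII"]


class TestPotential:
    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            TorsionPotential(centers=[(-75.0, 145.0)], kappa=8.0,
                             weights=[[0.0]])

    def test_energy_finite_everywhere(self):
        spec = MODEL_PEPTIDE.with_glyco_sites(
            glycosylation_sites(MODEL_PEPTIDE))
        pot = TorsionPotential.for_peptide(spec)
        rng = np.random.default_rng(0)
        phi = rng.uniform(-180, 180, size=(100, spec.n_residues))
        psi = rng.uniform(-180, 180, size=(100, spec.n_residues))
        assert np.isfinite(pot.residue_energy(phi, psi)).all()

    def test_glyco_weighting_applied_at_sites_only(self):
        spec = MODEL_PEPTIDE.with_glyco_sites(
            glycosylation_sites(MODEL_PEPTIDE))
        pot = TorsionPotential.for_peptide(spec, glyco_modifier=0.05)
        a_r = pot.basin_names.index("alpha_R")
        site_pos = [spec.position_of(n) - 1 for n in spec.glyco_sites]
        for i in range(spec.n_residues):
            if i in site_pos:
                assert pot.weights[i, a_r] == pytest.approx(0.2 * 0.05)
            else:
                assert pot.weights[i, a_r] == pytest.approx(0.2)

    def test_coupled_potential_sweep_runs(self):
        spec = PeptideSpec("TTTT")
        pot = TorsionPotential.for_peptide(spec, coupling=0.5)
        rng = np.random.default_rng(4)
        state = np.tile([-75.0, 145.0], (2, 4, 1))
        new, energies, acc = mc_sweep(state, pot, [300.0, 400.0], rng,
                                      step_deg=30.0)
        assert new.shape == state.shape and 0 <= acc <= 1
        expect = pot.residue_energy(new[..., 0], new[..., 1])
        assert np.allclose(energies, expect)
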