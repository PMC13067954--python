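"""Ramachandran histograms, Boltzmann inversion, region classification,
population tables, bootstrap intervals and comparisons."""

import numpy as np
import pandas as pd
import pytest

from conftest import (
    oracle_expected_populations,
    oracle_region_masks,
    oracle_region_of,
    sticky_se,
)
from ppiikit.analysis import (
    DEFAULT_REGIONS,
    DihedralSeries,
    classify_region,
    compare_populations,
    free_energy_surface,
    population_ci,
    ramachandran_histogram,
    region_populations,
)
from ppiikit.synthetic import BASIN_NAMES, GeneratorSpec, sample_ensemble
from ppiikit.util import KB_KCAL_MOL_K as KB


def series_from_angles(angles):
    return DihedralSeries(angles=np.asarray(angles, dtype=float))


def constant_series(phi, psi, n_frames=10, n_residues=2):
    return series_from_angles(np.tile([phi, psi], (n_frames, n_residues, 1)))


class TestHistogram:
    def test_identical_observations_occupy_one_bin(self):
        hist = ramachandran_histogram(constant_series(-75.0, 145.0), 72)
        assert hist.probabilities.max() == 1.0
        assert (hist.probabilities > 0).sum() == 1

    def test_two_equally_populated_bins(self):
        angles = np.array([[[-75.0, 145.0]], [[60.0, 45.0]]])
        hist = ramachandran_histogram(series_from_angles(angles), 72)
        assert sorted(hist.probabilities[hist.probabilities > 0]) == \
            [0.5, 0.5]

    def test_uniform_angles_fill_grid_uniformly(self):
        rng = np.random.default_rng(23)
        angles = rng.uniform(-180.0, 180.0, size=(250_000, 4, 2))
        angles[angles <= -180.0] = 180.0
        hist = ramachandran_histogram(series_from_angles(angles), 72)
        n = hist.n_observations
        p0 = 1.0 / 72 ** 2
        se = np.sqrt(p0 * (1 - p0) / n)
        # a pre-chosen bin is binomial around 1/5184 ...
        assert abs(hist.probabilities[10, 20] - p0) < 3 * se
        # ... and the extreme over all 5184 bins stays within the
        # order-statistic envelope (max z for 5184 trials ~ 4.1)
        assert abs(hist.probabilities - p0).max() < 5.5 * se

    def test_empty_series_rejected(self):
        empty = DihedralSeries(angles=np.full((3, 2, 2), np.nan))
        with pytest.raises(ValueError, match="no defined"):
            ramachandran_histogram(empty)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        angles = rng.uniform(-179.0, 180.0, size=(500, 3, 2))
        hist = ramachandran_histogram(series_from_angles(angles), 36)
        assert hist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestFreeEnergySurface:
    def test_uniform_probability_gives_zero_everywhere(self):
        p = np.full((6, 6), 1.0 / 36)
        surf = free_energy_surface(p, temperature=300.0)
        assert np.allclose(surf.delta_g, 0.0, atol=1e-12)

    def test_two_state_worked_example(self):
        # dG = -kB * 300 * ln(0.2 / 0.8) = 0.826 kcal/mol
        surf = free_energy_surface(np.array([[0.8, 0.2]]), temperature=300.0)
        assert surf.delta_g[0, 0] == 0.0
        assert surf.delta_g[0, 1] == pytest.approx(0.826, abs=5e-4)
        assert surf.delta_g[0, 1] == pytest.approx(
            -KB * 300.0 * np.log(0.2 / 0.8), abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            free_energy_surface(np.array([[0.4, 0.1]]), temperature=300.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            free_energy_surface(np.array([[0.5, 0.5]]), temperature=0.0)

    def test_empty_bins_are_undefined_not_zero(self):
        surf = free_energy_surface(np.array([[0.7, 0.3, 0.0]]),
                                   temperature=300.0)
        assert np.isnan(surf.delta_g[0, 2])
        assert np.nanmin(surf.delta_g) == 0.0

    def test_minimum_zero_at_most_populated_bin(self):
        rng = np.random.default_rng(8)
        p = rng.random((10, 10))
        p /= p.sum()
        surf = free_energy_surface(p, temperature=300.0)
        assert surf.delta_g[surf.max_bin] == 0.0
        assert np.nanmin(surf.delta_g) == 0.0
        assert np.all(surf.delta_g[np.isfinite(surf.delta_g)] >= 0.0)

    def test_temperature_scaling_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.random((20, 20))
        p[p < 0.2] = 0.0  # include empty bins
        p /= p.sum()
        g1 = free_energy_surface(p, temperature=300.0).delta_g
        g2 = free_energy_surface(p, temperature=450.0).delta_g
        mask = np.isfinite(g1)
        assert np.allclose(g2[mask], (450.0 / 300.0) * g1[mask], atol=1e-10)
        assert np.array_equal(mask, np.isfinite(g2))


class TestClassification:
    @pytest.mark.parametrize(
        "phi, psi, expected",
        [
            (-75.0, 145.0, "PPII"),
            (-60.0, -45.0, "alpha_R"),
            (150.0, 0.0, "coil"),
            (-120.0, -150.0, "beta"),  # psi lifts to 210
            (60.0, 45.0, "alpha_L"),
            (-90.0, 100.0, "coil"),  # exact boundary -> coil (strict bounds)
            (-160.0, 0.0, "coil"),
        ],
    )
    def test_known_points(self, phi, psi, expected):
        assert classify_region(phi, psi) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_region(np.nan, 0.0)

    def test_matches_independent_predicates_on_one_degree_grid(self):
        centers, oracle = oracle_region_masks(grid_step=1.0)
        ph, ps = np.meshgrid(centers, centers, indexing="ij")
        got = classify_region(ph, ps)
        assert (got == oracle).all()

    def test_named_regions_pairwise_disjoint_and_total(self):
        centers, _ = oracle_region_masks(grid_step=1.0)
        ph, ps = np.meshgrid(centers, centers, indexing="ij")
        member = DEFAULT_REGIONS.membership(ph, ps)
        stack = np.stack(list(member.values()))
        assert stack.sum(axis=0).max() <= 1  # pairwise disjoint
        # total: everything not in a named region is coil by construction
        labels = classify_region(ph, ps)
        assert set(np.unique(labels)) <= set(DEFAULT_REGIONS.names)


class TestRegionPopulations:
    def test_pure_ppii_series(self):
        table = region_populations(constant_series(-75.0, 145.0))
        assert np.allclose(table.fractions["PPII"], 1.0)

    def test_single_frame_gives_indicators(self):
        table = region_populations(constant_series(-60.0, -45.0, n_frames=1))
        assert set(table.fractions.to_numpy().ravel()) <= {0.0, 1.0}
        assert np.allclose(table.fractions["alpha_R"], 1.0)

    def test_rows_sum_to_one(self):
        spec = GeneratorSpec.uniform(5, n_frames=500, seed=3)
        series, _ = sample_ensemble(spec)
        table = region_populations(series)
        assert np.allclose(table.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_two_basin_recovery_against_quadrature(self):
        weights = {"PPII": 0.7, "beta": 0.3}
        spec = GeneratorSpec.uniform(1, weights=weights, kappa=32.0,
                                     rho=0.0, n_frames=100_000, seed=4)
        series, _ = sample_ensemble(spec)
        table = region_populations(series)
        expected = oracle_expected_populations(spec.weights[0], spec.kappa)
        for region in ("PPII", "beta"):
            se = sticky_se(expected[region], spec.n_frames, 0.0)
            assert abs(table.fractions[region].iloc[0] - expected[region]) \
                < 3 * se

    def test_permutation_invariance_over_frames(self):
        spec = GeneratorSpec.uniform(3, n_frames=400, seed=5)
        series, _ = sample_ensemble(spec)
        rng = np.random.default_rng(0)
        shuffled = DihedralSeries(
            angles=series.angles[rng.permutation(series.n_frames)],
            residue_labels=series.residue_labels)
        a = region_populations(series).fractions
        b = region_populations(shuffled).fractions
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            region_populations(
                DihedralSeries(angles=np.empty((0, 2, 2))))


class TestPopulationCI:
    def test_same_seed_identical_intervals(self):
        spec = GeneratorSpec.uniform(2, n_frames=300, seed=6)
        series, _ = sample_ensemble(spec)
        t1 = population_ci(series, n_boot=100, seed=11)
        t2 = population_ci(series, n_boot=100, seed=11)
        assert t1.ci_low.equals(t2.ci_low) and t1.ci_high.equals(t2.ci_high)

    def test_constant_series_zero_width(self):
        table = population_ci(constant_series(-75.0, 145.0, n_frames=50),
                              n_boot=100, seed=0)
        assert np.allclose(table.ci_low["PPII"], 1.0)
        assert np.allclose(table.ci_high["PPII"], 1.0)
        assert np.allclose(table.ci_low["coil"], 0.0)

    def test_intervals_bracket_point_estimate(self):
        spec = GeneratorSpec.uniform(3, n_frames=500, seed=7)
        series, _ = sample_ensemble(spec)
        table = population_ci(series, n_boot=200, seed=1)
        assert (table.ci_low.to_numpy() <= table.fractions.to_numpy()).all()
        assert (table.ci_high.to_numpy() >= table.fractions.to_numpy()).all()

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="block_length"):
            population_ci(constant_series(-75.0, 145.0, n_frames=5),
                          block_length=10)


class TestComparePopulations:
    def test_self_comparison_finds_nothing(self):
        spec = GeneratorSpec.uniform(4, n_frames=400, seed=8)
        series, _ = sample_ensemble(spec)
        table = population_ci(series, n_boot=200, seed=2)
        result = compare_populations(table, table)
        assert not result["significant"].any()
        assert np.allclose(result["difference"], 0.0)

    def test_requires_bootstrap_replicates(self):
        spec = GeneratorSpec.uniform(2, n_frames=100, seed=9)
        series, _ = sample_ensemble(spec)
        plain = region_populations(series)
        with pytest.raises(ValueError, match="bootstrap"):
            compare_populations(plain, plain)

    def test_mismatched_tables_rejected(self):
        s1, _ = sample_ensemble(GeneratorSpec.uniform(2, n_frames=100,
                                                      seed=1))
        s2, _ = sample_ensemble(GeneratorSpec.uniform(3, n_frames=100,
                                                      seed=1))
        t1 = population_ci(s1, n_boot=50, seed=0)
        t2 = population_ci(s2, n_boot=50, seed=0)
        with pytest.raises(ValueError, match="mismatched"):
            compare_populations(t1, t2)

    def test_detects_planted_difference(self):
        base = GeneratorSpec.uniform(1, weights={"PPII": 0.5, "alpha_R": 0.5},
                                     kappa=32.0, rho=0.0, n_frames=4000,
                                     seed=10)
        shifted = GeneratorSpec.uniform(
            1, weights={"PPII": 0.9, "alpha_R": 0.1}, kappa=32.0, rho=0.0,
            n_frames=4000, seed=11)
        sa, _ = sample_ensemble(base)
        sb, _ = sample_ensemble(shifted)
        ta = population_ci(sa, n_boot=300, seed=3)
        tb = population_ci(sb, n_boot=300, seed=4)
        result = compare_populations(ta, tb)
        flagged = result.loc[result["significant"], "region"].tolist()
        assert "PPII" in flagged and "alpha_R" in flagged
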