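"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately re-derive quantities by routes that do
not touch the package code paths they are used to check: region membership
is re-implemented from the printed inequalities, expected region
populations come from 2-D quadrature of the generator's mixture density,
and R_g / dihedral references use brute-force formulas.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppiikit.peptide import MODEL_PEPTIDE, glycosylation_sites


@pytest.fixture
def glyco_model_peptide():
    return MODEL_PEPTIDE.with_glyco_sites(glycosylation_sites(MODEL_PEPTIDE))


# ---------------------------------------------------------------------------
# independent region predicates (re-derived from the printed bounds, with the
# psi + 360 lift applied by brute force rather than via RegionSpec)

def oracle_region_of(phi: float, psi: float) -> str:
    def in_rect(phi, psi, plo, phi_hi, slo, shi):
        for lift in (0.0, 360.0):
            if plo < phi < phi_hi and slo < psi + lift < shi:
                return True
        return False

    if in_rect(phi, psi, -160, -20, -120, 50):
        return "alpha_R"
    if in_rect(phi, psi, -180, -90, 50, 240):
        return "beta"
    if in_rect(phi, psi, -90, 20, 50, 240):
        return "PPII"
    if in_rect(phi, psi, 30, 100, 0, 80):
        return "alpha_L"
    return "coil"


def oracle_region_masks(grid_step: float = 1.0):
    """Region masks on a grid of bin centers covering the torus."""
    centers = np.arange(-180 + grid_step / 2, 180, grid_step)
    ph, ps = np.meshgrid(centers, centers, indexing="ij")
    labels = np.vectorize(oracle_region_of)(ph, ps)
    return centers, labels


# ---------------------------------------------------------------------------
# quadrature oracle: expected region occupancies of the synthetic generator

_BASIN_CENTERS = {
    "PPII": (-75.0, 145.0),
    "alpha_R": (-60.0, -45.0),
    "beta": (-135.0, 135.0),
    "alpha_L": (60.0, 45.0),
}
_BASIN_ORDER = ("PPII", "alpha_R", "beta", "alpha_L", "coil")


def oracle_expected_populations(weights_row, kappa: float,
                                grid_step: float = 1.0) -> dict:
    """Region probabilities of the von-Mises-mixture generator, by quadrature.

    ``weights_row`` follows the generator's basin order (PPII, alpha_R,
    beta, alpha_L, coil).  Basin densities are evaluated on a regular grid
    and summed over the independently derived region masks, so leakage of
    basin mass across region boundaries is accounted for exactly (up to
    grid resolution).
    """
    centers, labels = oracle_region_masks(grid_step)
    ph, ps = np.meshgrid(centers, centers, indexing="ij")
    out = {name: 0.0 for name in ("PPII", "alpha_R", "beta", "alpha_L",
                                  "coil")}
    w = np.asarray(weights_row, dtype=float)
    w = w / w.sum()
    for b, name in enumerate(_BASIN_ORDER):
        if w[b] == 0:
            continue
        if name == "coil":
            dens = np.ones_like(ph)
        else:
            c_phi, c_psi = _BASIN_CENTERS[name]
            dens = np.exp(
                kappa * (np.cos(np.deg2rad(ph - c_phi))
                         + np.cos(np.deg2rad(ps - c_psi)))
            )
        dens = dens / dens.sum()
        for region in out:
            out[region] += w[b] * dens[labels == region].sum()
    return out


def sticky_se(p: float, n: int, rho: float) -> float:
    """Standard error of a mean of sticky-Markov indicators (lag-1 corr rho)."""
    return np.sqrt(p * (1 - p) / n * (1 + rho) / (1 - rho))


# ---------------------------------------------------------------------------
# brute-force geometry references

def brute_force_rg(xyz: np.ndarray, masses: np.ndarray) -> float:
    """Double-loop-free but literal evaluation of the R_g definition."""
    m = np.asarray(masses, dtype=float)
    com = np.zeros(3)
    for i in range(len(m)):
        com += m[i] * xyz[i]
    com /= m.sum()
    acc = 0.0
    for i in range(len(m)):
        acc += m[i] * np.dot(xyz[i] - com, xyz[i] - com)
    return float(np.sqrt(acc / m.sum()))
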