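"""Ramachandran analytics for dihedral ensembles.

Given per-frame, per-residue (phi, psi) series this module computes
2-D probability histograms over the torus, Boltzmann-inversion free-energy
surfaces dG = -kB T ln(P/Pmax), dihedral-based secondary-structure region
classification (alpha_R / beta / PPII / alpha_L / coil), per-residue region
populations with moving-block-bootstrap confidence intervals, and paired
glyco/non-glyco population comparisons.

Region bounds follow the literature convention used for mucin peptides:

* alpha_R: -160 < phi < -20 and -120 < psi < 50
* beta:    -180 < phi < -90 and   50 < psi < 240
* PPII:     -90 < phi <  20 and   50 < psi < 240
* alpha_L:   30 < phi < 100 and    0 < psi < 80
* coil: everything else

The beta/PPII psi upper bound of 240 exceeds the principal domain; psi
values below -120 are lifted by +360 before testing, so e.g. psi = -150
tests as 210.  Inequalities are strict: exact boundary values classify as
coil (a zero-measure set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import KB_KCAL_MOL_K


@dataclass(frozen=True)
class DihedralSeries:
    """Per-frame, per-residue (phi, psi) torsions in degrees on (-180, 180].

    ``angles`` has shape (n_frames, n_residues, 2).  NaN entries are allowed
    only as flagged terminal residues (undefined phi/psi); analytics skip
    them rather than impute.
    """

    angles: np.ndarray
    residue_labels: tuple = ()
    temperature: float | None = None
    source: str = ""

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 3 or a.shape[-1] != 2:
            raise ValueError("angles must have shape (frames, residues, 2)")
        finite = a[np.isfinite(a)]
        if finite.size and (finite.max() > 180.0 or finite.min() <= -180.0):
            raise ValueError("angles must lie in (-180, 180]")
        object.__setattr__(self, "angles", a)
        labels = tuple(self.residue_labels) if len(self.residue_labels) else \
            tuple(str(i + 1) for i in range(a.shape[1]))
        if len(labels) != a.shape[1]:
            raise ValueError("residue_labels length mismatch")
        object.__setattr__(self, "residue_labels", labels)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_residues(self) -> int:
        return self.angles.shape[1]


_DEFAULT_BOUNDS = {
    # name: (phi_lo, phi_hi, psi_lo, psi_hi), strict inequalities
    "alpha_R": (-160.0, -20.0, -120.0, 50.0),
    "beta": (-180.0, -90.0, 50.0, 240.0),
    "PPII": (-90.0, 20.0, 50.0, 240.0),
    "alpha_L": (30.0, 100.0, 0.0, 80.0),
}


@dataclass(frozen=True)
class RegionSpec:
    """Named rectangular (phi, psi) regions plus the coil complement."""

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    coil_label: str = "coil"

    @property
    def names(self) -> tuple:
        return tuple(self.bounds) + (self.coil_label,)

    def membership(self, phi, psi) -> dict:
        """Boolean membership arrays per named region (coil excluded)."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        out = {}
        for name, (plo, phi_hi, slo, shi) in self.bounds.items():
            psi_t = psi
            if shi > 180.0:
                # lift rule: psi below (shi - 360) tests 360 higher
                psi_t = np.where(psi < shi - 360.0, psi + 360.0, psi)
            out[name] = (
                (phi > plo) & (phi < phi_hi) & (psi_t > slo) & (psi_t < shi)
            )
        return out


DEFAULT_REGIONS = RegionSpec()


def classify_region(phi, psi, regions: RegionSpec = DEFAULT_REGIONS):
    """Classify (phi, psi) into a secondary-structure region label.

    Accepts scalars or arrays (broadcast together); returns a label or a
    string array.  Classification is total: anything outside the named
    regions is coil.  Non-finite angles are rejected.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not (np.isfinite(phi).all() and np.isfinite(psi).all()):
        raise ValueError("phi/psi must be finite")
    member = regions.membership(phi, psi)
    labels = np.full(np.broadcast(phi, psi).shape, regions.coil_label,
                     dtype=object)
    for name, mask in member.items():
        labels[mask] = name
    if labels.ndim == 0:
        return str(labels[()])
    return labels


def region_indicators(series: DihedralSeries,
                      regions: RegionSpec = DEFAULT_REGIONS) -> np.ndarray:
    """(frames, residues, regions) float indicators; NaN for undefined angles."""
    phi = series.angles[..., 0]
    psi = series.angles[..., 1]
    defined = np.isfinite(phi) & np.isfinite(psi)
    member = regions.membership(np.where(defined, phi, 0.0),
                                np.where(defined, psi, 0.0))
    named = np.stack([member[name] for name in regions.bounds], axis=-1)
    coil = defined & ~named.any(axis=-1)
    ind = np.concatenate([named, coil[..., None]], axis=-1).astype(float)
    ind[~defined] = np.nan
    return ind


@dataclass(frozen=True)
class RamachandranHistogram:
    """Normalized 2-D probability histogram over the torus."""

    probabilities: np.ndarray
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    n_observations: int


def ramachandran_histogram(series: DihedralSeries,
                           bins_per_axis: int = 72) -> RamachandranHistogram:
    """Pool all residues and frames into a normalized (phi, psi) histogram.

    The grid is regular over (-180, 180] on both axes.  Undefined (NaN)
    terminal angles are dropped.  At least one defined observation is
    required.
    """
    phi = series.angles[..., 0].ravel()
    psi = series.angles[..., 1].ravel()
    ok = np.isfinite(phi) & np.isfinite(psi)
    phi, psi = phi[ok], psi[ok]
    if phi.size == 0:
        raise ValueError("series contains no defined (phi, psi) observations")
    counts, phi_edges, psi_edges = np.histogram2d(
        phi, psi, bins=bins_per_axis, range=[[-180.0, 180.0], [-180.0, 180.0]]
    )
    return RamachandranHistogram(
        probabilities=counts / counts.sum(),
        phi_edges=phi_edges,
        psi_edges=psi_edges,
        n_observations=int(phi.size),
    )


@dataclass(frozen=True)
class FreeEnergySurface:
    """Boltzmann-inverted free-energy grid dG = -kB T ln(P/Pmax), kcal/mol.

    ``delta_g`` is NaN on empty bins (undefined, not infinite); its minimum
    over defined bins is exactly 0, attained at the most populated bin.
    """

    probabilities: np.ndarray
    delta_g: np.ndarray
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    temperature: float
    k_b: float
    max_bin: tuple

    def argmin_center(self) -> tuple:
        """(phi, psi) center of the global free-energy-minimum bin."""
        i, j = self.max_bin
        phi = 0.5 * (self.phi_edges[i] + self.phi_edges[i + 1])
        psi = 0.5 * (self.psi_edges[j] + self.psi_edges[j + 1])
        return float(phi), float(psi)

    def argmin_region(self, regions: RegionSpec = DEFAULT_REGIONS) -> str:
        return classify_region(*self.argmin_center(), regions=regions)


def free_energy_surface(histogram, temperature: float,
                        k_b: float = KB_KCAL_MOL_K) -> FreeEnergySurface:
    """Invert a probability histogram into a relative free-energy surface.

    ``histogram`` is a :class:`RamachandranHistogram` or a normalized
    probability grid (sum 1 within 1e-9; anything else is rejected).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(histogram, RamachandranHistogram):
        p = histogram.probabilities
        phi_edges, psi_edges = histogram.phi_edges, histogram.psi_edges
    else:
        p = np.asarray(histogram, dtype=float)
        phi_edges = np.linspace(-180.0, 180.0, p.shape[0] + 1)
        psi_edges = np.linspace(-180.0, 180.0, p.shape[-1] + 1) \
            if p.ndim > 1 else np.array([])
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be normalized to sum 1")
    p_max = p.max()
    max_bin = np.unravel_index(int(np.argmax(p)), p.shape)
    with np.errstate(divide="ignore"):
        dg = np.where(p > 0, -k_b * temperature * np.log(p / p_max), np.nan)
    return FreeEnergySurface(
        probabilities=p, delta_g=dg, phi_edges=np.asarray(phi_edges),
        psi_edges=np.asarray(psi_edges), temperature=float(temperature),
        k_b=float(k_b), max_bin=tuple(int(k) for k in max_bin),
    )


@dataclass(frozen=True)
class RegionPopulationTable:
    """Per-residue secondary-structure occupancy fractions (+ optional CIs).

    ``fractions`` is a residues x regions DataFrame whose rows sum to 1.
    When produced by :func:`population_ci` the table also carries percentile
    interval bounds and the raw bootstrap replicates (n_boot x residues x
    regions), which :func:`compare_populations` consumes.
    """

    fractions: pd.DataFrame
    n_frames: int
    level: float | None = None
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None
    bootstrap: np.ndarray | None = None
    block_length: int | None = None

    @property
    def regions(self) -> tuple:
        return tuple(self.fractions.columns)

    @property
    def residues(self) -> tuple:
        return tuple(self.fractions.index)


def region_populations(series: DihedralSeries,
                       regions: RegionSpec = DEFAULT_REGIONS
                       ) -> RegionPopulationTable:
    """Fraction of frames each residue spends in each region.

    Undefined terminal angles are excluded per residue; fractions are over
    that residue's defined frames and sum to 1.
    """
    if series.n_frames == 0:
        raise ValueError("series has no frames")
    ind = region_indicators(series, regions)
    with np.errstate(invalid="ignore"):
        frac = np.nanmean(ind, axis=0)
    table = pd.DataFrame(frac, index=list(series.residue_labels),
                         columns=list(regions.names))
    return RegionPopulationTable(fractions=table, n_frames=series.n_frames)


def moving_block_indices(n: int, block_length: int, rng) -> np.ndarray:
    """One moving-block bootstrap resample of frame indices 0..n-1."""
    n_blocks = -(-n // block_length)
    starts = rng.integers(0, n - block_length + 1, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()
    return idx[:n]


def default_block_length(n_frames: int) -> int:
    return int(np.ceil(n_frames ** (1.0 / 3.0)))


def population_ci(series: DihedralSeries,
                  regions: RegionSpec = DEFAULT_REGIONS,
                  level: float = 0.95,
                  block_length: int | None = None,
                  n_boot: int = 1000,
                  seed=None) -> RegionPopulationTable:
    """Region populations with moving-block-bootstrap percentile intervals.

    Contiguous blocks of frames are resampled so that temporal
    autocorrelation of the trajectory is preserved in the interval.  Block
    length defaults to ceil(n_frames^(1/3)).
    """
    if block_length is None:
        block_length = default_block_length(series.n_frames)
    if series.n_frames < 2 * block_length:
        raise ValueError("need at least 2 * block_length frames")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ind = region_indicators(series, regions)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot,) + ind.shape[1:], dtype=float)
    for b in range(n_boot):
        idx = moving_block_indices(series.n_frames, block_length, rng)
        with np.errstate(invalid="ignore"):
            boot[b] = np.nanmean(ind[idx], axis=0)
    alpha = 1.0 - level
    lo = np.nanquantile(boot, alpha / 2, axis=0)
    hi = np.nanquantile(boot, 1 - alpha / 2, axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.nanmean(ind, axis=0)
    labels = list(series.residue_labels)
    cols = list(regions.names)
    # percentile intervals are clipped to bracket the point estimate
    lo = np.minimum(lo, frac)
    hi = np.maximum(hi, frac)
    return RegionPopulationTable(
        fractions=pd.DataFrame(frac, index=labels, columns=cols),
        n_frames=series.n_frames, level=level,
        ci_low=pd.DataFrame(lo, index=labels, columns=cols),
        ci_high=pd.DataFrame(hi, index=labels, columns=cols),
        bootstrap=boot, block_length=block_length,
    )


def compare_populations(table_a: RegionPopulationTable,
                        table_b: RegionPopulationTable,
                        alpha: float = 0.05,
                        min_effect: float = 0.05) -> pd.DataFrame:
    """Bootstrap difference-of-fractions test between two population tables.

    Both tables must come from :func:`population_ci` (they carry bootstrap
    replicates) with matching residues and regions.  For each residue x
    region the difference (b - a) receives an *expanded-percentile*
    interval from independently paired bootstrap draws: the percentile
    level is widened by the Hesterberg small-sample calibration
    (t-quantile on the effective number of resampled blocks), which fixes
    the anticonservatism of the plain percentile interval at small frame
    counts and converges to it for long trajectories.  The difference is
    flagged significant when that interval excludes 0 at level ``alpha``
    *and* the point difference exceeds ``min_effect`` in absolute value
    (practical significance; set ``min_effect=0`` for a purely statistical
    flag).

    Returns a tidy DataFrame with columns residue, region, fraction_a,
    fraction_b, difference, ci_low, ci_high, significant.
    """
    from scipy import stats

    if table_a.bootstrap is None or table_b.bootstrap is None:
        raise ValueError("tables must carry bootstrap replicates "
                         "(use population_ci)")
    if table_a.residues != table_b.residues or table_a.regions != table_b.regions:
        raise ValueError("tables have mismatched residues or regions")
    n = min(table_a.bootstrap.shape[0], table_b.bootstrap.shape[0])
    diff_boot = table_b.bootstrap[:n] - table_a.bootstrap[:n]
    per_table = [max(t.n_frames // t.block_length, 2)
                 for t in (table_a, table_b) if t.block_length]
    n_units = min(per_table) if per_table else 10 ** 6
    df = max(n_units - 1, 1)
    z = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(n_units / df)
    alpha_adj = float(2 * stats.norm.cdf(-z))
    lo = np.nanquantile(diff_boot, alpha_adj / 2, axis=0)
    hi = np.nanquantile(diff_boot, 1 - alpha_adj / 2, axis=0)
    diff = table_b.fractions.to_numpy() - table_a.fractions.to_numpy()
    significant = ((lo > 0) | (hi < 0)) & (np.abs(diff) > min_effect)
    rows = []
    for i, res in enumerate(table_a.residues):
        for j, reg in enumerate(table_a.regions):
            rows.append({
                "residue": res, "region": reg,
                "fraction_a": table_a.fractions.iloc[i, j],
                "fraction_b": table_b.fractions.iloc[i, j],
                "difference": diff[i, j],
                "ci_low": lo[i, j], "ci_high": hi[i, j],
                "significant": bool(significant[i, j]),
            })
    return pd.DataFrame(rows)
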