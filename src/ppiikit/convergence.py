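"""Sampling-convergence diagnostics based on the radius of gyration.

A converged trajectory should give the same distribution of a global
observable over independent time intervals.  The diagnostic implemented
here: compute the per-frame radius of gyration

    R_g = sqrt( (1/M) * sum_i m_i * |r_i - R|^2 )

(M total mass, R the center of mass), split the post-burn-in window into
two equal contiguous halves, histogram both on 50 shared bins, and report
the overlap coefficient sum_bins min(p, q).  Overlap of at least 90% counts
as converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RgSeries:
    """Per-frame radius of gyration in Angstrom."""

    values: np.ndarray
    mass_convention: str = "equal"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.isfinite(v).all() or np.any(v < 0):
            raise ValueError("R_g values must be a finite nonnegative 1-D array")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.size


def radius_of_gyration(coordinates, masses=None) -> RgSeries:
    """Mass-weighted RMS distance from the center of mass, per frame.

    ``coordinates`` has shape (n_frames, n_atoms, 3) (a single frame
    (n_atoms, 3) is promoted) in Angstrom.  ``masses`` defaults to equal
    masses — the convention for backbone-only toy trajectories; pass
    per-atom masses for real all-atom coordinates.
    """
    xyz = np.asarray(coordinates, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    if xyz.ndim != 3 or xyz.shape[-1] != 3 or xyz.shape[1] < 1:
        raise ValueError("coordinates must have shape (frames, atoms, 3)")
    if masses is None:
        m = np.ones(xyz.shape[1])
        convention = "equal"
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (xyz.shape[1],) or np.any(m <= 0):
            raise ValueError("masses must be positive, one per atom")
        convention = "per-atom"
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[None, :, None] * xyz).sum(axis=1) / total
    sq = np.sum((xyz - com[:, None, :]) ** 2, axis=-1)
    rg = np.sqrt((m[None, :] * sq).sum(axis=1) / total)
    return RgSeries(values=rg, mass_convention=convention)


def split_halves(series):
    """Split a series into two equal contiguous halves (first gets n//2).

    Accepts an :class:`RgSeries` or a 1-D array; requires at least 4 frames.
    For an odd count the second half keeps the extra frame.
    """
    values = series.values if isinstance(series, RgSeries) else \
        np.asarray(series, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 frames to split")
    half = n // 2
    return values[:half], values[half:]


@dataclass(frozen=True)
class OverlapReport:
    """Histogram-overlap convergence verdict."""

    overlap: float
    n_bins: int
    bin_edges: np.ndarray
    threshold: float
    passed: bool


def histogram_overlap(a, b, n_bins: int = 50) -> float:
    """Overlap coefficient sum_bins min(p, q) of two samples.

    Both histograms share ``n_bins`` equal-width bins spanning the pooled
    range of the two samples; each is normalized to sum 1.  Returns a value
    in [0, 1]: 1 for identical samples, 0 for disjoint supports.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all values identical: total overlap by convention
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())


def convergence_check(series, n_bins: int = 50,
                      threshold: float = 0.90) -> OverlapReport:
    """Split-halves histogram-overlap convergence verdict for an R_g series.

    Pass iff overlap >= threshold (boundary counts as pass).
    """
    first, second = split_halves(series)
    values = series.values if isinstance(series, RgSeries) else \
        np.asarray(series, dtype=float)
    lo, hi = values.min(), values.max()
    overlap = histogram_overlap(first, second, n_bins=n_bins)
    edges = np.linspace(lo, hi, n_bins + 1) if lo < hi else np.array([lo, hi])
    return OverlapReport(overlap=overlap, n_bins=n_bins, bin_edges=edges,
                         threshold=threshold, passed=overlap >= threshold)
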