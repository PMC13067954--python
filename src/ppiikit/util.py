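"""Shared numerical helpers: angle wrapping, dihedrals, physical constants."""

from __future__ import annotations

import numpy as np

#: Boltzmann constant in kcal/(mol*K); free energies throughout are kcal/mol.
KB_KCAL_MOL_K = 0.0019872041


def wrap_angle(angle):
    """Wrap angles in degrees onto the periodic interval (-180, 180].

    Accepts scalars or arrays. 180 and -180 both map to +180 so that the
    domain is half-open, matching how dihedral series are stored.
    """
    a = np.asarray(angle, dtype=float)
    wrapped = -(((-a + 180.0) % 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def dihedral(p0, p1, p2, p3, degrees: bool = True):
    """Signed torsion angle of the four points, IUPAC sign convention.

    Points may carry arbitrary leading batch dimensions with trailing axis 3.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.arctan2(-y, x)
    if degrees:
        ang = np.degrees(ang)
    return ang if np.ndim(ang) else float(ang)


def angle_between(a, b, c, degrees: bool = True):
    """Bond angle a-b-c (vertex at b), batched like :func:`dihedral`."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    if degrees:
        ang = np.degrees(ang)
    return ang if np.ndim(ang) else float(ang)
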