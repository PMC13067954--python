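"""Mucin-domain peptide specifications and idealized backbone geometry.

Lubricin's central mucin domain is built from KEPAPTTP tandem repeats (with
occasional variants such as KEPAPTTT) that are densely O-glycosylated on
threonines.  This module represents such peptides (sequence, residue
numbering, glycosylation sites), counts repeat motifs and PPII-prone
residues, and constructs idealized N/CA/C backbone coordinates from
per-residue (phi, psi) torsions so that helical parameters (residues per
turn, rise, handedness) can be measured on them.

Only backbone heavy atoms are built.  Glycans and side chains are carried as
annotations, never as 3-D atoms; their conformational effect enters through
the sampler's potential instead.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .util import dihedral, wrap_angle

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Repeat motifs of the lubricin mucin domain: the canonical tandem repeat
#: and its most common single-residue variant.
REPEAT_MOTIFS = ("KEPAPTTP", "KEPAPTTT")

#: Residues with high intrinsic polyproline-II propensity.
HIGH_PPII_PROPENSITY = frozenset("PAK")


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, letter in enumerate(sequence):
        if letter not in AA_LETTERS:
            raise ValueError(
                f"invalid residue letter {letter!r} at position {i + 1}"
            )


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide with biological numbering and O-glycosylation annotations.

    Residue ``first_residue_number + k - 1`` is the k-th letter of
    ``sequence`` (1-based k).  ``glyco_sites`` holds residue *numbers* (not
    positions) carrying an O-linked GalNAc-Gal disaccharide; each must be a
    threonine or serine.
    """

    sequence: str
    first_residue_number: int = 1
    glyco_sites: frozenset = field(default_factory=frozenset)
    name: str = ""

    def __post_init__(self):
        _validate_sequence(self.sequence)
        object.__setattr__(self, "glyco_sites", frozenset(self.glyco_sites))
        for number in self.glyco_sites:
            letter = self.residue(number)
            if letter not in ("T", "S"):
                raise ValueError(
                    f"glyco site {number} is {letter}, not Thr/Ser"
                )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def residue_numbers(self) -> np.ndarray:
        start = self.first_residue_number
        return np.arange(start, start + self.n_residues)

    def residue(self, number: int) -> str:
        pos = number - self.first_residue_number
        if not 0 <= pos < self.n_residues:
            raise KeyError(f"residue number {number} outside peptide")
        return self.sequence[pos]

    def position_of(self, number: int) -> int:
        """1-based sequence position of a residue number."""
        self.residue(number)
        return number - self.first_residue_number + 1

    def with_glyco_sites(self, sites) -> "PeptideSpec":
        return replace(self, glyco_sites=frozenset(sites))


#: The modeled mucin-domain subsection, lubricin residues 393-410, spanning
#: one KEPAPTTP repeat and the common KEPAPTTT variant.
MODEL_PEPTIDE = PeptideSpec(
    sequence="PKEPAPTTTKEPAPTTPK",
    first_residue_number=393,
    name="lubricin mucin-domain model peptide (393-410)",
)

#: Threonine tetrapeptide used to probe threonine's intrinsic PPII propensity.
TETRAPEPTIDE = PeptideSpec(sequence="TTTT", first_residue_number=1,
                           name="threonine tetrapeptide")


def annotate_repeats(spec: PeptideSpec):
    """Locate mucin-domain repeat motifs, left to right, non-overlapping.

    Returns a list of ``(motif, start_position)`` with 1-based sequence
    positions.  Both the canonical KEPAPTTP repeat and the KEPAPTTT variant
    are matched; the leftmost match wins and occurrences never overlap.
    """
    pattern = re.compile("|".join(re.escape(m) for m in REPEAT_MOTIFS))
    return [(m.group(0), m.start() + 1) for m in pattern.finditer(spec.sequence)]


def ppii_propensity_count(sequence: str, high_set=HIGH_PPII_PROPENSITY) -> int:
    """Number of residues with high PPII propensity (default Pro/Ala/Lys)."""
    if sequence:
        _validate_sequence(sequence)
    high = frozenset(high_set)
    return sum(1 for letter in sequence if letter in high)


def glycosylation_sites(spec: PeptideSpec,
                        excluded_residue_numbers=frozenset({401})):
    """Threonine residue numbers eligible for O-glycosylation, ascending.

    By default residue 401 is excluded: lubricin's Thr401 (the third
    threonine of the model peptide) carries no glycan in vivo, so only the
    other four model-peptide threonines are glycosylated.  Excluded numbers
    that are not threonines trigger a warning and are ignored.
    """
    excluded = set(excluded_residue_numbers)
    thr = [int(n) for n in spec.residue_numbers if spec.residue(int(n)) == "T"]
    for number in sorted(excluded):
        try:
            letter = spec.residue(number)
        except KeyError:
            letter = None
        if letter != "T":
            warnings.warn(
                f"excluded residue {number} is not a threonine; ignored",
                stacklevel=2,
            )
    return [n for n in thr if n not in excluded]


def glycosylated_model_peptide() -> PeptideSpec:
    """The model peptide with its four in-vivo glycosylation sites attached."""
    return MODEL_PEPTIDE.with_glyco_sites(glycosylation_sites(MODEL_PEPTIDE))


@dataclass(frozen=True)
class BackboneGeometry:
    """Fixed internal coordinates of an idealized peptide backbone.

    Standard lengths/angles (Engh-Huber-style averages); the trans peptide
    bond (omega = 180) is the default.  All lengths in Angstrom, angles in
    degrees.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    angle_n_ca_c: float = 111.0
    angle_ca_c_n: float = 116.6
    angle_c_n_ca: float = 121.7
    omega: float = 180.0

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca"):
            if not 0 < getattr(self, name) < 180:
                raise ValueError(f"bond angle {name} must lie in (0, 180)")


@dataclass(frozen=True)
class BackboneConformation:
    """Built backbone: input torsions plus derived N/CA/C coordinates.

    ``coords`` has shape (n_residues, 3, 3): per residue the N, CA, C
    positions in Angstrom.  phi of the first residue and psi of the last are
    geometrically undefined; ``phi_defined``/``psi_defined`` flag them.
    """

    phi_psi: np.ndarray
    coords: np.ndarray
    geometry: BackboneGeometry
    sequence: str | None = None

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def phi_defined(self) -> np.ndarray:
        mask = np.ones(self.n_residues, dtype=bool)
        mask[0] = False
        return mask

    @property
    def psi_defined(self) -> np.ndarray:
        mask = np.ones(self.n_residues, dtype=bool)
        mask[-1] = False
        return mask

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[:, 1, :]


def _place_atom(a, b, c, bond_length, bond_angle_deg, torsion_deg):
    """NeRF placement of atom D from the three preceding atoms.

    D is set at distance ``bond_length`` from C, with bond angle B-C-D and
    torsion A-B-C-D as given.  Batched over leading dimensions.
    """
    theta = np.deg2rad(bond_angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc_u = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc_u)
    n_u = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m_u = np.cross(n_u, bc_u)
    # local displacement in the (bc, m, n) frame
    d_local = np.stack(
        [
            -np.cos(theta) * np.ones_like(chi),
            np.sin(theta) * np.cos(chi),
            np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    ) * bond_length
    return c + (
        d_local[..., 0:1] * bc_u + d_local[..., 1:2] * m_u + d_local[..., 2:3] * n_u
    )


def build_backbone_batch(phi_psi: np.ndarray,
                         geometry: BackboneGeometry = BackboneGeometry()
                         ) -> np.ndarray:
    """Build N/CA/C coordinates for many conformations at once.

    ``phi_psi`` has shape (..., n_residues, 2) in degrees; the returned array
    has shape (..., n_residues, 3, 3).  phi of residue 1 and psi of the last
    residue are ignored (undefined); NaN is tolerated there and only there.
    """
    angles = np.asarray(phi_psi, dtype=float)
    if angles.shape[-1] != 2 or angles.ndim < 2:
        raise ValueError("phi_psi must have shape (..., n_residues, 2)")
    n_res = angles.shape[-2]
    if n_res < 2:
        raise ValueError("chain must contain at least 2 residues")
    interior = angles.copy()
    interior[..., 0, 0] = 0.0  # undefined phi_1, value irrelevant
    interior[..., -1, 1] = 0.0  # undefined psi_n, value irrelevant
    if not np.isfinite(interior).all():
        raise ValueError("phi/psi angles must be finite where defined")

    batch = angles.shape[:-2]
    coords = np.empty(batch + (n_res, 3, 3), dtype=float)
    theta1 = np.deg2rad(geometry.angle_n_ca_c)
    coords[..., 0, 0, :] = 0.0
    coords[..., 0, 1, :] = np.array([geometry.n_ca, 0.0, 0.0])
    coords[..., 0, 2, :] = coords[..., 0, 1, :] + geometry.ca_c * np.array(
        [-np.cos(theta1), np.sin(theta1), 0.0]
    )
    omega = np.broadcast_to(geometry.omega, batch)
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = (coords[..., i - 1, k, :] for k in range(3))
        psi_prev = interior[..., i - 1, 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev,
                          geometry.c_n, geometry.angle_ca_c_n, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i,
                           geometry.n_ca, geometry.angle_c_n_ca, omega)
        c_i = _place_atom(c_prev, n_i, ca_i,
                          geometry.ca_c, geometry.angle_n_ca_c,
                          interior[..., i, 0])
        coords[..., i, 0, :] = n_i
        coords[..., i, 1, :] = ca_i
        coords[..., i, 2, :] = c_i
    return coords


def build_backbone(sequence_or_length, phi_psi,
                   geometry: BackboneGeometry = BackboneGeometry()
                   ) -> BackboneConformation:
    """Build a single idealized backbone from per-residue (phi, psi).

    ``sequence_or_length`` may be a one-letter sequence (validated) or an
    integer residue count.  Torsions are degrees, wrapped internally to
    (-180, 180].
    """
    if isinstance(sequence_or_length, str):
        _validate_sequence(sequence_or_length)
        sequence = sequence_or_length
        n_res = len(sequence)
    else:
        sequence = None
        n_res = int(sequence_or_length)
    angles = np.asarray(phi_psi, dtype=float)
    if angles.shape != (n_res, 2):
        raise ValueError(
            f"phi_psi shape {angles.shape} does not match {n_res} residues"
        )
    defined = np.isfinite(angles)
    defined_required = np.ones_like(defined)
    defined_required[0, 0] = defined_required[-1, 1] = False
    if not defined[defined_required].all():
        raise ValueError("phi/psi angles must be finite where defined")
    wrapped = angles.copy()
    wrapped[defined] = wrap_angle(angles[defined])
    coords = build_backbone_batch(wrapped, geometry)
    stored = wrapped.copy()
    stored[0, 0] = np.nan
    stored[-1, 1] = np.nan
    return BackboneConformation(phi_psi=stored, coords=coords,
                                geometry=geometry, sequence=sequence)


def extract_dihedrals(coords: np.ndarray):
    """Recompute (phi, psi) from N/CA/C coordinates.

    ``coords`` has shape (..., n_residues, 3, 3).  Returns an array shaped
    (..., n_residues, 2) in degrees with NaN where the torsion is undefined
    (phi of the first residue, psi of the last).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords[..., :, 0, :]
    ca = coords[..., :, 1, :]
    c = coords[..., :, 2, :]
    out = np.full(coords.shape[:-2] + (2,), np.nan)
    # phi_i = C(i-1) - N(i) - CA(i) - C(i)
    out[..., 1:, 0] = dihedral(c[..., :-1, :], n[..., 1:, :],
                               ca[..., 1:, :], c[..., 1:, :])
    # psi_i = N(i) - CA(i) - C(i) - N(i+1)
    out[..., :-1, 1] = dihedral(n[..., :-1, :], ca[..., :-1, :],
                                c[..., :-1, :], n[..., 1:, :])
    return out


@dataclass(frozen=True)
class HelixParameters:
    """Screw parameters of a uniform backbone helix."""

    residues_per_turn: float
    rise_per_residue: float
    handedness: str  # "left" or "right"
    twist_deg: float  # signed twist about the advancing axis


def helix_parameters(conf: BackboneConformation,
                     uniform_tol: float = 1e-6) -> HelixParameters:
    """Fit the helical screw of a uniform-(phi,psi) backbone.

    Successive residues of a uniform chain are related by one rigid screw
    transform; it is recovered by Kabsch superposition of consecutive
    N/CA/C triads.  Residues per turn is 360 over the screw twist; the
    handedness follows the right-hand rule about the axis of advance
    (positive twist while advancing = right-handed).
    """
    n_res = conf.n_residues
    if n_res < 6:
        raise ValueError("helix fit requires at least 6 residues")
    phi = conf.phi_psi[1:, 0]
    psi = conf.phi_psi[:-1, 1]
    if np.ptp(phi) > uniform_tol or np.ptp(psi) > uniform_tol:
        raise ValueError("helix fit requires a uniform (phi, psi) chain")

    twists = []
    rises = []
    turns = []
    for i in range(n_res - 1):
        src = conf.coords[i]
        dst = conf.coords[i + 1]
        src_c = src - src.mean(axis=0)
        dst_c = dst - dst.mean(axis=0)
        rot, _ = Rotation.align_vectors(dst_c, src_c)
        shift = dst.mean(axis=0) - rot.apply(src.mean(axis=0))
        rotvec = rot.as_rotvec()
        angle = np.linalg.norm(rotvec)
        axis = rotvec / angle
        rise = float(shift @ axis)
        signed = np.degrees(angle)
        if rise < 0:  # orient the axis along the direction of advance
            rise, signed = -rise, -signed
        twists.append(signed)
        rises.append(rise)
        turns.append(360.0 / np.degrees(angle))
    twist = float(np.mean(twists))
    return HelixParameters(
        residues_per_turn=float(np.mean(turns)),
        rise_per_residue=float(np.mean(rises)),
        handedness="right" if twist > 0 else "left",
        twist_deg=twist,
    )
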