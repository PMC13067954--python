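"""File formats: dihedral CSV, multi-model backbone PDB, run configs.

Interchange conventions: angles are degrees on (-180, 180] everywhere on
disk; residue columns are 1-based sequence positions (biological numbering
is recovered by adding ``first_residue_number - 1``); trajectories are
multi-model PDB files with N/CA/C ATOM records inside MODEL/ENDMDL frames
(read and written through biotite).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .analysis import DihedralSeries
from .peptide import BackboneConformation, extract_dihedrals
from .util import wrap_angle

DIHEDRAL_COLUMNS = ("frame", "residue", "phi", "psi")


def write_dihedral_csv(series: DihedralSeries, path,
                       energies=None) -> None:
    """Write a dihedral series as tidy CSV (frame, residue, phi, psi[, energy]).

    Frames and residues are 1-based; undefined terminal angles are written
    as empty fields.
    """
    n_f, n_r = series.n_frames, series.n_residues
    frame = np.repeat(np.arange(1, n_f + 1), n_r)
    residue = np.tile(np.arange(1, n_r + 1), n_f)
    data = {
        "frame": frame,
        "residue": residue,
        "phi": series.angles[..., 0].ravel(),
        "psi": series.angles[..., 1].ravel(),
    }
    if energies is not None:
        data["energy"] = np.repeat(np.asarray(energies, dtype=float), n_r)
    pd.DataFrame(data).to_csv(path, index=False)


def read_dihedral_csv(path, strict: bool = True,
                      temperature=None) -> DihedralSeries:
    """Read a tidy dihedral CSV back into a :class:`DihedralSeries`.

    In strict mode (default) angles outside (-180, 180] are rejected with
    the offending line number; in lenient mode they are wrapped with a
    warning.  Missing phi/psi fields become flagged NaN entries.
    """
    path = Path(path)
    try:
        frame_df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty dihedral CSV") from None
    missing = [c for c in DIHEDRAL_COLUMNS if c not in frame_df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(frame_df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("frame", "residue"):
        if frame_df[col].isna().any():
            line = int(frame_df[col].isna().idxmax()) + 2
            raise ValueError(f"{path}: malformed row at line {line}")
    angles = frame_df[["phi", "psi"]].to_numpy(dtype=float)
    finite = np.isfinite(angles)
    bad = finite & ((angles <= -180.0) | (angles > 180.0))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        if strict:
            raise ValueError(
                f"{path}: angle outside (-180, 180] at line {row + 2}"
            )
        warnings.warn(
            f"{path}: wrapping out-of-domain angles (first at line {row + 2})",
            stacklevel=2,
        )
        angles[finite] = wrap_angle(angles[finite])
    frames = np.sort(frame_df["frame"].unique())
    residues = np.sort(frame_df["residue"].unique())
    n_f, n_r = frames.size, residues.size
    if len(frame_df) != n_f * n_r:
        raise ValueError(f"{path}: ragged frame/residue table")
    order = np.lexsort((frame_df["residue"].to_numpy(),
                        frame_df["frame"].to_numpy()))
    grid = angles[order].reshape(n_f, n_r, 2)
    return DihedralSeries(angles=grid,
                          residue_labels=tuple(str(int(r)) for r in residues),
                          temperature=temperature, source=str(path))


def _as_atom_array(coords_frame, sequence=None, first_residue_number=1):
    n_res = coords_frame.shape[0]
    atoms = struc.AtomArray(n_res * 3)
    atoms.coord = coords_frame.reshape(-1, 3)
    atoms.atom_name = np.tile(np.array(["N", "CA", "C"]), n_res)
    atoms.element = np.tile(np.array(["N", "C", "C"]), n_res)
    atoms.res_id = np.repeat(
        np.arange(first_residue_number, first_residue_number + n_res), 3)
    if sequence is None:
        res_names = np.repeat(np.array(["GLY"]), n_res * 3)
    else:
        from biotite.sequence import ProteinSequence
        names = [ProteinSequence.convert_letter_1to3(a) for a in sequence]
        res_names = np.repeat(np.array(names), 3)
    atoms.res_name = res_names
    atoms.chain_id = np.full(n_res * 3, "A")
    atoms.hetero = np.zeros(n_res * 3, dtype=bool)
    return atoms


def write_multimodel_pdb(coords, path, sequence=None,
                         first_residue_number: int = 1) -> None:
    """Write backbone N/CA/C coordinates as a (multi-)model PDB file.

    ``coords`` is (n_residues, 3, 3) for one model or
    (n_frames, n_residues, 3, 3) for a trajectory (MODEL/ENDMDL framing).
    """
    coords = np.asarray(coords, dtype=float)
    if isinstance(coords, np.ndarray) and coords.ndim == 3:
        coords = coords[None]
    if coords.ndim != 4 or coords.shape[-2:] != (3, 3):
        raise ValueError("coords must be (frames, residues, 3, 3)")
    template = _as_atom_array(coords[0], sequence, first_residue_number)
    stack = struc.from_template(template, coords.reshape(coords.shape[0], -1, 3))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_conformation_pdb(conf: BackboneConformation, path,
                           first_residue_number: int = 1) -> None:
    write_multimodel_pdb(conf.coords, path, sequence=conf.sequence,
                         first_residue_number=first_residue_number)


def read_multimodel_pdb(path):
    """Read a backbone trajectory from a (multi-)model PDB file.

    Returns ``(coords, res_ids)`` with coords shaped
    (n_frames, n_residues, 3, 3) ordered N/CA/C per residue (atom order in
    the file is irrelevant — lookup is by atom name).  A residue missing
    any backbone atom gets NaN coordinates and a warning, never fabricated
    positions.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    res_ids = np.unique(stack.res_id)
    n_frames = stack.stack_depth()
    coords = np.full((n_frames, res_ids.size, 3, 3), np.nan)
    for j, rid in enumerate(res_ids):
        for k, name in enumerate(("N", "CA", "C")):
            sel = (stack.res_id == rid) & (stack.atom_name == name)
            idx = np.flatnonzero(sel)
            if idx.size == 0:
                warnings.warn(
                    f"{path}: residue {rid} missing backbone atom {name}; "
                    "flagged NaN", stacklevel=2)
                continue
            coords[:, j, k, :] = stack.coord[:, idx[0], :]
    return coords, res_ids


def dihedrals_from_coordinates(coords, res_ids=None,
                               temperature=None) -> DihedralSeries:
    """Backbone (phi, psi) per frame from an N/CA/C coordinate trajectory.

    phi_i = C(i-1)-N(i)-CA(i)-C(i), psi_i = N(i)-CA(i)-C(i)-N(i+1);
    terminal and incomplete residues are flagged NaN.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        coords = coords[None]
    angles = extract_dihedrals(coords)
    angles = np.where(np.isfinite(angles), wrap_angle(angles), np.nan)
    labels = tuple(str(int(r)) for r in res_ids) if res_ids is not None else ()
    return DihedralSeries(angles=angles, residue_labels=labels,
                          temperature=temperature, source="pdb")


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return loaded


def write_surface_text(surface, path) -> None:
    """Write a free-energy surface as gridded text (phi rows, psi columns)."""
    header = (
        f"# free energy surface, kcal/mol, T = {surface.temperature} K\n"
        f"# rows: phi bins {surface.phi_edges[0]}..{surface.phi_edges[-1]}, "
        f"cols: psi bins {surface.psi_edges[0]}..{surface.psi_edges[-1]}\n"
        "# empty bins written as nan\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, surface.delta_g, fmt="%.6f")
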