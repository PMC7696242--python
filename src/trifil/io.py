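"""Readers and writers for standard coordinate and trajectory formats.

PDB (multi-model) and GRO files go through biotite; XTC/DCD
trajectories are read through MDAnalysis against a PDB/GRO topology.
Internally everything is held in nm; biotite's angstrom convention and
MDAnalysis' angstrom coordinates are converted at the boundary.

Peptide bookkeeping is reconstructed from residue names: every ``ACE``
residue starts a new peptide (indices 0..4 through the ``NH2`` cap) and
``W`` residues are solvent beads (peptide id -1).
"""

from __future__ import annotations

import os

import numpy as np
import biotite.structure as struc
import biotite.structure.io.gro as gro_io
import biotite.structure.io.pdb as pdb_io

from .geometry import Box, GeometryError
from .model import SOLVENT_NAME, StructureFrame, Trajectory

_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "gro", "xtc", "dcd"):
        return ext
    raise ValueError(f"cannot infer file format from {path!r}")


def _element_for(name: str) -> str:
    if name == SOLVENT_NAME:
        return "C"
    for ch in name:
        if ch.isalpha():
            return ch.upper() if ch.upper() in "CNOHS" else "C"
    return "C"


def frame_to_atom_array(frame: StructureFrame) -> struc.AtomArray:
    """Convert to a biotite AtomArray (coordinates in angstrom)."""
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.coords * 10.0
    res_ids = np.empty(n, dtype=int)
    chain_ids = np.empty(n, dtype="U4")
    pep_mask = frame.peptide_ids >= 0
    res_ids[pep_mask] = (frame.peptide_ids[pep_mask] * 5
                         + frame.residue_indices[pep_mask] + 1)
    offset = int(res_ids[pep_mask].max()) if pep_mask.any() else 0
    # one residue id per solvent bead
    sol_idx = np.flatnonzero(~pep_mask)
    res_ids[sol_idx] = offset + 1 + np.arange(len(sol_idx))
    for i in range(n):
        pid = frame.peptide_ids[i]
        chain_ids[i] = _CHAIN_LETTERS[pid % 26] if pid >= 0 else "S"
    arr.chain_id = chain_ids
    arr.res_id = res_ids
    arr.res_name = frame.residue_names.astype("U5")
    arr.atom_name = frame.atom_names.astype("U6")
    arr.element = np.array([_element_for(a) for a in frame.atom_names], dtype="U2")
    arr.hetero = ~pep_mask
    if frame.box is not None:
        arr.box = np.diag(frame.box.lengths * 10.0)
    return arr


def atom_array_to_frame(arr: struc.AtomArray, frame_index: int = 0,
                        time: float | None = None) -> StructureFrame:
    """Convert a biotite AtomArray back, regrouping peptides by ACE caps."""
    names = [a.strip() for a in arr.atom_name]
    res_names = [r.strip() for r in arr.res_name]
    n = arr.array_length()
    peptide_ids = np.empty(n, dtype=int)
    residue_indices = np.empty(n, dtype=int)
    pid = -1
    res_counter = 0
    last_res_id = None
    for i in range(n):
        rn = res_names[i]
        new_residue = (last_res_id is None or arr.res_id[i] != last_res_id)
        last_res_id = arr.res_id[i]
        if rn == SOLVENT_NAME:
            peptide_ids[i] = -1
            residue_indices[i] = 0
            continue
        if new_residue:
            if rn == "ACE":
                pid += 1
                res_counter = 0
            else:
                res_counter += 1
        if pid < 0:
            raise ValueError("peptide atoms found before any ACE cap; "
                             "cannot reconstruct peptide grouping")
        peptide_ids[i] = pid
        residue_indices[i] = res_counter
    box = None
    if arr.box is not None:
        try:
            box = Box.from_vectors(np.asarray(arr.box) / 10.0)
        except GeometryError:
            raise
    return StructureFrame(names, residue_indices, res_names, peptide_ids,
                          arr.coord / 10.0, box=box, frame_index=frame_index,
                          time=time)


def write_structure(frame: StructureFrame, path: str, fmt: str | None = None) -> None:
    """Write a single frame as PDB or GRO."""
    fmt = _infer_format(path, fmt)
    arr = frame_to_atom_array(frame)
    if fmt == "pdb":
        f = pdb_io.PDBFile()
        f.set_structure(arr)
        f.write(path)
    elif fmt == "gro":
        f = gro_io.GROFile()
        f.set_structure(arr)
        f.write(path)
        # biotite stamps the title line with the wall clock; keep outputs
        # reproducible byte-for-byte under fixed seeds
        with open(path) as fh:
            lines = fh.readlines()
        lines[0] = "trifil structure\n"
        with open(path, "w") as fh:
            fh.writelines(lines)
    else:
        raise ValueError(f"unsupported structure format: {fmt}")


def write_trajectory(traj: Trajectory, path: str, fmt: str | None = None) -> None:
    """Write a trajectory as a multi-model PDB or an XTC file."""
    fmt = _infer_format(path, fmt)
    if fmt == "pdb":
        stack = struc.stack([frame_to_atom_array(f) for f in traj.frames])
        f = pdb_io.PDBFile()
        f.set_structure(stack)
        f.write(path)
    elif fmt in ("xtc", "dcd"):
        import MDAnalysis as mda
        first = traj.frames[0]
        n = first.n_atoms
        with mda.coordinates.XTC.XTCWriter(path, n) if fmt == "xtc" else \
                mda.coordinates.DCD.DCDWriter(path, n) as writer:
            u = mda.Universe.empty(n, trajectory=True)
            for i, fr in enumerate(traj.frames):
                u.atoms.positions = fr.coords * 10.0
                if fr.box is not None:
                    u.dimensions = [*(fr.box.lengths * 10.0), 90, 90, 90]
                u.trajectory.ts.frame = i
                u.trajectory.ts.time = fr.time if fr.time is not None else float(i)
                writer.write(u.atoms)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt}")


def read_models(path: str, fmt: str | None = None,
                validate: bool = True) -> list[StructureFrame]:
    """Read every model of a PDB/GRO file as its own StructureFrame."""
    fmt = _infer_format(path, fmt)
    if fmt == "pdb":
        f = pdb_io.PDBFile.read(path)
        obj = f.get_structure()
    elif fmt == "gro":
        f = gro_io.GROFile.read(path)
        obj = f.get_structure()
    else:
        raise ValueError(f"unsupported structure format: {fmt}")
    if isinstance(obj, struc.AtomArrayStack):
        arrays = list(obj)
    else:
        arrays = [obj]
    frames = [atom_array_to_frame(a, frame_index=i) for i, a in enumerate(arrays)]
    if validate:
        for fr in frames:
            fr.validate()
    return frames


def read_structure(path: str, fmt: str | None = None, model: int = 0,
                   validate: bool = True) -> StructureFrame:
    """Read one model (default: the first) of a PDB or GRO file."""
    frames = read_models(path, fmt, validate=validate)
    return frames[model]


def read_trajectory(topology_path: str, traj_path: str,
                    fmt: str | None = None, run_id: str = "run0",
                    validate: bool = True) -> Trajectory:
    """Read a trajectory against a PDB/GRO topology.

    Multi-model PDB trajectories are parsed directly; XTC/DCD go through
    MDAnalysis.  An empty trajectory or an atom-count mismatch between
    topology and trajectory is an error.
    """
    fmt = _infer_format(traj_path, fmt)
    if fmt in ("pdb", "gro"):
        frames = read_models(traj_path, fmt, validate=validate)
        if not frames:
            raise ValueError(f"trajectory {traj_path!r} contains no frames")
        top = read_structure(topology_path, validate=validate)
        if frames[0].n_atoms != top.n_atoms:
            raise ValueError(
                f"atom count mismatch: topology has {top.n_atoms}, "
                f"trajectory frames have {frames[0].n_atoms}")
        return Trajectory(frames=frames, run_id=run_id)
    if fmt not in ("xtc", "dcd"):
        raise ValueError(f"unsupported trajectory format: {fmt}")
    import MDAnalysis as mda
    top = read_structure(topology_path, validate=validate)
    u = mda.Universe(topology_path, traj_path)
    if len(u.atoms) != top.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {top.n_atoms}, "
            f"trajectory has {len(u.atoms)}")
    frames = []
    for ts in u.trajectory:
        fr = top.copy()
        fr.coords = ts.positions.astype(float) / 10.0
        fr.frame_index = ts.frame
        fr.time = float(ts.time) if ts.time is not None else None
        if ts.dimensions is not None and ts.dimensions[:3].all():
            if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
                raise GeometryError("only orthorhombic boxes are supported")
            fr.box = Box(*(ts.dimensions[:3] / 10.0))
        frames.append(fr)
    if not frames:
        raise ValueError(f"trajectory {traj_path!r} contains no frames")
    return Trajectory(frames=frames, run_id=run_id)
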