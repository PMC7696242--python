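"""Data model for capped tripeptide systems.

A system is a collection of tripeptides, each consisting of an
N-terminal acetyl cap (residue index 0), three amino-acid residues
(indices 1-3, Phe or Ile) and a C-terminal amide cap (index 4), plus
optional coarse-grained water beads (residue name ``W``, peptide id -1).
Every amino-acid residue must carry the backbone atoms N, CA, C, O and
the first sidechain atom CB; the amide hydrogen H is optional and can
be reconstructed with standard planar-amide geometry when absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Box, dihedral

BACKBONE_NAMES = ("N", "H", "CA", "C", "O")
REQUIRED_RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB")
CAP_N_INDEX = 0   # acetyl
CAP_C_INDEX = 4   # amide
AMINO_NAMES = {"PHE": "F", "ILE": "I"}
ONE_TO_THREE = {"F": "PHE", "I": "ILE"}
SOLVENT_NAME = "W"


class TopologyError(ValueError):
    """Raised when a structure violates the capped-tripeptide topology."""


@dataclass
class AtomRecord:
    """One particle; positions in nm."""

    atom_name: str
    residue_index: int
    residue_name: str
    peptide_id: int
    position: np.ndarray


class StructureFrame:
    """A single configuration: columnar atom bookkeeping plus coordinates.

    Parameters are parallel arrays over atoms.  ``peptide_id`` is 0-based
    and contiguous for peptides; solvent beads carry -1.
    """

    def __init__(self, atom_names, residue_indices, residue_names, peptide_ids,
                 coords, box: Box | None = None, frame_index: int = 0,
                 time: float | None = None):
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.peptide_ids = np.asarray(peptide_ids, dtype=int)
        self.coords = np.array(coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        n = len(self.atom_names)
        if not (len(self.residue_indices) == len(self.residue_names)
                == len(self.peptide_ids) == self.coords.shape[0] == n):
            raise ValueError("all atom columns must have equal length")
        self.box = box
        self.frame_index = frame_index
        self.time = time

    # -- construction -------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: list[AtomRecord], box: Box | None = None,
                   frame_index: int = 0, time: float | None = None) -> "StructureFrame":
        return cls(
            [a.atom_name for a in atoms],
            [a.residue_index for a in atoms],
            [a.residue_name for a in atoms],
            [a.peptide_id for a in atoms],
            np.array([a.position for a in atoms], dtype=float),
            box=box, frame_index=frame_index, time=time,
        )

    @property
    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(self.atom_names[i], int(self.residue_indices[i]),
                           self.residue_names[i], int(self.peptide_ids[i]),
                           self.coords[i].copy())
                for i in range(self.n_atoms)]

    def copy(self) -> "StructureFrame":
        return StructureFrame(self.atom_names.copy(), self.residue_indices.copy(),
                              self.residue_names.copy(), self.peptide_ids.copy(),
                              self.coords.copy(), box=self.box,
                              frame_index=self.frame_index, time=self.time)

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def peptides(self) -> np.ndarray:
        ids = np.unique(self.peptide_ids)
        return ids[ids >= 0]

    @property
    def n_peptides(self) -> int:
        return len(self.peptides())

    def mask(self, atom_name=None, residue_name=None, residue_index=None,
             peptide_id=None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)

        def crit(values, wanted):
            wanted = np.atleast_1d(wanted)
            return np.isin(values, wanted)

        if atom_name is not None:
            m &= crit(self.atom_names, atom_name)
        if residue_name is not None:
            m &= crit(self.residue_names, residue_name)
        if residue_index is not None:
            m &= crit(self.residue_indices, residue_index)
        if peptide_id is not None:
            m &= crit(self.peptide_ids, peptide_id)
        return m

    def indices(self, **kwargs) -> np.ndarray:
        return np.flatnonzero(self.mask(**kwargs))

    def _lookup(self) -> dict:
        """Lazy (peptide, residue, atom) -> row map.

        Rebuilt whenever a topology column is *replaced* (the mutation
        style used throughout); in-place element edits of topology
        arrays are not tracked.
        """
        key = (id(self.atom_names), id(self.residue_indices),
               id(self.peptide_ids))
        cached = getattr(self, "_lookup_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        table: dict = {}
        dup = set()
        for i in range(self.n_atoms):
            k = (int(self.peptide_ids[i]), int(self.residue_indices[i]),
                 self.atom_names[i])
            if k in table:
                dup.add(k)
            table[k] = i
        self._lookup_cache = (key, table, dup)
        return self._lookup_cache[1]

    def atom_index(self, peptide_id: int, residue_index: int, atom_name: str) -> int:
        table = self._lookup()
        key = (int(peptide_id), int(residue_index), atom_name)
        if key in self._lookup_cache[2]:
            raise TopologyError(
                f"peptide {peptide_id} residue {residue_index} has duplicate {atom_name}")
        if key not in table:
            raise TopologyError(
                f"peptide {peptide_id} residue {residue_index} misses atom {atom_name}")
        return table[key]

    def position(self, peptide_id: int, residue_index: int, atom_name: str) -> np.ndarray:
        return self.coords[self.atom_index(peptide_id, residue_index, atom_name)]

    def has_atom(self, peptide_id: int, residue_index: int, atom_name: str) -> bool:
        table = self._lookup()
        key = (int(peptide_id), int(residue_index), atom_name)
        return key in table and key not in self._lookup_cache[2]

    def peptide_sequence(self, peptide_id: int) -> str:
        letters = []
        for r in (1, 2, 3):
            idx = self.indices(peptide_id=peptide_id, residue_index=r)
            if len(idx) == 0:
                raise TopologyError(f"peptide {peptide_id} misses residue {r}")
            name = self.residue_names[idx[0]]
            if name not in AMINO_NAMES:
                raise TopologyError(
                    f"peptide {peptide_id} residue {r} has unsupported name {name}")
            letters.append(AMINO_NAMES[name])
        return "".join(letters)

    def peptide_centroid(self, peptide_id: int) -> np.ndarray:
        m = self.mask(peptide_id=peptide_id)
        return self.coords[m].mean(axis=0)

    # -- transforms ----------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "StructureFrame":
        out = self.copy()
        if rotation is not None:
            out.coords = out.coords @ np.asarray(rotation, float).T
        if translation is not None:
            out.coords = out.coords + np.asarray(translation, float)
        return out

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check the capped-tripeptide topology invariants.

        Raises :class:`TopologyError` naming the offending peptide and
        residue on the first violation found.
        """
        pids = self.peptides()
        if len(pids) and not np.array_equal(pids, np.arange(len(pids))):
            raise TopologyError(f"peptide ids are not contiguous from 0: {pids}")
        for pid in pids:
            for r in (1, 2, 3):
                for name in REQUIRED_RESIDUE_ATOMS:
                    if not self.has_atom(pid, r, name):
                        raise TopologyError(
                            f"peptide {pid} residue {r} misses backbone atom {name}")
            if not self.has_atom(pid, CAP_N_INDEX, "C"):
                raise TopologyError(f"peptide {pid} misses the acetyl cap carbonyl")
            if not self.has_atom(pid, CAP_C_INDEX, "N"):
                raise TopologyError(f"peptide {pid} misses the amide cap nitrogen")


@dataclass
class Trajectory:
    """Ordered frames of one simulation run; shared topology."""

    frames: list[StructureFrame]
    run_id: str = "run0"

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if f.n_atoms != ref.n_atoms or not np.array_equal(
                    f.atom_names, ref.atom_names):
                raise TopologyError("frames do not share atom ordering")


@dataclass
class Ensemble:
    """Independent runs of the same system (the error-bar unit)."""

    runs: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("an ensemble needs at least one run")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def iter_frames(self):
        for run in self.runs:
            for frame in run.frames:
                yield run.run_id, frame


_DIHEDRAL_ATOMS = {
    "phi1": [(0, "C"), (1, "N"), (1, "CA"), (1, "C")],
    "psi1": [(1, "N"), (1, "CA"), (1, "C"), (2, "N")],
    "phi2": [(1, "C"), (2, "N"), (2, "CA"), (2, "C")],
    "psi2": [(2, "N"), (2, "CA"), (2, "C"), (3, "N")],
    "phi3": [(2, "C"), (3, "N"), (3, "CA"), (3, "C")],
    "psi3": [(3, "N"), (3, "CA"), (3, "C"), (4, "N")],
}


def backbone_dihedrals(frame: StructureFrame, peptide_id: int) -> np.ndarray:
    """The six backbone torsions (phi1, psi1, phi2, psi2, phi3, psi3) in degrees.

    Terminal caps make phi1 and psi3 well defined; a missing cap atom
    raises :class:`TopologyError` naming the undefined dihedral.
    """
    values = []
    for name, spec in _DIHEDRAL_ATOMS.items():
        try:
            pts = [frame.position(peptide_id, r, a) for r, a in spec]
        except TopologyError as err:
            raise TopologyError(f"cannot evaluate {name}: {err}") from err
        values.append(dihedral(*pts))
    return np.array(values)


def reconstruct_amide_hydrogens(frame: StructureFrame) -> StructureFrame:
    """Return a frame with missing amide hydrogens rebuilt.

    H is placed 0.1 nm from N in the amide plane with the standard
    trans-amide geometry: C(prev)-N-H angle of 119 degrees and H anti
    to the following CA (torsion CA(prev)-C(prev)-N-H = 0, with the
    acetyl CH3 standing in for CA at residue 1).  Needed because the
    hydrogen-bond criterion uses the donor-hydrogen-acceptor angle.
    """
    from .geometry import nerf

    out = frame.copy()
    new_atoms = []
    for pid in frame.peptides():
        for r in (1, 2, 3, CAP_C_INDEX):
            if not frame.has_atom(pid, r, "N") or frame.has_atom(pid, r, "H"):
                continue
            n_pos = frame.position(pid, r, "N")
            c_prev = frame.position(pid, r - 1, "C")
            ca_prev = (frame.position(pid, r - 1, "CA") if r > 1
                       else frame.position(pid, 0, "CH3"))
            h_pos = nerf(ca_prev, c_prev, n_pos, 0.1, 119.0, 0.0)
            res_name = frame.residue_names[frame.atom_index(pid, r, "N")]
            new_atoms.append(AtomRecord("H", r, res_name, int(pid), h_pos))
    if not new_atoms:
        return out
    add = StructureFrame.from_atoms(new_atoms)
    out.atom_names = np.concatenate([out.atom_names, add.atom_names])
    out.residue_indices = np.concatenate([out.residue_indices, add.residue_indices])
    out.residue_names = np.concatenate([out.residue_names, add.residue_names])
    out.peptide_ids = np.concatenate([out.peptide_ids, add.peptide_ids])
    out.coords = np.vstack([out.coords, add.coords])
    return out


def concatenate_frames(frames: list[StructureFrame], box: Box | None = None,
                       renumber: bool = True) -> StructureFrame:
    """Merge frames into one, optionally renumbering peptide ids contiguously."""
    parts = [f.copy() for f in frames]
    offset = 0
    for f in parts:
        if renumber:
            pep = f.peptide_ids >= 0
            f.peptide_ids[pep] += offset
            offset += len(np.unique(f.peptide_ids[pep]))
    return StructureFrame(
        np.concatenate([f.atom_names for f in parts]),
        np.concatenate([f.residue_indices for f in parts]),
        np.concatenate([f.residue_names for f in parts]),
        np.concatenate([f.peptide_ids for f in parts]),
        np.vstack([f.coords for f in parts]),
        box=box if box is not None else parts[0].box,
    )
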