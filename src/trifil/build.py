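"""Synthetic structure generator for capped Phe/Ile tripeptides.

Builds single tripeptides at prescribed (phi, psi) targets by
sequential internal-coordinate placement (NeRF), stacks them into
in-register parallel filaments at a chosen rise, bundles filaments
laterally into fibers, adds a coarse-grained solvent shell, and emits
pseudo-trajectories whose per-peptide conformations are drawn from a
specified mixture of conformation codes.  All randomness is owned by
explicit seeds and is bitwise reproducible.

The generator emulates the study conditions of the self-assembly
simulations it stands in for: 30 peptides in a 6 x 6 x 6 nm periodic
box, three independent runs, filament rises in the 4.6-4.9 angstrom
range characteristic of cross-beta stacking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import Box, nerf, rotation_about_axis
from .model import (AtomRecord, Ensemble, ONE_TO_THREE, StructureFrame,
                    Trajectory, concatenate_frames)
from .states import ConformationCode, RegionMap

# Standard covalent geometry (nm / degrees).
BOND_N_CA = 0.146
BOND_CA_C = 0.152
BOND_C_N = 0.133
BOND_C_O = 0.123
BOND_N_H = 0.100
BOND_CA_CB = 0.153
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0
ANGLE_N_CA_CB = 109.5
OMEGA = 180.0
# Improper torsion C-N-CA-CB fixing L-amino-acid chirality
# (measured from the CCD ideal alanine geometry).
CB_TORSION = -120.0

DEFAULT_NOISE_SIGMA = 0.01   # nm; visible jitter, far below basin widths
DEFAULT_RISE_RANGE = (4.6, 4.9)   # angstrom, cross-beta stacking spacing
#: MARTINI-style 4-to-1 coarse water at bulk density (~33.4 waters/nm^3 / 4).
DEFAULT_WATER_DENSITY = 8.35  # beads / nm^3


class BuildError(ValueError):
    """Raised for invalid build specifications."""


@dataclass
class BuildSpec:
    """Targets for a single capped tripeptide.

    sequence is three letters over {F, I}; phi_psi_targets holds one
    (phi, psi) pair per residue in degrees.
    """

    sequence: str
    phi_psi_targets: tuple[tuple[float, float], ...]
    cap_n: bool = True
    cap_c: bool = True
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != 3 or any(ch not in ONE_TO_THREE
                                          for ch in self.sequence):
            raise BuildError(f"sequence must be 3 letters over F/I, "
                             f"got {self.sequence!r}")
        if len(self.phi_psi_targets) != 3:
            raise BuildError("need one (phi, psi) pair per residue")
        for phi, psi in self.phi_psi_targets:
            if not (-180 < phi <= 180 and -180 < psi <= 180):
                raise BuildError(f"targets must lie in (-180, 180], "
                                 f"got ({phi}, {psi})")


def build_tripeptide(spec: BuildSpec,
                     rng: np.random.Generator | None = None) -> StructureFrame:
    """Build one capped tripeptide at the spec's (phi, psi) targets.

    The backbone is extended atom by atom with standard bond lengths
    and angles, omega fixed at 180 and CB placed with L-amino-acid
    tetrahedral geometry.  Before noise, the measured backbone
    dihedrals reproduce the targets to better than 1e-4 degrees.
    Gaussian coordinate noise of ``noise_sigma`` is applied last,
    reproducibly from ``seed`` (or from ``rng`` when given).
    """
    pos: dict[tuple[int, str], np.ndarray] = {}
    # Acetyl cap: CH3-C(=O)- ; CH3 stands in for the previous CA.
    pos[(0, "CH3")] = np.zeros(3)
    pos[(0, "C")] = np.array([BOND_CA_C, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_CA_C_N)
    pos[(1, "N")] = pos[(0, "C")] + BOND_C_N * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    pos[(0, "O")] = nerf(pos[(1, "N")], pos[(0, "CH3")], pos[(0, "C")],
                         BOND_C_O, ANGLE_CA_C_O, 180.0)

    prev_ca = pos[(0, "CH3")]
    prev_c = pos[(0, "C")]
    for i in (1, 2, 3):
        phi, psi = spec.phi_psi_targets[i - 1]
        n_i = pos[(i, "N")]
        pos[(i, "H")] = nerf(prev_ca, prev_c, n_i, BOND_N_H, ANGLE_C_N_H, 0.0)
        ca_i = nerf(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        pos[(i, "CA")] = ca_i
        c_i = nerf(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        pos[(i, "C")] = c_i
        pos[(i, "CB")] = nerf(c_i, n_i, ca_i, BOND_CA_CB, ANGLE_N_CA_CB,
                              CB_TORSION)
        pos[(i + 1, "N")] = nerf(n_i, ca_i, c_i, BOND_C_N, ANGLE_CA_C_N, psi)
        pos[(i, "O")] = nerf(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O,
                             psi + 180.0)
        prev_ca, prev_c = ca_i, c_i
    # Amide cap: -NH2 (single in-plane H).
    pos[(4, "H")] = nerf(pos[(3, "CA")], pos[(3, "C")], pos[(4, "N")],
                         BOND_N_H, ANGLE_C_N_H, 0.0)

    atoms: list[AtomRecord] = []
    if spec.cap_n:
        for name in ("CH3", "C", "O"):
            atoms.append(AtomRecord(name, 0, "ACE", 0, pos[(0, name)]))
    for i in (1, 2, 3):
        res_name = ONE_TO_THREE[spec.sequence[i - 1]]
        for name in ("N", "H", "CA", "CB", "C", "O"):
            atoms.append(AtomRecord(name, i, res_name, 0, pos[(i, name)]))
    if spec.cap_c:
        for name in ("N", "H"):
            atoms.append(AtomRecord(name, 4, "NH2", 0, pos[(4, name)]))

    frame = StructureFrame.from_atoms(atoms)
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        frame.coords = frame.coords + rng.normal(
            0.0, spec.noise_sigma, frame.coords.shape)
    return frame


def build_from_code(sequence: str, code: ConformationCode, regions: RegionMap,
                    noise_sigma: float = 0.0,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> StructureFrame:
    """Build a tripeptide at the basin centres of a conformation code."""
    targets = tuple(regions.centers[s] for s in code.states)
    spec = BuildSpec(sequence=sequence, phi_psi_targets=targets,
                     noise_sigma=noise_sigma, seed=seed)
    return build_tripeptide(spec, rng=rng)


# ---------------------------------------------------------------------------
# Filaments and bundles
# ---------------------------------------------------------------------------

@dataclass
class FilamentSpec:
    """In-register parallel stack of one peptide along the z axis.

    ``rise`` is the adjacent-chain spacing in angstroms; when None it
    is drawn uniformly from the 4.6-4.9 angstrom cross-beta range.
    """

    n_copies: int = 6
    rise: float | None = 4.8
    twist_per_step: float = 0.0
    orient: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise BuildError("a filament needs at least 2 copies")
        if self.rise is not None and self.rise <= 0:
            raise BuildError("rise must be positive")

    def resolve_rise(self) -> float:
        if self.rise is not None:
            return float(self.rise)
        lo, hi = DEFAULT_RISE_RANGE
        return float(np.random.default_rng(self.seed).uniform(lo, hi))


STERIC_LIMIT = 0.05  # nm


def _steric_check(frame: StructureFrame, context: str) -> None:
    pids = frame.peptide_ids
    coords = frame.coords
    for pid in frame.peptides():
        a = coords[pids == pid]
        b = coords[(pids >= 0) & (pids > pid)]
        if len(b) == 0:
            continue
        d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
        if d.min() < STERIC_LIMIT:
            warnings.warn(f"steric collapse in {context}: interchain pair at "
                          f"{d.min():.4f} nm", stacklevel=3)
            return


def _align_strand_to_x(frame: StructureFrame) -> StructureFrame:
    """Centre the peptide and rotate its CA1->CA3 axis onto +x."""
    out = frame.copy()
    out.coords = out.coords - out.coords.mean(axis=0)
    v = out.position(0, 3, "CA") - out.position(0, 1, "CA")
    v = v / np.linalg.norm(v)
    target = np.array([1.0, 0.0, 0.0])
    axis = np.cross(v, target)
    if np.linalg.norm(axis) < 1e-12:
        if np.dot(v, target) > 0:
            return out
        axis, angle = np.array([0.0, 0.0, 1.0]), 180.0
    else:
        angle = np.degrees(np.arccos(np.clip(np.dot(v, target), -1, 1)))
    R = rotation_about_axis(axis, angle)
    out.coords = out.coords @ R.T
    return out


def orient_for_stacking(peptide: StructureFrame, rise_nm: float,
                        step: float = 2.0) -> StructureFrame:
    """Rotate a monomer so z-stacked copies can hydrogen bond.

    The strand axis (CA1->CA3) is aligned with x; the rotation about x
    is then chosen by grid search to maximise the number of backbone
    hydrogen bonds between a copy and its z-translated neighbour,
    breaking ties by the smallest donor-acceptor distance.
    """
    from .interactions import InteractionCriteria, detect_hbonds

    base = _align_strand_to_x(peptide)
    crit = InteractionCriteria()
    best = None
    for ang in np.arange(0.0, 360.0, step):
        cand = base.transformed(rotation=rotation_about_axis([1, 0, 0], ang))
        upper = cand.copy()
        upper.coords = upper.coords + np.array([0.0, 0.0, rise_nm])
        upper.peptide_ids = np.ones(upper.n_atoms, dtype=int)
        pair = concatenate_frames([cand, upper], renumber=False)
        hbonds = detect_hbonds(pair, crit)
        # tie-break: closest donor-acceptor approach
        d_min = _min_no_distance(pair)
        key = (-len(hbonds), d_min)
        if best is None or key < best[0]:
            best = (key, ang)
    return base.transformed(rotation=rotation_about_axis([1, 0, 0], best[1]))


def _min_no_distance(pair: StructureFrame) -> float:
    n_idx = pair.indices(atom_name="N", peptide_id=1)
    o_idx = pair.indices(atom_name="O", peptide_id=0)
    if len(n_idx) == 0 or len(o_idx) == 0:
        return np.inf
    d = pair.coords[n_idx][:, None, :] - pair.coords[o_idx][None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).min())


def build_filament(peptide: StructureFrame, spec: FilamentSpec) -> StructureFrame:
    """Stack ``n_copies`` of a peptide along z at the given rise and twist.

    Copy i carries peptide id i.  Steric collapse (any interchain pair
    closer than 0.05 nm) produces a warning, not an error.
    """
    if peptide.n_peptides != 1:
        raise BuildError("build_filament expects a single tripeptide")
    rise_nm = spec.resolve_rise() / 10.0
    base = orient_for_stacking(peptide, rise_nm) if spec.orient \
        else peptide.transformed(translation=-peptide.coords.mean(axis=0))
    copies = []
    for i in range(spec.n_copies):
        c = base.copy()
        if spec.twist_per_step:
            R = rotation_about_axis([0, 0, 1], i * spec.twist_per_step)
            c.coords = c.coords @ R.T
        c.coords = c.coords + np.array([0.0, 0.0, i * rise_nm])
        c.peptide_ids = np.full(c.n_atoms, i, dtype=int)
        copies.append(c)
    out = concatenate_frames(copies, renumber=False)
    _steric_check(out, "build_filament")
    return out


def bundle_arrangement(n_filaments: int, radius: float,
                       rotations: list[float] | None = None
                       ) -> list[tuple[float, float, float]]:
    """Symmetric lateral placement of filaments around the fiber axis."""
    out = []
    for k in range(n_filaments):
        ang = 360.0 * k / n_filaments
        rot = rotations[k] if rotations is not None else ang + 90.0
        out.append((radius * np.cos(np.radians(ang)),
                    radius * np.sin(np.radians(ang)), rot))
    return out


def build_bundle(filaments: list[StructureFrame],
                 arrangement: list[tuple[float, float, float]]) -> StructureFrame:
    """Rigidly place filaments laterally and merge them into one fiber.

    Each arrangement entry is (dx, dy, rotation about z in degrees);
    peptide ids are renumbered contiguously.  A single filament is
    returned unchanged (identity).
    """
    if len(filaments) != len(arrangement):
        raise BuildError("one arrangement entry per filament required")
    placed = []
    for fil, (dx, dy, rot) in zip(filaments, arrangement):
        R = rotation_about_axis([0, 0, 1], rot)
        placed.append(fil.transformed(rotation=R,
                                      translation=np.array([dx, dy, 0.0])))
    if len(placed) == 1:
        return placed[0]
    out = concatenate_frames(placed, renumber=True)
    _steric_check(out, "build_bundle")
    return out


def _min_interfilament_distance(filament: StructureFrame, n: int,
                                radius: float) -> float:
    arr = bundle_arrangement(n, radius)
    placed = []
    for (dx, dy, rot) in arr[:2]:
        R = rotation_about_axis([0, 0, 1], rot)
        placed.append(filament.transformed(
            rotation=R, translation=np.array([dx, dy, 0.0])))
    a, b = placed[0].coords, placed[1].coords
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).min())


def fit_bundle_radius(filament: StructureFrame, n_filaments: int = 3,
                      gap: float = 0.3) -> float:
    """Smallest symmetric-bundle radius with the requested surface gap (nm).

    Deterministic bisection on the minimum inter-filament atom distance;
    a gap between the steric limit and the contact cutoff guarantees the
    bundle is a single contact-connected aggregate without collisions.
    """
    lo, hi = 0.05, 6.0
    f_hi = _min_interfilament_distance(filament, n_filaments, hi) - gap
    if f_hi < 0:
        raise BuildError("cannot separate filaments within search range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _min_interfilament_distance(filament, n_filaments, mid) - gap < 0:
            lo = mid
        else:
            hi = mid
    return hi


def four_filament_arrangement(filament: StructureFrame, gap: float = 0.3
                              ) -> list[tuple[float, float, float]]:
    """Three-filament bundle plus one filament packed against its side.

    Emulates the fiber motif in which an additional filament associates
    laterally with a symmetric three-filament bundle.
    """
    r3 = fit_bundle_radius(filament, 3, gap=gap)
    arr = bundle_arrangement(3, r3)
    core = build_bundle([filament.copy() for _ in range(3)], arr)

    def min_dist(x: float) -> float:
        extra = filament.transformed(
            rotation=rotation_about_axis([0, 0, 1], 90.0),
            translation=np.array([x, 0.0, 0.0]))
        d = core.coords[:, None, :] - extra.coords[None, :, :]
        return float(np.sqrt((d ** 2).sum(-1)).min())

    lo, hi = r3, r3 + 8.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) - gap < 0:
            lo = mid
        else:
            hi = mid
    return arr + [(hi, 0.0, 90.0)]


# ---------------------------------------------------------------------------
# Solvent
# ---------------------------------------------------------------------------

def add_solvent_shell(frame: StructureFrame, box: Box,
                      density: float = DEFAULT_WATER_DENSITY,
                      exclusion_radius: float = 0.45,
                      seed: int = 0) -> StructureFrame:
    """Add coarse water beads uniformly at random outside the solute.

    The candidate count is Poisson(density x box volume); candidates
    within ``exclusion_radius`` (nm, minimum image) of any solute atom
    are rejected, so the accepted count is Poisson in the free volume.
    """
    out = frame.copy()
    out.box = box
    if density <= 0:
        return out
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(density * box.volume)
    cand = rng.uniform(0.0, 1.0, size=(n_cand, 3)) * box.lengths
    if frame.n_atoms > 0:
        from scipy.spatial import cKDTree
        solute = np.mod(frame.coords, box.lengths)
        tree = cKDTree(solute, boxsize=box.lengths)
        dist, _ = tree.query(cand, k=1)
        cand = cand[dist >= exclusion_radius]
    n_new = len(cand)
    out.atom_names = np.concatenate([out.atom_names,
                                     np.array(["W"] * n_new, dtype=object)])
    out.residue_indices = np.concatenate([out.residue_indices,
                                          np.zeros(n_new, dtype=int)])
    out.residue_names = np.concatenate([out.residue_names,
                                        np.array(["W"] * n_new, dtype=object)])
    out.peptide_ids = np.concatenate([out.peptide_ids,
                                      np.full(n_new, -1, dtype=int)])
    out.coords = np.vstack([out.coords, cand]) if n_new else out.coords
    return out


# ---------------------------------------------------------------------------
# Mixture pseudo-trajectories
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """Mixture of conformation codes sampled per peptide and frame."""

    components: list[tuple[ConformationCode, float]]
    n_frames: int = 200
    n_runs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise BuildError("mixture weights must be >= 0 and sum to 1")


@dataclass
class GridPlacement:
    """Dispersed-monomer placement on a cubic lattice inside the box."""

    box: Box = field(default_factory=lambda: Box(6.0, 6.0, 6.0))
    n_peptides: int = 30


def _grid_sites(box: Box, n: int) -> np.ndarray:
    per_edge = int(np.ceil(n ** (1.0 / 3.0)))
    ticks = [(np.arange(per_edge) + 0.5) * L / per_edge for L in box.lengths]
    grid = np.array(np.meshgrid(*ticks, indexing="ij")).reshape(3, -1).T
    return grid[:n]


_TEMPLATE_CACHE: dict = {}


def _template(sequence: str, code: ConformationCode, regions: RegionMap):
    """Ideal noise-free fixture for a code plus precomputed torsion rows.

    Returns (frame, quads) where ``quads`` is an (8, 4) index array for
    phi1, psi1, phi2, psi2, phi3, psi3, theta1, theta2.
    """
    key = (sequence, str(code),
           tuple(sorted((s.value, c) for s, c in regions.centers.items())))
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    frame = build_from_code(sequence, code, regions)
    from .model import _DIHEDRAL_ATOMS
    quads = []
    for spec in _DIHEDRAL_ATOMS.values():
        quads.append([frame.atom_index(0, r, a) for r, a in spec])
    for i in (1, 2):
        quads.append([frame.atom_index(0, i, "CB"),
                      frame.atom_index(0, i, "CA"),
                      frame.atom_index(0, i + 1, "CA"),
                      frame.atom_index(0, i + 1, "CB")])
    entry = (frame, np.array(quads, dtype=int))
    _TEMPLATE_CACHE[key] = entry
    return entry


def _realize_code(sequence: str, code: ConformationCode, regions: RegionMap,
                  noise_sigma: float, rng: np.random.Generator,
                  ideal_group, max_attempts: int = 100) -> StructureFrame:
    """Build a peptide whose *realized* labels match the drawn code.

    Coordinate noise is truncated by rejection: a sample whose jitter
    carries a dihedral across a classification boundary (conformation
    code or sidechain topology group) is redrawn, so the mixture weights
    are realized exactly up to draw statistics.
    """
    from .geometry import dihedrals_batch
    from .sidechain import ThetaPair, topology_group
    from .states import ConformationCode as Code, classify_residue, reduce_code

    template, quads = _template(sequence, code, regions)
    coords = None
    for _ in range(max_attempts):
        coords = template.coords + rng.normal(0.0, noise_sigma,
                                              template.coords.shape) \
            if noise_sigma > 0 else template.coords.copy()
        if noise_sigma == 0:
            break
        d = dihedrals_batch(coords[quads[:, 0]], coords[quads[:, 1]],
                            coords[quads[:, 2]], coords[quads[:, 3]])
        states = tuple(classify_residue(d[2 * i], d[2 * i + 1], regions)
                       for i in range(3))
        if reduce_code(Code(states), regions) == code and \
                topology_group(ThetaPair(d[6], d[7])) == ideal_group:
            break
    else:
        warnings.warn(f"could not realize code {code} within {max_attempts} "
                      f"noise draws; keeping last sample", stacklevel=2)
    pep = template.copy()
    pep.coords = coords
    return pep


def make_mixture_trajectory(sequence: str, mixture: MixtureSpec,
                            assembly: FilamentSpec | None = None,
                            regions: RegionMap | None = None,
                            placement: GridPlacement | None = None,
                            noise_sigma: float = DEFAULT_NOISE_SIGMA) -> Ensemble:
    """Pseudo-trajectories with per-peptide conformations drawn iid.

    Every peptide in every frame draws a conformation code from the
    mixture, is rebuilt at the basin centres of that code with truncated
    Gaussian coordinate noise (see :func:`_realize_code`), and is either
    dispersed on a lattice in the box (default, emulating monomeric
    ensembles) or stacked along z at the given filament rise.  Returns
    ``n_runs`` independent trajectories.
    """
    from .sidechain import theta_pair, topology_group

    regions = regions or RegionMap.default()
    placement = placement or GridPlacement()
    codes = [c for c, _ in mixture.components]
    weights = np.array([w for _, w in mixture.components], dtype=float)
    ideal_groups = [topology_group(theta_pair(_template(sequence, c, regions)[0], 0))
                    for c in codes]
    seeds = np.random.SeedSequence(mixture.seed).spawn(mixture.n_runs)
    n_pep = placement.n_peptides
    sites = _grid_sites(placement.box, n_pep)
    rise_nm = assembly.resolve_rise() / 10.0 if assembly is not None else None

    runs = []
    for r in range(mixture.n_runs):
        rng = np.random.default_rng(seeds[r])
        frames = []
        for f in range(mixture.n_frames):
            draw = rng.choice(len(codes), size=n_pep, p=weights)
            peptides = []
            for k in range(n_pep):
                pep = _realize_code(sequence, codes[draw[k]], regions,
                                    noise_sigma, rng, ideal_groups[draw[k]])
                pep.coords = pep.coords - pep.coords.mean(axis=0)
                if rise_nm is not None:
                    pep = _align_strand_to_x(pep)
                    pep.coords = pep.coords + np.array([0.0, 0.0, k * rise_nm])
                else:
                    pep.coords = pep.coords + sites[k]
                pep.peptide_ids = np.full(pep.n_atoms, k, dtype=int)
                peptides.append(pep)
            frame = concatenate_frames(peptides, box=placement.box,
                                       renumber=False)
            frame.frame_index = f
            frames.append(frame)
        runs.append(Trajectory(frames=frames, run_id=f"run{r}"))
    return Ensemble(runs=runs)
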