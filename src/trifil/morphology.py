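"""Aggregate detection, filament identification and reference comparison.

Aggregates are connected components of the peptide contact graph (an
edge whenever any interchain particle pair is within the contact
cutoff).  Within an aggregate, in-register parallel filaments are
chains of peptide pairs whose residue-wise CA-CA spacing sits in the
cross-beta range and that share at least one interchain backbone
hydrogen bond.  Sampled conformers can be compared against reference
(crystal-like) conformers by minimum Kabsch RMSD over backbone + CB
atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import kabsch_superpose, min_image_distance
from .interactions import InteractionCriteria, count_contacts, detect_hbonds
from .model import StructureFrame
from .states import RegionMap, classify_peptide

#: Adjacent-chain CA-CA spacing accepted as filament stacking (nm).
RISE_WINDOW = (0.40, 0.60)
#: Atom selection for reference RMSD comparisons (backbone + CB).
RMSD_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass
class AssemblyGraph:
    """Peptide-level contact graph with aggregate components."""

    n_peptides: int
    edges: list[tuple[int, int]]
    components: list[list[int]] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_peptides))
        g.add_edges_from(self.edges)
        return g


def aggregate_components(frame: StructureFrame,
                         criteria: InteractionCriteria | None = None
                         ) -> AssemblyGraph:
    """Contact graph over peptides and its connected components.

    All peptide particles (backbone and sidechain) participate in the
    edge criterion; components are sorted by size (desc), then lowest id.
    """
    criteria = criteria or InteractionCriteria()
    pids = frame.peptides()
    pep_idx = np.flatnonzero(frame.peptide_ids >= 0)
    _, pairs = count_contacts(frame, pep_idx, pep_idx, criteria)
    edges = set()
    for a, b in pairs:
        pa, pb = int(frame.peptide_ids[a]), int(frame.peptide_ids[b])
        if pa != pb:
            edges.add((min(pa, pb), max(pa, pb)))
    g = nx.Graph()
    g.add_nodes_from(int(p) for p in pids)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return AssemblyGraph(n_peptides=len(pids), edges=sorted(edges),
                         components=comps)


def _in_register_spacing(frame: StructureFrame, pid_a: int, pid_b: int) -> float:
    """Mean residue-wise CA-CA distance between two peptides (nm)."""
    d = [min_image_distance(frame.position(pid_a, r, "CA"),
                            frame.position(pid_b, r, "CA"), frame.box)
         for r in (1, 2, 3)]
    return float(np.mean(d))


def detect_filaments(graph: AssemblyGraph, frame: StructureFrame,
                     rise_window: tuple[float, float] = RISE_WINDOW,
                     criteria: InteractionCriteria | None = None
                     ) -> list[list[int]]:
    """In-register stacked chains of peptides within each aggregate.

    A stacking link requires the in-register (residue i to residue i)
    mean CA-CA distance inside ``rise_window`` and at least one
    interchain backbone hydrogen bond between the two peptides.  Link
    components of two or more peptides are returned ordered along their
    principal axis; unlinked peptides are left out (singletons).
    """
    criteria = criteria or InteractionCriteria()
    from .model import reconstruct_amide_hydrogens
    fr = reconstruct_amide_hydrogens(frame)
    hbonds = detect_hbonds(fr, criteria, reconstruct_h=False)
    hb_pairs = set()
    for n_i, _, a_i in hbonds:
        pa, pb = int(fr.peptide_ids[n_i]), int(fr.peptide_ids[a_i])
        hb_pairs.add((min(pa, pb), max(pa, pb)))
    link = nx.Graph()
    for comp in graph.components:
        link.add_nodes_from(comp)
        for i, pa in enumerate(comp):
            for pb in comp[i + 1:]:
                if (pa, pb) not in hb_pairs:
                    continue
                spacing = _in_register_spacing(frame, pa, pb)
                if rise_window[0] <= spacing <= rise_window[1]:
                    link.add_edge(pa, pb)
    filaments = []
    for comp in nx.connected_components(link):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        centroids = np.array([
            np.mean([frame.position(p, r, "CA") for r in (1, 2, 3)], axis=0)
            for p in comp])
        center = centroids.mean(axis=0)
        _, s, vt = np.linalg.svd(centroids - center)
        order = np.argsort(centroids @ vt[0])
        filaments.append([comp[i] for i in order])
    filaments.sort(key=lambda f: f[0])
    return filaments


def interchain_rise(filament: list[int], frame: StructureFrame
                    ) -> tuple[float, float]:
    """Mean and sd of adjacent-chain spacing along a filament, in angstrom.

    The spacing of an adjacent pair is the in-register mean CA-CA
    distance; the filament must be ordered along its axis (as returned
    by :func:`detect_filaments`).
    """
    if len(filament) < 2:
        raise ValueError("a filament needs at least two peptides")
    spacings = [_in_register_spacing(frame, a, b) * 10.0
                for a, b in zip(filament[:-1], filament[1:])]
    return float(np.mean(spacings)), float(np.std(spacings))


@dataclass
class ReferenceConformer:
    """A reference (e.g. crystal) conformer for minimum-RMSD comparison."""

    label: str
    frame: StructureFrame
    code: str | None = None


def _comparison_coords(frame: StructureFrame, peptide_id: int,
                       atoms: tuple[str, ...]) -> np.ndarray:
    coords = []
    for r in (1, 2, 3):
        for name in atoms:
            coords.append(frame.position(peptide_id, r, name))
    return np.array(coords)


def min_rmsd_to_reference(sampled: list[StructureFrame],
                          reference: ReferenceConformer,
                          atoms: tuple[str, ...] = RMSD_ATOMS,
                          regions: RegionMap | None = None
                          ) -> tuple[int, float, str]:
    """Best-matching sampled conformer against a reference structure.

    Every sampled conformer (single-peptide frames) is Kabsch-superposed
    onto the reference over the comparison atom selection; the smallest
    RMSD wins, ties resolved by first occurrence.  Returns the index of
    the best conformer, its RMSD in angstrom and its conformation code.
    """
    if not sampled:
        raise ValueError("no sampled conformers supplied")
    regions = regions or RegionMap.default()
    ref_coords = _comparison_coords(reference.frame,
                                    int(reference.frame.peptides()[0]), atoms)
    best_idx, best_rmsd = None, np.inf
    for i, conf in enumerate(sampled):
        pid = int(conf.peptides()[0])
        coords = _comparison_coords(conf, pid, atoms)
        _, _, rmsd = kabsch_superpose(coords, ref_coords)
        if rmsd < best_rmsd:
            best_idx, best_rmsd = i, rmsd
    best_frame = sampled[best_idx]
    code = str(classify_peptide(best_frame, int(best_frame.peptides()[0]),
                                regions))
    return best_idx, float(best_rmsd), code


def morphology_report(frame: StructureFrame,
                      criteria: InteractionCriteria | None = None) -> dict:
    """Per-frame morphology summary: components, filaments, rises."""
    criteria = criteria or InteractionCriteria()
    graph = aggregate_components(frame, criteria)
    filaments = detect_filaments(graph, frame, criteria=criteria)
    rises = [interchain_rise(f, frame) for f in filaments]
    return {
        "frame_index": int(frame.frame_index),
        "n_peptides": int(frame.n_peptides),
        "n_components": len(graph.components),
        "component_sizes": [len(c) for c in graph.components],
        "filaments": [list(map(int, f)) for f in filaments],
        "rises_angstrom": [{"mean": m, "sd": s} for m, s in rises],
    }
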