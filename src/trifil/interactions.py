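"""Noncovalent-interaction accounting inside fibrous assemblies.

Implements geometric contact counting (two particles within 0.65 nm),
hydrogen-bond detection (donor-acceptor distance < 0.35 nm and
donor-hydrogen-acceptor angle > 120 degrees), sidechain solvent
exposure (coarse water beads in contact with sidechain particles), a
fiber-core filter (peptides within 1 nm of the fibrous segment's axis)
and the per-peptide interaction profile over the six bar families:
Phe-sidechain/water, Ile-sidechain/water, Phe-Phe, Ile-Ile, Phe-Ile
sidechain contacts and interchain backbone hydrogen bonds.

Contact families operate on sidechain particles only (CB and beyond);
all counts except hydrogen bonds are per-residue normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import min_image_distance, pairwise_min_image, planar_angle
from .model import (BACKBONE_NAMES, Ensemble, SOLVENT_NAME, StructureFrame,
                    TopologyError, reconstruct_amide_hydrogens)


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds, defaults exactly as conventionally printed."""

    contact_cutoff: float = 0.65   # nm
    hb_da_cutoff: float = 0.35     # nm, donor-acceptor
    hb_angle_min: float = 120.0    # degrees, donor-H-acceptor
    core_radius: float = 1.0       # nm, fiber-core filter

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hb_da_cutoff", "hb_angle_min",
                     "core_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


PROFILE_FAMILIES = ("phe_sc_water", "ile_sc_water", "phe_phe", "ile_ile",
                    "phe_ile", "hb")

_NONSIDECHAIN = set(BACKBONE_NAMES) | {"CH3", SOLVENT_NAME}


def sidechain_indices(frame: StructureFrame, residue_name: str | None = None
                      ) -> np.ndarray:
    """Indices of sidechain particles (CB and beyond) of amino-acid residues."""
    m = (frame.peptide_ids >= 0)
    m &= np.isin(frame.residue_indices, (1, 2, 3))
    m &= ~np.isin(frame.atom_names, list(_NONSIDECHAIN))
    if residue_name is not None:
        m &= frame.residue_names == residue_name
    return np.flatnonzero(m)


def water_indices(frame: StructureFrame) -> np.ndarray:
    return frame.indices(residue_name=SOLVENT_NAME)


def _residue_key(frame: StructureFrame, idx: np.ndarray) -> np.ndarray:
    """Unique per-(peptide, residue) key; solvent beads get unique keys."""
    key = frame.peptide_ids[idx] * 16 + frame.residue_indices[idx]
    sol = frame.peptide_ids[idx] < 0
    key[sol] = -(idx[sol] + 1) * 16
    return key


def count_contacts(frame: StructureFrame, sel_a: np.ndarray, sel_b: np.ndarray,
                   criteria: InteractionCriteria | None = None
                   ) -> tuple[int, np.ndarray]:
    """Count particle pairs of two selections within the contact cutoff.

    Distances are minimum-image when the frame has a box.  Pairs within
    the same residue of the same peptide are excluded; when the two
    selections are identical each unordered pair is counted once.
    Returns the count and an (n, 2) array of atom-index pairs.
    """
    criteria = criteria or InteractionCriteria()
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        return 0, np.empty((0, 2), dtype=int)
    same = len(sel_a) == len(sel_b) and np.array_equal(np.sort(sel_a),
                                                       np.sort(sel_b))
    cutoff = criteria.contact_cutoff
    if frame.box is not None:
        L = frame.box.lengths
        coords_a = np.mod(frame.coords[sel_a], L)
        coords_b = np.mod(frame.coords[sel_b], L)
        tree_a = cKDTree(coords_a, boxsize=L)
        if same:
            raw = [(sel_a[i], sel_a[j])
                   for i, j in tree_a.query_pairs(cutoff)]
        else:
            tree_b = cKDTree(coords_b, boxsize=L)
            neighbours = tree_a.query_ball_tree(tree_b, cutoff)
            raw = [(sel_a[i], sel_b[j])
                   for i, nb in enumerate(neighbours) for j in nb]
    else:
        d = pairwise_min_image(frame.coords[sel_a], frame.coords[sel_b], None)
        if same:
            ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
            raw = list(zip(sel_a[ii], sel_a[jj]))
        else:
            ii, jj = np.nonzero(d <= cutoff)
            raw = list(zip(sel_a[ii], sel_b[jj]))
    if not raw:
        return 0, np.empty((0, 2), dtype=int)
    pairs = np.array(raw, dtype=int)
    if not same:
        # drop duplicates arising from overlapping selections
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        if len(pairs) == 0:
            return 0, np.empty((0, 2), dtype=int)
    ka = _residue_key(frame, pairs[:, 0])
    kb = _residue_key(frame, pairs[:, 1])
    pairs = pairs[ka != kb]
    if not same and len(pairs):
        # count each unordered pair once when selections overlap
        canon = np.sort(pairs, axis=1)
        pairs = np.unique(canon, axis=0)
    return len(pairs), pairs


def hbond_participants(frame: StructureFrame, include_caps: bool = True):
    """Donor (N, H) pairs and acceptor O indices of backbone/cap amides."""
    donor_res = (1, 2, 3, 4) if include_caps else (1, 2, 3)
    acceptor_res = (0, 1, 2, 3) if include_caps else (1, 2, 3)
    donors = []
    for i in np.flatnonzero(frame.mask(atom_name="N")):
        pid = int(frame.peptide_ids[i])
        r = int(frame.residue_indices[i])
        if pid < 0 or r not in donor_res:
            continue
        h = frame.indices(peptide_id=pid, residue_index=r, atom_name="H")
        if len(h) == 0:
            raise TopologyError(
                f"peptide {pid} residue {r}: no amide H for donor N "
                f"(reconstruct hydrogens first)")
        donors.append((i, int(h[0])))
    acc_mask = frame.mask(atom_name="O") & (frame.peptide_ids >= 0) \
        & np.isin(frame.residue_indices, acceptor_res)
    return donors, np.flatnonzero(acc_mask)


def detect_hbonds(frame: StructureFrame, criteria: InteractionCriteria | None = None,
                  include_intra: bool = False, include_caps: bool = True,
                  reconstruct_h: bool = True) -> list[tuple[int, int, int]]:
    """Geometric hydrogen bonds as (donor N, H, acceptor O) atom indices.

    Donors are backbone and cap amide N-H groups, acceptors backbone and
    cap carbonyl oxygens.  A bond requires donor-acceptor distance below
    the cutoff and a donor-hydrogen-acceptor angle above the minimum.
    By default only interchain bonds (distinct peptides) are reported.
    """
    criteria = criteria or InteractionCriteria()
    if reconstruct_h:
        needs_h = any(
            not frame.has_atom(pid, r, "H")
            for pid in frame.peptides() for r in (1, 2, 3, 4)
            if frame.has_atom(pid, r, "N"))
        if needs_h:
            frame = reconstruct_amide_hydrogens(frame)
    donors, acceptors = hbond_participants(frame, include_caps)
    if not donors or len(acceptors) == 0:
        return []
    out = []
    box = frame.box
    acc_coords = frame.coords[acceptors]
    for n_idx, h_idx in donors:
        n_pos = frame.coords[n_idx]
        for a_idx, a_pos in zip(acceptors, acc_coords):
            if not include_intra and \
                    frame.peptide_ids[n_idx] == frame.peptide_ids[a_idx]:
                continue
            if min_image_distance(n_pos, a_pos, box) >= criteria.hb_da_cutoff:
                continue
            if planar_angle(n_pos, frame.coords[h_idx], a_pos) > \
                    criteria.hb_angle_min:
                out.append((n_idx, h_idx, int(a_idx)))
    return out


def solvent_exposure(frame: StructureFrame,
                     residues: list[tuple[int, int]] | None = None,
                     criteria: InteractionCriteria | None = None
                     ) -> dict[tuple[int, int], int]:
    """Water beads in contact with each residue's sidechain particles.

    A bead counts once per residue no matter how many sidechain
    particles it touches; the contact cutoff is reused for
    solvent contacts.
    """
    criteria = criteria or InteractionCriteria()
    w_idx = water_indices(frame)
    if residues is None:
        residues = [(int(pid), r) for pid in frame.peptides() for r in (1, 2, 3)]
    counts: dict[tuple[int, int], int] = {}
    if len(w_idx) == 0:
        return {key: 0 for key in residues}
    if frame.box is not None:
        L = frame.box.lengths
        w_tree = cKDTree(np.mod(frame.coords[w_idx], L), boxsize=L)
    else:
        w_tree = cKDTree(frame.coords[w_idx])
    for pid, r in residues:
        sc = sidechain_indices(frame)
        sc = sc[(frame.peptide_ids[sc] == pid) & (frame.residue_indices[sc] == r)]
        if len(sc) == 0:
            counts[(pid, r)] = 0
            continue
        coords = frame.coords[sc]
        if frame.box is not None:
            coords = np.mod(coords, frame.box.lengths)
        hits = w_tree.query_ball_point(coords, criteria.contact_cutoff)
        beads = {b for lst in hits for b in lst}
        counts[(pid, r)] = len(beads)
    return counts


def core_filter(frame: StructureFrame,
                criteria: InteractionCriteria | None = None,
                mode: str = "axis") -> list[int]:
    """Peptides near the interior of the largest fibrous segment.

    The fiber axis is the principal axis of the largest aggregate's
    peptide-centroid cloud; peptides whose centroid lies within
    ``core_radius`` of that axis are retained.  ``mode='point'``
    switches to the literal distance-to-centroid reading.  Rigid-motion
    invariant.
    """
    from .morphology import aggregate_components

    criteria = criteria or InteractionCriteria()
    pids = frame.peptides()
    if len(pids) == 0:
        raise ValueError("core_filter: frame contains no peptides")
    graph = aggregate_components(frame, criteria)
    largest = max(graph.components, key=lambda c: (len(c), -min(c)))
    centroids = {int(pid): frame.peptide_centroid(pid) for pid in pids}
    cloud = np.array([centroids[p] for p in largest])
    center = cloud.mean(axis=0)
    axis = None
    if mode == "axis" and len(largest) >= 2:
        u, s, vt = np.linalg.svd(cloud - center)
        if s[0] > 1e-9:
            axis = vt[0]
    kept = []
    for pid in pids:
        d = centroids[int(pid)] - center
        if axis is not None:
            d = d - np.dot(d, axis) * axis
        if np.linalg.norm(d) <= criteria.core_radius:
            kept.append(int(pid))
    return kept


@dataclass
class InteractionProfile:
    """Across-run summary of the six per-peptide interaction families."""

    summary: pd.DataFrame          # index family, columns mean/sd
    per_run: pd.DataFrame          # index family, one column per run

    def to_json(self, path: str) -> None:
        def cell(fam, col):
            v = float(self.summary.loc[fam, col])
            return None if np.isnan(v) else v  # family absent from sequence

        payload = {fam: {"mean": cell(fam, "mean"), "sd": cell(fam, "sd")}
                   for fam in self.summary.index}
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _residue_counts(frame: StructureFrame, pid: int) -> dict[str, int]:
    seq = frame.peptide_sequence(pid)
    return {"PHE": seq.count("F"), "ILE": seq.count("I")}


def _frame_metrics(frame: StructureFrame, criteria: InteractionCriteria,
                   normalize: bool) -> pd.DataFrame:
    """Per-peptide family values for the core peptides of one frame."""
    kept = core_filter(frame, criteria)
    if not kept:
        raise ValueError("interaction_profile: core filter left an empty "
                         "peptide selection")
    frame = reconstruct_amide_hydrogens(frame)
    sc_phe = sidechain_indices(frame, "PHE")
    sc_ile = sidechain_indices(frame, "ILE")
    _, pp = count_contacts(frame, sc_phe, sc_phe, criteria)
    _, ii = count_contacts(frame, sc_ile, sc_ile, criteria)
    _, pi = count_contacts(frame, sc_phe, sc_ile, criteria)
    hbonds = detect_hbonds(frame, criteria, reconstruct_h=False)
    water = solvent_exposure(frame, criteria=criteria)

    def pairs_touching(pairs: np.ndarray, pid: int) -> int:
        if len(pairs) == 0:
            return 0
        m = (frame.peptide_ids[pairs[:, 0]] == pid) | \
            (frame.peptide_ids[pairs[:, 1]] == pid)
        return int(m.sum())

    rows = {}
    for pid in kept:
        n_res = _residue_counts(frame, pid)
        seq = frame.peptide_sequence(pid)
        phe_w = sum(water[(pid, r + 1)] for r, ch in enumerate(seq) if ch == "F")
        ile_w = sum(water[(pid, r + 1)] for r, ch in enumerate(seq) if ch == "I")
        n_hb = sum(1 for (n_i, _, a_i) in hbonds
                   if pid in (frame.peptide_ids[n_i], frame.peptide_ids[a_i]))
        vals = {
            "phe_sc_water": (phe_w, n_res["PHE"]),
            "ile_sc_water": (ile_w, n_res["ILE"]),
            "phe_phe": (pairs_touching(pp, pid), n_res["PHE"]),
            "ile_ile": (pairs_touching(ii, pid), n_res["ILE"]),
            "phe_ile": (pairs_touching(pi, pid),
                        n_res["PHE"] + n_res["ILE"]),
            "hb": (n_hb, 1),
        }
        row = {}
        for fam, (count, divisor) in vals.items():
            if fam != "hb" and divisor == 0:
                row[fam] = np.nan      # family not defined for this sequence
            else:
                row[fam] = count / divisor if normalize else float(count)
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def interaction_profile(ensemble: Ensemble,
                        criteria: InteractionCriteria | None = None,
                        normalize: bool = True) -> InteractionProfile:
    """Mean per-peptide interaction profile with across-run error bars.

    Applies the core filter per frame, averages each family over core
    peptides and frames within a run, then reports mean and sample
    standard deviation across runs.
    """
    criteria = criteria or InteractionCriteria()
    per_run = {}
    for run in ensemble.runs:
        frames = [_frame_metrics(f, criteria, normalize) for f in run.frames]
        stacked = pd.concat(frames, axis=0)
        per_run[run.run_id] = stacked.mean(axis=0, skipna=True)
    per_run_df = pd.DataFrame(per_run).reindex(list(PROFILE_FAMILIES))
    mean = per_run_df.mean(axis=1)
    sd = per_run_df.std(axis=1, ddof=1) if per_run_df.shape[1] > 1 else \
        pd.Series(0.0, index=per_run_df.index)
    summary = pd.DataFrame({"mean": mean, "sd": sd.fillna(0.0)})
    return InteractionProfile(summary=summary, per_run=per_run_df)
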