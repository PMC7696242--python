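"""Independent brute-force oracles used to cross-check the kernels.

These deliberately use different formulations from the package
implementations: plane-projection for torsions, a 27-image enumeration
for periodic distances, the Horn quaternion eigenvalue method for
superposition, and O(n^2) Python loops for contacts and hydrogen bonds.
"""

from __future__ import annotations

import itertools

import numpy as np


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Torsion via projection onto the plane perpendicular to the axis."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    u = p1 - p2
    v = p4 - p3
    u_perp = u - np.dot(u, axis) * axis
    v_perp = v - np.dot(v, axis) * axis
    cosang = np.dot(u_perp, v_perp) / (np.linalg.norm(u_perp)
                                       * np.linalg.norm(v_perp))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # sign: positive if v_perp is clockwise from u_perp looking along axis
    sign = np.sign(np.dot(np.cross(u_perp, v_perp), axis))
    val = sign * ang if sign != 0 else ang
    if val <= -180.0:
        val += 360.0
    return float(val)


def angle_oracle(p1, p2, p3) -> float:
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def min_image_oracle(a, b, lengths) -> float:
    """Minimum distance over all 27 neighbour images."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    L = np.asarray(lengths, float)
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = L * np.array([sx, sy, sz])
        best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def quaternion_rmsd_oracle(mobile, reference) -> float:
    """Minimal RMSD via Horn's quaternion eigenvalue method (angstrom)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.max(np.linalg.eigvalsh(K))
    sq_dev = np.sum(P0 ** 2) + np.sum(Q0 ** 2) - 2.0 * lam_max
    msd = max(sq_dev, 0.0) / len(P)
    return float(np.sqrt(msd)) * 10.0


def contact_count_oracle(frame, sel_a, sel_b, cutoff) -> int:
    """O(n^2) contact count mirroring the package's pair semantics:
    unordered unique pairs, intra-residue pairs excluded."""
    def res_key(i):
        pid = frame.peptide_ids[i]
        if pid < 0:
            return ("sol", i)
        return (int(pid), int(frame.residue_indices[i]))

    lengths = frame.box.lengths if frame.box is not None else None
    hits = set()
    for i in sel_a:
        for j in sel_b:
            if i == j or res_key(i) == res_key(j):
                continue
            d = frame.coords[i] - frame.coords[j]
            if lengths is not None:
                d = d - lengths * np.round(d / lengths)
            if np.linalg.norm(d) <= cutoff:
                hits.add((min(i, j), max(i, j)))
    return len(hits)


def hbond_oracle(frame, da_cutoff, angle_min, include_intra=False) -> set:
    """Brute-force donor/acceptor enumeration over backbone amides.

    Returns the set of (donor N index, acceptor O index) pairs.
    """
    lengths = frame.box.lengths if frame.box is not None else None
    donors = []
    for i in range(frame.n_atoms):
        if frame.atom_names[i] != "N" or frame.peptide_ids[i] < 0:
            continue
        if frame.residue_indices[i] not in (1, 2, 3, 4):
            continue
        h = [j for j in range(frame.n_atoms)
             if frame.atom_names[j] == "H"
             and frame.peptide_ids[j] == frame.peptide_ids[i]
             and frame.residue_indices[j] == frame.residue_indices[i]]
        donors.append((i, h[0]))
    acceptors = [i for i in range(frame.n_atoms)
                 if frame.atom_names[i] == "O" and frame.peptide_ids[i] >= 0
                 and frame.residue_indices[i] in (0, 1, 2, 3)]
    found = set()
    for n_i, h_i in donors:
        for a_i in acceptors:
            if not include_intra and \
                    frame.peptide_ids[n_i] == frame.peptide_ids[a_i]:
                continue
            d = frame.coords[n_i] - frame.coords[a_i]
            if lengths is not None:
                d = d - lengths * np.round(d / lengths)
            if np.linalg.norm(d) >= da_cutoff:
                continue
            if angle_oracle(frame.coords[n_i], frame.coords[h_i],
                            frame.coords[a_i]) > angle_min:
                found.add((n_i, a_i))
    return found
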