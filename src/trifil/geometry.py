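"""Low-level geometric kernels shared by every analysis module.

Conventions
-----------
* Cartesian coordinates are in nanometres.
* Angles are in degrees.  Torsions follow the IUPAC sign convention
  (positive clockwise when looking from the second towards the third
  defining atom) and lie in the half-open interval ``(-180, 180]``.
* Periodic systems are restricted to orthorhombic boxes; superposition
  RMSD is *reported* in angstroms, matching the units customary for
  fibril spacings and structural comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Vectors shorter than this (nm) are treated as degenerate.
DEGENERACY_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent input geometry."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        edges = (self.lx, self.ly, self.lz)
        if not all(np.isfinite(edges)) or min(edges) <= 0:
            raise GeometryError(f"box edges must be positive and finite, got {edges}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return float(self.lx * self.ly * self.lz)

    @classmethod
    def from_vectors(cls, vectors: np.ndarray) -> "Box":
        """Build from a 3x3 lattice-vector matrix, rejecting triclinic cells."""
        v = np.asarray(vectors, dtype=float)
        if v.shape != (3, 3):
            raise GeometryError(f"expected a 3x3 lattice matrix, got shape {v.shape}")
        off_diag = v - np.diag(np.diag(v))
        if np.any(np.abs(off_diag) > 1e-6):
            raise GeometryError("only orthorhombic boxes are supported")
        return cls(*np.diag(v))


def _vec(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("coordinates must be finite")
    return a


def _wrap_halfopen(angle: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    if a <= -180.0:
        a += 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees) defined by four points.

    The same kernel evaluates backbone phi/psi and the sidechain
    rotation angle theta (torsion of the two CA->CB vectors about the
    CA-CA axis).

    Raises
    ------
    GeometryError
        If consecutive points coincide or the three bond vectors are
        collinear, so no torsion is defined.
    """
    p1, p2, p3, p4 = _vec(p1), _vec(p2), _vec(p3), _vec(p4)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < DEGENERACY_TOL:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < DEGENERACY_TOL or np.linalg.norm(n2) < DEGENERACY_TOL:
        raise GeometryError("collinear points in dihedral")
    b2_hat = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2_hat))
    return _wrap_halfopen(np.degrees(np.arctan2(y, x)))


def dihedrals_batch(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                    p4: np.ndarray) -> np.ndarray:
    """Vectorized signed torsions (degrees) for (n, 3) point quadruples.

    Same convention as :func:`dihedral`; degenerate rows yield NaN
    instead of raising.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b2_hat = b2 / b2n
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * b2_hat, axis=-1)
        out = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < DEGENERACY_TOL) | \
        (np.linalg.norm(n2, axis=-1) < DEGENERACY_TOL)
    out = np.where(bad, np.nan, out)
    out = np.where(out <= -180.0, out + 360.0, out)
    return out


def planar_angle(p1, p2, p3) -> float:
    """Angle at the vertex ``p2`` in degrees, in [0, 180]."""
    p1, p2, p3 = _vec(p1), _vec(p2), _vec(p3)
    u = p1 - p2
    v = p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < DEGENERACY_TOL or nv < DEGENERACY_TOL:
        raise GeometryError("coincident points in planar angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def min_image_displacement(a, b, box: Box | None = None) -> np.ndarray:
    """Displacement b->a under the minimum-image convention."""
    d = _vec(a) - _vec(b)
    if box is not None:
        L = box.lengths
        d -= L * np.round(d / L)
    return d


def min_image_distance(a, b, box: Box | None = None) -> float:
    """Shortest distance (nm) over periodic images; Euclidean when no box."""
    return float(np.linalg.norm(min_image_displacement(a, b, box)))


def pairwise_min_image(coords_a: np.ndarray, coords_b: np.ndarray,
                       box: Box | None = None) -> np.ndarray:
    """Dense (n, m) matrix of minimum-image distances."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        L = box.lengths
        d -= L * np.round(d / L)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_coords(coords: np.ndarray, box: Box) -> np.ndarray:
    """Wrap coordinates into the primary image [0, L)."""
    return np.mod(np.asarray(coords, dtype=float), box.lengths)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays in nm, n >= 3, equal length.

    Returns
    -------
    rotation : (3, 3) ndarray
    translation : (3,) ndarray
        Such that ``mobile @ rotation.T + translation`` best fits
        ``reference`` in the least-squares sense.
    rmsd : float
        Minimal RMSD, reported in angstroms.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"length mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise GeometryError("superposition requires >= 3 points of shape (n, 3)")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P0 @ R.T
    rmsd_nm = float(np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=1))))
    t = qc - pc @ R.T
    return R, t, rmsd_nm * 10.0


def raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD in angstroms without superposition (coordinates in nm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError("length mismatch in raw_rmsd")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))) * 10.0


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A, B, C.

    D is ``bond`` nm from C, the B-C-D angle is ``angle_deg`` and the
    A-B-C-D torsion is ``torsion_deg`` (natural extension reference
    frame construction).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis through the origin."""
    u = _vec(axis)
    n = np.linalg.norm(u)
    if n < DEGENERACY_TOL:
        raise GeometryError("zero-length rotation axis")
    u = u / n
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)
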