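"""Frame-level geometric descriptors and their per-trajectory series.

Distances are in angstrom, angles in degrees.  All descriptors are invariant
under rigid motion of the frame; the plane angle is deliberately *not*
folded to [0, 90] because its orientation (atom order of each triple)
carries meaning for the stereochemistry criterion, while the principal-axis
angle *is* folded because axes are unsigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import DegenerateGeometryError, DescriptorSeries, Frame, Trajectory

__all__ = [
    "distance",
    "min_group_distance",
    "plane_angle",
    "dihedral",
    "superpose_rmsd",
    "rmsd_series",
    "geometric_center_distance",
    "principal_axis_angle",
    "SuperpositionResult",
]

_COLLINEAR_TOL = 1e-9


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance between atoms ``i`` and ``j`` in angstrom."""
    a, b = frame.coords[i], frame.coords[j]
    return float(np.linalg.norm(a - b))


def min_group_distance(
    frame: Frame, group_a: Sequence[int], group_b: Sequence[int]
) -> tuple[float, tuple[int, int]]:
    """Minimum pairwise distance between two atom groups and the achieving
    pair; ties broken by lowest (index_a, index_b)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("min_group_distance: empty atom group")
    ga = sorted(int(i) for i in group_a)
    gb = sorted(int(j) for j in group_b)
    d = cdist(frame.coords[ga], frame.coords[gb])
    flat = np.argmin(d)  # first occurrence wins -> lowest-index pair
    ia, ib = np.unravel_index(flat, d.shape)
    return float(d[ia, ib]), (ga[ia], gb[ib])


def _plane_normal(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    n = np.cross(q - p, r - q)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(q - p) * np.linalg.norm(r - q), 1e-300)
    if norm / scale < _COLLINEAR_TOL:
        raise DegenerateGeometryError("plane atoms are collinear")
    return n / norm


def plane_angle(
    frame: Frame, triple_a: Sequence[int], triple_b: Sequence[int]
) -> float:
    """Angle in [0, 180] degrees between the oriented normals of two atom
    planes.

    Normals are oriented by the listed atom order, n = (b-a) x (c-b); the
    angle is not folded to [0, 90], so the atom order of each triple is part
    of the contract.
    """
    a, b, c = (frame.coords[i] for i in triple_a)
    d, e, f = (frame.coords[i] for i in triple_b)
    n1 = _plane_normal(a, b, c)
    n2 = _plane_normal(d, e, f)
    cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def dihedral(frame: Frame, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle i-j-k-l in degrees, IUPAC sign convention.

    cis (eclipsed) = 0, trans = 180; range (-180, 180].
    """
    p0, p1, p2, p3 = (frame.coords[x] for x in (i, j, k, l))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    n1 = np.linalg.norm(b1)
    if n1 < _COLLINEAR_TOL:
        raise DegenerateGeometryError("central dihedral atoms coincide")
    b1u = b1 / n1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < _COLLINEAR_TOL or np.linalg.norm(w) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("three consecutive dihedral atoms are collinear")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1u, v), w))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3) proper rotation applied to the mobile frame
    translation: np.ndarray  # (3,)
    rmsd: float  # angstrom, after superposition


def superpose_rmsd(
    frame_a: Frame, frame_b: Frame, selection: Sequence[int]
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``frame_b`` onto ``frame_a``
    over ``selection`` (Kabsch, proper rotation enforced).

    The returned transform maps mobile coordinates x_b to R @ x_b + t; the
    RMSD is computed after applying it.
    """
    sel = list(selection)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    a = frame_a.coords[sel]
    b = frame_b.coords[sel]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - ca, b - cb)
    rmat = rot.as_matrix()
    t = ca - rmat @ cb
    # recompute the residual directly; the rssd reported by align_vectors
    # carries sqrt(machine-eps) noise near zero
    fitted = (b - cb) @ rmat.T + ca
    rmsd = float(np.sqrt(np.mean(np.sum((a - fitted) ** 2, axis=1))))
    return SuperpositionResult(rotation=rmat, translation=t, rmsd=rmsd)


def rmsd_series(
    trajectory: Trajectory,
    selection: Sequence[int],
    reference: Optional[Frame] = None,
    name: str = "rmsd",
) -> DescriptorSeries:
    """Per-frame RMSD to a reference frame (default: first frame) after
    optimal superposition over ``selection``."""
    ref = trajectory.frames[0] if reference is None else reference
    ids, vals = [], []
    for fr in trajectory:
        try:
            res = superpose_rmsd(ref, fr, selection)
        except (ValueError, DegenerateGeometryError) as exc:
            raise type(exc)(f"frame {fr.frame_id}: {exc}") from exc
        ids.append(fr.frame_id)
        vals.append(res.rmsd)
    return DescriptorSeries(name=name, frame_ids=np.array(ids), values=np.array(vals), unit="angstrom")


def geometric_center_distance(
    frame: Frame, set_a: Sequence[int], set_b: Sequence[int]
) -> float:
    """Distance between the unweighted centroids of two atom sets."""
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("geometric_center_distance: empty atom set")
    ca = frame.coords[list(set_a)].mean(axis=0)
    cb = frame.coords[list(set_b)].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Eigenvector of the largest eigenvalue of the (unweighted) gyration
    tensor; raises if that eigenvalue is degenerate."""
    if coords.shape[0] < 4:
        raise ValueError("principal axis needs at least 4 points")
    centered = coords - coords.mean(axis=0)
    gyr = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(gyr)
    if evals[-1] <= 0:
        raise DegenerateGeometryError("degenerate point set: zero gyration")
    if (evals[-1] - evals[-2]) / evals[-1] < 1e-6:
        raise DegenerateGeometryError("axis ambiguous: largest gyration eigenvalue degenerate")
    return evecs[:, -1]


def principal_axis_angle(
    frame: Frame, set_a: Sequence[int], set_b: Sequence[int]
) -> float:
    """Angle in [0, 90] degrees between the longest principal axes of the
    gyration tensors of two point sets (axes are unsigned, hence folded)."""
    u = _principal_axis(frame.coords[list(set_a)])
    v = _principal_axis(frame.coords[list(set_b)])
    cosang = abs(float(np.dot(u, v)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
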