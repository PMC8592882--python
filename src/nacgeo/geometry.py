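"""Vector geometry and rigid-body superposition.

All distances are in Å and all angles are reported in degrees; cosines are
taken in radians at a single conversion point (:func:`angle` /
``np.cos(np.radians(...))`` in callers).  RMSD is mass-unweighted (uniform
weights), the cpptraj-style default for coordinate RMSD.

The superposition is the classic Kabsch SVD solution with the reflection
branch handled explicitly: the rotation returned always has det(R) = +1,
so the fit is a proper rigid motion even for near-degenerate atom sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "distance",
    "angle",
    "kabsch",
    "superpose",
    "pairwise_rmsd",
    "rmsd_to_reference",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation then translation)."""

    rotation: np.ndarray  # 3x3 orthonormal, det = +1
    translation: np.ndarray  # length-3, Å

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def distance(a, b) -> float:
    """Euclidean distance |a - b| in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


def angle(a, vertex, c) -> float:
    """Interior angle a-vertex-c in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u1 = a - v
    u2 = c - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle undefined: zero-length arm at the vertex")
    cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (N, 3) arrays of paired atoms, N >= 3.

    Returns
    -------
    (transform, rmsd) where ``transform.apply(mobile)`` best fits
    ``reference`` and rmsd is the root-mean-square residual after the fit.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 paired atoms")
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    P0 = P - cP
    Q0 = Q - cQ
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # Collinear (or planar-degenerate) sets make the rotation about the
    # degenerate axis arbitrary; the fit itself is still well defined.
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn("degenerate (collinear) atom set; rotation is not unique", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    # rmsd from the actual residuals: the singular-value shortcut
    # E0 - 2*sum(S) cancels catastrophically near zero
    resid = Q0 - P0 @ R.T
    return RigidTransform(R, t), float(np.sqrt((resid**2).sum() / n))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Convenience: transformed mobile coordinates plus the fit RMSD."""
    tf, rmsd = kabsch(mobile, reference)
    return tf.apply(mobile), rmsd


def _batch_rmsd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Best-fit RMSD for stacked coordinate pairs.

    A, B : (M, N, 3) centered-or-not coordinate batches (paired along M).
    Returns an (M,) array.  Uses the Kabsch singular values only, so no
    rotation matrices are materialised.
    """
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    H = np.einsum("mni,mnj->mij", A, B)
    U, _, Vt = np.linalg.svd(H)
    sign = np.where(np.linalg.det(U @ Vt) < 0, -1.0, 1.0)
    Vt[:, 2, :] *= sign[:, None]
    R = np.einsum("mji,mkj->mik", Vt, U)  # V @ diag(1,1,d) @ U.T
    resid = B - np.einsum("mni,mki->mnk", A, R)  # B - A @ R.T
    n = A.shape[1]
    return np.sqrt((resid**2).sum(axis=(1, 2)) / n)


def rmsd_to_reference(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Best-fit RMSD of each frame (F, N, 3) to one reference (N, 3)."""
    frames = np.asarray(frames, dtype=float)
    ref = np.broadcast_to(np.asarray(reference, dtype=float), frames.shape)
    return _batch_rmsd(frames, ref)


def pairwise_rmsd(traj, sel=None) -> np.ndarray:
    """Symmetric F x F matrix of pairwise best-fit RMSD (Å).

    ``traj`` may be a :class:`~nacgeo.structio.Trajectory` or a raw
    (F, N, 3) array; ``sel`` restricts the metric to a selection
    (expression string, :class:`AtomSelection`, or index array).
    """
    from .structio import AtomSelection, Trajectory, select

    if isinstance(traj, Trajectory):
        coords = traj.coords
        if sel is not None:
            if isinstance(sel, (str, AtomSelection)):
                idx = select(traj.topology, sel)
            else:
                idx = np.asarray(sel, dtype=int)
            if idx.size == 0:
                raise ValueError("empty selection for pairwise RMSD")
            coords = coords[:, idx, :]
    else:
        coords = np.asarray(traj, dtype=float)
        if sel is not None:
            coords = coords[:, np.asarray(sel, dtype=int), :]
    F = coords.shape[0]
    if F < 2:
        raise ValueError("pairwise RMSD requires at least 2 frames")
    iu, ju = np.triu_indices(F, k=1)
    vals = np.empty(iu.size)
    # chunk the pair list to bound peak memory on long trajectories
    chunk = max(1, int(2e7) // max(coords.shape[1], 1))
    for lo in range(0, iu.size, chunk):
        hi = min(lo + chunk, iu.size)
        vals[lo:hi] = _batch_rmsd(coords[iu[lo:hi]], coords[ju[lo:hi]])
    out = np.zeros((F, F))
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out
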