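"""Rigid-body transforms and least-squares superposition.

The superposition is the closed-form Kabsch-Umeyama solution: given two
matched point sets it returns the proper rotation and translation that
minimise the RMSD of the moved set onto the fixed set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["RigidTransform", "superpose"]

#: tolerance for orthogonality / unit-determinant checks
_ORTHO_TOL = 1e-8
#: smallest singular value of the centred coordinate matrix below which a
#: point set is treated as coplanar/collinear and the superposition rejected
_DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t in Angstroms."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector)."""
        xyz = np.asarray(coords, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def superpose(query_pts: np.ndarray, target_pts: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper rigid motion mapping ``target_pts`` onto ``query_pts``.

    Parameters
    ----------
    query_pts, target_pts
        Matched (N, 3) coordinate arrays, N >= 3, in corresponding order.

    Returns
    -------
    (transform, rmsd)
        ``transform.apply(target_pts)`` is the least-squares fit onto
        ``query_pts``; ``rmsd`` is its residual in Angstroms.

    Raises
    ------
    DegenerateGeometryError
        If either point set is (near-)coplanar or collinear, judged by the
        smallest singular value of the centred coordinates.
    """
    P = np.asarray(query_pts, dtype=float)
    Q = np.asarray(target_pts, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (N, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 matched points")

    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc

    for label, X in (("query", P0), ("target", Q0)):
        if np.linalg.svd(X, compute_uv=False)[-1] < _DEGENERACY_TOL:
            raise DegenerateGeometryError(f"{label} points are coplanar/collinear")

    # covariance of target against query; SVD gives the optimal rotation,
    # with the determinant correction enforcing a proper rotation
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc

    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd
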