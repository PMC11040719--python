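"""Per-atom solvent-accessible surface area (Shrake-Rupley).

Test-sphere SASA on heavy atoms: each atom is surrounded by a deterministic
golden-spiral shell of points at (vdW radius + probe radius); points not
buried inside any neighbouring shell count toward the accessible area.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["shrake_rupley_sasa", "VDW_RADII", "PROBE_RADIUS", "N_SPHERE_POINTS"]

# heavy-atom van der Waals radii (Angstroms); values as used by common
# SASA implementations (Bondi-type)
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.80
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


def _golden_spiral(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors (deterministic)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom SASA in A^2 for heavy atoms at ``coords``.

    Parameters
    ----------
    coords : (N, 3) array
    elements : element symbols, one per atom (unknown symbols get a
        generic 1.8 A radius)
    """
    xyz = np.asarray(coords, dtype=float)
    n = len(xyz)
    if n == 0:
        return np.zeros(0)
    radii = np.array([VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in elements])
    shell = radii + probe_radius
    sphere = _golden_spiral(n_points)

    tree = cKDTree(xyz)
    areas = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + shell[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], shell[i] + shell.max()) if j != i]
        if neighbors:
            nb = np.array(neighbors)
            # a test point is buried if inside any neighbour's solvent shell
            d2 = ((pts[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (shell[nb] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * shell[i] ** 2 * accessible / n_points
    return areas
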