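"""Tetrahedral pattern generation and conversion to toleranced database filters.

Over one chain's interface points, every 4-subset whose six pairwise
distances lie inside [minDist, maxDist] forms a candidate tetrahedron.
Candidates are sorted by decreasing size (sum of edge lengths), greedily
selected so every coverable point sits in at least one kept tetrahedron,
topped up to ``noffilters``, and finally annotated into property- and
distance-constrained filters for the interface database.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import TooSmallInterfaceError
from .interface import ChainInterface, InterfacePoint

__all__ = [
    "SearchParams",
    "Tetrahedron",
    "TetrahedronFilter",
    "enumerate_tetrahedra",
    "select_filters",
    "annotate_filter",
    "make_filters",
    "constraint_key",
    "filters_to_text",
    "filters_from_text",
]

#: above this point count, enumeration is restricted to each point's
#: nearest in-range neighbours to bound the O(n^4) subset scan
FULL_ENUMERATION_LIMIT = 120
NEIGHBOR_CAP = 20

#: edge order of a tetrahedron over corners (0,1,2,3)
EDGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class SearchParams:
    """Every tunable of the search pipeline, with screening defaults.

    Distances in Angstroms.  ``prefilter_radius``, ``kdtree_threshold`` and
    ``interface_cutoff`` are fixed characteristics of the method rather
    than user-level knobs.
    """

    min_dist: float = 1.0
    max_dist: float = 14.0
    dist_tolerance: float = 1.0
    scoring_radius: float = 1.5
    noffilters: int = 30
    filter_hierarchy_level: int = 2
    two_sided_scoring: bool = False
    reduction_mode: str = "calpha"
    prefilter_radius: float = 6.0
    kdtree_threshold: int = 100
    interface_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if not (0 < self.min_dist < self.max_dist):
            raise ValueError("require 0 < minDist < maxDist")
        if self.dist_tolerance <= 0 or self.scoring_radius <= 0:
            raise ValueError("distTolerance and scoringRadius must be positive")
        if self.noffilters < 1:
            raise ValueError("noffilters must be >= 1")
        if self.filter_hierarchy_level not in (1, 2, 3, 4):
            raise ValueError("filterHierarchyLevel must be 1..4")
        if self.reduction_mode not in ("calpha", "restricted", "all"):
            raise ValueError("reduction_mode must be calpha, restricted or all")

    @classmethod
    def runtime_optimized(cls, **overrides) -> "SearchParams":
        """Fast screening preset: minDist 1, maxDist 14, scoringRadius 1.5, distTolerance 1.0."""
        base = dict(min_dist=1.0, max_dist=14.0, scoring_radius=1.5, dist_tolerance=1.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def accuracy_optimized(cls, **overrides) -> "SearchParams":
        """Accuracy preset: minDist 2, maxDist 14, scoringRadius 1.5, distTolerance 1.5."""
        base = dict(min_dist=2.0, max_dist=14.0, scoring_radius=1.5, dist_tolerance=1.5)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Tetrahedron:
    """Four interface-point indices plus the six pairwise edge lengths."""

    corner_indices: tuple[int, int, int, int]
    edge_lengths: tuple[float, ...]

    @property
    def size(self) -> float:
        return float(sum(self.edge_lengths))


@dataclass(frozen=True)
class TetrahedronFilter:
    """A database query: four property constraints + six toleranced edges."""

    corner_constraints: tuple[tuple, tuple, tuple, tuple]
    edge_intervals: tuple[tuple[float, float], ...]
    hierarchy_level: int
    source: tuple  # (interface key, corner indices)


def constraint_key(point: InterfacePoint, level: int) -> tuple:
    """Property tuple a target point must equal at the given hierarchy level.

    Level 1 uses the interaction (pharmacophore) type alone; level 2 adds
    the chemical element, with alpha carbons carried as their own element
    token ``CA*``; levels 3 and 4 describe the residue (class or exact
    name), element and backbone/side-chain flag.
    """
    if level == 1:
        return (point.ptype,)
    if level == 2:
        token = "CA*" if point.is_calpha else point.element
        return (token, point.ptype)
    if level == 3:
        return (point.residue_class, point.element, point.is_backbone)
    if level == 4:
        return (point.residue_name, point.element, point.is_backbone)
    raise ValueError(f"invalid hierarchy level: {level}")


def _pairdist(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(coords))


def enumerate_tetrahedra(iface: ChainInterface, params: SearchParams) -> list[Tetrahedron]:
    """All tetrahedra whose six edges lie in [minDist, maxDist].

    Result is sorted by decreasing size, ties broken by lexicographic
    corner indices.  Beyond ``FULL_ENUMERATION_LIMIT`` points the scan is
    restricted to combinations within each point's nearest in-range
    neighbours (deterministic).
    """
    n = len(iface.points)
    if n < 4:
        raise TooSmallInterfaceError(
            f"{iface.structure_id}:{iface.chain_id} has {n} points; need >= 4"
        )
    coords = iface.coords()
    dist = _pairdist(coords)
    in_range = (dist >= params.min_dist) & (dist <= params.max_dist)
    np.fill_diagonal(in_range, False)

    quads: list[tuple[int, int, int, int]]
    if n <= FULL_ENUMERATION_LIMIT:
        quads = _enumerate_cliques(in_range, n)
    else:
        quads = _enumerate_neighborhood(dist, in_range, n)

    tets = []
    for q in quads:
        edges = tuple(float(dist[q[i], q[j]]) for i, j in EDGE_PAIRS)
        tets.append(Tetrahedron(corner_indices=q, edge_lengths=edges))
    tets.sort(key=lambda t: (-t.size, t.corner_indices))
    return tets


def _enumerate_cliques(in_range: np.ndarray, n: int) -> list[tuple[int, int, int, int]]:
    # exhaustive i<j<k<l scan with adjacency pruning; output equals the
    # brute-force test over all 4-subsets
    out: list[tuple[int, int, int, int]] = []
    for i in range(n - 3):
        adj_i = in_range[i]
        for j in range(i + 1, n - 2):
            if not adj_i[j]:
                continue
            common_ij = adj_i & in_range[j]
            ks = np.nonzero(common_ij[j + 1 :])[0] + j + 1
            for k in ks:
                common = common_ij & in_range[k]
                ls = np.nonzero(common[k + 1 :])[0] + k + 1
                for l in ls:
                    out.append((i, int(j), int(k), int(l)))
    return out


def _enumerate_neighborhood(
    dist: np.ndarray, in_range: np.ndarray, n: int
) -> list[tuple[int, int, int, int]]:
    seen: set[tuple[int, int, int, int]] = set()
    for i in range(n):
        nb = np.nonzero(in_range[i])[0]
        order = np.lexsort((nb, dist[i, nb]))
        nb = nb[order][:NEIGHBOR_CAP]
        for trio in combinations(sorted(nb.tolist()), 3):
            quad = tuple(sorted((i, *trio)))
            if quad in seen:
                continue
            if all(in_range[a, b] for a, b in combinations(quad, 2)):
                seen.add(quad)  # type: ignore[arg-type]
    return sorted(seen)  # type: ignore[arg-type]


def select_filters(
    tetrahedra: list[Tetrahedron], n_points: int, params: SearchParams
) -> list[Tetrahedron]:
    """Greedy cover of the interface points, topped up to ``noffilters``.

    Scanning in decreasing-size order, a tetrahedron is kept iff it covers
    a point not yet covered.  If the cover uses fewer than ``noffilters``
    tetrahedra, the largest remaining ones are added until
    min(noffilters, available) are selected; if the cover alone exceeds
    ``noffilters``, only its ``noffilters`` largest members are kept.
    """
    if not tetrahedra:
        return []
    covered: set[int] = set()
    kept: list[Tetrahedron] = []
    rest: list[Tetrahedron] = []
    for tet in tetrahedra:
        if any(c not in covered for c in tet.corner_indices):
            kept.append(tet)
            covered.update(tet.corner_indices)
        else:
            rest.append(tet)
    if len(kept) > params.noffilters:
        return kept[: params.noffilters]  # already in decreasing-size order
    top_up = params.noffilters - len(kept)
    return kept + rest[:top_up]


def annotate_filter(
    tet: Tetrahedron, iface: ChainInterface, params: SearchParams
) -> TetrahedronFilter:
    """Convert a selected tetrahedron into a toleranced database filter."""
    constraints = tuple(
        constraint_key(iface.points[c], params.filter_hierarchy_level)
        for c in tet.corner_indices
    )
    intervals = tuple(
        (d - params.dist_tolerance, d + params.dist_tolerance) for d in tet.edge_lengths
    )
    return TetrahedronFilter(
        corner_constraints=constraints,  # type: ignore[arg-type]
        edge_intervals=intervals,
        hierarchy_level=params.filter_hierarchy_level,
        source=(iface.key, tet.corner_indices),
    )


def make_filters(iface: ChainInterface, params: SearchParams) -> list[TetrahedronFilter]:
    """Full query-side pipeline: enumerate, select, annotate."""
    tets = enumerate_tetrahedra(iface, params)
    chosen = select_filters(tets, len(iface.points), params)
    return [annotate_filter(t, iface, params) for t in chosen]


def _fmt_constraint(c: tuple) -> str:
    return "|".join(str(v) for v in c)


def _parse_constraint(text: str, level: int) -> tuple:
    parts = text.split("|")
    if level in (3, 4):
        parts[-1] = parts[-1] == "True"  # type: ignore[call-overload]
    return tuple(parts)


def filters_to_text(filters: list[TetrahedronFilter]) -> str:
    """Line-oriented serialization: 4 constraint tuples + 6 edge intervals."""
    lines = []
    for f in filters:
        cons = "\t".join(_fmt_constraint(c) for c in f.corner_constraints)
        edges = "\t".join(f"{lo:.6f},{hi:.6f}" for lo, hi in f.edge_intervals)
        lines.append(f"L{f.hierarchy_level}\t{cons}\t{edges}")
    return "\n".join(lines) + ("\n" if lines else "")


def filters_from_text(text: str) -> list[TetrahedronFilter]:
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        level = int(fields[0][1:])
        cons = tuple(_parse_constraint(c, level) for c in fields[1:5])
        edges = tuple(tuple(float(v) for v in e.split(",")) for e in fields[5:11])
        out.append(
            TetrahedronFilter(
                corner_constraints=cons,  # type: ignore[arg-type]
                edge_intervals=edges,  # type: ignore[arg-type]
                hierarchy_level=level,
                source=(("", "", None), (-1, -1, -1, -1)),
            )
        )
    return out
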