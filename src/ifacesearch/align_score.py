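"""Superposition, hit selection and similarity scoring.

Each filter match yields a rigid superposition of the target onto the
query (Kabsch-Umeyama on the four matched corners).  Candidate alignments
are ranked by a cheap Calpha-based shape prefilter (6 A radius); per
target, the best ceil(sqrt(n)) of the n candidates go on to full scoring.

Three similarity scores are reported per alignment: the shape score (the
fraction of query points with a target point within the scoring radius),
the pharma score (the same matches weighted by a pharmacophore-type
compatibility matrix), and the SP-score, their equally weighted
combination.  All are normalized by the point count of the larger of the
two compared single-chain interfaces, so a hit scores 1 only when both
sides overlap completely.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DegenerateGeometryError
from .geometry import RigidTransform, superpose
from .interface import PTYPES, ChainInterface, InterfacePair
from .matchdb import match_filter_against_points
from .tetrascan import SearchParams, constraint_key, make_filters

__all__ = [
    "ScoringMatrix",
    "HitScore",
    "pharma_increment",
    "prefilter_shape",
    "select_top_hits",
    "score_alignment",
    "compare_pair",
    "search_all",
]

log = logging.getLogger(__name__)

# pharmacophore compatibility of two matched points, in the type order
# (Acc/Don, Acc, Don, Aro, HyPhob, Ca, Pos/Don, Neg/Acc); unit diagonal,
# partial credit for donor/acceptor overlap, aromatic-hydrophobic contact
# and charge-compatible polar pairs
_DEFAULT_MATRIX = np.array(
    [
        [1.0, 0.6, 0.6, 0.0, 0.0, 0.0, 0.6, 0.6],
        [0.6, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.8],
        [0.6, 0.0, 1.0, 0.0, 0.0, 0.0, 0.8, 0.0],
        [0.0, 0.0, 0.0, 1.0, 0.8, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.8, 1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
        [0.6, 0.0, 0.8, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.6, 0.8, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass(frozen=True)
class ScoringMatrix:
    """Symmetric 8x8 pharmacophore-pair similarity table with unit diagonal."""

    values: np.ndarray = field(default_factory=lambda: _DEFAULT_MATRIX.copy())
    types: tuple[str, ...] = PTYPES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.types), len(self.types)):
            raise ValueError("matrix shape does not match the type alphabet")
        if not np.allclose(v, v.T):
            raise ValueError("scoring matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("scoring matrix must have a unit diagonal")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("scoring matrix values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls) -> "ScoringMatrix":
        return cls()

    def lookup(self, t1: str, t2: str) -> float:
        try:
            return float(self.values[self.types.index(t1), self.types.index(t2)])
        except ValueError:
            return 0.0  # unknown/Other types never add pharmacophore credit


def pharma_increment(t1: str, t2: str, matrix: ScoringMatrix | None = None) -> float:
    """Pharmacophore similarity credit for one matched point pair."""
    return (matrix or ScoringMatrix.default()).lookup(t1, t2)


@dataclass
class HitScore:
    """One candidate alignment of a target interface onto the query."""

    query_key: tuple
    target_key: tuple
    chain_pairing: str
    transform: RigidTransform | None
    shape: float
    pharma: float
    sp: float
    n_query_points: int
    n_target_points: int
    rmsd: float = float("nan")
    n_matches: int = 0
    prefilter: float = 0.0

    def __post_init__(self) -> None:
        if self.pharma > self.shape + 1e-9:
            raise ValueError("pharma score cannot exceed shape score")


def _null_hit(query_key: tuple, target_key: tuple) -> HitScore:
    return HitScore(
        query_key=query_key,
        target_key=target_key,
        chain_pairing="",
        transform=None,
        shape=0.0,
        pharma=0.0,
        sp=0.0,
        n_query_points=0,
        n_target_points=0,
    )


def _nearest_within(
    query_xyz: np.ndarray, target_xyz: np.ndarray, radius: float, kdtree_threshold: int
) -> np.ndarray:
    """Index of the nearest target point within ``radius`` per query point (-1 if none).

    A linear scan is used for small targets, a space-partitioning tree for
    targets with at least ``kdtree_threshold`` points; both return
    identical results.
    """
    if len(target_xyz) < kdtree_threshold:
        d = cdist(query_xyz, target_xyz)
        nearest = np.argmin(d, axis=1)
        dmin = d[np.arange(len(query_xyz)), nearest]
    else:
        tree = cKDTree(target_xyz)
        dmin, nearest = tree.query(query_xyz)
    out = np.where(dmin <= radius, nearest, -1)
    return out.astype(int)


def prefilter_shape(
    query_side: ChainInterface,
    target_side: ChainInterface,
    t: RigidTransform,
    params: SearchParams,
) -> float:
    """Calpha-only shape score with the fixed 6 A prefilter radius."""
    q = query_side.calpha_coords()
    tgt = target_side.calpha_coords()
    if len(q) == 0 or len(tgt) == 0:
        return 0.0
    nearest = _nearest_within(q, t.apply(tgt), params.prefilter_radius, params.kdtree_threshold)
    return float((nearest >= 0).sum()) / max(len(q), len(tgt))


def select_top_hits(hits: list[HitScore], per_target_n: int | None = None) -> list[HitScore]:
    """Per target, keep the ceil(sqrt(n)) candidates with the best prefilter score.

    n is the number of candidate hits in that target; ties are broken by
    lower corner RMSD, then by stable input order.  ``per_target_n``
    overrides the sqrt rule when given (mainly for testing).
    """
    groups: dict[tuple, list[tuple[int, HitScore]]] = {}
    for i, h in enumerate(hits):
        groups.setdefault(tuple(h.target_key), []).append((i, h))
    kept: list[tuple[int, HitScore]] = []
    for group in groups.values():
        n_keep = per_target_n if per_target_n is not None else math.ceil(math.sqrt(len(group)))
        ranked = sorted(group, key=lambda ih: (-ih[1].prefilter, ih[1].rmsd, ih[0]))
        kept.extend(ranked[:n_keep])
    kept.sort(key=lambda ih: ih[0])  # restore deterministic input order
    return [h for _, h in kept]


def score_alignment(
    query_side: ChainInterface,
    target_side: ChainInterface,
    t: RigidTransform,
    params: SearchParams,
    matrix: ScoringMatrix | None = None,
) -> HitScore:
    """Full shape/pharma/SP scores of one superposed side pair.

    For each query point the nearest transformed target point within
    ``scoringRadius`` is sought; a find counts 1 toward the shape score
    and the type-pair matrix value toward the pharma score.  Both sums
    are divided by the larger side's point count.
    """
    matrix = matrix or ScoringMatrix.default()
    q_pts = query_side.points
    t_pts = target_side.points
    nq, nt = len(q_pts), len(t_pts)
    if nq == 0 or nt == 0:
        log.warning("empty point set in scoring; returning zero scores")
        return _null_hit(query_side.key, target_side.key)

    nearest = _nearest_within(
        query_side.coords(), t.apply(target_side.coords()),
        params.scoring_radius, params.kdtree_threshold,
    )
    shape_counter = 0
    pharma_counter = 0.0
    for qi, ti in enumerate(nearest):
        if ti < 0:
            continue
        shape_counter += 1
        pharma_counter += matrix.lookup(q_pts[qi].ptype, t_pts[ti].ptype)
    denom = max(nq, nt)
    shape = shape_counter / denom
    pharma = pharma_counter / denom
    return HitScore(
        query_key=query_side.key,
        target_key=target_side.key,
        chain_pairing="",
        transform=t,
        shape=shape,
        pharma=pharma,
        sp=(shape + pharma) / 2.0,
        n_query_points=nq,
        n_target_points=nt,
    )


def _candidate_transforms(
    query_side: ChainInterface,
    target_side: ChainInterface,
    filters,
    params: SearchParams,
) -> list[HitScore]:
    """Match filters, superpose every mapping, attach prefilter scores."""
    if len(target_side.points) < 4:
        return []
    t_keys = [constraint_key(p, params.filter_hierarchy_level) for p in target_side.points]
    t_xyz = target_side.coords()
    t_dist = squareform(pdist(t_xyz)) if len(t_xyz) > 1 else np.zeros((1, 1))
    q_xyz = query_side.coords()

    candidates: list[HitScore] = []
    for flt in filters:
        mappings = match_filter_against_points(flt, t_keys, t_dist)
        q_corners = flt.source[1]
        q_corner_xyz = q_xyz[list(q_corners)]
        for mapping in mappings:
            try:
                transform, rmsd = superpose(q_corner_xyz, t_xyz[list(mapping)])
            except DegenerateGeometryError:
                log.debug("degenerate 4-point match discarded")
                continue
            pf = prefilter_shape(query_side, target_side, transform, params)
            candidates.append(
                HitScore(
                    query_key=query_side.key,
                    target_key=target_side.key,
                    chain_pairing="",
                    transform=transform,
                    shape=0.0,
                    pharma=0.0,
                    sp=0.0,
                    rmsd=rmsd,
                    prefilter=pf,
                    n_query_points=len(query_side.points),
                    n_target_points=len(target_side.points),
                )
            )
    return candidates


_PAIRING_LABELS = {(0, 0): "AA'", (0, 1): "AB'", (1, 0): "BA'", (1, 1): "BB'"}


def compare_pair(
    query: InterfacePair,
    target: InterfacePair,
    params: SearchParams | None = None,
    matrix: ScoringMatrix | None = None,
    query_filters: list | None = None,
) -> HitScore:
    """Best alignment of a target interface onto the query over all chain pairings.

    Runs the full pipeline (filters, matching, superposition, prefilter,
    sqrt-of-hits selection, scoring) for every available query-side /
    target-side pairing - four for a two-sided query, two for one-sided -
    and returns the highest-SP hit.  With ``twoSidedScoring`` enabled, each
    candidate's score is averaged with the partner-side pairing scored
    under the same transform.

    ``query_filters`` may carry pre-built filters (one list per query
    side) to amortize filter generation over many targets.
    """
    params = params or SearchParams()
    matrix = matrix or ScoringMatrix.default()
    q_sides = query.sides()
    t_sides = target.sides()
    if query_filters is None:
        query_filters = [make_filters(qs, params) for qs in q_sides]

    best: HitScore | None = None
    for qi, qs in enumerate(q_sides):
        for ti, ts in enumerate(t_sides):
            label = _PAIRING_LABELS[(qi, ti)]
            candidates = _candidate_transforms(qs, ts, query_filters[qi], params)
            top = select_top_hits(candidates)
            for cand in top:
                scored = score_alignment(qs, ts, cand.transform, params, matrix)
                scored = replace(
                    scored,
                    chain_pairing=label,
                    rmsd=cand.rmsd,
                    prefilter=cand.prefilter,
                    n_matches=len(candidates),
                )
                if params.two_sided_scoring:
                    q_partner = q_sides[1 - qi] if len(q_sides) == 2 else None
                    t_partner = t_sides[1 - ti] if len(t_sides) == 2 else None
                    if q_partner is not None and t_partner is not None:
                        other = score_alignment(
                            q_partner, t_partner, cand.transform, params, matrix
                        )
                        scored = replace(
                            scored,
                            shape=(scored.shape + other.shape) / 2.0,
                            pharma=(scored.pharma + other.pharma) / 2.0,
                            sp=(scored.sp + other.sp) / 2.0,
                        )
                if best is None or scored.sp > best.sp:
                    best = scored
    if best is None:
        best = _null_hit(q_sides[0].key, t_sides[0].key if t_sides else ("", "", ""))
        best = replace(best, chain_pairing="", n_query_points=len(q_sides[0].points))
    return best


def search_all(
    query: InterfacePair,
    targets: list[InterfacePair],
    params: SearchParams | None = None,
    matrix: ScoringMatrix | None = None,
) -> list[HitScore]:
    """Best hit per target for a panel of targets, query filters built once."""
    params = params or SearchParams()
    filters = [make_filters(qs, params) for qs in query.sides()]
    return [
        compare_pair(query, tgt, params=params, matrix=matrix, query_filters=filters)
        for tgt in targets
    ]
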