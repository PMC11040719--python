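"""Benchmark metrics: enrichment factors, ROC AUC, alignment RMSD.

The actives/inactives framing follows virtual-screening practice: every
query-target comparison carries a similarity score and a known label, and
the metrics quantify how strongly the known-similar pairs concentrate at
the top of the ranked list.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError
from .geometry import RigidTransform

# the synthetic fixtures live next door; re-exported here so the benchmark
# surface is one module
from .synthetic import (  # noqa: F401
    SyntheticComplexSpec,
    make_decoy_panel,
    make_toy_complex,
    random_rigid_transform,
)

__all__ = [
    "BenchmarkRecord",
    "enrichment_factor",
    "roc_auc",
    "alignment_rmsd",
    "homodimer_alignment_rmsd",
    "SyntheticComplexSpec",
    "make_toy_complex",
    "make_decoy_panel",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One scored query-target comparison with its known label."""

    query_key: str
    target_key: str
    label: str  # "active" | "inactive"
    score: float
    score_name: str = "sp"

    def __post_init__(self) -> None:
        if self.label not in ("active", "inactive"):
            raise ValueError(f"unknown label: {self.label!r}")
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")


def _sorted_labels(records: list[BenchmarkRecord]) -> np.ndarray:
    # descending by score; ties keep stable input order
    order = sorted(range(len(records)), key=lambda i: (-records[i].score, i))
    return np.array([records[i].label == "active" for i in order], dtype=bool)


def enrichment_factor(
    records: list[BenchmarkRecord], fraction: float, normalized: bool = True
) -> float:
    """Enrichment of actives in the top ``fraction`` of the ranked list.

    Raw EF is the actives rate in the top ceil(fraction*N) relative to the
    overall actives rate; the normalized EF divides the retrieved actives
    by the maximum retrievable count min(A, ceil(fraction*N)), so it lies
    in [0, 1] with 1 for a perfect early ranking.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    labels = _sorted_labels(records)
    n = len(labels)
    n_act = int(labels.sum())
    if n_act == 0 or n_act == n:
        raise UndefinedMetricError("need at least one active and one inactive")
    top = math.ceil(fraction * n)
    found = int(labels[:top].sum())
    if normalized:
        return found / min(n_act, top)
    return (found / top) / (n_act / n)


def roc_auc(records: list[BenchmarkRecord]) -> float:
    """Area under the ROC curve via the rank-sum formulation (ties count 1/2)."""
    scores = np.array([r.score for r in records], dtype=float)
    labels = np.array([r.label == "active" for r in records], dtype=bool)
    n_act = int(labels.sum())
    n_inact = len(labels) - n_act
    if n_act == 0 or n_inact == 0:
        raise UndefinedMetricError("need both labels for an ROC curve")
    ranks = rankdata(scores)  # average ranks on ties
    auc = (ranks[labels].sum() - n_act * (n_act + 1) / 2.0) / (n_act * n_inact)
    return float(auc)


def alignment_rmsd(transform: RigidTransform, reference_pairs: tuple[np.ndarray, np.ndarray]) -> float:
    """RMSD of transformed target reference atoms against the query's.

    ``reference_pairs`` is (query_coords, target_coords), matched (N, 3)
    arrays, typically Calpha positions of the structurally equivalent
    residues.
    """
    q, t = (np.asarray(a, dtype=float).reshape(-1, 3) for a in reference_pairs)
    if len(q) == 0 or len(q) != len(t):
        raise ValueError("need equally many non-empty reference pairs")
    moved = transform.apply(t)
    return float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))


def homodimer_alignment_rmsd(
    transform: RigidTransform,
    query_pairs: tuple[np.ndarray, np.ndarray],
    swapped_pairs: tuple[np.ndarray, np.ndarray],
) -> float:
    """Minimum RMSD over the two chain assignments of a homodimer."""
    return min(alignment_rmsd(transform, query_pairs), alignment_rmsd(transform, swapped_pairs))
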