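"""Replica-level summary statistics and between-ligand comparisons.

Category fractions are reported two ways, because percentages pooled
over frames and percentages averaged over replicas differ whenever
replica lengths differ: ``per_replica`` carries one (direct,
water-mediated-only, none) triple per replica, ``pooled`` is the
frame-count-weighted aggregate.  Between-ligand comparisons use Welch's
unequal-variance two-sample t-test on per-replica summaries — replicas,
not frames, are the independent unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .contacts import ContactCategory
from .errors import InsufficientReplicatesError
from .lifetimes import aggregate_replicas

__all__ = [
    "CategoryFractions",
    "DistanceSummary",
    "ComparisonResult",
    "category_fractions",
    "distance_summary",
    "compare_ligands",
]


@dataclass
class CategoryFractions:
    """Per-replica and frame-pooled polar-contact category fractions."""

    per_replica: list[tuple[int, float, float, float]]  # (id, direct, water, none)
    pooled: tuple[float, float, float]
    frame_counts: list[int]

    def pooled_percent(self) -> tuple[float, float, float]:
        return tuple(100.0 * f for f in self.pooled)  # type: ignore[return-value]


@dataclass
class DistanceSummary:
    """Average contact distance, per replica and across replicas."""

    interaction_key: tuple | str
    per_replica_means: list[float]
    mean: float
    sem: float
    excluded_replicas: list[int]


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    test_name: str
    n_a: int
    n_b: int


def _category_name(c) -> str:
    return c.value if isinstance(c, ContactCategory) else str(c)


def category_fractions(
    series: Sequence[tuple[int, Sequence]],
) -> CategoryFractions:
    """Fractions of the three polar-contact categories.

    ``series`` is a list of ``(replica_id, categories)`` pairs, one per
    replica.  Per-replica triples always sum to 1; the pooled triple is
    the frame-count-weighted mean (equivalently, counts pooled over all
    frames of all replicas).
    """
    if not series:
        raise ValueError("category_fractions: no replicas")
    per_replica: list[tuple[int, float, float, float]] = []
    frame_counts: list[int] = []
    totals = np.zeros(3)
    for replica_id, cats in series:
        names = [_category_name(c) for c in cats]
        n = len(names)
        if n == 0:
            raise ValueError(f"replica {replica_id}: empty category series")
        counts = np.array(
            [
                names.count("DIRECT_INTERACTION"),
                names.count("WATER_MEDIATED_ONLY"),
                names.count("NO_POLAR_CONTACT"),
            ],
            dtype=float,
        )
        if counts.sum() != n:
            raise ValueError(f"replica {replica_id}: unknown category present")
        totals += counts
        frame_counts.append(n)
        f = counts / n
        per_replica.append((replica_id, float(f[0]), float(f[1]), float(f[2])))
    pooled = totals / totals.sum()
    return CategoryFractions(
        per_replica=per_replica,
        pooled=(float(pooled[0]), float(pooled[1]), float(pooled[2])),
        frame_counts=frame_counts,
    )


def distance_summary(
    per_replica_distances: Sequence[tuple[int, Sequence[float]]],
    interaction_key: tuple | str = "",
) -> DistanceSummary:
    """Average distance of a contact, conditional on the contact existing.

    ``per_replica_distances`` maps each replica to the distances observed
    in frames where the contact was present.  Replicas with no qualifying
    frames are excluded from the mean and reported in
    ``excluded_replicas``.
    """
    means: list[float] = []
    excluded: list[int] = []
    for replica_id, distances in per_replica_distances:
        distances = list(distances)
        if distances:
            means.append(float(np.mean(distances)))
        else:
            excluded.append(replica_id)
    if not means:
        raise ValueError("distance_summary: no qualifying frames in any replica")
    agg = aggregate_replicas(means)
    return DistanceSummary(
        interaction_key=interaction_key,
        per_replica_means=means,
        mean=agg.mean,
        sem=agg.sem,
        excluded_replicas=excluded,
    )


def compare_ligands(
    a: Sequence[float], b: Sequence[float], label: str = ""
) -> ComparisonResult:
    """Welch's unequal-variance two-sample t-test on per-replica values.

    Two-sided p-value.  Identical groups give statistic 0 and p = 1.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError(
            f"compare_ligands{f' ({label})' if label else ''}: "
            f"need >= 2 replicas per group, got {len(a)} and {len(b)}"
        )
    if np.allclose(a, np.mean(a)) and np.allclose(b, np.mean(b)) and np.isclose(
        np.mean(a), np.mean(b)
    ):
        # degenerate zero-variance identical groups: no evidence of difference
        return ComparisonResult(0.0, 1.0, "welch_t", len(a), len(b))
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="welch_t",
        n_a=len(a),
        n_b=len(b),
    )
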