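"""Align cluster rows across images and average cluster sets.

k-means bins carry no positional meaning across images (cluster 1 of one
butterfly may be its yellow patch, cluster 1 of another its black patch), so
before any bin-by-bin metric the bins are matched by minimum total Euclidean
center distance -- the linear assignment (Hungarian) problem. Histogram bins
share grid boundaries and are already positionally aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .binning import ClusterSet, ColorBin
from .errors import IncompatibleClusterSetsError

__all__ = ["ClusterAlignment", "align_clusters", "order_clusters", "combine_cluster_sets"]


@dataclass
class ClusterAlignment:
    """Bijections matching each set's bins to the reference set's bins."""

    reference_label: str
    permutations: list[np.ndarray]  # per set: ordered[i] = set.bins[perm[i]]
    total_cost: float


def _check_compatible(sets: list[ClusterSet]) -> None:
    if not sets:
        raise IncompatibleClusterSetsError("no cluster sets given")
    k, space = sets[0].k, sets[0].space
    for s in sets[1:]:
        if s.k != k:
            raise IncompatibleClusterSetsError(
                f"bin count mismatch: {sets[0].label or 'set 0'} has {k} bins, "
                f"{s.label or 'another set'} has {s.k}"
            )
        if s.space != space:
            raise IncompatibleClusterSetsError(
                f"color space mismatch: {space} vs {s.space}"
            )


def align_clusters(sets: list[ClusterSet]) -> ClusterAlignment:
    """Match every set's bins to the first set's bins by center distance.

    The assignment minimizes the summed Euclidean distance between matched
    centers; sizes do not enter the cost (they belong to the weighted
    metric, not the ordering step).
    """
    _check_compatible(sets)
    reference = sets[0]
    permutations = [np.arange(reference.k)]
    total = 0.0
    for s in sets[1:]:
        cost = cdist(reference.centers, s.centers)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(reference.k, dtype=np.int64)
        perm[rows] = cols
        permutations.append(perm)
        total += float(cost[rows, cols].sum())
    return ClusterAlignment(
        reference_label=reference.label, permutations=permutations, total_cost=total
    )


def order_clusters(sets: list[ClusterSet]) -> list[ClusterSet]:
    """Reorder every set's bins to match the first (reference) set.

    The reference set is returned unchanged; each other set is permuted so
    that bin i everywhere is the bin most similar to reference bin i under
    the optimal bijection.
    """
    alignment = align_clusters(sets)
    return [s.permuted(perm) for s, perm in zip(sets, alignment.permutations)]


def combine_cluster_sets(
    sets: list[ClusterSet], weight_centers_by: str = "count"
) -> ClusterSet:
    """Average aligned cluster sets into one profile.

    Per matched bin: size is the plain mean of sizes (each image counts
    equally in the profile), center is the pixel-count-weighted mean of
    centers by default (``weight_centers_by="equal"`` switches to an
    unweighted mean). A bin empty in every set falls back to its geometric
    box midpoint when histogram bounds are available.
    """
    _check_compatible(sets)
    if weight_centers_by not in ("count", "equal"):
        raise ValueError("weight_centers_by must be 'count' or 'equal'")
    first = sets[0]
    specs = {s.spec for s in sets if s.method == "histogram"}
    if len(specs) > 1:
        raise IncompatibleClusterSetsError(
            "histogram sets must share one HistogramSpec to be combined"
        )
    bins = []
    for i in range(first.k):
        members = [s.bins[i] for s in sets]
        size = float(np.mean([b.size for b in members]))
        counts = np.array([b.count for b in members], dtype=float)
        if weight_centers_by == "equal":
            counts = np.ones_like(counts)
        total = counts.sum()
        if total > 0:
            center = (
                np.stack([b.center for b in members]) * counts[:, None]
            ).sum(axis=0) / total
        elif first.bins[i].bounds is not None:
            center = first.bins[i].bounds.mean(axis=1)
        else:
            center = np.stack([b.center for b in members]).mean(axis=0)
        bins.append(
            ColorBin(
                center=center,
                size=size,
                count=int(np.sum([b.count for b in members])),
                bounds=first.bins[i].bounds,
            )
        )
    return ClusterSet(
        bins=bins,
        space=first.space,
        method=first.method,
        label="combined",
        spec=first.spec,
    )
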