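"""Pairwise color distances between cluster sets and labeled matrices.

The headline metric is the earth mover's distance (EMD, 1-Wasserstein): the
minimum cost of transforming one color profile into the other, where moving
mass p between bin centers c1, c2 costs p * ||c1 - c2||. It rewards both
similar colors and similar amounts, and unlike bin-by-bin metrics it knows
that dark brown is close to black. EMD is solved exactly as the balanced
transportation linear program over the nonzero bins.

In RGB and HSV space the maximum possible EMD is sqrt(3), the cube diagonal
(all mass moved as far as possible), so RGB/HSV EMDs can be normalized to
[0, 1]. CIE Lab has no universal maximum, so Lab EMDs are reported raw.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .binning import ClusterSet
from .errors import ConfigurationError, IncompatibleClusterSetsError

__all__ = [
    "TransportPlan",
    "DistanceMatrix",
    "emd",
    "emd_plan",
    "chi_squared",
    "color_distance",
    "weighted_pairs",
    "distance_matrix",
    "METRICS",
    "MAX_RGB_EMD",
]

logger = logging.getLogger(__name__)

MAX_RGB_EMD = float(np.sqrt(3.0))

_MASS_TOL = 1e-8


@dataclass
class TransportPlan:
    """An optimal flow between two weighted bin-center point sets."""

    flows: np.ndarray  # n_a x n_b, mass moved from bin i of a to bin j of b
    ground_distances: np.ndarray  # Euclidean center distances, same shape
    cost: float


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise color distances."""

    labels: list[str]
    values: np.ndarray
    metric: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")

    def to_csv(self, path) -> None:
        """Write as CSV with labels in the first row and column, bit-exact."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["", *self.labels])
            for label, row in zip(self.labels, self.values):
                writer.writerow([label, *[repr(float(v)) for v in row]])

    @classmethod
    def from_csv(cls, path, metric: str = "", normalized: bool = False):
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        labels = rows[0][1:]
        values = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
        return cls(labels=labels, values=values, metric=metric, normalized=normalized)

    def to_square_txt(self, path) -> None:
        """Square tab-separated dialect: header row of labels, label-led rows."""
        with open(path, "w") as fh:
            fh.write("\t".join(["", *self.labels]) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write("\t".join([label, *[repr(float(v)) for v in row]]) + "\n")

    @classmethod
    def from_square_txt(cls, path, metric: str = "", normalized: bool = False):
        with open(path) as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh]
        labels = rows[0][1:]
        values = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
        return cls(labels=labels, values=values, metric=metric, normalized=normalized)


def _check_spaces(a: ClusterSet, b: ClusterSet) -> None:
    if a.space != b.space:
        raise IncompatibleClusterSetsError(
            f"cannot compare {a.space} profile with {b.space} profile"
        )


def _nonzero(cs: ClusterSet) -> tuple[np.ndarray, np.ndarray]:
    sizes = cs.sizes
    keep = sizes > 0
    return cs.centers[keep], sizes[keep]


def emd_plan(a: ClusterSet, b: ClusterSet) -> TransportPlan:
    """Solve the balanced transportation LP between two profiles.

    Zero-size bins carry no mass and are excluded to keep the program
    nondegenerate. Both profiles must be normalized (sizes summing to 1).
    """
    _check_spaces(a, b)
    ca, wa = _nonzero(a)
    cb, wb = _nonzero(b)
    if abs(wa.sum() - 1.0) > 1e-6 or abs(wb.sum() - 1.0) > 1e-6:
        raise IncompatibleClusterSetsError(
            "EMD requires normalized profiles (bin sizes summing to 1); got "
            f"{wa.sum():.6g} and {wb.sum():.6g}"
        )
    d = cdist(ca, cb)
    n, m = d.shape
    if n == 1:
        flows = wb[None, :].copy()
        return TransportPlan(flows, d, float((flows * d).sum()))
    if m == 1:
        flows = wa[:, None].copy()
        return TransportPlan(flows, d, float((flows * d).sum()))
    # variables x[i, j] flattened row-major; rows sum to wa, columns to wb.
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([wa, wb])
    res = linprog(d.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - balanced problems are feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    flows = res.x.reshape(n, m)
    return TransportPlan(flows, d, float(res.fun))


def emd(a: ClusterSet, b: ClusterSet) -> float:
    """Earth mover's distance between two cluster sets (unnormalized)."""
    return emd_plan(a, b).cost


def chi_squared(a: ClusterSet, b: ClusterSet) -> float:
    """Bin-wise chi-squared distance on sizes: sum (sa-sb)^2 / (sa+sb).

    Requires positionally aligned sets; centers are ignored, so profiles
    with identical size vectors but different colors score 0 (the metric's
    documented blind spot).
    """
    if a.k != b.k:
        raise IncompatibleClusterSetsError(
            f"chi-squared needs equal bin counts, got {a.k} and {b.k}"
        )
    sa, sb = a.sizes, b.sizes
    denom = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, (sa - sb) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    return float(terms.sum())


def color_distance(a: ClusterSet, b: ClusterSet) -> float:
    """Mean Euclidean distance between matched bin centers; sizes ignored."""
    _check_spaces(a, b)
    if a.k != b.k:
        raise IncompatibleClusterSetsError(
            f"color distance needs equal bin counts, got {a.k} and {b.k}"
        )
    return float(np.linalg.norm(a.centers - b.centers, axis=1).mean())


def weighted_pairs(
    a: ClusterSet, b: ClusterSet, size_weight: float = 0.5, color_weight: float = 0.5
) -> float:
    """Weighted blend of per-pair center distance and size difference.

    Per matched bin: color_weight * ||ca - cb|| + size_weight * |sa - sb|,
    averaged over bins. Weights must sum to 1.
    """
    _check_spaces(a, b)
    if a.k != b.k:
        raise IncompatibleClusterSetsError(
            f"weighted distance needs equal bin counts, got {a.k} and {b.k}"
        )
    if abs(size_weight + color_weight - 1.0) > 1e-9:
        raise ConfigurationError(
            f"size_weight + color_weight must equal 1, got "
            f"{size_weight} + {color_weight}"
        )
    center_d = np.linalg.norm(a.centers - b.centers, axis=1)
    size_d = np.abs(a.sizes - b.sizes)
    return float((color_weight * center_d + size_weight * size_d).mean())


METRICS = {
    "emd": emd,
    "chisq": chi_squared,
    "color": color_distance,
    "weighted": weighted_pairs,
}


def distance_matrix(
    sets: list[ClusterSet],
    metric: str = "emd",
    normalize: bool = True,
    size_weight: float = 0.5,
    color_weight: float = 0.5,
) -> DistanceMatrix:
    """All-pairs distances for a list of cluster sets.

    RGB/HSV EMDs are divided by sqrt(3) (the maximum possible score) when
    ``normalize`` is set; Lab profiles have no absolute maximum, so the flag
    is ignored there with a warning.
    """
    if metric not in METRICS:
        valid = ", ".join(sorted(METRICS))
        raise ConfigurationError(f"unknown metric {metric!r}; valid metrics: {valid}")
    if len(sets) < 2:
        raise IncompatibleClusterSetsError("need at least 2 cluster sets")
    space = sets[0].space
    do_normalize = normalize and metric == "emd"
    if do_normalize and space == "lab":
        logger.warning(
            "EMD has no absolute maximum in CIE Lab space; "
            "reporting unnormalized distances"
        )
        do_normalize = False
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "weighted":
                d = weighted_pairs(sets[i], sets[j], size_weight, color_weight)
            else:
                d = METRICS[metric](sets[i], sets[j])
            values[i, j] = values[j, i] = d
    if do_normalize:
        values /= MAX_RGB_EMD
    labels = [s.label or f"image_{i}" for i, s in enumerate(sets)]
    return DistanceMatrix(
        labels=labels, values=values, metric=metric, normalized=do_normalize
    )
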