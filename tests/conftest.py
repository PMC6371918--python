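"""Shared fixtures and independent oracles for the chromadist test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from chromadist.binning import ClusterSet, ColorBin
from chromadist.fixtures import generate_quantity_set


def make_cluster_set(
    centers, sizes, space="rgb", method="kmeans", label="", total=1000
) -> ClusterSet:
    """Build a ClusterSet directly from center/size arrays (test helper)."""
    centers = np.asarray(centers, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    bins = [
        ColorBin(center=c, size=float(s), count=int(round(s * total)))
        for c, s in zip(centers, sizes)
    ]
    return ClusterSet(bins=bins, space=space, method=method, label=label)


def emd_by_atom_splitting(centers_a, sizes_a, centers_b, sizes_b, denom: int) -> float:
    """Independent EMD oracle: split mass into equal atoms, solve assignment.

    When every size is an integer multiple of 1/denom, the transportation
    optimum is attained at a vertex that matches equal-mass atoms one to
    one, so the minimum-cost perfect matching of the atom expansion (solved
    as linear assignment) equals the EMD exactly. This route never touches
    the package's LP formulation.
    """
    atoms_a, atoms_b = [], []
    for c, s in zip(centers_a, sizes_a):
        atoms_a.extend([c] * int(round(s * denom)))
    for c, s in zip(centers_b, sizes_b):
        atoms_b.extend([c] * int(round(s * denom)))
    assert len(atoms_a) == len(atoms_b) == denom
    atoms_a = np.asarray(atoms_a)
    atoms_b = np.asarray(atoms_b)
    cost = np.linalg.norm(atoms_a[:, None, :] - atoms_b[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / denom)


def random_profile_pair(rng: np.random.Generator, k_max: int = 5, denom: int = 12):
    """A random pair of normalized profiles with sizes on a 1/denom grid."""
    ka = int(rng.integers(1, k_max + 1))
    kb = int(rng.integers(1, k_max + 1))

    def sizes(k):
        cuts = np.sort(rng.choice(np.arange(1, denom), size=k - 1, replace=False))
        parts = np.diff(np.concatenate([[0], cuts, [denom]]))
        return parts / denom

    return (
        rng.random((ka, 3)),
        sizes(ka),
        rng.random((kb, 3)),
        sizes(kb),
    )


def brute_force_assignment_cost(centers_ref, centers_other) -> float:
    """Exhaustive-permutation minimum of the summed center distances."""
    k = len(centers_ref)
    best = np.inf
    for perm in itertools.permutations(range(k)):
        cost = sum(
            float(np.linalg.norm(centers_ref[i] - centers_other[p]))
            for i, p in enumerate(perm)
        )
        best = min(best, cost)
    return best


@pytest.fixture(scope="session")
def quantity_dir(tmp_path_factory):
    """The five cyan/red proportion squares A-E as 100 x 100 PNGs."""
    outdir = tmp_path_factory.mktemp("quantity")
    generate_quantity_set(outdir, size=100)
    return outdir
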