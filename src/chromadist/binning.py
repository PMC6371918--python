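"""Reduce pixel sets to cluster sets: 3D histograms and k-means palettes.

A ``ClusterSet`` is the color profile of one image: an ordered list of bins,
each holding a 3D center (the mean color of its member pixels) and a size
(the proportion of object pixels it captures). Two binning routes exist:

* **histogram** -- the color space is partitioned into a fixed grid of
  axis-aligned boxes. Boundaries are shared across images, so bin *i* means
  the same region everywhere and profiles are positionally comparable. Empty
  bins keep size 0 with the box's geometric midpoint as a placeholder center.
* **k-means** -- pixel-driven clustering into exactly k groups; centers land
  on the image's actual dominant colors but bin identity is per-image, so
  cross-image comparison needs Hungarian alignment (see ``cluster_ops``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import ChannelBoundsError, ChromadistError, IncompatibleClusterSetsError
from .image_io import CHANNEL_NAMES, Backgrounds, PixelSet, load_image
from .color_spaces import convert_pixels

__all__ = [
    "ColorBin",
    "HistogramSpec",
    "ClusterSet",
    "default_channel_bounds",
    "histogram_bin",
    "kmeans_bin",
    "bin_image_set",
]

#: Default per-channel [min, max] bounds in each space. Lab a/b use the
#: practical bounds of RGB-derived colors.
_DEFAULT_BOUNDS = {
    "rgb": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    "hsv": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    "lab": ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0)),
}


def default_channel_bounds(space: str) -> tuple[tuple[float, float], ...]:
    return _DEFAULT_BOUNDS[space.lower()]


@dataclass(frozen=True)
class HistogramSpec:
    """Grid layout for fixed-boundary histogram binning.

    ``bins_per_channel`` gives the number of equal-width divisions of each
    channel; ``channel_bounds`` the [min, max] range divided. Narrowing the
    bounds (e.g. Lab a in [-20, 40] for a brown-only image set) concentrates
    bins where the data live; pixels outside the bounds are a hard error.
    """

    bins_per_channel: tuple[int, int, int] = (3, 3, 3)
    channel_bounds: tuple[tuple[float, float], ...] | None = None
    space: str = "rgb"

    def __post_init__(self) -> None:
        bins = tuple(int(b) for b in self.bins_per_channel)
        if len(bins) != 3 or any(b < 1 for b in bins):
            raise ValueError("bins_per_channel must be 3 positive integers")
        space = self.space.lower()
        if space not in _DEFAULT_BOUNDS:
            raise ValueError(f"unknown color space {self.space!r}")
        bounds = self.channel_bounds or default_channel_bounds(space)
        bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        if len(bounds) != 3 or any(lo >= hi for lo, hi in bounds):
            raise ValueError("channel_bounds must be 3 (min, max) pairs with min < max")
        object.__setattr__(self, "bins_per_channel", bins)
        object.__setattr__(self, "channel_bounds", bounds)
        object.__setattr__(self, "space", space)

    @property
    def n_bins(self) -> int:
        b = self.bins_per_channel
        return b[0] * b[1] * b[2]

    def edges(self, channel: int) -> np.ndarray:
        lo, hi = self.channel_bounds[channel]
        return np.linspace(lo, hi, self.bins_per_channel[channel] + 1)

    def midpoints(self) -> np.ndarray:
        """Geometric midpoints of all bins, in lexicographic bin order."""
        mids = [0.5 * (self.edges(c)[:-1] + self.edges(c)[1:]) for c in range(3)]
        grid = np.stack(np.meshgrid(*mids, indexing="ij"), axis=-1)
        return grid.reshape(-1, 3)


@dataclass
class ColorBin:
    """One cluster: a 3D center plus the proportion of pixels it holds."""

    center: np.ndarray
    size: float
    count: int
    bounds: np.ndarray | None = None  # 3 x 2 [low, high) box, histogram only

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)


@dataclass
class ClusterSet:
    """The color profile of one image: ordered bins in one color space."""

    bins: list[ColorBin]
    space: str
    method: str  # "histogram" | "kmeans"
    label: str = ""
    spec: HistogramSpec | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.bins)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([b.size for b in self.bins])

    @property
    def centers(self) -> np.ndarray:
        return np.stack([b.center for b in self.bins])

    @property
    def counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins])

    def permuted(self, order: Sequence[int]) -> "ClusterSet":
        """A copy with bins reordered; sizes travel with their centers."""
        return ClusterSet(
            bins=[self.bins[i] for i in order],
            space=self.space,
            method=self.method,
            label=self.label,
            spec=self.spec,
            metadata=dict(self.metadata),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write bins as CSV: one row per bin, channels then size and count.

        Floats are written with repr-level precision so a reload is
        bit-exact; this is the package's interchange format.
        """
        names = CHANNEL_NAMES[self.space]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([*names, "size", "count"])
            for b in self.bins:
                writer.writerow(
                    [repr(float(v)) for v in b.center]
                    + [repr(float(b.size)), str(int(b.count))]
                )

    @classmethod
    def from_csv(
        cls, path: str | Path, space: str, method: str = "histogram", label: str = ""
    ) -> "ClusterSet":
        bins = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)  # header
            for row in reader:
                bins.append(
                    ColorBin(
                        center=np.array([float(v) for v in row[:3]]),
                        size=float(row[3]),
                        count=int(row[4]),
                    )
                )
        return cls(bins=bins, space=space.lower(), method=method, label=label)


def histogram_bin(
    pixels: PixelSet, spec: HistogramSpec | None = None, label: str = ""
) -> ClusterSet:
    """Assign each pixel to one grid box and summarize the boxes.

    Boxes are half-open [low, high) per channel with the top box closed at
    the channel maximum, so assignment is a partition. Bins are emitted in
    lexicographic order of (channel-1, channel-2, channel-3) box indices.
    Pixels outside the channel bounds raise ChannelBoundsError rather than
    being silently truncated.
    """
    spec = spec or HistogramSpec(space=pixels.space)
    if spec.space != pixels.space:
        raise IncompatibleClusterSetsError(
            f"histogram spec is for {spec.space} but pixels are {pixels.space}"
        )
    coords = pixels.coords
    if len(coords) == 0:
        raise ChromadistError("cannot bin an empty pixel set")
    names = CHANNEL_NAMES[pixels.space]
    nbins = spec.bins_per_channel
    idx = np.empty((len(coords), 3), dtype=np.int64)
    for c in range(3):
        lo, hi = spec.channel_bounds[c]
        vals = coords[:, c]
        if vals.min() < lo or vals.max() > hi:
            raise ChannelBoundsError(
                f"channel {names[c]}: pixels span [{vals.min():.6g}, "
                f"{vals.max():.6g}] but bounds are [{lo:g}, {hi:g}]"
            )
        width = (hi - lo) / nbins[c]
        ix = np.floor((vals - lo) / width).astype(np.int64)
        idx[:, c] = np.minimum(ix, nbins[c] - 1)  # close the top bin at hi
    flat = (idx[:, 0] * nbins[1] + idx[:, 1]) * nbins[2] + idx[:, 2]
    counts = np.bincount(flat, minlength=spec.n_bins)
    sums = np.zeros((spec.n_bins, 3))
    for c in range(3):
        sums[:, c] = np.bincount(flat, weights=coords[:, c], minlength=spec.n_bins)
    midpoints = spec.midpoints()
    total = len(coords)
    edges = [spec.edges(c) for c in range(3)]
    bins: list[ColorBin] = []
    for i in range(spec.n_bins):
        i1, rem = divmod(i, nbins[1] * nbins[2])
        i2, i3 = divmod(rem, nbins[2])
        box = np.array(
            [
                [edges[0][i1], edges[0][i1 + 1]],
                [edges[1][i2], edges[1][i2 + 1]],
                [edges[2][i3], edges[2][i3 + 1]],
            ]
        )
        n = int(counts[i])
        center = sums[i] / n if n > 0 else midpoints[i]
        bins.append(ColorBin(center=center, size=n / total, count=n, bounds=box))
    return ClusterSet(
        bins=bins, space=pixels.space, method="histogram", label=label, spec=spec
    )


def kmeans_bin(
    pixels: PixelSet,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    label: str = "",
) -> ClusterSet:
    """Cluster pixels into exactly k color bins by k-means.

    Lloyd iterations with k-means++ seeding, best of ``restarts``
    initializations by within-cluster sum of squares; deterministic for a
    fixed seed. Requires at least k distinct pixel colors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = pixels.coords
    if len(coords) == 0:
        raise ChromadistError("cannot cluster an empty pixel set")
    n_distinct = len(np.unique(coords, axis=0))
    if n_distinct < k:
        raise ChromadistError(
            f"only {n_distinct} distinct pixel colors but k={k}; choose k <= "
            f"{n_distinct}"
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed))
    assignments = km.fit_predict(coords)
    total = len(coords)
    bins = []
    for i in range(k):
        members = coords[assignments == i]
        n = len(members)
        center = members.mean(axis=0) if n else km.cluster_centers_[i]
        bins.append(ColorBin(center=center, size=n / total, count=n))
    cs = ClusterSet(bins=bins, space=pixels.space, method="kmeans", label=label)
    cs.metadata.update({"seed": int(seed), "restarts": int(restarts), "k": int(k)})
    return cs


def bin_image_set(
    paths: Sequence[str | Path],
    background: Backgrounds,
    space: str = "rgb",
    ref_white: str = "D65",
    method: str = "histogram",
    spec: HistogramSpec | None = None,
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
) -> list[ClusterSet]:
    """Bin every image in a set with one shared configuration.

    Images are processed in sorted path order; labels are file stems. All
    images are attempted before failing, so one bad file reports alongside
    the others rather than hiding them.
    """
    paths = sorted(Path(p) for p in paths)
    if len(paths) < 2:
        raise ChromadistError(
            f"need at least 2 images for a distance matrix, got {len(paths)}"
        )
    space = space.lower()
    if method == "histogram" and spec is None:
        spec = HistogramSpec(space=space)
    results: list[ClusterSet] = []
    failures: list[str] = []
    for path in paths:
        try:
            _, pixels = load_image(path, background)
            pixels = convert_pixels(pixels, space, white=ref_white)
            if method == "histogram":
                cs = histogram_bin(pixels, spec, label=path.stem)
            elif method == "kmeans":
                cs = kmeans_bin(pixels, k, seed=seed, restarts=restarts,
                                label=path.stem)
            else:
                raise ChromadistError(f"unknown binning method {method!r}")
            results.append(cs)
        except ChromadistError as exc:
            failures.append(f"{path}: {exc}")
    if failures:
        raise ChromadistError(
            "failed to bin {} image(s):\n{}".format(len(failures), "\n".join(failures))
        )
    return results
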