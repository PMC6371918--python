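"""One-command pipeline: image directory -> color distance matrix + reports.

Mirrors the library stages in order -- load and mask, convert color space,
bin, (align k-means bins), compute the pairwise matrix -- and writes the
matrix CSV, per-image cluster CSVs, a clustered heatmap, and a metadata
record of every parameter and seed, so a run is reproducible from its
artifacts alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import __version__
from .binning import HistogramSpec, bin_image_set, default_channel_bounds
from .cluster_ops import order_clusters
from .color_spaces import REFERENCE_WHITES, reference_white
from .distances import METRICS, DistanceMatrix, distance_matrix
from .errors import ChromadistError, ConfigurationError
from .image_io import CHANNEL_NAMES, BackgroundRange, PixelSet
from . import color_spaces

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "image_cluster_pipeline", "render_heatmap", "plot_pixels"]

#: Shown alongside every heatmap: the dendrogram is for eyeballing, the
#: matrix itself is the result.
HEATMAP_CAVEAT = (
    "The hierarchical clustering shown in the heatmap is intended as a "
    "visual tool for inspecting the results; interpret the quantitative "
    "distance matrix, not the tree."
)


@dataclass
class PipelineConfig:
    """Validated bundle of every user-specifiable pipeline parameter."""

    input_dir: str
    output_dir: str
    color_space: str = "rgb"
    ref_white: str = "D65"
    lower: tuple[float, float, float] = (1.0, 1.0, 1.0)
    upper: tuple[float, float, float] = (1.0, 1.0, 1.0)
    method: str = "histogram"
    bins_per_channel: tuple[int, int, int] = (3, 3, 3)
    k: int = 3
    a_bounds: tuple[float, float] | None = None
    b_bounds: tuple[float, float] | None = None
    metric: str = "emd"
    normalize: bool = True
    size_weight: float = 0.5
    color_weight: float = 0.5
    seed: int = 0
    restarts: int = 10
    sample_limit: int = color_spaces.DEFAULT_SAMPLE_LIMIT
    heatmap_linkage: str = "complete"

    def __post_init__(self) -> None:
        self.color_space = self.color_space.lower()
        if self.color_space not in CHANNEL_NAMES:
            raise ConfigurationError(
                f"unknown color space {self.color_space!r}; valid: rgb, hsv, lab"
            )
        reference_white(self.ref_white)  # raises on bad name
        if self.method not in ("histogram", "kmeans"):
            raise ConfigurationError(
                f"unknown binning method {self.method!r}; valid: histogram, kmeans"
            )
        if self.metric not in METRICS:
            raise ConfigurationError(
                f"unknown metric {self.metric!r}; valid: {', '.join(sorted(METRICS))}"
            )
        if self.method == "kmeans" and self.k < 1:
            raise ConfigurationError("k must be >= 1")
        # constructing these validates bounds and weights up front
        self.background()
        if self.method == "histogram":
            self.histogram_spec()
        if self.metric == "weighted" and abs(
            self.size_weight + self.color_weight - 1.0
        ) > 1e-9:
            raise ConfigurationError("size_weight + color_weight must equal 1")

    def background(self) -> BackgroundRange:
        return BackgroundRange(lower=self.lower, upper=self.upper)

    def histogram_spec(self) -> HistogramSpec:
        bounds = list(default_channel_bounds(self.color_space))
        if self.color_space == "lab":
            if self.a_bounds is not None:
                bounds[1] = tuple(self.a_bounds)
            if self.b_bounds is not None:
                bounds[2] = tuple(self.b_bounds)
        return HistogramSpec(
            bins_per_channel=self.bins_per_channel,
            channel_bounds=tuple(bounds),
            space=self.color_space,
        )


def _find_images(input_dir: Path) -> list[Path]:
    exts = {".png", ".jpg", ".jpeg"}
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in exts)
    if len(paths) < 2:
        raise ChromadistError(
            f"{input_dir}: need at least 2 PNG/JPEG images, found {len(paths)}"
        )
    return paths


def image_cluster_pipeline(config: PipelineConfig) -> DistanceMatrix:
    """Run the full pipeline and write all artifacts to the output directory.

    On failure, partially written artifacts from this run are removed so the
    output directory never holds a half-result.
    """
    input_dir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        paths = _find_images(input_dir)
        logger.info("binning %d images from %s", len(paths), input_dir)
        sets = bin_image_set(
            paths,
            background=config.background(),
            space=config.color_space,
            ref_white=config.ref_white,
            method=config.method,
            spec=config.histogram_spec() if config.method == "histogram" else None,
            k=config.k,
            seed=config.seed,
            restarts=config.restarts,
        )
        if config.method == "kmeans":
            logger.info("aligning k-means bins across images (Hungarian)")
            sets = order_clusters(sets)
        logger.info("computing %s distance matrix", config.metric)
        matrix = distance_matrix(
            sets,
            metric=config.metric,
            normalize=config.normalize,
            size_weight=config.size_weight,
            color_weight=config.color_weight,
        )
        matrix_path = outdir / "distance_matrix.csv"
        matrix.to_csv(matrix_path)
        written.append(matrix_path)
        for cs in sets:
            p = outdir / f"clusters_{cs.label}.csv"
            cs.to_csv(p)
            written.append(p)
        heatmap_path = outdir / "heatmap.png"
        render_heatmap(matrix, heatmap_path, linkage=config.heatmap_linkage)
        written.append(heatmap_path)
        meta_path = outdir / "run_metadata.json"
        meta = {
            "chromadist_version": __version__,
            "parameters": asdict(config),
            "images": [str(p) for p in paths],
            "note": HEATMAP_CAVEAT,
        }
        meta_path.write_text(json.dumps(meta, indent=2))
        written.append(meta_path)
        return matrix
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _leaf_order(matrix: DistanceMatrix, linkage: str) -> tuple[np.ndarray, np.ndarray]:
    condensed = squareform(matrix.values, checks=False)
    # optimal leaf ordering minimizes adjacent-leaf distances, so similar
    # images sit next to each other in the heatmap
    link = hierarchy.linkage(condensed, method=linkage, optimal_ordering=True)
    order = hierarchy.leaves_list(link)
    return link, order


def render_heatmap(
    matrix: DistanceMatrix, outfile: str | Path, linkage: str = "complete"
) -> Path:
    """Heatmap of the matrix with rows/columns ordered by hierarchical clustering.

    A dendrogram is drawn above the heatmap. The clustering is a reading
    aid, not an inference (see HEATMAP_CAVEAT, embedded in the figure).
    """
    link, order = _leaf_order(matrix, linkage)
    values = matrix.values[np.ix_(order, order)]
    labels = [matrix.labels[i] for i in order]
    fig = plt.figure(figsize=(7, 8))
    ax_dendro = fig.add_axes([0.15, 0.76, 0.7, 0.18])
    hierarchy.dendrogram(link, ax=ax_dendro, no_labels=True, color_threshold=0)
    ax_dendro.set_axis_off()
    ax = fig.add_axes([0.15, 0.12, 0.7, 0.6])
    im = ax.imshow(values, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90)
    ax.set_yticks(range(len(labels)), labels)
    title = matrix.metric.upper()
    if matrix.normalized:
        title += " (normalized)"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.text(0.02, 0.01, HEATMAP_CAVEAT, fontsize=6, wrap=True)
    outfile = Path(outfile)
    fig.savefig(outfile, dpi=150)
    plt.close(fig)
    return outfile


def plot_pixels(
    pixels: PixelSet,
    outfile: str | Path,
    max_points: int = 50_000,
    seed: int = 0,
    ref_white: str = "D65",
) -> Path:
    """Static 3D scatter of a pixel set, each point drawn in its own color.

    Sets larger than ``max_points`` are subsampled (seed logged) to keep the
    figure renderable. Axis labels and ranges follow the active color space.
    """
    if len(pixels) == 0:
        raise ChromadistError("cannot plot an empty pixel set")
    coords = pixels.coords
    if len(coords) > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(coords), size=max_points, replace=False)
        coords = coords[idx]
        logger.info("plot_pixels: subsampled to %d points (seed=%d)", max_points, seed)
    display = PixelSet(coords, space=pixels.space)
    if pixels.space == "lab":
        rgb = color_spaces.lab_to_rgb(display, white=ref_white).coords
        bounds = default_channel_bounds("lab")
    elif pixels.space == "hsv":
        rgb = color_spaces.hsv_to_rgb(display).coords
        bounds = default_channel_bounds("hsv")
    else:
        rgb = coords
        bounds = default_channel_bounds("rgb")
    names = CHANNEL_NAMES[pixels.space]
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(coords[:, 0], coords[:, 1], coords[:, 2], c=np.clip(rgb, 0, 1), s=2)
    for setter, name, (lo, hi) in zip(
        (ax.set_xlim, ax.set_ylim, ax.set_zlim), names, bounds
    ):
        setter(lo, hi)
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.set_zlabel(names[2])
    outfile = Path(outfile)
    fig.savefig(outfile, dpi=150)
    plt.close(fig)
    return outfile
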