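"""Synthetic benchmark images: color-proportion squares and green-screen scenes.

Two canonical benchmark sets probe the two axes a color distance must
resolve. The *quantity* set holds color identity fixed (cyan vs red, which
sit at opposite corners of the RGB cube) and varies only the proportions, in
quarter steps. The *similarity* set holds proportion fixed (solid squares)
and varies the color along a blue-to-yellow line. Green-screen scenes plant
known patch colors and proportions on a chroma-key background so the full
mask -> bin -> recover chain can be verified against ground truth.

All files are written as lossless 8-bit PNG; histogram and transport
metrics are invariant to pixel layout, so mixed squares use contiguous
blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_io import save_image

__all__ = [
    "CYAN",
    "RED",
    "BLUE",
    "YELLOW",
    "SceneSpec",
    "generate_quantity_set",
    "generate_similarity_endpoints",
    "generate_greenscreen_scene",
]

CYAN = (0.0, 1.0, 1.0)
RED = (1.0, 0.0, 0.0)
BLUE = (0.0, 0.0, 1.0)
YELLOW = (1.0, 1.0, 0.0)

#: Cyan proportions of the five quantity squares A-E.
QUANTITY_PROPORTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)


def _two_color_square(size: int, color_a, color_b, prop_a: float) -> np.ndarray:
    """Square with the first ``prop_a`` of pixels (row-major) in color_a."""
    n = size * size
    n_a = round(prop_a * n)
    flat = np.empty((n, 3))
    flat[:n_a] = color_a
    flat[n_a:] = color_b
    return flat.reshape(size, size, 3)


def generate_quantity_set(outdir: str | Path, size: int = 100) -> list[Path]:
    """Write the five cyan/red proportion squares A-E as PNGs.

    A is all cyan; B 3/4 cyan 1/4 red; C half and half; D 1/4 cyan; E all
    red. ``size`` must be divisible by 4 so quarter proportions are exact
    pixel counts.
    """
    if size % 4 != 0:
        raise ValueError("size must be divisible by 4 for exact quarter proportions")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, prop in zip("ABCDE", QUANTITY_PROPORTIONS):
        path = outdir / f"{label}.png"
        save_image(_two_color_square(size, CYAN, RED, prop), path)
        paths.append(path)
    return paths


def generate_similarity_endpoints(
    outdir: str | Path, size: int = 100, steps: int = 2
) -> list[Path]:
    """Write solid squares sampling a blue-to-yellow gradient.

    Endpoints are exactly (0,0,1) and (1,1,0); interior squares are linear
    RGB interpolants (a plain parameterization of the segment, chosen for
    reproducibility -- only the endpoints are calibrated anchors).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, t in enumerate(np.linspace(0.0, 1.0, steps)):
        color = (1 - t) * np.array(BLUE) + t * np.array(YELLOW)
        img = np.broadcast_to(color, (size, size, 3)).copy()
        path = outdir / f"gradient_{i:02d}.png"
        save_image(img, path)
        paths.append(path)
    return paths


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a green-screen scene with planted patch proportions."""

    size: int = 100
    patches: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((1.0, 0.0, 0.0), 0.5),
        ((0.0, 0.0, 1.0), 0.3),
        ((1.0, 1.0, 0.0), 0.2),
    )
    background: tuple[float, float, float] = (0.0, 1.0, 0.0)
    layout: str = "blocks"  # "blocks" | "stripes"
    seed: int = 0
    object_fraction: float = 0.5  # share of the frame covered by the object

    def __post_init__(self) -> None:
        props = [p for _, p in self.patches]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("patch proportions must sum to 1")
        for color, _ in self.patches:
            if any(v < 0 or v > 1 for v in color):
                raise ValueError("patch colors must lie in [0,1]^3")
        if self.layout not in ("blocks", "stripes"):
            raise ValueError("layout must be 'blocks' or 'stripes'")


def generate_greenscreen_scene(
    spec: SceneSpec, outdir: str | Path, name: str = "scene"
) -> tuple[Path, Path]:
    """Write a scene PNG plus a JSON ground-truth sidecar.

    Non-background pixels realize the patch proportions exactly (pixel
    counts are integers by construction after largest-remainder rounding).
    The background color must be separated from every patch color by more
    than 0.1 on at least one channel so a chroma-key range around it cannot
    swallow object pixels.
    """
    bg = np.array(spec.background)
    for color, _ in spec.patches:
        if np.max(np.abs(np.array(color) - bg)) <= 0.1:
            raise ValueError(
                f"patch color {color} is within 0.1 of the background {spec.background}"
            )
    n_total = spec.size * spec.size
    n_object = int(round(spec.object_fraction * n_total))
    props = np.array([p for _, p in spec.patches])
    counts = np.floor(props * n_object).astype(int)
    remainders = props * n_object - counts
    for i in np.argsort(-remainders)[: n_object - counts.sum()]:
        counts[i] += 1
    flat = np.broadcast_to(bg, (n_total, 3)).copy()
    colors = np.repeat(
        np.array([c for c, _ in spec.patches]), counts, axis=0
    )
    if spec.layout == "blocks":
        flat[:n_object] = colors
    else:  # stripes: interleave object rows with background rows
        rng = np.random.default_rng(spec.seed)
        positions = np.sort(rng.choice(n_total, size=n_object, replace=False))
        flat[positions] = colors
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{name}.png"
    save_image(flat.reshape(spec.size, spec.size, 3), img_path)
    truth_path = outdir / f"{name}.truth.json"
    truth = {
        "background": list(spec.background),
        "patches": [
            {"color": list(c), "proportion": float(p), "pixels": int(n)}
            for (c, p), n in zip(spec.patches, counts)
        ],
        "n_object_pixels": int(n_object),
        "size": spec.size,
        "layout": spec.layout,
        "seed": spec.seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return img_path, truth_path
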