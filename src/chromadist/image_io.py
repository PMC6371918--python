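"""Image loading and chroma-key background masking.

Images are read into H x W x 3 float arrays on a 0-1 scale (RGB order).
A pixel belongs to the background iff its value falls inside a user-declared
inclusive RGB range on every channel simultaneously -- the chroma-key
convention used for green-screen masks. Masking yields a flat ``PixelSet``,
the unit that flows through color conversion and binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import EmptyObjectError, ImageFormatError

__all__ = [
    "BackgroundRange",
    "ImageArray",
    "PixelSet",
    "load_image",
    "mask_background",
]

#: Channel labels per color space, used for CSV headers and plot axes.
CHANNEL_NAMES = {
    "rgb": ("R", "G", "B"),
    "hsv": ("H", "S", "V"),
    "lab": ("L", "a", "b"),
}


@dataclass(frozen=True)
class BackgroundRange:
    """Inclusive lower/upper RGB bounds defining pixels to ignore.

    A pixel is background iff ``lower[i] <= value[i] <= upper[i]`` holds for
    all three channels at once. Bounds are on the 0-1 scale.
    """

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = tuple(float(v) for v in self.lower)
        hi = tuple(float(v) for v in self.upper)
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("background bounds must be RGB triplets")
        for i, (a, b) in enumerate(zip(lo, hi)):
            if a > b:
                raise ValueError(
                    f"background lower bound exceeds upper bound on channel {i}: "
                    f"{a} > {b}"
                )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels (N x 3) inside this range on all channels."""
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((pixels >= lo) & (pixels <= hi), axis=-1)


Backgrounds = Union[BackgroundRange, Sequence[BackgroundRange]]


@dataclass
class ImageArray:
    """An RGB image as an H x W x 3 float array with channels on [0, 1]."""

    data: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {data.shape}")
        if data.min() < 0.0 or data.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        self.data = data

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class PixelSet:
    """A flat set of color coordinates in a declared space.

    ``coords`` is N x 3 in row-major scan order of the source image;
    ``n_source_pixels`` records how many object (non-background) pixels the
    source image held, which anchors bin-size proportions downstream.
    """

    coords: np.ndarray
    space: str = "rgb"
    n_source_pixels: int = field(default=-1)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"expected N x 3 coordinates, got shape {coords.shape}")
        space = self.space.lower()
        if space not in CHANNEL_NAMES:
            raise ValueError(f"unknown color space {self.space!r}")
        self.coords = coords
        self.space = space
        if self.n_source_pixels < 0:
            self.n_source_pixels = len(coords)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def channel_names(self) -> tuple[str, str, str]:
        return CHANNEL_NAMES[self.space]

    def to_csv(self, path: str | Path) -> None:
        """Write the pixels as a headered CSV (columns = channel names)."""
        header = ",".join(self.channel_names)
        np.savetxt(path, self.coords, delimiter=",", header=header, comments="")


def _as_ranges(background: Backgrounds) -> list[BackgroundRange]:
    if isinstance(background, BackgroundRange):
        return [background]
    return list(background)


def _read_rgb_array(path: Path) -> np.ndarray:
    """Decode a PNG/JPEG into an H x W x 3 float array on [0, 1].

    Fully transparent pixels are flagged by mapping them into every
    background range later; partially transparent pixels are composited
    over white first. Raises ImageFormatError for anything that is not a
    readable RGB(-promotable) image.
    """
    try:
        with Image.open(path) as img:
            mode = img.mode
            if mode == "P":
                img = img.convert("RGBA")
                mode = "RGBA"
            if mode not in ("RGB", "RGBA"):
                raise ImageFormatError(
                    f"{path}: unsupported image mode {mode!r}; "
                    "expected an RGB or RGBA PNG/JPEG"
                )
            arr = np.asarray(img, dtype=np.float64)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path}: not a readable PNG or JPEG image") from exc
    except FileNotFoundError:
        raise
    maxval = 65535.0 if arr.max() > 255.0 else 255.0
    arr = arr / maxval
    if arr.shape[2] == 4:
        rgb, alpha = arr[..., :3], arr[..., 3:4]
        # composite partial alpha over white; alpha == 0 handled by caller
        out = rgb * alpha + (1.0 - alpha)
        out[np.squeeze(alpha, -1) == 0.0] = np.nan  # sentinel: force background
        return out
    return arr


def mask_background(image: ImageArray, background: Backgrounds) -> PixelSet:
    """Drop every pixel inside any of the background ranges.

    Returns the remaining pixels (row-major order) as an RGB PixelSet. An
    empty result is allowed here; ``load_image`` turns it into an error.
    """
    flat = image.data.reshape(-1, 3)
    masked = np.zeros(len(flat), dtype=bool)
    for rng in _as_ranges(background):
        masked |= rng.contains(flat)
    kept = flat[~masked]
    return PixelSet(kept, space="rgb", n_source_pixels=len(kept))


def load_image(
    path: str | Path, background: Backgrounds
) -> tuple[ImageArray, PixelSet]:
    """Read a PNG/JPEG and separate object pixels from the background range.

    Returns the full image array and the PixelSet of non-background pixels.
    Raises ImageFormatError for unreadable or non-RGB files and
    EmptyObjectError if no object pixels remain.
    """
    path = Path(path)
    arr = _read_rgb_array(path)
    transparent = np.isnan(arr[..., 0])
    arr = np.where(np.isnan(arr), 0.0, arr)
    image = ImageArray(arr, source_path=str(path))
    flat = image.data.reshape(-1, 3)
    masked = transparent.reshape(-1)
    for rng in _as_ranges(background):
        masked |= rng.contains(flat)
    kept = flat[~masked]
    if len(kept) == 0:
        raise EmptyObjectError(
            f"{path}: every pixel falls inside the background range; "
            "no object pixels to analyze"
        )
    return image, PixelSet(kept, space="rgb", n_source_pixels=len(kept))


def save_image(image: ImageArray | np.ndarray, path: str | Path) -> None:
    """Write an RGB float array to an 8-bit PNG (lossless)."""
    data = image.data if isinstance(image, ImageArray) else np.asarray(image)
    quantized = np.round(np.clip(data, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(quantized, mode="RGB").save(path)
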