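"""Conversions among RGB, HSV, and CIE L*a*b* pixel sets.

The RGB <-> Lab chain is sRGB inverse companding -> linear RGB -> XYZ
(IEC 61966-2-1 sRGB primaries, D65) -> CIE L*a*b* relative to a chosen
standard-illuminant reference white. Non-D65 whites are reached by Bradford
chromatic adaptation. HSV is the standard hexcone model with all three
channels on [0, 1] (hue = angle / 360 degrees).

Large pixel sets can be subsampled before the (nonlinear, hence slowest)
Lab conversion with ``sample_for_conversion``; the default cap is 100,000
pixels, which preserves the color distribution to well within binning
resolution.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import color as _skcolor

from .errors import ConfigurationError
from .image_io import PixelSet

__all__ = [
    "REFERENCE_WHITES",
    "reference_white",
    "rgb_to_lab",
    "lab_to_rgb",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "convert_pixels",
    "sample_for_conversion",
    "DEFAULT_SAMPLE_LIMIT",
    "DEFAULT_SAMPLE_SEED",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_LIMIT = 100_000
DEFAULT_SAMPLE_SEED = 0

#: CIE 1931 2-degree observer tristimulus values, Y normalized to 1.
REFERENCE_WHITES: dict[str, tuple[float, float, float]] = {
    "A": (1.09850, 1.0, 0.35585),
    "B": (0.99072, 1.0, 0.85223),
    "C": (0.98074, 1.0, 1.18232),
    "E": (1.0, 1.0, 1.0),
    "D50": (0.96422, 1.0, 0.82521),
    "D55": (0.95682, 1.0, 0.92149),
    "D65": (0.95047, 1.0, 1.08883),
    "D75": (0.94972, 1.0, 1.22638),
}

# sRGB (linear) -> XYZ under D65, IEC 61966-2-1.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)

# Bradford cone-response matrix for chromatic adaptation.
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
_BRADFORD_INV = np.linalg.inv(_BRADFORD)

_D65 = np.array(REFERENCE_WHITES["D65"])


def reference_white(name: str) -> np.ndarray:
    """Look up a standard illuminant's tristimulus values (Y = 1)."""
    key = name.upper()
    if key not in REFERENCE_WHITES:
        valid = ", ".join(sorted(REFERENCE_WHITES))
        raise ConfigurationError(
            f"unknown reference white {name!r}; valid names: {valid}"
        )
    return np.array(REFERENCE_WHITES[key])


def _adaptation_matrix(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Bradford transform mapping XYZ under `source` white to `target` white."""
    cone_src = _BRADFORD @ source
    cone_dst = _BRADFORD @ target
    return _BRADFORD_INV @ np.diag(cone_dst / cone_src) @ _BRADFORD


def _srgb_inverse_companding(v: np.ndarray) -> np.ndarray:
    # linear segment below 0.04045, power segment above
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_companding(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, None)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA, t**3, 3.0 * _DELTA**2 * (t - 4.0 / 29.0))


def _rgb_array_to_lab(rgb: np.ndarray, white: np.ndarray) -> np.ndarray:
    linear = _srgb_inverse_companding(rgb)
    xyz = linear @ _SRGB_TO_XYZ.T
    if not np.allclose(white, _D65):
        xyz = xyz @ _adaptation_matrix(_D65, white).T
    f = _lab_f(xyz / white)
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def _lab_array_to_rgb(lab: np.ndarray, white: np.ndarray) -> tuple[np.ndarray, int]:
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * white
    if not np.allclose(white, _D65):
        xyz = xyz @ _adaptation_matrix(white, _D65).T
    linear = xyz @ _XYZ_TO_SRGB.T
    rgb = _srgb_companding(np.clip(linear, 0.0, None))
    clipped = int(np.count_nonzero(np.any((rgb < 0.0) | (rgb > 1.0), axis=-1)))
    return np.clip(rgb, 0.0, 1.0), clipped


def rgb_to_lab(pixels: PixelSet, white: str = "D65") -> PixelSet:
    """Convert an RGB PixelSet to CIE L*a*b* under the named reference white."""
    if pixels.space != "rgb":
        raise ValueError(f"expected RGB pixels, got {pixels.space}")
    wp = reference_white(white)
    lab = _rgb_array_to_lab(pixels.coords, wp)
    return PixelSet(lab, space="lab", n_source_pixels=pixels.n_source_pixels)


def lab_to_rgb(pixels: PixelSet, white: str = "D65") -> PixelSet:
    """Convert Lab pixels back to sRGB; out-of-gamut results are clipped.

    Clipping is logged (count of affected pixels) rather than raised: the
    inverse map is used for rendering bin colors, where a nearest-gamut
    color is the right answer.
    """
    if pixels.space != "lab":
        raise ValueError(f"expected Lab pixels, got {pixels.space}")
    wp = reference_white(white)
    rgb, clipped = _lab_array_to_rgb(pixels.coords, wp)
    if clipped:
        logger.warning("lab_to_rgb: clipped %d out-of-gamut pixels", clipped)
    return PixelSet(rgb, space="rgb", n_source_pixels=pixels.n_source_pixels)


def rgb_to_hsv(pixels: PixelSet) -> PixelSet:
    """Convert RGB to hexcone HSV with all channels on [0, 1]."""
    if pixels.space != "rgb":
        raise ValueError(f"expected RGB pixels, got {pixels.space}")
    hsv = _skcolor.rgb2hsv(pixels.coords.reshape(-1, 1, 3)).reshape(-1, 3)
    return PixelSet(hsv, space="hsv", n_source_pixels=pixels.n_source_pixels)


def hsv_to_rgb(pixels: PixelSet) -> PixelSet:
    """Inverse hexcone transform, HSV -> RGB."""
    if pixels.space != "hsv":
        raise ValueError(f"expected HSV pixels, got {pixels.space}")
    rgb = _skcolor.hsv2rgb(pixels.coords.reshape(-1, 1, 3)).reshape(-1, 3)
    return PixelSet(rgb, space="rgb", n_source_pixels=pixels.n_source_pixels)


def convert_pixels(pixels: PixelSet, space: str, white: str = "D65") -> PixelSet:
    """Convert an RGB PixelSet into the requested analysis space."""
    space = space.lower()
    if space == "rgb":
        return pixels
    if space == "hsv":
        return rgb_to_hsv(pixels)
    if space == "lab":
        return rgb_to_lab(pixels, white=white)
    raise ConfigurationError(f"unknown color space {space!r}; valid: rgb, hsv, lab")


def sample_for_conversion(
    pixels: PixelSet,
    limit: int = DEFAULT_SAMPLE_LIMIT,
    seed: int = DEFAULT_SAMPLE_SEED,
) -> PixelSet:
    """Uniform subsample without replacement when N exceeds `limit`.

    Identity when N <= limit. Reproducible for a fixed seed; the seed is the
    caller's to record. The sample becomes the new object pixel set, so bin
    proportions downstream are relative to the sample.
    """
    if limit < 1:
        raise ValueError("sample limit must be >= 1")
    if len(pixels) <= limit:
        return pixels
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pixels), size=limit, replace=False)
    idx.sort()
    return PixelSet(pixels.coords[idx], space=pixels.space)
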