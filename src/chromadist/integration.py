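"""Optional integration checks against published example photographs.

The flower, butterfly, and flounder examples in the original study depend on
photographs distributed in a companion repository, not regenerable from
stated numbers. These helpers run the corresponding analyses *if* a user
supplies local copies of those photos; they are documentation-grade checks,
not part of the test suite, and raise FileNotFoundError cleanly when the
photos are absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .binning import HistogramSpec, histogram_bin
from .color_spaces import rgb_to_lab
from .image_io import BackgroundRange, load_image

__all__ = ["flower_histogram_check"]

#: Published 8-bin Lab histogram of the green-screened flower photo
#: (2 bins/channel, a/b bounds +/-100, D65): the two nonzero bins.
FLOWER_EXPECTED_NONZERO = [
    {"L": 23.72, "a": 13.98, "b": 18.18, "size": 0.15},
    {"L": 77.16, "a": 11.82, "b": 77.82, "size": 0.82},
]


def flower_histogram_check(photo_path: str | Path) -> dict:
    """Recompute the flower's 8-bin Lab histogram from a local photo.

    Returns a dict with the computed bins and the published nonzero rows for
    side-by-side comparison. Raises FileNotFoundError if the photo is not
    present locally.
    """
    photo_path = Path(photo_path)
    if not photo_path.exists():
        raise FileNotFoundError(
            f"{photo_path}: the flower photograph is not distributed with "
            "chromadist; supply a local copy to run this check"
        )
    background = BackgroundRange(lower=(0.0, 0.6, 0.0), upper=(0.4, 1.0, 0.4))
    _, pixels = load_image(photo_path, background)
    lab = rgb_to_lab(pixels, white="D65")
    spec = HistogramSpec(
        bins_per_channel=(2, 2, 2),
        channel_bounds=((0.0, 100.0), (-100.0, 100.0), (-100.0, 100.0)),
        space="lab",
    )
    hist = histogram_bin(lab, spec, label=photo_path.stem)
    return {
        "computed": [
            {"center": list(np.round(b.center, 2)), "size": round(b.size, 2)}
            for b in hist.bins
        ],
        "published_nonzero": FLOWER_EXPECTED_NONZERO,
    }
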