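"""Measurement areas and their CIELAB color summaries.

A measurement area is a binary pixel mask over the photograph — in the
clinical workflow, area 1 is the whole irradiated breast and area 2 the
non-irradiated contralateral breast serving as the patient's own
baseline.  Color statistics (per-channel mean and SD) are computed over
every pixel inside the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio

from .colorspace import LabImage

__all__ = [
    "MeasurementArea",
    "ColorSummary",
    "load_mask",
    "check_minimum_area",
    "summarize_area",
    "MINIMUM_AREA_PIXELS",
]

logger = logging.getLogger(__name__)

# Clinical protocol floor for a stable whole-area mean: one megapixel.
MINIMUM_AREA_PIXELS = 1_000_000


@dataclass
class MeasurementArea:
    """Binary region of interest with a semantic label
    (``irradiated``, ``control``, or any other name)."""

    mask: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if not self.mask.any():
            raise ValueError("empty measurement area")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class ColorSummary:
    """Mean and SD of L*, a*, b* over one measurement area.

    SDs use the population denominator (n): within a single area they are
    descriptive, not inferential.
    """

    mean_L: float
    mean_a: float
    mean_b: float
    sd_L: float
    sd_a: float
    sd_b: float
    pixel_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_L <= 100.0):
            raise ValueError("mean_L must lie in [0, 100]")
        if min(self.sd_L, self.sd_a, self.sd_b) < 0:
            raise ValueError("SDs must be nonnegative")
        if self.pixel_count <= 0:
            raise ValueError("pixel_count must be positive")


def load_mask(path, image_shape: tuple[int, int], label: str = "other") -> MeasurementArea:
    """Read a single-channel 8-bit mask PNG; nonzero pixels are inside.

    The mask must match the photograph's H×W exactly.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[-1] not in (1, 2):  # tolerate grayscale(+alpha) stored with channels
            raise ValueError(f"mask at {path} is not single-channel (shape {arr.shape})")
        arr = arr[..., 0]
    if arr.shape != tuple(image_shape):
        raise ValueError(
            f"mask dimensions {arr.shape} do not match image dimensions {tuple(image_shape)}"
        )
    if not (arr != 0).any():
        raise ValueError("empty measurement area")
    return MeasurementArea(arr != 0, label=label)


def check_minimum_area(area: MeasurementArea, minimum: int = MINIMUM_AREA_PIXELS) -> bool:
    """Warn (never fail) when an area is below the protocol's pixel floor.

    Returns True when the area passes.  The floor is a warning so that
    small bench-scale images remain analysable.
    """
    if area.pixel_count < minimum:
        logger.warning(
            "measurement area %r has %d pixels, below the recommended minimum of %d",
            area.label,
            area.pixel_count,
            minimum,
        )
        return False
    return True


def summarize_area(lab: LabImage, area: MeasurementArea) -> ColorSummary:
    """Arithmetic mean and population SD of each Lab channel over the mask."""
    if lab.shape != area.shape:
        raise ValueError(
            f"image dimensions {lab.shape} do not match mask dimensions {area.shape}"
        )
    m = area.mask
    L, a, b = lab.L[m], lab.a[m], lab.b[m]
    return ColorSummary(
        mean_L=float(L.mean()),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_L=float(L.std()),
        sd_a=float(a.std()),
        sd_b=float(b.std()),
        pixel_count=int(m.sum()),
    )
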