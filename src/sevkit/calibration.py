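"""Color calibration from a photographed reference card.

A reference card with patches of known color is photographed alongside
the skin.  Comparing the observed patch colors with their nominal values
yields a per-image color correction that removes illumination casts and
exposure differences, so CIELAB measurements are comparable across
photographs.

The correction model is affine in linear RGB: observed linear-RGB colors
are mapped through a 3×3 matrix plus offset fitted by ordinary least
squares over the card patches.  Affine-in-linear absorbs both a global
chromatic cast (matrix) and an exposure/black-level shift (offset) and
has a closed-form fit; nonlinear (polynomial) models are deliberately out
of scope.

Patch locations are supplied by a :class:`CardLayout` config (JSON or
YAML), not detected automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .colorspace import RGBImage, srgb_to_linear, linear_to_srgb

__all__ = [
    "CardPatch",
    "CardLayout",
    "CalibrationTransform",
    "extract_patch_colors",
    "fit_color_correction",
    "apply_correction",
    "default_card_layout",
    "COLORCHECKER_SRGB",
]

# Nominal 8-bit sRGB coordinates of the classic 24-patch color rendition
# chart (rows: natural, miscellaneous, primary/secondary, grayscale).
COLORCHECKER_SRGB: dict[str, tuple[int, int, int]] = {
    "dark_skin": (115, 82, 68),
    "light_skin": (194, 150, 130),
    "blue_sky": (98, 122, 157),
    "foliage": (87, 108, 67),
    "blue_flower": (133, 128, 177),
    "bluish_green": (103, 189, 170),
    "orange": (214, 126, 44),
    "purplish_blue": (80, 91, 166),
    "moderate_red": (193, 90, 99),
    "purple": (94, 60, 108),
    "yellow_green": (157, 188, 64),
    "orange_yellow": (224, 163, 46),
    "blue": (56, 61, 150),
    "green": (70, 148, 73),
    "red": (175, 54, 60),
    "yellow": (231, 199, 31),
    "magenta": (187, 86, 149),
    "cyan": (8, 133, 161),
    "white": (243, 243, 242),
    "neutral_8": (200, 200, 200),
    "neutral_6_5": (160, 160, 160),
    "neutral_5": (122, 122, 121),
    "neutral_3_5": (85, 85, 85),
    "black": (52, 52, 52),
}


@dataclass
class CardPatch:
    """One card patch: id, pixel rectangle (x0, y0, x1, y1; 0-based,
    half-open) and nominal sRGB triple in [0, 1]."""

    patch_id: str
    rect: tuple[int, int, int, int]
    reference_srgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"patch {self.patch_id!r}: empty rectangle {self.rect}")
        ref = np.asarray(self.reference_srgb, dtype=float)
        if ref.shape != (3,) or ref.min() < 0 or ref.max() > 1:
            raise ValueError(f"patch {self.patch_id!r}: reference sRGB must be 3 values in [0, 1]")


@dataclass
class CardLayout:
    """Geometry and reference colors of the card as photographed."""

    patches: list[CardPatch]

    def __post_init__(self) -> None:
        if len(self.patches) < 4:
            raise ValueError("a card layout needs at least 4 patches")
        rects = [p.rect for p in self.patches]
        for i, r in enumerate(rects):
            for s in rects[i + 1 :]:
                if r[0] < s[2] and s[0] < r[2] and r[1] < s[3] and s[1] < r[3]:
                    raise ValueError("patch rectangles overlap")

    @property
    def reference_srgb(self) -> np.ndarray:
        return np.array([p.reference_srgb for p in self.patches])

    @property
    def reference_linear(self) -> np.ndarray:
        return srgb_to_linear(self.reference_srgb)

    def to_dict(self) -> dict:
        return {
            "patches": [
                {"id": p.patch_id, "rect": list(p.rect), "reference_srgb": list(p.reference_srgb)}
                for p in self.patches
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CardLayout":
        return cls(
            [
                CardPatch(p["id"], tuple(p["rect"]), tuple(p["reference_srgb"]))
                for p in d["patches"]
            ]
        )

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "CardLayout":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def default_card_layout(
    patch_size: int = 20, gap: int = 4, origin: tuple[int, int] = (0, 0), cols: int = 6
) -> CardLayout:
    """A 24-patch chart laid out on a ``cols``-wide grid.

    Used both to render the card into synthetic images and as the default
    fixture layout; real photographs need a layout matching where the card
    actually sits in the frame.
    """
    ox, oy = origin
    patches = []
    for i, (name, srgb8) in enumerate(COLORCHECKER_SRGB.items()):
        r, c = divmod(i, cols)
        x0 = ox + c * (patch_size + gap)
        y0 = oy + r * (patch_size + gap)
        patches.append(
            CardPatch(name, (x0, y0, x0 + patch_size, y0 + patch_size), tuple(v / 255.0 for v in srgb8))
        )
    return CardLayout(patches)


@dataclass
class CalibrationTransform:
    """Fitted affine color correction in linear RGB.

    ``fit_residual`` is the root-mean-square patch error (linear-RGB
    units, all channels pooled) after applying the correction to the
    observed patch colors.
    """

    matrix: np.ndarray
    offset: np.ndarray
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.matrix.shape != (3, 3) or self.offset.shape != (3,):
            raise ValueError("matrix must be 3×3 and offset length 3")
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.offset))):
            raise ValueError("transform parameters must be finite")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("correction matrix is singular")
        if self.fit_residual < 0:
            raise ValueError("fit_residual must be nonnegative")

    def apply_to_colors(self, colors: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of linear-RGB colors (no clipping)."""
        return np.asarray(colors, dtype=float) @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "CalibrationTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "fit_residual": float(self.fit_residual),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CalibrationTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["matrix"]), np.array(d["offset"]), d["fit_residual"])


def extract_patch_colors(img: RGBImage, layout: CardLayout, min_pixels: int = 25) -> np.ndarray:
    """Mean linear-RGB color of every card patch, in layout order.

    The mean is taken in linear light (sRGB input is decoded first) so
    that patch averages commute with the affine correction model.
    """
    lin = img.pixels if img.encoding == "linear" else srgb_to_linear(img.pixels)
    out = np.empty((len(layout.patches), 3))
    for i, p in enumerate(layout.patches):
        x0, y0, x1, y1 = p.rect
        if x0 < 0 or y0 < 0 or x1 > img.width or y1 > img.height:
            raise ValueError(f"patch {p.patch_id!r} rectangle {p.rect} lies outside the image")
        if (x1 - x0) * (y1 - y0) < min_pixels:
            raise ValueError(
                f"patch {p.patch_id!r} has {(x1 - x0) * (y1 - y0)} pixels; "
                f"at least {min_pixels} required for a stable mean"
            )
        out[i] = lin[y0:y1, x0:x1].reshape(-1, 3).mean(axis=0)
    return out


def fit_color_correction(observed: np.ndarray, reference: np.ndarray) -> CalibrationTransform:
    """Least-squares affine map taking observed patch colors to reference.

    Both arguments are N×3 linear-RGB arrays in matching order, N ≥ 4.
    Raises if the observed patches are chromatically degenerate (e.g. an
    all-gray card), which leaves the affine fit underdetermined.
    """
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape or observed.ndim != 2 or observed.shape[1] != 3:
        raise ValueError("observed and reference must be N×3 arrays of equal length")
    n = observed.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 patches to fit an affine correction, got {n}")
    design = np.hstack([observed, np.ones((n, 1))])
    if np.linalg.matrix_rank(design, tol=1e-10) < 4:
        raise ValueError(
            "patch set is chromatically degenerate (observed colors span fewer than "
            "3 dimensions, e.g. an all-gray card); the affine fit is underdetermined"
        )
    coef, *_ = np.linalg.lstsq(design, reference, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    resid = reference - (observed @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationTransform(matrix, offset, rms)


def calibrate_from_image(img: RGBImage, layout: CardLayout) -> CalibrationTransform:
    """Convenience: extract patch colors and fit the correction."""
    return fit_color_correction(extract_patch_colors(img, layout), layout.reference_linear)


def apply_correction(img: RGBImage, t: CalibrationTransform) -> RGBImage:
    """Apply a fitted correction to a whole image.

    The affine map acts per pixel in linear RGB; results are clipped to
    [0, 1] (count reported on ``clipped_pixels``) and re-encoded to sRGB.
    """
    lin = img.pixels if img.encoding == "linear" else srgb_to_linear(img.pixels)
    corrected = t.apply_to_colors(lin)
    clipped = int(np.count_nonzero(np.any((corrected < -1e-9) | (corrected > 1 + 1e-9), axis=-1)))
    corrected = np.clip(corrected, 0.0, 1.0)
    return RGBImage(linear_to_srgb(corrected), encoding="srgb", clipped_pixels=clipped)
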