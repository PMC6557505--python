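"""Pixel-wise conversion between sRGB and CIELAB.

Skin photographs arrive as gamma-encoded sRGB; all colorimetric analysis
happens in CIELAB (D65 white point, 2° standard observer), the
device-independent space in which L* is perceptual lightness (0 black,
100 white), a* the green–red axis and b* the blue–yellow axis.  The
conversion chain is the standard one: sRGB transfer-function decoding to
linear light, the sRGB primary matrix to XYZ, then the CIE cube-root
mapping to L*a*b*.

The white point used for normalisation is the XYZ of linear RGB (1,1,1)
under the sRGB matrix, so reference white maps to exactly
(L*, a*, b*) = (100, 0, 0) and every neutral gray has a* = b* = 0 to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

__all__ = [
    "RGBImage",
    "LabImage",
    "srgb_to_linear",
    "linear_to_srgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "read_image",
    "write_image",
]

# sRGB (IEC 61966-2-1) primaries -> XYZ, D65.  White = M @ (1,1,1).
XYZ_FROM_LINEAR_RGB = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)
LINEAR_RGB_FROM_XYZ = np.linalg.inv(XYZ_FROM_LINEAR_RGB)
WHITE_POINT = XYZ_FROM_LINEAR_RGB.sum(axis=1)  # (0.9505, 1.0000, 1.0890)

_DELTA = 6.0 / 29.0


@dataclass
class RGBImage:
    """An H×W×3 image with channel values in [0, 1].

    ``encoding`` records whether the values are gamma-encoded sRGB (the
    normal state of a photograph on disk) or linear light.
    ``clipped_pixels`` is set by operations that had to clip out-of-range
    results (gamut mapping, calibration) and is ``None`` otherwise.
    """

    pixels: np.ndarray
    encoding: str = "srgb"
    clipped_pixels: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected an H×W×3 array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.encoding not in ("srgb", "linear"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixel values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_array(cls, arr: np.ndarray, encoding: str = "srgb") -> "RGBImage":
        """Build from an integer or float array; integers are normalised
        by the dtype maximum (255 for uint8, 65535 for uint16)."""
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        return cls(arr.astype(float), encoding=encoding)


@dataclass
class LabImage:
    """Per-pixel CIELAB coordinates of an image.

    L is lightness in [0, 100]; a and b are the chromatic opponent axes
    (unbounded in principle; finite always).  All three share the source
    image's H×W shape.
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (self.L.shape == self.a.shape == self.b.shape) or self.L.ndim != 2:
            raise ValueError("L, a, b must be 2-D arrays of identical shape")
        for name, ch in (("L", self.L), ("a", self.a), ("b", self.b)):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"{name} channel contains non-finite values")
        if self.L.min() < -1e-9 or self.L.max() > 100.0 + 1e-9:
            raise ValueError("L* must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def stack(self) -> np.ndarray:
        """Return an H×W×3 array with channels (L, a, b)."""
        return np.stack([self.L, self.a, self.b], axis=-1)

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "LabImage":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[..., 0], arr[..., 1], arr[..., 2])


def srgb_to_linear(v):
    """Decode sRGB-encoded values in [0, 1] to linear light.

    Piecewise IEC 61966-2-1 transfer function: linear segment below
    0.04045, power 2.4 above.  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)) or v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("sRGB values must be finite and in [0, 1]")
    out = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    return out if out.ndim else float(out)


def linear_to_srgb(v):
    """Encode linear-light values in [0, 1] to sRGB (inverse of
    :func:`srgb_to_linear`)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)) or v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("linear values must be finite and in [0, 1]")
    out = np.where(v <= 0.04045 / 12.92, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)
    return out if out.ndim else float(out)


def _f(t: np.ndarray) -> np.ndarray:
    # CIE lightness companding: cube root above (6/29)^3, linear below.
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def _f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > _DELTA, u**3, 3.0 * _DELTA**2 * (u - 4.0 / 29.0))


def rgb_to_lab(img: RGBImage) -> LabImage:
    """Convert an RGB image to CIELAB (D65, 2° observer).

    Gamma-encoded input is decoded to linear light first; images already
    flagged ``linear`` skip that step.
    """
    rgb = img.pixels
    if img.encoding == "srgb":
        rgb = srgb_to_linear(rgb)
    xyz = rgb @ XYZ_FROM_LINEAR_RGB.T
    fxyz = _f(xyz / WHITE_POINT)
    L = 116.0 * fxyz[..., 1] - 16.0
    a = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    b = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    # guard against -1e-15 style round-off at pure black
    return LabImage(np.clip(L, 0.0, 100.0), a, b)


def lab_to_rgb(lab: LabImage) -> RGBImage:
    """Convert CIELAB back to sRGB.

    Exact inverse of :func:`rgb_to_lab` for in-gamut colors.  Out-of-gamut
    results are clipped to [0, 1]; the number of affected pixels is
    reported on the returned image's ``clipped_pixels`` field rather than
    raised, since clipping is routine when rendering synthetic colors.
    """
    fy = (lab.L + 16.0) / 116.0
    fx = fy + lab.a / 500.0
    fz = fy - lab.b / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1) * WHITE_POINT
    rgb_lin = xyz @ LINEAR_RGB_FROM_XYZ.T
    # tolerance keeps pure round-off (≲1e-12) out of the clipped count
    clipped = int(np.count_nonzero(np.any((rgb_lin < -1e-9) | (rgb_lin > 1 + 1e-9), axis=-1)))
    rgb_lin = np.clip(rgb_lin, 0.0, 1.0)
    return RGBImage(linear_to_srgb(rgb_lin), encoding="srgb", clipped_pixels=clipped)


def read_image(path) -> RGBImage:
    """Read an 8- or 16-bit PNG/TIFF as an sRGB-encoded :class:`RGBImage`.

    Integer samples are normalised by the dtype maximum; an alpha channel,
    if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return RGBImage.from_array(arr, encoding="srgb")


def write_image(img: RGBImage, path, bit_depth: int = 8) -> None:
    """Write an sRGB image as PNG (8-bit) or TIFF (8- or 16-bit).

    16-bit color PNG is refused: no available codec round-trips it, and a
    silent depth downgrade would corrupt calibration data.  Use TIFF for
    16-bit output.
    """
    if img.encoding != "srgb":
        img = RGBImage(linear_to_srgb(img.pixels), encoding="srgb")
    if bit_depth == 8:
        arr = np.round(img.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        if str(path).lower().endswith(".png"):
            raise ValueError("16-bit color PNG is not supported; write a TIFF instead")
        arr = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, arr)
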