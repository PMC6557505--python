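"""Standard Erythema Value (SEV) and baseline-subtracted ΔSEV.

Redness alone (a*) under-reports erythema on pigmented skin: increased
pigmentation lowers L* and with it a*, so light and dark skin at the same
physiological redness return different a*.  SEV compensates by weighting
redness with the lightness deficit:

    SEV = (L*max − L*) · a*        per pixel, L*max = 100 by default

(L*max = 100 is the top of the CIELAB lightness scale).  The area SEV is
the arithmetic mean of per-pixel SEVs over the measurement mask; the SEV
of the area's *mean color* is also exposed, and for inhomogeneous areas
the two differ by exactly the covariance of (−L*) and a* over the mask.

ΔSEV subtracts the patient's own baseline (the contralateral control
area), removing inter-patient baseline skin-tone scatter:

    ΔSEV = SEV(measured area) − SEV(baseline area)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import LabImage
from .measurement import ColorSummary, MeasurementArea

__all__ = ["SEVResult", "DeltaSEV", "sev_map", "delta_sev", "sev_of_mean_color"]

DEFAULT_L_MAX = 100.0


@dataclass
class SEVResult:
    """Per-pixel SEV map (NaN outside the mask) with its area mean/SD."""

    sev_map: np.ndarray
    mean_sev: float
    sd_sev: float
    l_max: float = DEFAULT_L_MAX
    label: str = "other"

    def __post_init__(self) -> None:
        self.sev_map = np.asarray(self.sev_map, dtype=float)
        if self.sev_map.ndim != 2:
            raise ValueError("sev_map must be 2-D")
        if self.sd_sev < 0:
            raise ValueError("sd_sev must be nonnegative")


@dataclass
class DeltaSEV:
    """Baseline-subtracted erythema value for one patient/time point."""

    value: float
    sev_measured: float
    sev_baseline: float

    def __post_init__(self) -> None:
        if not np.isclose(self.value, self.sev_measured - self.sev_baseline):
            raise ValueError("value must equal sev_measured - sev_baseline")


def sev_map(lab: LabImage, area: MeasurementArea, l_max: float = DEFAULT_L_MAX) -> SEVResult:
    """Per-pixel SEV over a measurement area, with area mean and SD.

    Raises if any masked L* exceeds ``l_max``: with the default ceiling of
    100 that signals a broken upstream conversion, not a valid color.
    """
    if lab.shape != area.shape:
        raise ValueError(f"image dimensions {lab.shape} do not match mask {area.shape}")
    m = area.mask
    if np.any(lab.L[m] > l_max + 1e-9):
        raise ValueError(
            f"L* exceeds l_max={l_max} inside the measurement area; "
            "check the color conversion or the l_max setting"
        )
    smap = np.full(lab.shape, np.nan)
    smap[m] = (l_max - lab.L[m]) * lab.a[m]
    vals = smap[m]
    return SEVResult(
        sev_map=smap,
        mean_sev=float(vals.mean()),
        sd_sev=float(vals.std()),
        l_max=l_max,
        label=area.label,
    )


def delta_sev(measured: SEVResult, baseline: SEVResult) -> DeltaSEV:
    """ΔSEV = mean SEV of the measured area minus the baseline area's.

    Both results must share the same L*max, otherwise their SEV scales are
    incommensurable.
    """
    if measured.l_max != baseline.l_max:
        raise ValueError(
            f"l_max mismatch: measured uses {measured.l_max}, baseline {baseline.l_max}"
        )
    return DeltaSEV(
        value=measured.mean_sev - baseline.mean_sev,
        sev_measured=measured.mean_sev,
        sev_baseline=baseline.mean_sev,
    )


def sev_of_mean_color(summary: ColorSummary, l_max: float = DEFAULT_L_MAX) -> float:
    """SEV of the area's mean color, (l_max − mean L*) · mean a*.

    For a uniform area this equals the per-pixel mean SEV; over an
    inhomogeneous area the per-pixel mean exceeds it by cov(−L*, a*).
    Exposed for sensitivity comparison; the per-pixel mean is canonical.
    """
    return (l_max - summary.mean_L) * summary.mean_a
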