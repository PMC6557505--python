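"""Synthetic skin photographs and cohorts with known ground truth.

No patient images are distributable, so every pipeline stage is exercised
against simulations whose true colors, erythema fields and effect sizes
are known exactly.

The image generator renders a two-breast scene in CIELAB: a uniform
baseline skin tone (default: the control-skin means of a white European
breast-cancer cohort, L* 66.66, a* 6.91, b* 16.53), an "irradiated"
region where a spatially smooth erythema field raises a* and lowers L* —
irradiated skin reacts inhomogeneously, so the field is low-pass-filtered
seeded noise rather than a flat offset — per-pixel Lab noise, an optional
global affine cast in linear RGB (mis-set white balance / exposure), and
an optional rendered reference card for the calibration stage.

The cohort generator draws per-patient baseline tones and arm-specific
irradiation effects (defaults match the reported arm contrasts:
irradiated a* 11.4 ± 4.0 under dexpanthenol ointment vs 15.6 ± 4.9 under
the milk-protein product), then simulates two observers' CTCAE grades as
a noisy threshold function of the true ΔSEV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationTransform, CardLayout, default_card_layout, apply_correction
from .colorspace import LabImage, RGBImage, lab_to_rgb
from .cohort import PatientRecord
from .erythema import DEFAULT_L_MAX, delta_sev, sev_map
from .measurement import ColorSummary, MeasurementArea, summarize_area

__all__ = [
    "SkinImageSpec",
    "SkinImageSample",
    "CohortSpec",
    "generate_skin_image",
    "generate_cohort",
    "BASELINE_LAB",
    "BASELINE_SD",
    "IRRADIATED_LAB",
    "ARM_EFFECTS",
]

# Cohort control-skin means and between-patient SDs (L*, a*, b*).
BASELINE_LAB = (66.66, 6.91, 16.53)
BASELINE_SD = (6.99, 3.16, 4.75)
# Cohort irradiated-skin means (both arms pooled).
IRRADIATED_LAB = (58.60, 12.83, 14.63)

# Per-arm mean irradiation effect (ΔL*, Δa*, Δb*) relative to baseline and
# the between-patient SD of the effect.  Means reconstruct the reported
# per-arm irradiated values (a* 11.4 vs 15.6, b* 13.4 vs 17.0, L* drop
# shared); effect SDs chosen so the irradiated a* SDs land near the
# reported 4.0 / 4.9.
ARM_EFFECTS = {
    "Bepanthen": {"mean": (-8.06, 4.49, -3.13), "sd": (2.0, 2.45, 2.0)},
    "R1R2": {"mean": (-8.06, 8.69, 0.47), "sd": (2.0, 3.74, 2.0)},
}


@dataclass
class SkinImageSpec:
    """Parameters of one synthetic skin photograph.

    erythema_amplitude / erythema_l_drop are the *peak* Δa* rise and ΔL*
    drop of the smooth field (the spatial field spans [0, 1], so the area
    mean shift is roughly half the peak).  field_smoothness is the
    Gaussian correlation length in pixels; pixel_noise_sd is per-channel
    Lab noise.  cast, if given, corrupts the rendered image in linear RGB
    after the card is drawn, so the calibration stage can undo it.
    """

    baseline_lab: tuple[float, float, float] = BASELINE_LAB
    erythema_amplitude: float = 11.8
    erythema_l_drop: float = 16.1
    field_smoothness: float = 12.0
    pixel_noise_sd: float = 0.8
    cast: CalibrationTransform | None = None
    include_card: bool = True
    image_size: tuple[int, int] = (192, 288)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: every synthetic image must be reproducible")
        if not 0.0 < self.baseline_lab[0] < 100.0:
            raise ValueError("baseline L* must lie in (0, 100)")
        if self.erythema_amplitude < 0 or self.erythema_l_drop < 0:
            raise ValueError("erythema amplitudes must be nonnegative")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be nonnegative")
        if min(self.image_size) < 32:
            raise ValueError("image must be at least 32×32")


@dataclass
class SkinImageSample:
    """A rendered image plus everything the generator knows to be true."""

    rgb: RGBImage
    lab_truth: LabImage
    masks: dict[str, MeasurementArea]
    card_layout: CardLayout | None
    true_summaries: dict[str, ColorSummary]
    true_delta_sev: float


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded white noise, Gaussian-smoothed and min-max rescaled to [0, 1].

    A correlation length much larger than the image means a spatially
    constant reaction; short-circuit to the flat field at 0.5 (the
    large-sigma limit) instead of filtering.
    """
    if not np.isfinite(sigma) or sigma >= 4 * max(shape):
        return np.full(shape, 0.5)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (raw - lo) / (hi - lo)


def _scene_masks(h: int, w: int, card_rows: int) -> tuple[np.ndarray, np.ndarray]:
    """Irradiated region on the left half, control on the right, with a
    margin and (optionally) a card strip at the bottom kept clear."""
    usable_h = h - card_rows
    margin_y = max(2, usable_h // 10)
    margin_x = max(2, w // 20)
    irr = np.zeros((h, w), dtype=bool)
    ctrl = np.zeros((h, w), dtype=bool)
    irr[margin_y : usable_h - margin_y, margin_x : w // 2 - margin_x] = True
    ctrl[margin_y : usable_h - margin_y, w // 2 + margin_x : w - margin_x] = True
    return irr, ctrl


def generate_skin_image(spec: SkinImageSpec) -> SkinImageSample:
    """Render one synthetic photograph and return it with its ground truth.

    The truth summaries and ΔSEV are computed from the exact Lab field
    used for rendering (erythema plus pixel noise, before gamut clipping
    and sRGB encoding), so pipeline recovery error isolates rendering
    and calibration effects.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)

    card_layout = None
    card_rows = 0
    if spec.include_card:
        patch = max(8, min(h, w) // 16)
        gap = max(2, patch // 5)
        card_rows = 4 * (patch + gap) + gap
        card_layout = default_card_layout(patch_size=patch, gap=gap, origin=(gap, h - card_rows + gap))

    irr_mask, ctrl_mask = _scene_masks(h, w, card_rows)

    L0, a0, b0 = spec.baseline_lab
    L = np.full((h, w), float(L0))
    a = np.full((h, w), float(a0))
    b = np.full((h, w), float(b0))

    fld = _smooth_field((h, w), spec.field_smoothness, rng)
    a[irr_mask] += spec.erythema_amplitude * fld[irr_mask]
    L[irr_mask] -= spec.erythema_l_drop * fld[irr_mask]

    if spec.pixel_noise_sd > 0:
        L += rng.normal(0.0, spec.pixel_noise_sd, (h, w))
        a += rng.normal(0.0, spec.pixel_noise_sd, (h, w))
        b += rng.normal(0.0, spec.pixel_noise_sd, (h, w))

    if L.min() < 0.0 or L.max() > 100.0:
        raise ValueError(
            f"spec pushes L* outside [0, 100] (range {L.min():.2f}..{L.max():.2f}); "
            "reduce erythema_l_drop or pixel_noise_sd"
        )

    lab_truth = LabImage(L, a, b)
    rgb = lab_to_rgb(lab_truth)

    if card_layout is not None:
        px = rgb.pixels.copy()
        for p in card_layout.patches:
            x0, y0, x1, y1 = p.rect
            px[y0:y1, x0:x1] = p.reference_srgb
        rgb = RGBImage(px, encoding="srgb", clipped_pixels=rgb.clipped_pixels)

    if spec.cast is not None:
        rgb = apply_correction(rgb, spec.cast)

    masks = {
        "irradiated": MeasurementArea(irr_mask, label="irradiated"),
        "control": MeasurementArea(ctrl_mask, label="control"),
    }
    true_summaries = {k: summarize_area(lab_truth, m) for k, m in masks.items()}
    true_dsev = delta_sev(
        sev_map(lab_truth, masks["irradiated"]), sev_map(lab_truth, masks["control"])
    ).value

    return SkinImageSample(
        rgb=rgb,
        lab_truth=lab_truth,
        masks=masks,
        card_layout=card_layout,
        true_summaries=true_summaries,
        true_delta_sev=true_dsev,
    )


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-arm cohort.

    Per-patient baseline tones are normal around ``baseline_mean`` with
    ``baseline_sd``; each patient's irradiated tone is baseline plus an
    arm-specific normal effect.  In fast mode each area's pixels are
    sampled directly in Lab (``n_pixels`` per area with ``within_sd``
    within-image scatter) instead of rendering full images — two orders
    of magnitude faster, identical summary-level behavior.

    Grades: observer grade = 1 + #{ΔSEV thresholds exceeded}, with
    observer-specific threshold offsets and a small probability of a ±1
    slip, the minimal model producing realistic inter-observer
    disagreement.
    """

    n_per_arm: tuple[int, int] = (66, 34)  # (Bepanthen, R1R2)
    arm_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in ARM_EFFECTS.items()})
    baseline_mean: tuple[float, float, float] = BASELINE_LAB
    baseline_sd: tuple[float, float, float] = BASELINE_SD
    n_pixels: int = 1000
    within_sd: tuple[float, float, float] = (3.0, 1.5, 1.5)
    grade_thresholds: tuple[float, float] = (250.0, 480.0)
    observer_offsets: tuple[float, float] = (0.0, 130.0)
    grade_slip_prob: float = 0.08
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_per_arm) < 2:
            raise ValueError("need at least 2 patients per arm")
        if min(self.baseline_sd) < 0 or min(self.within_sd) < 0:
            raise ValueError("SDs must be nonnegative")
        if not 0 <= self.grade_slip_prob <= 1:
            raise ValueError("grade_slip_prob must be a probability")


def _grade(dsev: np.ndarray, thresholds, offset: float, slip: np.ndarray) -> np.ndarray:
    g = np.ones(len(dsev), dtype=int)
    for t in thresholds:
        g += (dsev > t + offset).astype(int)
    return np.clip(g + slip, 0, 4)


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], dict]:
    """Simulate a cohort; returns the patient records and the ground truth
    (per-patient true Lab means and true ΔSEV, plus the spec's effects).

    Each patient's measured summaries come from ``n_pixels`` Lab samples
    per area, and ΔSEV is the per-pixel mean SEV difference — the same
    estimator the imaging pipeline applies to real photographs.
    """
    rng = np.random.default_rng(spec.seed)
    arms = np.concatenate(
        [np.repeat(arm, n) for arm, n in zip(("Bepanthen", "R1R2"), spec.n_per_arm)]
    )
    n = len(arms)
    base_mean = np.asarray(spec.baseline_mean)
    base_sd = np.asarray(spec.baseline_sd)
    baselines = rng.normal(base_mean, base_sd, size=(n, 3))
    # keep tones physically plausible: L* in (5, 95), a*,b* free
    baselines[:, 0] = np.clip(baselines[:, 0], 5.0, 95.0)

    effects = np.empty((n, 3))
    for arm, cfg in spec.arm_effects.items():
        sel = arms == arm
        effects[sel] = rng.normal(
            np.asarray(cfg["mean"]), np.asarray(cfg["sd"]), size=(int(sel.sum()), 3)
        )
    irradiated = baselines + effects
    irradiated[:, 0] = np.clip(irradiated[:, 0], 5.0, 95.0)

    within = np.asarray(spec.within_sd)
    npx = spec.n_pixels
    ctrl_px = baselines[:, None, :] + rng.normal(0.0, within, size=(n, npx, 3))
    irr_px = irradiated[:, None, :] + rng.normal(0.0, within, size=(n, npx, 3))
    for px in (ctrl_px, irr_px):
        px[..., 0] = np.clip(px[..., 0], 0.0, 100.0)

    def _summaries(px: np.ndarray) -> list[ColorSummary]:
        mean = px.mean(axis=1)
        sd = px.std(axis=1)
        return [
            ColorSummary(*mean[i], *sd[i], pixel_count=npx) for i in range(n)
        ]

    ctrl_sum = _summaries(ctrl_px)
    irr_sum = _summaries(irr_px)
    sev_ctrl = ((DEFAULT_L_MAX - ctrl_px[..., 0]) * ctrl_px[..., 1]).mean(axis=1)
    sev_irr = ((DEFAULT_L_MAX - irr_px[..., 0]) * irr_px[..., 1]).mean(axis=1)
    dsev = sev_irr - sev_ctrl

    true_dsev = (DEFAULT_L_MAX - irradiated[:, 0]) * irradiated[:, 1] - (
        DEFAULT_L_MAX - baselines[:, 0]
    ) * baselines[:, 1]

    slips = rng.choice([-1, 0, 1], size=(2, n), p=[spec.grade_slip_prob / 2, 1 - spec.grade_slip_prob, spec.grade_slip_prob / 2])
    grades1 = _grade(true_dsev, spec.grade_thresholds, spec.observer_offsets[0], slips[0])
    grades2 = _grade(true_dsev, spec.grade_thresholds, spec.observer_offsets[1], slips[1])

    fitz = rng.choice([2, 3, 4], size=n, p=[0.32, 0.60, 0.08])

    records = [
        PatientRecord(
            patient_id=f"P{i + 1:03d}",
            arm=str(arms[i]),
            fitzpatrick=int(fitz[i]),
            control_summary=ctrl_sum[i],
            irradiated_summary=irr_sum[i],
            delta_sev=float(dsev[i]),
            grades={"obs1": int(grades1[i]), "obs2": int(grades2[i])},
        )
        for i in range(n)
    ]
    truth = {
        "baseline_lab": baselines,
        "irradiated_lab": irradiated,
        "true_delta_sev": true_dsev,
        "mean_sev_irradiated": sev_irr,
        "arm_effects": spec.arm_effects,
        "arms": arms,
    }
    return records, truth
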