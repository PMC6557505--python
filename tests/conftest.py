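import numpy as np
import pytest

from sevkit import RGBImage, default_card_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def card_layout():
    """24-patch chart layout sized for a small test frame."""
    return default_card_layout(patch_size=10, gap=2)


def render_card_image(layout, cast=None, noise_sd=0.0, seed=0, shape=None):
    """Render a flat image containing the card's patches at their
    reference colors, optionally corrupted by an affine cast in linear
    RGB and per-pixel noise.  Shared by calibration tests."""
    from sevkit.colorspace import linear_to_srgb, srgb_to_linear

    if shape is None:
        h = max(p.rect[3] for p in layout.patches) + 2
        w = max(p.rect[2] for p in layout.patches) + 2
        shape = (h, w)
    gen = np.random.default_rng(seed)
    px = np.full((*shape, 3), 0.5)
    for p in layout.patches:
        x0, y0, x1, y1 = p.rect
        px[y0:y1, x0:x1] = p.reference_srgb
    if cast is not None:
        lin = srgb_to_linear(px)
        lin = np.clip(lin @ cast.matrix.T + cast.offset, 0.0, 1.0)
        px = linear_to_srgb(lin)
    if noise_sd > 0:
        px = np.clip(px + gen.normal(0.0, noise_sd, px.shape), 0.0, 1.0)
    return RGBImage(px, encoding="srgb")
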