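import numpy as np
import pytest

from zonescore import DEFAULT_SCHEME, LabelMask, SyntheticSpec

BG = DEFAULT_SCHEME.label("background")
TP = DEFAULT_SCHEME.label("tumor_k17pos")
TN = DEFAULT_SCHEME.label("tumor_k17neg")
CD4 = DEFAULT_SCHEME.label("cd4")
CD8 = DEFAULT_SCHEME.label("cd8")
CD16 = DEFAULT_SCHEME.label("cd16")
CD163 = DEFAULT_SCHEME.label("cd163")


def make_mask(pixels, resolution=1.0, case_id="test") -> LabelMask:
    return LabelMask(
        pixels=np.asarray(pixels, dtype=np.int64),
        resolution_um_per_px=resolution,
        case_id=case_id,
        scheme=DEFAULT_SCHEME,
    )


def random_tumor_mask(rng, shape=(60, 60), resolution=1.0,
                      p_pos=0.05, p_neg=0.05, p_immune=0.05) -> LabelMask:
    """Random sparse label mask guaranteed to contain tumor pixels."""
    h, w = shape
    u = rng.random((h, w))
    pix = np.full((h, w), BG, dtype=np.int64)
    pix[u < p_pos] = TP
    pix[(u >= p_pos) & (u < p_pos + p_neg)] = TN
    lo = p_pos + p_neg
    for i, lab in enumerate((CD4, CD8, CD16, CD163)):
        sel = (u >= lo + i * p_immune / 4) & (u < lo + (i + 1) * p_immune / 4)
        pix[sel] = lab
    if not ((pix == TP) | (pix == TN)).any():
        pix[h // 2, w // 2] = TP
    return make_mask(pix, resolution)


def small_spec(**overrides) -> SyntheticSpec:
    """Down-scaled generator settings for fast tests.

    1 um/px on a 320 um field with a few 40 um nests keeps a full
    generate+zone+score cycle well under 100 ms while leaving tens of cells
    per marker in the stromal band.
    """
    params = dict(
        image_shape=(320, 320),
        resolution_um_per_px=1.0,
        n_nests=7,
        nest_scale_um=40.0,
        base_intensity=600.0,
        seed=0,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
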