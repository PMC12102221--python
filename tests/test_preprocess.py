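"""Per-stage contracts of the preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcnpipe.io_core import ConfigError, DataError, ImageStack, PipelineConfig
from lcnpipe.preprocess import (
    PIPELINE_STAGES,
    auto_brightness_correct,
    binarize,
    clahe,
    gaussian_denoise,
    normalize_intensity,
    preprocess_pipeline,
    resample_isotropic,
    sigmoid_contrast,
)


def stack_of(vox, voxel=(1.0, 0.2, 0.2)):
    return ImageStack(np.asarray(vox, float), voxel)


def random_stack(rng, shape=(4, 32, 32), voxel=(1.0, 0.2, 0.2)):
    return stack_of(rng.uniform(0, 1, shape), voxel)


# -- brightness ------------------------------------------------------------

def test_brightness_constant_slice_is_identity():
    s = stack_of(np.full((2, 40, 40), 0.5))
    out = auto_brightness_correct(s, kernel_um=4.0, stride_um=1.0)
    assert np.allclose(out.voxels, 0.5)
    assert out.provenance[-1] == "brightness"


def test_brightness_single_window_equals_global_stretch(rng):
    sl = rng.uniform(0.2, 0.9, (1, 30, 30))
    s = stack_of(sl, voxel=(1.0, 1.0, 1.0))
    # kernel covering the whole slice, zero saturation, guard disabled
    out = auto_brightness_correct(
        s, kernel_um=60.0, stride_um=10.0, saturation_fraction=0.0, min_range_fraction=0.0
    )
    expected = (sl - sl.min()) / (sl.max() - sl.min())
    assert np.allclose(out.voxels, expected, atol=1e-12)


def test_brightness_equalizes_illumination_gradient(rng):
    # fixed pattern modulated by a left-to-right illumination ramp
    pattern = 0.5 + 0.4 * np.sin(2 * np.pi * np.arange(96) / 8.0)[None, :] * np.ones((96, 1))
    ramp = np.linspace(0.4, 1.0, 96)[None, :]
    sl = (pattern * ramp)[None]
    s = stack_of(sl, voxel=(1.0, 1.0, 1.0))
    out = auto_brightness_correct(s, kernel_um=16.0, stride_um=4.0, saturation_fraction=0.0)
    # contrast (std) per column block should be equalized across the ramp
    def block_std(img):
        return np.array([img[0, :, i : i + 16].std() for i in range(8, 80, 16)])
    before = block_std(sl)
    after = block_std(out.voxels)
    assert before.max() / before.min() > 1.5  # the ramp produces real imbalance
    assert after.max() / after.min() < 1.05


def test_brightness_requires_kernel_above_stride():
    s = stack_of(np.zeros((1, 8, 8)))
    with pytest.raises(ConfigError):
        auto_brightness_correct(s, kernel_um=1.0, stride_um=2.0)


def test_brightness_kernel_under_two_pixels_rejected():
    s = stack_of(np.zeros((1, 8, 8)), voxel=(1.0, 1.0, 1.0))
    with pytest.raises(ConfigError, match="2 px"):
        auto_brightness_correct(s, kernel_um=1.4, stride_um=0.5)


# -- gaussian --------------------------------------------------------------

def test_gauss_constant_image_unchanged():
    s = stack_of(np.full((2, 16, 16), 0.3))
    out = gaussian_denoise(s, 3.25)
    assert np.allclose(out.voxels, 0.3)


def test_gauss_impulse_mass_and_sigma():
    """0.2 µm pixels with coefficient 3.25 give a 0.65 px sigma kernel."""
    vox = np.zeros((1, 41, 41))
    vox[0, 20, 20] = 1.0
    out = gaussian_denoise(stack_of(vox), 3.25).voxels[0]
    assert abs(out.sum() - 1.0) < 1e-6  # kernel mass is normalized
    yy, xx = np.mgrid[0:41, 0:41]
    var_y = float((out * (yy - 20) ** 2).sum())
    var_x = float((out * (xx - 20) ** 2).sum())
    assert var_y == pytest.approx(0.65**2, rel=0.05)
    assert var_x == pytest.approx(0.65**2, rel=0.05)


def test_gauss_rejects_anisotropic_in_plane():
    s = ImageStack(np.zeros((2, 8, 8)), (1.0, 0.2, 0.3))
    with pytest.raises(DataError, match="resample"):
        gaussian_denoise(s, 3.25)


# -- normalize -------------------------------------------------------------

def test_normalize_affine_map():
    out = normalize_intensity(stack_of(np.array([[[0.2, 0.4, 0.6]]])))
    assert np.allclose(out.voxels, [[[0.0, 0.5, 1.0]]])


def test_normalize_idempotent_on_spanning_stack(rng):
    vox = rng.uniform(0, 1, (3, 8, 8))
    vox.flat[0], vox.flat[1] = 0.0, 1.0
    out = normalize_intensity(stack_of(vox))
    assert np.allclose(out.voxels, vox)


def test_normalize_constant_stack_raises():
    with pytest.raises(DataError, match="constant"):
        normalize_intensity(stack_of(np.full((2, 4, 4), 0.7)))


def test_normalize_postcondition_exact_bounds(rng):
    for _ in range(5):
        out = normalize_intensity(random_stack(rng))
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0


# -- clahe -----------------------------------------------------------------

def test_clahe_constant_slice_stays_constant():
    out = clahe(stack_of(np.full((2, 40, 40), 0.25)), kernel_um=2.0)
    for z in range(2):
        assert np.ptp(out.voxels[z]) < 1e-9


def test_clahe_brightens_dim_tubes_on_dark_background():
    sl = np.full((64, 64), 0.05)
    tube = np.zeros((64, 64), bool)
    tube[30:34, :] = True
    sl[tube] = 0.3  # dim structure
    s = stack_of(sl[None], voxel=(1.0, 0.2, 0.2))
    out = clahe(s, kernel_um=6.0, clip_limit=0.01)
    assert out.voxels[0][tube].mean() > sl[tube].mean()


def test_clahe_output_in_unit_interval(rng):
    out = clahe(random_stack(rng), kernel_um=2.0)
    assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0


# -- sigmoid ---------------------------------------------------------------

def test_sigmoid_midpoint_maps_to_half():
    s = stack_of(np.array([[[0.3]]]))
    out = sigmoid_contrast(s, gain=10.0, cutoff_mode=0.3)
    assert out.voxels.flat[0] == pytest.approx(0.5)


def test_sigmoid_closed_form_value():
    s = stack_of(np.array([[[0.0]]]))
    out = sigmoid_contrast(s, gain=10.0, cutoff_mode=0.5)
    assert out.voxels.flat[0] == pytest.approx(1.0 / (1.0 + np.exp(5.0)), rel=1e-9)


def test_sigmoid_rejects_nonpositive_gain():
    with pytest.raises(ConfigError):
        sigmoid_contrast(stack_of(np.zeros((1, 2, 2))), gain=0.0)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=16), st.floats(1.0, 30.0))
def test_sigmoid_preserves_monotone_ordering(values, gain):
    vox = np.asarray(values).reshape(1, 1, -1)
    out = sigmoid_contrast(stack_of(vox), gain=gain, cutoff_mode=0.5).voxels
    order = np.argsort(vox.ravel())
    assert np.all(np.diff(out.ravel()[order]) >= -1e-12)


# -- resample --------------------------------------------------------------

def test_resample_halves_in_plane_shape():
    s = stack_of(np.zeros((10, 100, 100)), voxel=(0.4, 0.2, 0.2))
    out = resample_isotropic(s, 0.4)
    assert out.shape == (10, 50, 50)
    assert out.voxel_size_um == (0.4, 0.4, 0.4)


def test_resample_identity_when_already_isotropic(rng):
    vox = rng.uniform(0, 1, (8, 8, 8))
    s = stack_of(vox, voxel=(0.4, 0.4, 0.4))
    out = resample_isotropic(s, 0.4)
    assert out.shape == (8, 8, 8)
    assert np.allclose(out.voxels, vox, atol=1e-6)


def test_resample_constant_stays_constant():
    s = stack_of(np.full((6, 20, 20), 0.42), voxel=(1.0, 0.2, 0.2))
    out = resample_isotropic(s, 0.4)
    assert np.allclose(out.voxels, 0.42, atol=1e-9)


def test_resample_target_coarser_than_extent_rejected():
    s = stack_of(np.zeros((2, 20, 20)), voxel=(1.0, 0.2, 0.2))
    with pytest.raises(DataError, match="coarser"):
        resample_isotropic(s, 10.0)


# -- binarize --------------------------------------------------------------

def test_binarize_thresholds_inclusively():
    iso = (0.4, 0.4, 0.4)
    assert binarize(stack_of(np.full((2, 3, 3), 0.7), iso), 0.6).mask.all()
    assert binarize(stack_of(np.full((2, 3, 3), 0.6), iso), 0.6).mask.all()
    assert not binarize(stack_of(np.full((2, 3, 3), 0.59), iso), 0.6).mask.any()


def test_binarize_requires_isotropic():
    with pytest.raises(DataError, match="isotropic"):
        binarize(stack_of(np.zeros((2, 3, 3)), (1.0, 0.2, 0.2)), 0.6)


def test_binarize_is_deterministic(rng):
    s = stack_of(rng.uniform(0, 1, (3, 8, 8)), (0.4, 0.4, 0.4))
    a = binarize(s, 0.6).mask
    b = binarize(s, 0.6).mask
    assert np.array_equal(a, b)


# -- whole chain -----------------------------------------------------------

def test_pipeline_provenance_lists_stages_in_order(rng):
    s = random_stack(rng, shape=(6, 40, 40))
    out = preprocess_pipeline(s, PipelineConfig())
    assert tuple(out.provenance[-7:]) == PIPELINE_STAGES


def test_pipeline_constant_dark_stack_raises_degenerate(rng):
    s = stack_of(np.zeros((4, 40, 40)))
    with pytest.raises(DataError, match="constant"):
        preprocess_pipeline(s, PipelineConfig())


def test_pipeline_deterministic(rng):
    vox = rng.uniform(0, 1, (6, 40, 40))
    cfg = PipelineConfig()
    a = preprocess_pipeline(stack_of(vox), cfg).mask
    b = preprocess_pipeline(stack_of(vox.copy()), cfg).mask
    assert np.array_equal(a, b)


def test_intensity_stages_map_unit_interval_into_itself(rng):
    s = random_stack(rng)
    stages = [
        lambda x: auto_brightness_correct(x, 4.0, 1.0),
        lambda x: gaussian_denoise(x, 3.25),
        normalize_intensity,
        lambda x: clahe(x, 2.0),
        lambda x: sigmoid_contrast(x, 10.0, "auto"),
        lambda x: resample_isotropic(x, 0.4),
    ]
    for fn in stages:
        out = fn(s)
        assert out.voxels.min() >= -1e-12 and out.voxels.max() <= 1 + 1e-12
        if fn is not stages[-1]:
            assert out.shape == s.shape  # only resampling changes shape
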