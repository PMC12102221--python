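"""Pre-processing chain: raw anisotropic stack -> isotropic binary LCN mask.

Stage order (fixed): per-slice sliding-window brightness correction ->
per-slice Gaussian denoising -> global intensity normalization -> per-slice
CLAHE -> sigmoid contrast correction -> trilinear isotropic resampling ->
thresholding. Every intensity stage maps [0, 1] into [0, 1]; only the
resampling stage changes the grid.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage import exposure

from .io_core import ConfigError, DataError, ImageStack, PipelineConfig, um_to_vox
from .segment import BinaryStack

log = logging.getLogger(__name__)

__all__ = [
    "auto_brightness_correct",
    "gaussian_denoise",
    "normalize_intensity",
    "clahe",
    "sigmoid_contrast",
    "resample_isotropic",
    "binarize",
    "preprocess_pipeline",
    "PIPELINE_STAGES",
]

PIPELINE_STAGES = (
    "brightness",
    "gauss",
    "normalize",
    "clahe",
    "sigmoid",
    "resample",
    "binarize",
)


def _window_centers(extent: int, win: int, stride: int) -> np.ndarray:
    """Window-center coordinates covering [0, extent) at the given stride."""
    half = win / 2.0
    if extent <= win:
        return np.array([extent / 2.0])
    first, last = half, extent - half
    n = max(int(np.floor((last - first) / stride)) + 1, 1)
    centers = first + stride * np.arange(n)
    if centers[-1] < last - 1e-9:
        centers = np.append(centers, last)
    return centers


def auto_brightness_correct(
    stack: ImageStack,
    kernel_um: float = 50.0,
    stride_um: float = 8.0,
    saturation_fraction: float = 0.0035,
    min_range_fraction: float = 0.2,
) -> ImageStack:
    """Per-slice sliding-window brightness/contrast stretch.

    Each z-slice is covered by square windows of side ``kernel_um`` placed
    every ``stride_um``. In each window the low/high bounds are the
    quantiles saturating ``saturation_fraction / 2`` of the pixels at each
    tail; the bounds are bilinearly interpolated between window centers
    and a linear stretch ``(v - low) / (high - low)`` (clipped to [0, 1])
    is applied. Windows whose dynamic range falls below
    ``min_range_fraction`` of the robust stack range carry no usable
    signal (e.g. pure background) and are left unstretched, which keeps
    empty regions from being amplified into full-scale noise.
    """
    if not (kernel_um > stride_um > 0):
        raise ConfigError(f"need kernel_um > stride_um > 0, got {kernel_um}, {stride_um}")
    pz, py, px = stack.voxel_size_um
    if abs(py - px) > 1e-9:
        raise DataError("in-plane pixel sizes must be equal; resample first")
    win = um_to_vox(kernel_um, py, what="brightness kernel")
    stride = max(um_to_vox(stride_um, py, what="brightness stride"), 1)
    if win < 2:
        raise ConfigError(f"brightness kernel converts to {win} px (< 2 px) at {py} µm pitch")

    g_lo, g_hi = np.percentile(stack.voxels, [0.5, 99.5])
    min_range = max(min_range_fraction * (g_hi - g_lo), 1e-12)
    q = saturation_fraction / 2.0

    out = np.empty_like(stack.voxels, dtype=np.float64)
    H, W = stack.shape[1:]
    cy = _window_centers(H, win, stride)
    cx = _window_centers(W, win, stride)
    for z in range(stack.shape[0]):
        sl = stack.voxels[z]
        lo = np.empty((cy.size, cx.size))
        hi = np.empty((cy.size, cx.size))
        for i, yc in enumerate(cy):
            y0, y1 = max(int(round(yc - win / 2)), 0), min(int(round(yc + win / 2)), H)
            for j, xc in enumerate(cx):
                x0, x1 = max(int(round(xc - win / 2)), 0), min(int(round(xc + win / 2)), W)
                window = sl[y0:y1, x0:x1]
                if q > 0:
                    wl, wh = np.quantile(window, [q, 1.0 - q])
                else:
                    wl, wh = float(window.min()), float(window.max())
                if wh - wl < min_range:
                    wl, wh = 0.0, 1.0  # degenerate window: identity stretch
                lo[i, j], hi[i, j] = wl, wh
        if cy.size == 1 and cx.size == 1:
            lo_map = np.full((H, W), lo[0, 0])
            hi_map = np.full((H, W), hi[0, 0])
        else:
            yy, xx = np.meshgrid(
                np.clip(np.arange(H) + 0.5, cy[0], cy[-1]),
                np.clip(np.arange(W) + 0.5, cx[0], cx[-1]),
                indexing="ij",
            )
            pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
            if cy.size == 1:
                pts_1d = pts[:, 1]
                lo_map = np.interp(pts_1d, cx, lo[0]).reshape(H, W)
                hi_map = np.interp(pts_1d, cx, hi[0]).reshape(H, W)
            elif cx.size == 1:
                pts_1d = pts[:, 0]
                lo_map = np.interp(pts_1d, cy, lo[:, 0]).reshape(H, W)
                hi_map = np.interp(pts_1d, cy, hi[:, 0]).reshape(H, W)
            else:
                lo_map = RegularGridInterpolator((cy, cx), lo)(pts).reshape(H, W)
                hi_map = RegularGridInterpolator((cy, cx), hi)(pts).reshape(H, W)
        span = np.maximum(hi_map - lo_map, 1e-12)
        out[z] = np.clip((sl - lo_map) / span, 0.0, 1.0)
    return stack.replace(voxels=out, stage="brightness")


def gaussian_denoise(stack: ImageStack, coeff: float = 3.25, dims: int = 2) -> ImageStack:
    """Gaussian noise filter; sigma in pixels = ``coeff`` × in-plane pixel size in µm."""
    if coeff <= 0:
        raise ConfigError(f"gauss coefficient must be > 0, got {coeff}")
    pz, py, px = stack.voxel_size_um
    if abs(py - px) > 1e-9:
        raise DataError("in-plane pixel sizes must be equal; resample first")
    sigma_px = coeff * py
    if dims == 2:
        out = ndimage.gaussian_filter(stack.voxels, sigma=(0.0, sigma_px, sigma_px), mode="reflect")
    elif dims == 3:
        out = ndimage.gaussian_filter(stack.voxels, sigma=sigma_px, mode="reflect")
    else:
        raise ConfigError(f"gauss_dims must be 2 or 3, got {dims}")
    return stack.replace(voxels=out, stage="gauss")


def normalize_intensity(stack: ImageStack) -> ImageStack:
    """Affine map of the whole stack so min -> 0 and max -> 1."""
    lo = float(stack.voxels.min())
    hi = float(stack.voxels.max())
    if hi - lo < 1e-12:
        raise DataError("constant stack: nothing to normalize")
    out = (stack.voxels - lo) / (hi - lo)
    return stack.replace(voxels=out, stage="normalize")


def clahe(
    stack: ImageStack,
    kernel_um: float = 6.0,
    clip_limit: float = 0.01,
    min_range_fraction: float = 0.2,
) -> ImageStack:
    """Per-slice contrast-limited adaptive histogram equalization.

    Slices whose robust dynamic range falls below ``min_range_fraction``
    of the robust stack range contain background only; equalizing them
    would blow noise up to full scale, so they pass through unchanged.
    """
    pz, py, px = stack.voxel_size_um
    if abs(py - px) > 1e-9:
        raise DataError("in-plane pixel sizes must be equal; resample first")
    k = um_to_vox(kernel_um, py, what="clahe kernel")
    if k < 2:
        raise ConfigError(f"CLAHE kernel converts to {k} px (< 2 px) at {py} µm pitch")
    H, W = stack.shape[1:]
    if k > min(H, W):
        log.info("CLAHE kernel %d px exceeds slice %dx%d; falling back to one tile", k, H, W)
        k = min(H, W)
    vox = np.clip(stack.voxels, 0.0, 1.0)
    g_lo, g_hi = np.percentile(vox, [0.5, 99.5])
    min_range = max(min_range_fraction * (g_hi - g_lo), 1e-12)
    out = np.empty_like(vox)
    for z in range(stack.shape[0]):
        sl = vox[z]
        s_lo, s_hi = np.percentile(sl, [0.5, 99.5])
        if s_hi - s_lo < min_range:
            out[z] = sl  # background-only (or constant) slice: nothing to equalize
            continue
        out[z] = exposure.equalize_adapthist(sl, kernel_size=k, clip_limit=clip_limit)
    return stack.replace(voxels=np.clip(out, 0.0, 1.0), stage="clahe")


def sigmoid_contrast(
    stack: ImageStack, gain: float = 10.0, cutoff_mode: str | float = "auto"
) -> ImageStack:
    """Sigmoid contrast correction ``out = 1 / (1 + exp(gain (cutoff - in)))``.

    With ``cutoff_mode='auto'`` the cutoff is image specific: the midpoint
    of the robust intensity range [p1, p99] of the stack.
    """
    if gain <= 0:
        raise ConfigError(f"sigmoid gain must be > 0, got {gain}")
    if isinstance(cutoff_mode, str):
        if cutoff_mode != "auto":
            raise ConfigError(f"cutoff_mode must be 'auto' or numeric, got {cutoff_mode!r}")
        p1, p99 = np.percentile(stack.voxels, [1.0, 99.0])
        cutoff = float(p1 + p99) / 2.0
    else:
        cutoff = float(cutoff_mode)
    out = 1.0 / (1.0 + np.exp(gain * (cutoff - stack.voxels)))
    return stack.replace(voxels=out, stage="sigmoid")


def resample_isotropic(stack: ImageStack, target_um: float = 0.4) -> ImageStack:
    """Trilinear resampling onto an isotropic grid of pitch ``target_um``.

    The new shape per axis is ``round(extent_um / target_um)``; voxel
    centers sit at integer multiples of the pitch on both grids.
    """
    if target_um <= 0:
        raise ConfigError(f"target pitch must be > 0, got {target_um}")
    new_shape = tuple(
        int(np.floor(ext / target_um + 0.5)) for ext in stack.extent_um
    )
    if min(new_shape) < 1:
        raise DataError(
            f"target pitch {target_um} µm is coarser than the stack extent {stack.extent_um} µm"
        )
    grids = [
        np.arange(n_new) * target_um / pitch
        for n_new, pitch in zip(new_shape, stack.voxel_size_um)
    ]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        stack.voxels, np.stack([zz, yy, xx]), order=1, mode="nearest"
    )
    return stack.replace(
        voxels=out, voxel_size_um=(target_um,) * 3, stage="resample"
    )


def binarize(stack: ImageStack, threshold: float = 0.6) -> BinaryStack:
    """Threshold the isotropic stack: mask = (intensity >= threshold)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigError(f"threshold must lie in (0, 1), got {threshold}")
    if not stack.is_isotropic():
        raise DataError(
            f"binarize requires an isotropic stack; got voxel sizes {stack.voxel_size_um} "
            "(resample first)"
        )
    mask = stack.voxels >= threshold
    return BinaryStack(mask, stack.voxel_size_um[0], stack.provenance + ["binarize"])


def preprocess_pipeline(stack: ImageStack, config: PipelineConfig) -> BinaryStack:
    """Run the full chain brightness -> gauss -> normalize -> clahe ->
    sigmoid -> resample -> binarize with the given configuration."""
    config.validate()
    stages = [
        ("brightness", lambda s: auto_brightness_correct(
            s,
            config.brightness_kernel_um,
            config.brightness_stride_um,
            config.brightness_saturation_fraction,
            config.min_signal_range_fraction,
        )),
        ("gauss", lambda s: gaussian_denoise(s, config.gauss_sigma_coeff, config.gauss_dims)),
        ("normalize", normalize_intensity),
        ("clahe", lambda s: clahe(s, config.clahe_kernel_um, config.clahe_clip_limit, config.min_signal_range_fraction)),
        ("sigmoid", lambda s: sigmoid_contrast(s, config.sigmoid_gain, config.sigmoid_cutoff_mode)),
        ("resample", lambda s: resample_isotropic(s, config.target_iso_um)),
    ]
    cur = stack
    for name, fn in stages:
        try:
            cur = fn(cur)
        except (DataError, ConfigError) as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
    try:
        return binarize(cur, config.binarize_threshold)
    except (DataError, ConfigError) as exc:
        raise type(exc)(f"[stage binarize] {exc}") from exc
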