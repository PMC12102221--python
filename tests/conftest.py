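"""Shared fixtures: hand-built voxel scenes used as segmentation oracles.

The builders rasterize analytic solids (balls, tubes, polyline tubes)
directly on the isotropic working grid, independently of the phantom
module's renderer, so tests compare pipeline output against geometry
constructed by a second code path.
"""

from __future__ import annotations

import numpy as np
import pytest

from lcnpipe.io_core import PipelineConfig
from lcnpipe.segment import BinaryStack

PITCH = 0.4  # µm, the isotropic working pitch


def empty_mask(shape: tuple[int, int, int]) -> np.ndarray:
    return np.zeros(shape, bool)


def add_ball(mask: np.ndarray, center_um, radius_um: float, pitch: float = PITCH) -> None:
    grids = [np.arange(n) * pitch for n in mask.shape]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    c = np.asarray(center_um, float)
    mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius_um**2


def add_polyline_tube(
    mask: np.ndarray, points_um, radius_um: float, pitch: float = PITCH
) -> float:
    """Paint a tube along a polyline; returns the polyline arc length (µm)."""
    pts = np.asarray(points_um, float)
    grids = [np.arange(n) * pitch for n in mask.shape]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1)
    arc = 0.0
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = p1 - p0
        L2 = float(np.dot(seg, seg))
        arc += np.sqrt(L2)
        if L2 < 1e-12:
            d = np.linalg.norm(p - p0, axis=-1)
        else:
            t = np.clip(np.sum((p - p0) * seg, axis=-1) / L2, 0.0, 1.0)
            d = np.linalg.norm(p - (p0 + t[..., None] * seg), axis=-1)
        mask |= d <= radius_um
    return arc


def add_tube(mask, p0_um, p1_um, radius_um: float, pitch: float = PITCH) -> float:
    return add_polyline_tube(mask, [p0_um, p1_um], radius_um, pitch)


def binary(mask: np.ndarray, pitch: float = PITCH) -> BinaryStack:
    return BinaryStack(mask, pitch)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
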