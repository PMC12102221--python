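"""Lacuna identification and canalicular skeletonization.

The binarized LCN mask mixes two structure classes: thick ellipsoidal
lacunae and thin tubular canaliculi. Lacunae are found as cores of the
Euclidean distance transform (EDT) and grown back to the mask boundary;
everything else is canalicular and is reduced to a one-voxel-thick
medial skeleton for network analysis.

Connectivity convention: 26-connectivity for foreground, which pairs
with 6-connectivity of the background (the standard complementary pair
that avoids topological paradoxes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .io_core import DataError, ImageStack

log = logging.getLogger(__name__)

_S26 = np.ones((3, 3, 3), bool)


def _ball_structure(radius: int) -> np.ndarray:
    r = max(int(radius), 1)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r**2

__all__ = [
    "BinaryStack",
    "LacunaLabels",
    "Skeleton",
    "identify_lacunae",
    "canalicular_mask",
    "skeletonize_canaliculi",
]


@dataclass
class BinaryStack:
    """A segmented LCN mask at isotropic resolution."""

    mask: np.ndarray
    voxel_size_um: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 3:
            raise DataError(f"mask must be 3D, got ndim={self.mask.ndim}")
        if self.voxel_size_um <= 0:
            raise DataError(f"voxel size must be > 0 µm, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def volume_um3(self) -> float:
        return float(self.mask.size) * self.voxel_size_um**3

    @classmethod
    def from_stack(cls, stack: ImageStack, threshold: float = 0.5) -> "BinaryStack":
        if not stack.is_isotropic():
            raise DataError(f"mask stack must be isotropic, got voxel sizes {stack.voxel_size_um}")
        return cls(stack.voxels >= threshold, stack.voxel_size_um[0], list(stack.provenance))


@dataclass
class LacunaLabels:
    """Labeled lacunae (1..N) on the isotropic grid with per-lacuna properties."""

    labels: np.ndarray
    voxel_size_um: float
    table: pd.DataFrame  # label, cz_um, cy_um, cx_um, volume_vox, volume_um3, edge_touching

    @property
    def n(self) -> int:
        return len(self.table)

    def centroids_um(self) -> np.ndarray:
        return self.table[["cz_um", "cy_um", "cx_um"]].to_numpy(float)

    def edge_touching_labels(self) -> list[int]:
        return self.table.loc[self.table.edge_touching, "label"].astype(int).tolist()


@dataclass
class Skeleton:
    """One-voxel-thick medial representation of the canaliculi."""

    skeleton_mask: np.ndarray
    voxel_size_um: float
    component_ids: np.ndarray  # int labels of 26-connected skeleton components
    n_components: int

    @property
    def n_voxels(self) -> int:
        return int(self.skeleton_mask.sum())


def _empty_lacuna_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["label", "cz_um", "cy_um", "cx_um", "volume_vox", "volume_um3", "edge_touching"]
    ).astype({"label": int, "volume_vox": int, "edge_touching": bool})


def _lacuna_table(labels: np.ndarray, n: int, pitch: float) -> pd.DataFrame:
    if n == 0:
        return _empty_lacuna_table()
    ids = np.arange(1, n + 1)
    centroids = ndimage.center_of_mass(labels > 0, labels, ids)
    volumes = ndimage.sum_labels(np.ones_like(labels, np.int64), labels, ids).astype(int)
    faces = np.zeros_like(labels, bool)
    faces[[0, -1], :, :] = True
    faces[:, [0, -1], :] = True
    faces[:, :, [0, -1]] = True
    touching = set(np.unique(labels[faces])) - {0}
    rows = [
        {
            "label": int(i),
            "cz_um": c[0] * pitch,
            "cy_um": c[1] * pitch,
            "cx_um": c[2] * pitch,
            "volume_vox": int(v),
            "volume_um3": float(v) * pitch**3,
            "edge_touching": int(i) in touching,
        }
        for i, c, v in zip(ids, centroids, volumes)
    ]
    return pd.DataFrame(rows)


def identify_lacunae(
    binary: BinaryStack,
    dist_thresh_vox: float = 5.0,
    min_size_vox: int = 25,
    dilation_dist_vox: int = 2,
    limit_fraction: float = 0.1,
) -> LacunaLabels:
    """Identify lacunae as thick cores of the LCN mask and grow them to full bodies.

    Procedure:

    1. EDT of the mask; seed voxels have EDT >= ``dist_thresh_vox``.
    2. 26-connected seed components below ``min_size_vox`` voxels are dropped.
    3. Each surviving seed grows by 1-voxel geodesic dilation steps inside
       the mask. Growth of a candidate stops once a step would add fewer
       than ``limit_fraction`` of its current volume (and at least
       ``dilation_dist_vox`` steps have been taken). While a step grows
       through the lacuna body it adds a large relative shell, so growth
       runs to the mask boundary; creep into thin canaliculi adds a tiny
       fraction and halts immediately. This also acts as an anti-merge
       guard: two lacunae bridged by a canaliculus stop before meeting.
    4. Voxels claimed by several candidates in the same step go to the
       candidate with the nearest seed centroid (ties: lower label id).
    5. Each grown label is finished with a morphological opening (ball of
       radius ``dilation_dist_vox``): lacunae are smooth convex bodies
       while canaliculi are thin, so the opening releases canalicular
       voxels swallowed during growth back to the canalicular compartment
       without changing the lacuna body. The erosion half of the opening
       treats the outside of the stack as foreground so that lacunae cut
       by a stack face keep their face contact.

    An empty mask yields an empty labeling (not an error).
    """
    if binary.mask.ndim != 3:
        raise DataError("binary stack must be 3D")
    pitch = binary.voxel_size_um
    mask = binary.mask
    if not mask.any():
        return LacunaLabels(np.zeros_like(mask, np.int32), pitch, _empty_lacuna_table())

    edt = ndimage.distance_transform_edt(mask)
    seeds = edt >= dist_thresh_vox
    seed_labels, n_seed = ndimage.label(seeds, structure=_S26)
    if n_seed == 0:
        return LacunaLabels(np.zeros_like(mask, np.int32), pitch, _empty_lacuna_table())

    sizes = np.bincount(seed_labels.ravel())
    keep = np.flatnonzero(sizes >= min_size_vox)
    keep = keep[keep > 0]
    if keep.size == 0:
        return LacunaLabels(np.zeros_like(mask, np.int32), pitch, _empty_lacuna_table())
    remap = np.zeros(n_seed + 1, np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    labels = remap[seed_labels]
    n = int(keep.size)

    seed_centroids = np.asarray(
        ndimage.center_of_mass(labels > 0, labels, np.arange(1, n + 1))
    ).reshape(n, 3)
    volumes = np.bincount(labels.ravel(), minlength=n + 1).astype(np.int64)

    # Per-label bounding boxes, padded as we grow, keep the dilation cheap.
    boxes = ndimage.find_objects(labels)
    active = np.ones(n + 1, bool)
    active[0] = False
    max_steps = 4 * max(labels.shape)
    for step in range(1, max_steps + 1):
        if not active.any():
            break
        claims: dict[tuple[int, int, int], list[int]] = {}
        frontier_of: dict[int, np.ndarray] = {}
        for lab in range(1, n + 1):
            if not active[lab]:
                continue
            sl = boxes[lab - 1]
            sl = tuple(
                slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                for s, dim in zip(sl, labels.shape)
            )
            local = labels[sl] == lab
            grown = ndimage.binary_dilation(local, _S26)
            new = grown & mask[sl] & (labels[sl] == 0)
            coords = np.argwhere(new)
            if coords.size:
                coords = coords + np.array([s.start for s in sl])
            frontier_of[lab] = coords
            boxes[lab - 1] = sl
            for c in map(tuple, coords):
                claims.setdefault(c, []).append(lab)
        # Resolve contested voxels by nearest seed centroid, ties to lower id.
        assignment: dict[int, list[tuple[int, int, int]]] = {lab: [] for lab in frontier_of}
        for voxel, labs in claims.items():
            if len(labs) == 1:
                assignment[labs[0]].append(voxel)
            else:
                d = [float(np.sum((np.asarray(voxel) - seed_centroids[l - 1]) ** 2)) for l in labs]
                assignment[labs[int(np.argmin(d))]].append(voxel)
        grew_any = False
        for lab, voxels in assignment.items():
            growth = len(voxels)
            if growth == 0:
                active[lab] = False
                continue
            if step > dilation_dist_vox and growth < limit_fraction * volumes[lab]:
                active[lab] = False
                continue
            idx = tuple(np.asarray(voxels).T)
            labels[idx] = lab
            volumes[lab] += growth
            grew_any = True
        if not grew_any:
            break

    # Opening pass: release thin (canalicular) bites from each label.
    ball = _ball_structure(int(round(dilation_dist_vox)))
    pad = int(round(dilation_dist_vox)) + 1
    for lab in range(1, n + 1):
        sl = ndimage.find_objects((labels == lab).astype(np.int8))
        if not sl or sl[0] is None:
            continue
        sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl[0], labels.shape)
        )
        local = labels[sl] == lab
        eroded = ndimage.binary_erosion(local, ball, border_value=1)
        opened = ndimage.binary_dilation(eroded, ball) & local
        opened |= local & (seed_labels[sl] > 0)  # never drop seed-core voxels
        if opened.any():
            labels[sl][local & ~opened] = 0

    table = _lacuna_table(labels, n, pitch)
    log.info("identified %d lacunae (%d touching a stack face)", n, int(table.edge_touching.sum()))
    return LacunaLabels(labels.astype(np.int32), pitch, table)


def canalicular_mask(binary: BinaryStack, lacunae: LacunaLabels) -> BinaryStack:
    """LCN mask minus labeled lacuna voxels: the canalicular compartment."""
    if binary.mask.shape != lacunae.labels.shape:
        raise DataError(
            f"mask shape {binary.mask.shape} != labels shape {lacunae.labels.shape}"
        )
    mask = binary.mask & (lacunae.labels == 0)
    return BinaryStack(mask, binary.voxel_size_um, binary.provenance + ["canalicular_mask"])


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3), np.uint8)
    kernel[1, 1, 1] = 0
    return ndimage.convolve(mask.astype(np.uint8), kernel, mode="constant")


def _lacuna_adjacent(mask: np.ndarray, lacuna_labels: np.ndarray | None, radius: int = 2) -> np.ndarray:
    """Boolean grid of voxels within ``radius`` (Chebyshev) of a lacuna voxel."""
    if lacuna_labels is None:
        return np.zeros_like(mask, bool)
    near = ndimage.binary_dilation(lacuna_labels > 0, _S26, iterations=radius)
    return near & mask


_OFFSETS = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
)
_STEP_LEN = np.linalg.norm(_OFFSETS, axis=1)


def _prune_once(skel: np.ndarray, pitch: float, prune_um: float, protected: np.ndarray) -> tuple[np.ndarray, bool]:
    """Remove terminal branches shorter than prune_um that carry no protected voxel."""
    counts = _neighbor_count(skel)
    removed = False
    out = skel.copy()
    # Isolated voxels: zero-length terminal structures.
    isolated = skel & (counts == 0)
    if isolated.any():
        drop = isolated & ~protected
        if drop.any():
            out[drop] = False
            removed = True
    endpoints = np.argwhere(skel & (counts == 1))
    shape = skel.shape
    for ep in map(tuple, endpoints):
        if not out[ep]:
            continue
        branch = [ep]
        length = 0.0
        prev = None
        cur = ep
        hit_junction = False
        while True:
            nbrs = []
            for off, sl in zip(_OFFSETS, _STEP_LEN):
                c = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if 0 <= c[0] < shape[0] and 0 <= c[1] < shape[1] and 0 <= c[2] < shape[2] and out[c] and c != prev:
                    nbrs.append((c, sl))
            nxt = [nb for nb in nbrs if nb[0] != prev]
            if prev is None:
                candidates = nxt
            else:
                candidates = nxt
            if len(candidates) == 0:
                break  # isolated path; treat as terminal
            if len(candidates) > 1:
                hit_junction = True
                break
            c, sl = candidates[0]
            length += sl * pitch
            if counts[c] >= 3:
                hit_junction = True
                break
            branch.append(c)
            prev, cur = cur, c
            if length >= prune_um:
                break
        if length < prune_um and not any(protected[v] for v in branch):
            for v in branch:
                out[v] = False
            removed = True
    return out, removed


def skeletonize_canaliculi(
    canal: BinaryStack,
    prune_um: float = 1.0,
    lacunae: LacunaLabels | None = None,
) -> Skeleton:
    """Medial-axis thinning of the canalicular mask with spur pruning.

    Terminal branches shorter than ``prune_um`` that do not touch a lacuna
    surface are thinning artifacts and are removed; the volume is re-thinned
    afterwards so the result stays a valid skeleton.
    """
    pitch = canal.voxel_size_um
    mask = canal.mask
    if not mask.any():
        empty = np.zeros_like(mask, bool)
        return Skeleton(empty, pitch, np.zeros_like(mask, np.int32), 0)
    skel = skeletonize(mask).astype(bool)
    labels = lacunae.labels if lacunae is not None else None
    protected = _lacuna_adjacent(np.ones_like(mask, bool), labels)
    prune_rounds = 0
    while prune_rounds < 8:
        skel, removed = _prune_once(skel, pitch, prune_um, protected)
        prune_rounds += 1
        if not removed:
            break
        skel = skeletonize(skel).astype(bool)
    comp, ncomp = ndimage.label(skel, structure=_S26)
    return Skeleton(skel, pitch, comp.astype(np.int32), int(ncomp))
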