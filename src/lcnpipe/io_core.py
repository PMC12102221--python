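"""Image-stack I/O, pipeline configuration and result serialization.

Conventions used throughout the package
---------------------------------------
* Volumes are indexed ``(z, y, x)``, 0-based.
* Physical coordinates are voxel-center positions in micrometres; the
  center of voxel ``i`` along an axis of pitch ``p`` sits at ``i * p``.
* Micrometre parameters are converted to voxels with round-half-up and
  the conversion is logged, so that the mix of micrometre and voxel
  calibration values stays auditable.
* Intensities are mapped into ``[0, 1]`` at read time (integer TIFF data
  is divided by the dtype maximum) because every contrast stage assumes
  a unit histogram interval.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "LcnError",
    "ConfigError",
    "DataError",
    "ImageStack",
    "PipelineConfig",
    "um_to_vox",
    "read_stack",
    "write_stack",
    "write_results",
    "read_graphml",
]


class LcnError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(LcnError):
    """Invalid, missing or inconsistent configuration."""


class DataError(LcnError):
    """Input data that violates a pipeline precondition."""


def um_to_vox(value_um: float, pitch_um: float, *, what: str = "") -> int:
    """Convert a micrometre length to voxels, rounding half up.

    A single documented rounding convention avoids silent unit bugs when
    micrometre calibration values meet voxel-based ones.
    """
    if pitch_um <= 0:
        raise ConfigError(f"voxel pitch must be > 0 µm, got {pitch_um}")
    n = int(math.floor(value_um / pitch_um + 0.5))
    if what:
        log.debug("%s: %.4g µm -> %d voxels at %.4g µm pitch", what, value_um, n, pitch_um)
    return n


@dataclass
class ImageStack:
    """A 3D grayscale stack with per-axis voxel sizes in µm.

    Attributes
    ----------
    voxels : ndarray, shape (z, y, x)
        Scalar intensity grid.
    voxel_size_um : (float, float, float)
        Pitch along (z, y, x) in µm.
    intensity_range : (float, float)
        Declared valid intensity interval; after normalization stages
        this is (0, 1).
    provenance : list of str
        Ordered names of the operations applied so far.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    intensity_range: tuple[float, float] = (0.0, 1.0)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DataError(f"stack must be 3D (z, y, x); got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise DataError(f"all dimensions must be >= 1; got shape {self.voxels.shape}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise DataError(f"voxel sizes must be three positive values, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis (n_voxels × pitch)."""
        return tuple(n * p for n, p in zip(self.shape, self.voxel_size_um))  # type: ignore[return-value]

    def is_isotropic(self, tol: float = 1e-6) -> bool:
        z, y, x = self.voxel_size_um
        return abs(z - y) <= tol and abs(y - x) <= tol

    def replace(
        self,
        voxels: np.ndarray | None = None,
        voxel_size_um: tuple[float, float, float] | None = None,
        stage: str | None = None,
    ) -> "ImageStack":
        """Return a copy with updated voxels and the stage appended to provenance."""
        prov = list(self.provenance)
        if stage is not None:
            prov.append(stage)
        return ImageStack(
            voxels=self.voxels if voxels is None else voxels,
            voxel_size_um=self.voxel_size_um if voxel_size_um is None else voxel_size_um,
            intensity_range=self.intensity_range,
            provenance=prov,
        )


# The calibration values of the reference processing protocol. Lengths are in
# µm where the source states µm, and in voxels (at the isotropic working
# pitch) where the source states voxels.
_CONFIG_DOC = {
    "brightness_kernel_um": "sliding-window side for per-slice brightness correction",
    "brightness_stride_um": "spacing of brightness-correction windows",
    "brightness_saturation_fraction": "fraction of pixels saturated at both tails of each window",
    "min_signal_range_fraction": "brightness windows / CLAHE slices whose dynamic range falls below this fraction of the robust stack range carry no signal and are left unchanged",
    "gauss_sigma_coeff": "Gaussian sigma in px = coeff × in-plane pixel size in µm",
    "gauss_dims": "2 = per-slice filtering, 3 = volumetric",
    "clahe_kernel_um": "CLAHE tile side",
    "clahe_clip_limit": "normalized CLAHE clip limit",
    "sigmoid_gain": "gain of the sigmoid contrast correction",
    "sigmoid_cutoff_mode": "'auto' (midpoint of robust [p1, p99] range) or a number in (0, 1)",
    "target_iso_um": "isotropic working pitch after resampling",
    "binarize_threshold": "binarization threshold (inclusive >=)",
    "lacuna_dist_thresh_vox": "EDT seed threshold identifying potential lacunae (voxels)",
    "lacuna_min_size_vox": "minimum seed-component size in voxels",
    "lacuna_dilation_dist_vox": "minimum number of label-growth steps (voxels)",
    "lacuna_dilation_limit_fraction": "relative per-step growth below which label growth stops",
    "skeleton_prune_um": "terminal skeleton branches shorter than this and not touching a lacuna are removed",
    "edge_policy": "'include_all' or 'exclude_touching' (drop lacunae touching a stack face)",
    "rng_seed": "seed for any stochastic auxiliary step",
}


@dataclass
class PipelineConfig:
    """All tunable parameters of the processing chain, with the reference protocol defaults."""

    brightness_kernel_um: float = 50.0
    brightness_stride_um: float = 8.0
    brightness_saturation_fraction: float = 0.0035
    min_signal_range_fraction: float = 0.2
    gauss_sigma_coeff: float = 3.25
    gauss_dims: int = 2
    clahe_kernel_um: float = 6.0
    clahe_clip_limit: float = 0.01
    sigmoid_gain: float = 10.0
    sigmoid_cutoff_mode: str | float = "auto"
    target_iso_um: float = 0.4
    binarize_threshold: float = 0.6
    lacuna_dist_thresh_vox: float = 5.0
    lacuna_min_size_vox: int = 25
    lacuna_dilation_dist_vox: int = 2
    lacuna_dilation_limit_fraction: float = 0.1
    skeleton_prune_um: float = 1.0
    edge_policy: str = "include_all"
    rng_seed: int = 0

    def validate(self) -> "PipelineConfig":
        positive = [
            "brightness_kernel_um",
            "brightness_stride_um",
            "gauss_sigma_coeff",
            "clahe_kernel_um",
            "clahe_clip_limit",
            "sigmoid_gain",
            "target_iso_um",
            "lacuna_dist_thresh_vox",
            "lacuna_min_size_vox",
            "lacuna_dilation_dist_vox",
            "skeleton_prune_um",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ConfigError(f"binarize_threshold must lie in (0, 1), got {self.binarize_threshold}")
        if not (0.0 <= self.lacuna_dilation_limit_fraction <= 1.0):
            raise ConfigError(
                "lacuna_dilation_limit_fraction must lie in [0, 1], "
                f"got {self.lacuna_dilation_limit_fraction}"
            )
        if not (0.0 <= self.brightness_saturation_fraction < 1.0):
            raise ConfigError(
                "brightness_saturation_fraction must lie in [0, 1), "
                f"got {self.brightness_saturation_fraction}"
            )
        if self.brightness_kernel_um <= self.brightness_stride_um:
            raise ConfigError(
                "brightness_kernel_um must exceed brightness_stride_um "
                f"({self.brightness_kernel_um} <= {self.brightness_stride_um})"
            )
        if self.gauss_dims not in (2, 3):
            raise ConfigError(f"gauss_dims must be 2 or 3, got {self.gauss_dims}")
        if self.edge_policy not in ("include_all", "exclude_touching"):
            raise ConfigError(f"unknown edge_policy {self.edge_policy!r}")
        if isinstance(self.sigmoid_cutoff_mode, str):
            if self.sigmoid_cutoff_mode != "auto":
                raise ConfigError(
                    f"sigmoid_cutoff_mode must be 'auto' or a number, got {self.sigmoid_cutoff_mode!r}"
                )
        elif not (0.0 < float(self.sigmoid_cutoff_mode) < 1.0):
            raise ConfigError("numeric sigmoid_cutoff_mode must lie in (0, 1)")
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict, *, strict: bool = False) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(fields)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if strict:
            missing = set(fields) - set(data)
            if missing:
                details = ", ".join(
                    f"{name} (default {fields[name].default!r})" for name in sorted(missing)
                )
                raise ConfigError(f"missing config keys: {details}")
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path: str | Path, *, strict: bool = False) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {p} must contain a key-value mapping")
        return cls.from_dict(data, strict=strict)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @staticmethod
    def describe(name: str) -> str:
        return _CONFIG_DOC.get(name, "")


# -- TIFF I/O --------------------------------------------------------------

def _resolution_to_pitch(tag_value) -> float | None:
    try:
        num, den = tag_value
        if num == 0:
            return None
        return float(den) / float(num)
    except Exception:
        return None


def read_stack(path: str | Path, voxel_size_um: tuple[float, float, float] | None = None) -> ImageStack:
    """Read a single-channel multi-page TIFF as an :class:`ImageStack`.

    Integer data is mapped into [0, 1] by dividing by the dtype maximum.
    Voxel sizes come from the argument when given, otherwise from ImageJ
    style TIFF metadata (``spacing`` plus X/Y resolution tags).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image stack: {p}")
    with tifffile.TiffFile(p) as tf:
        arr = tf.asarray()
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise DataError(
                f"expected a single-channel z-stack, got array of shape {arr.shape}; "
                "multi-channel / RGB TIFFs are not supported"
            )
        if voxel_size_um is None:
            meta = tf.imagej_metadata or {}
            z = meta.get("spacing")
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            x = _resolution_to_pitch(xres.value) if xres is not None else None
            y = _resolution_to_pitch(yres.value) if yres is not None else None
            if z is None or x is None or y is None:
                missing = [n for n, v in (("spacing(z)", z), ("YResolution", y), ("XResolution", x)) if v is None]
                raise DataError(
                    f"voxel size not provided and not resolvable from TIFF metadata of {p}; "
                    f"missing: {', '.join(missing)}"
                )
            voxel_size_um = (float(z), float(y), float(x))
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        vox = arr.astype(np.float64) / float(info.max)
    else:
        vox = arr.astype(np.float64)
        if vox.size and (vox.min() < -1e-9 or vox.max() > 1 + 1e-9):
            log.warning("float TIFF %s has values outside [0, 1]; clipping", p)
            vox = np.clip(vox, 0.0, 1.0)
    return ImageStack(voxels=vox, voxel_size_um=voxel_size_um, provenance=["read"])


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-style float32 TIFF with µm calibration."""
    z, y, x = stack.voxel_size_um
    tifffile.imwrite(
        Path(path),
        stack.voxels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZYX"},
    )


# -- results ---------------------------------------------------------------

def _flatten_graph_for_graphml(g: nx.Graph) -> nx.Graph:
    """GraphML supports scalar attributes only; expand positions, drop voxel paths."""
    out = nx.MultiGraph() if g.is_multigraph() else nx.Graph()
    for n, attrs in g.nodes(data=True):
        a = dict(attrs)
        pos = a.pop("position_um", None)
        a.pop("voxels", None)
        if pos is not None:
            a["pz_um"], a["py_um"], a["px_um"] = (float(v) for v in pos)
        out.add_node(n, **{k: v for k, v in a.items() if np.isscalar(v)})
    for u, v, attrs in g.edges(data=True):
        a = {k: val for k, val in attrs.items() if np.isscalar(val)}
        out.add_edge(u, v, **a)
    return out


def write_results(report, graph, out_dir: str | Path) -> dict[str, Path]:
    """Write the morphometry report and network graph of one analyzed stack.

    Emits ``metrics.csv`` (flat scalar metrics), ``lacunae.csv`` (per-lacuna
    centroid, volume and distances), ``graph.graphml`` and ``report.json``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise DataError(f"output directory not writable: {out}") from exc

    paths = {
        "metrics": out / "metrics.csv",
        "lacunae": out / "lacunae.csv",
        "graph": out / "graph.graphml",
        "report": out / "report.json",
    }
    scalars = report.scalar_metrics()
    pd.DataFrame([scalars]).to_csv(paths["metrics"], index=False)
    per_lacuna = report.per_lacuna
    if per_lacuna is None:
        per_lacuna = pd.DataFrame(
            columns=["label", "cz_um", "cy_um", "cx_um", "volume_vox", "volume_um3",
                     "edge_touching", "d_L_um", "d_net_um"]
        )
    per_lacuna.to_csv(paths["lacunae"], index=False)
    g = graph if isinstance(graph, nx.Graph) else graph.graph
    nx.write_graphml(_flatten_graph_for_graphml(g), paths["graph"])
    paths["report"].write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return paths


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path), force_multigraph=True)
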