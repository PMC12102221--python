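"""End-to-end orchestration: stack (real or simulated) -> report files."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .connectome import analyze
from .io_core import (
    DataError,
    ImageStack,
    PipelineConfig,
    write_results,
    write_stack,
)
from .preprocess import PIPELINE_STAGES, preprocess_pipeline

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(
    stack: ImageStack,
    config: PipelineConfig,
    out_dir: str | Path,
    manual_counts=None,
    save_intermediates: bool = False,
):
    """Run preprocess -> segment -> connectome on a stack and write results.

    When ``manual_counts`` (a :class:`lcnpipe.agreement.PairedCounts`) is
    given, the method-agreement report is computed and written alongside.
    Returns the morphometry report, the graph and the output paths.
    A run manifest (config hash, seed, stages, version) accompanies the
    outputs so a run can be reproduced exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate()

    binary = preprocess_pipeline(stack, config)
    report, graph, lacunae, skeleton = analyze(binary, config)
    paths = write_results(report, graph, out)

    if save_intermediates:
        mask_stack = ImageStack(
            binary.mask.astype(float),
            (binary.voxel_size_um,) * 3,
            provenance=binary.provenance,
        )
        write_stack(mask_stack, out / "mask.tif")
        paths["mask"] = out / "mask.tif"

    if manual_counts is not None:
        from .agreement import compare_counts

        agreement = compare_counts(manual_counts)
        (out / "agreement.json").write_text(
            json.dumps(agreement.to_dict(), indent=2, sort_keys=True)
        )
        paths["agreement"] = out / "agreement.json"

    manifest = {
        "package": "lcnpipe",
        "version": __version__,
        "config_sha256": config.sha256(),
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "stages": list(PIPELINE_STAGES),
        "input_shape": list(stack.shape),
        "input_voxel_size_um": list(stack.voxel_size_um),
        "input_provenance": list(stack.provenance),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = out / "manifest.json"
    return report, graph, paths
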