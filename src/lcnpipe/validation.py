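"""Oracle-based validation studies: pipeline output versus phantom ground truth.

These drivers generate seeded phantoms, push the rendered stacks through
the full analysis chain and compare the recovered morphometry with the
generative truth. They back both the test suite and the reproduction
script, so the numbers reported there are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import analyze
from .io_core import PipelineConfig
from .phantom import PhantomParams, degrade, render_stack, sample_truth, truth_metrics
from .preprocess import preprocess_pipeline

__all__ = [
    "PhantomRecovery",
    "AgingPair",
    "n_valid_truth_lacunae",
    "run_recovery",
    "run_aging_pair",
]

# Aging-pair phantoms are smaller than the single-phantom study volumes so a
# baseline/degraded pair costs about as much as one full-size phantom.
AGING_PARAMS = dict(domain_um=(50.0, 30.0, 30.0), n_lacunae=5)
AGING_DEGRADE = dict(canaliculus_keep_fraction=0.5, length_scale=0.8)


@dataclass
class PhantomRecovery:
    seed: int
    truth_n_lacunae: int
    truth_n_valid: int
    truth_n_edge_touching: int
    truth_total_length_um: float
    recovered_n_lacunae: int
    recovered_n_excl_edge: int
    recovered_n_edge_touching: int
    recovered_total_length_um: float
    n_nodes: int
    n_edges: int
    mean_node_degree: float | None
    node_proportion_sum: float
    d_L_um: np.ndarray
    d_net_um: np.ndarray

    @property
    def count_exact(self) -> bool:
        return self.recovered_n_lacunae == self.truth_n_valid

    @property
    def length_rel_error(self) -> float:
        return self.recovered_total_length_um / self.truth_total_length_um - 1.0

    @property
    def edge_policy_identity(self) -> bool:
        """include_all − exclude_touching equals the truth edge-touching count."""
        return (
            self.recovered_n_lacunae - self.recovered_n_excl_edge
            == self.truth_n_edge_touching
        )


@dataclass
class AgingPair:
    seed: int
    base_canalicular_density: float
    aged_canalicular_density: float
    base_n_nodes: int
    aged_n_nodes: int
    base_d_lc: float
    aged_d_lc: float

    @property
    def signature_correct(self) -> bool:
        return (
            self.aged_canalicular_density < self.base_canalicular_density
            and self.aged_n_nodes < self.base_n_nodes
            and self.aged_d_lc > self.base_d_lc
        )


def n_valid_truth_lacunae(truth, config: PipelineConfig) -> int:
    """Truth lacunae detectable under the calibration: the ellipsoid eroded
    by the EDT seed threshold must still hold the minimum seed volume."""
    pitch = config.target_iso_um
    erode = config.lacuna_dist_thresh_vox * pitch
    n = 0
    for lac in truth.lacunae:
        semi = np.maximum(lac.semi_axes_um - erode, 0.0)
        core_vox = 4.0 / 3.0 * np.pi * np.prod(semi) / pitch**3
        if core_vox >= config.lacuna_min_size_vox:
            n += 1
    return n


def _recover(truth, render_seed: int, config: PipelineConfig):
    rng = np.random.default_rng(render_seed)
    stack = render_stack(truth, rng)
    binary = preprocess_pipeline(stack, config)
    return analyze(binary, config)


def run_recovery(
    seed: int,
    params: PhantomParams | None = None,
    config: PipelineConfig | None = None,
) -> PhantomRecovery:
    """Generate one phantom, run the full pipeline, compare against truth."""
    config = config or PipelineConfig()
    if params is None:
        params = PhantomParams(rng_seed=seed)
    else:
        params = PhantomParams(**{**params.to_dict(), "rng_seed": seed})
    rng = np.random.default_rng(seed)
    truth = sample_truth(params, rng)
    stack = render_stack(truth, rng)
    binary = preprocess_pipeline(stack, config)
    report, graph, lacunae, skeleton = analyze(binary, config)
    tm = truth_metrics(truth)
    n_edge = report.n_lacunae_edge_touching
    per_lac = report.per_lacuna
    return PhantomRecovery(
        seed=seed,
        truth_n_lacunae=len(truth.lacunae),
        truth_n_valid=n_valid_truth_lacunae(truth, config),
        truth_n_edge_touching=truth.n_edge_touching(),
        truth_total_length_um=tm.canalicular_total_length_um,
        recovered_n_lacunae=report.n_lacunae,
        recovered_n_excl_edge=report.n_lacunae - n_edge,
        recovered_n_edge_touching=n_edge,
        recovered_total_length_um=report.canalicular_total_length_um,
        n_nodes=report.n_nodes,
        n_edges=report.n_edges,
        mean_node_degree=report.mean_node_degree,
        node_proportion_sum=float(sum(report.node_proportions.values())),
        d_L_um=per_lac.d_L_um.to_numpy(float) if per_lac is not None else np.empty(0),
        d_net_um=per_lac.d_net_um.to_numpy(float) if per_lac is not None else np.empty(0),
    )


def run_aging_pair(seed: int, config: PipelineConfig | None = None) -> AgingPair:
    """Baseline vs degraded phantom pair, both recovered through the pipeline."""
    config = config or PipelineConfig()
    params = PhantomParams(rng_seed=seed, **AGING_PARAMS)
    rng = np.random.default_rng(seed)
    truth = sample_truth(params, rng)
    aged = degrade(truth, seed=seed, **AGING_DEGRADE)
    base_rep, *_ = _recover(truth, seed + 10_000, config)
    aged_rep, *_ = _recover(aged, seed + 10_000, config)
    return AgingPair(
        seed=seed,
        base_canalicular_density=base_rep.canalicular_density_um2,
        aged_canalicular_density=aged_rep.canalicular_density_um2,
        base_n_nodes=base_rep.n_nodes,
        aged_n_nodes=aged_rep.n_nodes,
        base_d_lc=base_rep.d_LC_mean_um,
        aged_d_lc=aged_rep.d_LC_mean_um,
    )
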