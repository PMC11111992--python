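"""Monte-Carlo estimators of explanation and prediction uncertainty.

Measurement uncertainty: variance of the pushed-forward saliency over draws
of the reversible acquisition transform (feature noise + node permutation).
Structural uncertainty: variance of the saliency over random-walk resamples
of the edge set.  The joint decomposition applies the law of total variance
over a J x K grid of (weight draw, data draw) saliency maps:

    total = E_Omega[ Var_data[S] ] + Var_Omega[ E_data[S] ]
          =        aleatoric       +       epistemic

The identity is exact for uncorrected (1/N) moments, which the report
asserts; Bessel-corrected (1/(N-1)) versions of all maps are reported
alongside, matching the convention of the per-source estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .explain import SaliencyMap, edge_saliency_gradient, node_saliency_gradcam
from .graphs import AttributedGraph
from .models import DecoderState, GNNSpec, ParameterSample, PointState, predict
from .transforms import (
    Transformation,
    WalkConfig,
    invert_transform,
    pushforward_saliency,
    sample_transformation,
    sample_walk_graph,
)

__all__ = [
    "UncertaintyReport",
    "grid_moments",
    "measurement_uncertainty",
    "structural_uncertainty",
    "decompose_uncertainty",
    "prediction_uncertainty",
]

DataMode = Literal["measurement", "structural", "both"]


@dataclass
class UncertaintyReport:
    """Per-element variance maps plus scalar summaries for one graph."""

    target_class: int
    level: str
    total_var: np.ndarray
    aleatoric_var: np.ndarray
    epistemic_var: np.ndarray
    measurement_var: np.ndarray | None = None
    structural_var: np.ndarray | None = None
    total_var_bessel: np.ndarray | None = None
    aleatoric_var_bessel: np.ndarray | None = None
    epistemic_var_bessel: np.ndarray | None = None
    mean_map: np.ndarray | None = None
    sample_counts: tuple[int, int] = (0, 0)
    seed: int | None = None

    @property
    def scalar_summaries(self) -> dict[str, float]:
        out = {
            "total": float(self.total_var.mean()),
            "aleatoric": float(self.aleatoric_var.mean()),
            "epistemic": float(self.epistemic_var.mean()),
        }
        if self.measurement_var is not None:
            out["measurement"] = float(self.measurement_var.mean())
        if self.structural_var is not None:
            out["structural"] = float(self.structural_var.mean())
        return out

    def to_json(self) -> str:
        import json

        payload = {
            "target_class": self.target_class,
            "level": self.level,
            "sample_counts": list(self.sample_counts),
            "seed": self.seed,
            "scalar_summaries": self.scalar_summaries,
        }
        for name in ("total_var", "aleatoric_var", "epistemic_var",
                     "measurement_var", "structural_var", "mean_map"):
            value = getattr(self, name)
            if value is not None:
                payload[name] = np.asarray(value).tolist()
        return json.dumps(payload)


def grid_moments(
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uncorrected (total, aleatoric, epistemic) moments of a J x K sample grid.

    ``grid`` has shape (J, K, *element_shape): rows share a weight draw,
    columns are independent data draws.  The law of total variance holds
    exactly: total == aleatoric + epistemic elementwise.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim < 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
        raise ValueError("grid must have shape (J, K, ...)")
    row_means = grid.mean(axis=1)
    grand_mean = row_means.mean(axis=0)
    aleatoric = (grid**2).mean(axis=(0, 1)) - (row_means**2).mean(axis=0)
    epistemic = (row_means**2).mean(axis=0) - grand_mean**2
    total = (grid**2).mean(axis=(0, 1)) - grand_mean**2
    return total, aleatoric, epistemic


def _bessel(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bessel-corrected analogues (reported alongside; not additive)."""
    j, k = grid.shape[0], grid.shape[1]
    row_means = grid.mean(axis=1)
    total = grid.reshape(j * k, *grid.shape[2:]).var(axis=0, ddof=1) if j * k > 1 else \
        np.zeros(grid.shape[2:])
    aleatoric = grid.var(axis=1, ddof=1).mean(axis=0) if k > 1 else np.zeros(grid.shape[2:])
    epistemic = row_means.var(axis=0, ddof=1) if j > 1 else np.zeros(grid.shape[2:])
    return total, aleatoric, epistemic


def _saliency_fn(
    spec: GNNSpec, c: int, level: str
) -> Callable[[AttributedGraph, ParameterSample], np.ndarray]:
    if level == "node":
        return lambda g, om: node_saliency_gradcam(g, om, spec, c).node_scores
    if level == "edge":
        return lambda g, om: edge_saliency_gradient(g, om, spec, c).edge_scores
    raise ValueError(f"level must be 'node' or 'edge', got {level!r}")


def measurement_uncertainty(
    g: AttributedGraph,
    omega: ParameterSample,
    spec: GNNSpec,
    c: int,
    noise_sd: float = 0.1,
    noisy_fraction: float = 0.1,
    I: int = 30,
    seed: int | np.random.Generator = 0,
    level: str = "node",
    permute: bool = True,
    transformations: Sequence[Transformation] | None = None,
    rectify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Bessel-corrected elementwise variance of the saliency over I transforms.

    Each sample inverse-transforms the observed graph, computes the saliency
    there, and pushes it forward; returns ``(variance, mean)``.
    ``transformations`` pins the draws (cycled) for oracle tests; ``permute``
    False pins the permutation to the identity, isolating feature noise.
    """
    if I < 2:
        raise ValueError("need at least I=2 transform draws for a variance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = []
    for i in range(I):
        if transformations is not None:
            t = transformations[i % len(transformations)]
        else:
            t = sample_transformation(g, noise_sd, noisy_fraction, rng, permute=permute)
        g_rec = invert_transform(g, t)
        if level == "node":
            s = node_saliency_gradcam(g_rec, omega, spec, c, rectify=rectify)
        else:
            s = edge_saliency_gradient(g_rec, omega, spec, c)
        s = pushforward_saliency(s, t)
        samples.append(s.node_scores if level == "node" else s.edge_scores)
    stack = np.stack(samples)
    return stack.var(axis=0, ddof=1), stack.mean(axis=0)


def structural_uncertainty(
    g: AttributedGraph,
    omega: ParameterSample,
    spec: GNNSpec,
    c: int,
    walk_cfg: WalkConfig | None = None,
    I: int = 30,
    seed: int | np.random.Generator = 0,
    level: str = "node",
    sampler: Callable[[AttributedGraph, np.random.Generator], AttributedGraph] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bessel-corrected variance of the saliency over I walk-resampled graphs.

    ``sampler(g, rng)`` overrides the walk sampler (e.g. pinned for tests);
    the default draws :func:`sample_walk_graph` with ``walk_cfg``.
    """
    if I < 2:
        raise ValueError("need at least I=2 graph draws for a variance")
    walk_cfg = walk_cfg or WalkConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fn = _saliency_fn(spec, c, level)
    samples = []
    for _ in range(I):
        gi = sampler(g, rng) if sampler is not None else sample_walk_graph(g, walk_cfg, rng)
        samples.append(fn(gi, omega))
    stack = np.stack(samples)
    return stack.var(axis=0, ddof=1), stack.mean(axis=0)


def _data_draw(
    g: AttributedGraph,
    rng: np.random.Generator,
    mode: DataMode,
    noise_sd: float,
    noisy_fraction: float,
    walk_cfg: WalkConfig,
    permute: bool,
) -> tuple[AttributedGraph, Transformation | None]:
    """One draw of data randomness: walk resample and/or reversible transform."""
    gi = g
    if mode in ("structural", "both"):
        gi = sample_walk_graph(gi, walk_cfg, rng)
    t = None
    if mode in ("measurement", "both"):
        t = sample_transformation(gi, noise_sd, noisy_fraction, rng, permute=permute)
        gi = invert_transform(gi, t)
    return gi, t


def decompose_uncertainty(
    g: AttributedGraph,
    state: "DecoderState | PointState",
    spec: GNNSpec,
    c: int,
    J: int = 8,
    K: int = 8,
    noise_sd: float = 0.1,
    noisy_fraction: float = 0.1,
    walk_cfg: WalkConfig | None = None,
    seed: int = 0,
    level: str = "node",
    data_mode: DataMode = "both",
    permute: bool = True,
    include_marginals: bool = False,
) -> UncertaintyReport:
    """Total/aleatoric/epistemic decomposition over a J x K saliency grid.

    Outer loop: J weight draws from the decoder posterior.  Inner loop: K
    independent data draws (transform and/or walk resample per ``data_mode``).
    ``include_marginals`` additionally runs the single-source measurement and
    structural estimators with the first weight draw.
    """
    if J < 2 or K < 2:
        raise ValueError("need J >= 2 and K >= 2 for the decomposition")
    walk_cfg = walk_cfg or WalkConfig()
    rng = np.random.default_rng(seed)
    fn = _saliency_fn(spec, c, level)
    omegas = [state.sample_omega(rng) for _ in range(J)]
    # common random numbers: the K data draws are shared across the J weight
    # draws, so a degenerate (point-mass) posterior shows exactly zero
    # epistemic variance and the j-rows differ only through Omega
    draws = [
        _data_draw(g, rng, data_mode, noise_sd, noisy_fraction, walk_cfg, permute)
        for _ in range(K)
    ]
    rows = []
    for omega in omegas:
        row = []
        for gi, t in draws:
            s = fn(gi, omega)
            if t is not None:
                s = (
                    pushforward_saliency(
                        SaliencyMap(target_class=c, node_scores=s), t
                    ).node_scores
                    if level == "node"
                    else pushforward_saliency(
                        SaliencyMap(target_class=c, edge_scores=s), t
                    ).edge_scores
                )
            row.append(s)
        rows.append(np.stack(row))
    grid = np.stack(rows)  # (J, K, ...)
    total, aleatoric, epistemic = grid_moments(grid)
    total_b, aleatoric_b, epistemic_b = _bessel(grid)

    measurement = structural = None
    if include_marginals:
        measurement, _ = measurement_uncertainty(
            g, omegas[0], spec, c, noise_sd, noisy_fraction, I=K, seed=rng,
            level=level, permute=permute,
        )
        structural, _ = structural_uncertainty(
            g, omegas[0], spec, c, walk_cfg, I=K, seed=rng, level=level
        )
    return UncertaintyReport(
        target_class=c,
        level=level,
        total_var=total,
        aleatoric_var=aleatoric,
        epistemic_var=epistemic,
        measurement_var=measurement,
        structural_var=structural,
        total_var_bessel=total_b,
        aleatoric_var_bessel=aleatoric_b,
        epistemic_var_bessel=epistemic_b,
        mean_map=grid.mean(axis=(0, 1)),
        sample_counts=(J, K),
        seed=seed if isinstance(seed, int) else None,
    )


def prediction_uncertainty(
    g: AttributedGraph,
    state: "DecoderState | PointState",
    spec: GNNSpec,
    J: int = 8,
    K: int = 4,
    noise_sd: float = 0.1,
    noisy_fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
    samples: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Scalar predictive-uncertainty score for one graph.

    The score is the (population) variance of the predicted-class probability
    across the J*K per-sample predictive vectors; per-class variances are
    returned alongside.  ``samples`` pins the per-sample vectors directly.
    """
    if samples is None:
        if J * K < 2:
            raise ValueError("need J*K >= 2 prediction samples")
        _, samples = predict(
            g, state, spec, J=J, K=K, noise_sd=noise_sd,
            noisy_fraction=noisy_fraction, seed=seed,
        )
    samples = np.asarray(samples, dtype=np.float64)
    mean = samples.mean(axis=0)
    per_class = samples.var(axis=0, ddof=0)
    # constant columns are exactly zero-variance (no floating residue)
    per_class[np.ptp(samples, axis=0) == 0] = 0.0
    predicted = int(np.argmax(mean))
    return float(per_class[predicted]), per_class
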