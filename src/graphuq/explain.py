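"""Post-hoc saliency maps and their transform-aware Monte-Carlo expectation.

Node importance follows the graph Grad-CAM formulation: with H the final
message-passing layer's node embeddings and y^c the pre-softmax score for the
target class, channel weights are the mean gradients

    alpha_k = (1/|V|) * sum_n  d y^c / d H_{n,k}

and the node score is S_n = ReLU(sum_k alpha_k H_{n,k}).  Edge importance is
the magnitude of the class-score gradient with respect to the raw adjacency
entries (chain-ruled through the degree normalization of the forward pass),
symmetrized.  The expected explanation integrates either map over draws of
the reversible acquisition transform and of the decoded model weights,
pushing each per-draw map back to observed-node coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .graphs import AttributedGraph
from .models import (
    DecoderState,
    GNNSpec,
    ParameterSample,
    PointState,
    _forward_ad,
    normalized_adjacency,
)
from .transforms import (
    invert_transform,
    pushforward_saliency,
    sample_transformation,
)

__all__ = [
    "SaliencyMap",
    "node_saliency_gradcam",
    "edge_saliency_gradient",
    "expected_explanation",
]


@dataclass
class SaliencyMap:
    """Node- and/or edge-level importance scores for one target class."""

    target_class: int
    node_scores: np.ndarray | None = None
    edge_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.node_scores is None and self.edge_scores is None:
            raise ValueError("a saliency map needs node scores, edge scores, or both")
        if self.node_scores is not None:
            self.node_scores = np.asarray(self.node_scores, dtype=np.float64)
        if self.edge_scores is not None:
            self.edge_scores = np.asarray(self.edge_scores, dtype=np.float64)

    @property
    def node_count(self) -> int:
        if self.node_scores is not None:
            return self.node_scores.shape[0]
        return self.edge_scores.shape[0]

    def to_json(self) -> str:
        payload: dict = {"target_class": int(self.target_class)}
        if self.node_scores is not None:
            payload["node_scores"] = self.node_scores.tolist()
        if self.edge_scores is not None:
            i, j = np.nonzero(np.triu(self.edge_scores, k=1))
            payload["edge_scores"] = [
                [int(a), int(b), float(self.edge_scores[a, b])] for a, b in zip(i, j)
            ]
            payload["n_nodes"] = int(self.edge_scores.shape[0])
        return json.dumps(payload)

    @classmethod
    def from_json(cls, payload: str | Path) -> "SaliencyMap":
        if isinstance(payload, Path):
            payload = payload.read_text()
        d = json.loads(payload)
        node = None if "node_scores" not in d else np.asarray(d["node_scores"])
        edge = None
        if "edge_scores" in d:
            n = d["n_nodes"]
            edge = np.zeros((n, n))
            for a, b, v in d["edge_scores"]:
                edge[a, b] = edge[b, a] = v
        return cls(target_class=d["target_class"], node_scores=node, edge_scores=edge)


def _check_class(c: int, spec: GNNSpec) -> None:
    if not (0 <= c < spec.class_count):
        raise ValueError(f"class {c} outside {{0..{spec.class_count - 1}}}")


def node_saliency_gradcam(
    g: AttributedGraph,
    omega: ParameterSample,
    spec: GNNSpec,
    c: int,
    rectify: bool = True,
) -> SaliencyMap:
    """Grad-CAM node saliency for class ``c`` (nonnegative after ReLU).

    ``rectify=False`` returns the raw channel-weighted activations, which is
    the quantity with a closed-form distribution under Gaussian feature noise.
    """
    _check_class(c, spec)
    params = {k: Tensor(v) for k, v in omega.arrays().items()}
    x = Tensor(g.features, requires_grad=True)
    a_norm = Tensor(normalized_adjacency(g.adjacency))
    logits, embeddings = _forward_ad(x, a_norm, params, spec)
    logits[c].backward()
    alpha = embeddings.grad.mean(axis=0)  # mean gradient per channel
    scores = embeddings.data @ alpha
    if rectify:
        scores = np.maximum(scores, 0.0)
    return SaliencyMap(target_class=c, node_scores=scores)


def edge_saliency_gradient(
    g: AttributedGraph,
    omega: ParameterSample,
    spec: GNNSpec,
    c: int,
    masked: bool = True,
) -> SaliencyMap:
    """Gradient edge saliency: |d y^c / d A_ij|, symmetrized.

    The derivative is taken with respect to the raw adjacency entries, with
    the degree normalization of the forward pass included in the chain rule.
    ``masked=True`` zeroes scores on non-edges.
    """
    _check_class(c, spec)
    params = {k: Tensor(v) for k, v in omega.arrays().items()}
    n = g.node_count
    a_raw = Tensor(g.adjacency.astype(np.float64), requires_grad=True)
    # normalization built from autodiff ops so the gradient chains through it
    a_hat = a_raw + np.eye(n)
    d_inv = a_hat.sum(axis=1, keepdims=True) ** -0.5
    a_norm = a_hat * d_inv * d_inv.T
    logits, _ = _forward_ad(Tensor(g.features), a_norm, params, spec)
    logits[c].backward()
    grad = np.abs(a_raw.grad)
    scores = 0.5 * (grad + grad.T)
    if masked:
        scores = scores * (g.adjacency > 0)
    np.fill_diagonal(scores, 0.0)
    return SaliencyMap(target_class=c, edge_scores=scores)


def _saliency_both(
    g: AttributedGraph, omega: ParameterSample, spec: GNNSpec, c: int
) -> SaliencyMap:
    node = node_saliency_gradcam(g, omega, spec, c)
    edge = edge_saliency_gradient(g, omega, spec, c)
    return SaliencyMap(
        target_class=c, node_scores=node.node_scores, edge_scores=edge.edge_scores
    )


def expected_explanation(
    g: AttributedGraph,
    state: "DecoderState | PointState",
    spec: GNNSpec,
    c: int,
    I: int = 8,
    J: int = 8,
    noise_sd: float = 0.1,
    noisy_fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
    level: str = "node",
    permute: bool = True,
    transformations=None,
) -> tuple[SaliencyMap, list[SaliencyMap]]:
    """MC estimate of the expected explanation over transforms and weights.

    For each of J decoded weight draws and I transform draws, the observed
    graph is inverse-transformed, the saliency computed there, and the map
    pushed forward to observed coordinates; the arithmetic mean over all
    draws and the per-draw maps are returned.  ``transformations`` pins the
    transform draws (cycled) for reproducibility tests; ``level`` is
    ``"node"``, ``"edge"`` or ``"both"``.
    """
    if I < 1 or J < 1:
        raise ValueError("I and J must be >= 1")
    _check_class(c, spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    compute = {
        "node": lambda gg, om: node_saliency_gradcam(gg, om, spec, c),
        "edge": lambda gg, om: edge_saliency_gradient(gg, om, spec, c),
        "both": lambda gg, om: _saliency_both(gg, om, spec, c),
    }[level]
    maps: list[SaliencyMap] = []
    draw = 0
    for _ in range(J):
        omega = state.sample_omega(rng)
        for _ in range(I):
            if transformations is not None:
                t = transformations[draw % len(transformations)]
            else:
                t = sample_transformation(g, noise_sd, noisy_fraction, rng, permute=permute)
            g_rec = invert_transform(g, t)
            maps.append(pushforward_saliency(compute(g_rec, omega), t))
            draw += 1
    node = edge = None
    if maps[0].node_scores is not None:
        node = np.mean([m.node_scores for m in maps], axis=0)
    if maps[0].edge_scores is not None:
        edge = np.mean([m.edge_scores for m in maps], axis=0)
    return SaliencyMap(target_class=c, node_scores=node, edge_scores=edge), maps
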