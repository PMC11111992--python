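"""Reversible graph acquisition transforms and random-walk resampling.

The acquisition model treats an observed graph as a node-permuted copy of the
true graph whose node features carry additive Gaussian measurement noise on a
random subset of nodes:

    X_obs = P X_true + eps,    A_obs = P A_true P^T,

with P the permutation matrix of a uniformly drawn bijection xi.  The
transform is exactly invertible (subtract eps, apply the inverse
permutation), leaves the graph label unchanged, and pushes saliency maps
forward by the same permutation.  Structural volatility is modeled
separately by resampling the edge set as the union of edges traversed by
random walks with restart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graphs import AttributedGraph

__all__ = [
    "Transformation",
    "WalkConfig",
    "identity_transformation",
    "sample_transformation",
    "apply_transform",
    "invert_transform",
    "pushforward_saliency",
    "pushforward_node_scores",
    "pushforward_edge_scores",
    "sample_walk_graph",
]


@dataclass
class Transformation:
    """One draw of (permutation xi, feature noise eps).

    ``permutation[v]`` is the index that input node ``v`` occupies after the
    transform.  Noise rows are zero outside the sampled noisy subset.
    """

    permutation: np.ndarray
    feature_noise: np.ndarray
    noise_sd: float = 0.0
    noisy_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=np.int64)
        self.feature_noise = np.asarray(self.feature_noise, dtype=np.float64)
        n = self.permutation.shape[0]
        if sorted(self.permutation.tolist()) != list(range(n)):
            raise ValueError("permutation must be a bijection on {0..n-1}")
        if self.feature_noise.shape[0] != n:
            raise ValueError("feature_noise rows must equal permutation length")

    @property
    def node_count(self) -> int:
        return self.permutation.shape[0]

    @property
    def inverse_permutation(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(self.node_count)
        return inv

    def is_identity(self) -> bool:
        return bool(
            np.array_equal(self.permutation, np.arange(self.node_count))
            and not self.feature_noise.any()
        )

    # replayable-experiment serialization
    def to_json(self) -> str:
        return json.dumps(
            {
                "permutation": self.permutation.tolist(),
                "feature_noise": self.feature_noise.tolist(),
                "noise_sd": self.noise_sd,
                "noisy_fraction": self.noisy_fraction,
            }
        )

    @classmethod
    def from_json(cls, payload: str | Path) -> "Transformation":
        if isinstance(payload, Path):
            payload = payload.read_text()
        d = json.loads(payload)
        return cls(
            permutation=np.asarray(d["permutation"]),
            feature_noise=np.asarray(d["feature_noise"]),
            noise_sd=d["noise_sd"],
            noisy_fraction=d["noisy_fraction"],
        )


def identity_transformation(g: AttributedGraph) -> Transformation:
    return Transformation(
        permutation=np.arange(g.node_count),
        feature_noise=np.zeros_like(g.features),
    )


def sample_transformation(
    g: AttributedGraph,
    noise_sd: float,
    noisy_fraction: float,
    seed: int | np.random.Generator,
    permute: bool = True,
) -> Transformation:
    """Draw a uniform node permutation and a sparse Gaussian noise matrix.

    Exactly ``round(noisy_fraction * n_nodes)`` nodes (without replacement)
    receive i.i.d. N(0, noise_sd^2) noise on every feature channel; the other
    rows are zero.  ``permute=False`` pins the permutation to the identity,
    which isolates the additive-noise component in the estimators.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not (0 <= noisy_fraction <= 1):
        raise ValueError("noisy_fraction must lie in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = g.node_count
    perm = rng.permutation(n) if permute else np.arange(n)
    noise = np.zeros_like(g.features)
    k = int(round(noisy_fraction * n))
    if k > 0 and noise_sd > 0:
        noisy = rng.choice(n, size=k, replace=False)
        noise[noisy] = rng.normal(0.0, noise_sd, size=(k, g.feature_dim))
    return Transformation(perm, noise, noise_sd=noise_sd, noisy_fraction=noisy_fraction)


def apply_transform(g: AttributedGraph, t: Transformation) -> AttributedGraph:
    """Observed graph: permuted features/adjacency plus feature noise.

    The label (and any truth masks) travel with the nodes; small acquisition
    deviations are assumed not to change the class.
    """
    if t.node_count != g.node_count:
        raise ValueError("transformation size does not match graph")
    inv = t.inverse_permutation
    features = g.features[inv] + t.feature_noise
    adjacency = g.adjacency[np.ix_(inv, inv)]
    node_truth = None if g.node_truth is None else g.node_truth[inv]
    edge_truth = None if g.edge_truth is None else g.edge_truth[np.ix_(inv, inv)]
    return AttributedGraph(
        features=features,
        adjacency=adjacency,
        label=g.label,
        node_truth=node_truth,
        edge_truth=edge_truth,
    )


def invert_transform(g_obs: AttributedGraph, t: Transformation) -> AttributedGraph:
    """Exact left inverse of :func:`apply_transform`: subtract noise, unpermute."""
    if t.node_count != g_obs.node_count:
        raise ValueError("transformation size does not match graph")
    perm = t.permutation
    features = (g_obs.features - t.feature_noise)[perm]
    adjacency = g_obs.adjacency[np.ix_(perm, perm)]
    node_truth = None if g_obs.node_truth is None else g_obs.node_truth[perm]
    edge_truth = None if g_obs.edge_truth is None else g_obs.edge_truth[np.ix_(perm, perm)]
    return AttributedGraph(
        features=features,
        adjacency=adjacency,
        label=g_obs.label,
        node_truth=node_truth,
        edge_truth=edge_truth,
    )


def pushforward_node_scores(scores: np.ndarray, t: Transformation) -> np.ndarray:
    out = np.empty_like(scores)
    out[t.permutation] = scores
    return out


def pushforward_edge_scores(scores: np.ndarray, t: Transformation) -> np.ndarray:
    inv = t.inverse_permutation
    return scores[np.ix_(inv, inv)]


def pushforward_saliency(s, t: Transformation):
    """Permute a saliency map into observed-node coordinates (values unchanged)."""
    from .explain import SaliencyMap

    if not isinstance(s, SaliencyMap):
        raise TypeError("expected a SaliencyMap")
    node = None
    if s.node_scores is not None:
        if s.node_scores.shape[0] != t.node_count:
            raise ValueError("saliency dimension does not match transformation")
        node = pushforward_node_scores(s.node_scores, t)
    edge = None
    if s.edge_scores is not None:
        if s.edge_scores.shape[0] != t.node_count:
            raise ValueError("saliency dimension does not match transformation")
        edge = pushforward_edge_scores(s.edge_scores, t)
    return SaliencyMap(node_scores=node, edge_scores=edge, target_class=s.target_class)


@dataclass
class WalkConfig:
    """Random-walk resampling parameters: R walks of W steps with restart."""

    walk_count: int = 20
    walk_length: int = 10
    restart_prob: float = 0.1
    seed: int = 0

    def validate(self) -> "WalkConfig":
        if self.walk_count < 0:
            raise ValueError("walk_count must be >= 0")
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if not (0 <= self.restart_prob <= 1):
            raise ValueError("restart_prob must lie in [0,1]")
        return self


def sample_walk_graph(
    g: AttributedGraph,
    cfg: WalkConfig,
    draw_seed: int | np.random.Generator,
) -> AttributedGraph:
    """Resample the edge set as the union of edges traversed by random walks.

    RNG protocol (replayable by an independent simulator): for each of the R
    walks, draw the start node uniformly (``rng.integers(n)``); then for each
    of the W steps draw a restart uniform (``rng.random()``); on restart jump
    to the start node, otherwise draw a uniform neighbor index
    (``rng.integers(len(neighbors))``) and traverse that edge.  A node with no
    neighbors ends the walk.  Nodes, features, label and truth masks are kept;
    only the edge set shrinks to the traversed union (a subset of the input
    edges), so with R*W large on a connected graph the input is recovered.
    """
    cfg.validate()
    rng = (
        draw_seed
        if isinstance(draw_seed, np.random.Generator)
        else np.random.default_rng(draw_seed)
    )
    n = g.node_count
    if cfg.walk_count > 0 and g.edge_count == 0:
        import warnings

        warnings.warn("walk sampling requested on an edgeless graph", stacklevel=2)
        return g.copy()
    neighbors = [np.nonzero(g.adjacency[v])[0] for v in range(n)]
    traversed = np.zeros((n, n), dtype=np.int8)
    for _ in range(cfg.walk_count):
        start = int(rng.integers(n))
        current = start
        for _ in range(cfg.walk_length):
            if rng.random() < cfg.restart_prob:
                current = start
                continue
            nbrs = neighbors[current]
            if len(nbrs) == 0:
                break
            nxt = int(nbrs[int(rng.integers(len(nbrs)))])
            traversed[current, nxt] = traversed[nxt, current] = 1
            current = nxt
    edge_truth = None
    if g.edge_truth is not None:
        edge_truth = (g.edge_truth & traversed).astype(np.int8)
    return AttributedGraph(
        features=g.features.copy(),
        adjacency=traversed,
        label=g.label,
        node_truth=None if g.node_truth is None else g.node_truth.copy(),
        edge_truth=edge_truth,
    )
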