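"""Graph classifier, variational parameter decoder, ELBO training, prediction.

The classifier F(X, A, Omega) is an L-layer GCN-style network: each layer
multiplies by the symmetric degree-normalized adjacency (with self-loops),
applies an affine map and a ReLU; a mean readout over nodes feeds a linear
head and a softmax over classes.

Instead of a point estimate of the weights Omega, a three-layer feed-forward
decoder (hypernetwork) q_theta(Omega|z) maps a standard-Gaussian latent z to
a full weight vector; the induced mixture over Omega is the approximate
posterior.  Training minimizes

    L = gamma * KL_hat - (1/(J*K)) sum_j sum_k sum_t log F(T_k^{-1}(X_t - eps_k), A_t, Omega_j)[y_t]

where KL_hat is the Jensen upper-bound surrogate E_z KL[q(Omega|z) || N(0,I)]
in closed Gaussian form per z-sample, and each inner likelihood term applies a
freshly drawn reversible transform to the training graph.  Prediction
averages F over J decoded weight draws and K transform draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._autodiff import Tensor
from .graphs import AttributedGraph, Dataset
from .transforms import invert_transform, sample_transformation

__all__ = [
    "GNNSpec",
    "ParameterSample",
    "DecoderState",
    "PointState",
    "TrainConfig",
    "TrainResult",
    "init_decoder",
    "decode_parameters",
    "normalized_adjacency",
    "gnn_forward",
    "gnn_logits",
    "elbo_loss",
    "train",
    "predict",
    "default_noise_sd",
    "save_checkpoint",
    "load_checkpoint",
]


# ----------------------------------------------------------------- GNN spec


@dataclass(frozen=True)
class GNNSpec:
    """Architecture of the graph classifier (mean readout, softmax output)."""

    input_dim: int
    hidden_dims: tuple[int, ...] = (16, 16)
    class_count: int = 2

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.class_count < 2 or len(self.hidden_dims) < 1:
            raise ValueError("need input_dim >= 1, class_count >= 2, >= 1 layer")
        if any(d < 1 for d in self.hidden_dims):
            raise ValueError("hidden dims must be positive")

    @property
    def layer_count(self) -> int:
        return len(self.hidden_dims)

    def manifest(self) -> list[tuple[str, tuple[int, ...]]]:
        """Ordered (name, shape) pairs for every weight block."""
        shapes: list[tuple[str, tuple[int, ...]]] = []
        prev = self.input_dim
        for l, dim in enumerate(self.hidden_dims):
            shapes.append((f"layer{l}.W", (prev, dim)))
            shapes.append((f"layer{l}.b", (dim,)))
            prev = dim
        shapes.append(("head.W", (prev, self.class_count)))
        shapes.append(("head.b", (self.class_count,)))
        return shapes

    @property
    def param_count(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.manifest())


@dataclass
class ParameterSample:
    """One flattened weight vector Omega plus the manifest to unflatten it."""

    flat_values: np.ndarray
    manifest: list[tuple[str, tuple[int, ...]]]

    def __post_init__(self) -> None:
        self.flat_values = np.asarray(self.flat_values, dtype=np.float64)
        total = sum(int(np.prod(s)) for _, s in self.manifest)
        if self.flat_values.shape != (total,):
            raise ValueError(
                f"flat length {self.flat_values.shape} does not match manifest total {total}"
            )

    def arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        offset = 0
        for name, shape in self.manifest:
            size = int(np.prod(shape))
            out[name] = self.flat_values[offset : offset + size].reshape(shape)
            offset += size
        return out

    @classmethod
    def from_arrays(
        cls, arrays: dict[str, np.ndarray], spec: GNNSpec
    ) -> "ParameterSample":
        manifest = spec.manifest()
        flat = np.concatenate(
            [np.asarray(arrays[name], dtype=np.float64).ravel() for name, _ in manifest]
        )
        return cls(flat, manifest)


# ------------------------------------------------------------------ forward


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    a_hat = np.asarray(adjacency, dtype=np.float64) + np.eye(adjacency.shape[0])
    d_inv = a_hat.sum(axis=1) ** -0.5
    return a_hat * d_inv[:, None] * d_inv[None, :]


def _forward_np(
    x: np.ndarray, a_norm: np.ndarray, params: dict[str, np.ndarray], spec: GNNSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pure-NumPy forward: (class probabilities, final node embeddings, logits)."""
    h = x
    for l in range(spec.layer_count):
        h = np.maximum(a_norm @ h @ params[f"layer{l}.W"] + params[f"layer{l}.b"], 0.0)
    pooled = h.mean(axis=0)
    logits = pooled @ params["head.W"] + params["head.b"]
    shifted = logits - logits.max()
    probs = np.exp(shifted) / np.exp(shifted).sum()
    return probs, h, logits


def gnn_forward(
    g: AttributedGraph, omega: ParameterSample, spec: GNNSpec
) -> np.ndarray:
    """Class-probability vector (nonnegative, sums to one)."""
    params = omega.arrays()
    if params["layer0.W"].shape[0] != g.feature_dim:
        raise ValueError("graph feature dimension does not match GNN input_dim")
    probs, _, _ = _forward_np(g.features, normalized_adjacency(g.adjacency), params, spec)
    return probs


def gnn_logits(
    g: AttributedGraph, omega: ParameterSample, spec: GNNSpec
) -> np.ndarray:
    """Pre-softmax class scores (the quantities saliency differentiates)."""
    params = omega.arrays()
    _, _, logits = _forward_np(g.features, normalized_adjacency(g.adjacency), params, spec)
    return logits


def _forward_ad(
    x: Tensor, a_norm: Tensor, params: dict[str, Tensor], spec: GNNSpec
) -> tuple[Tensor, Tensor]:
    """Autodiff forward used by training and saliency: (logits, final embeddings)."""
    h = x
    for l in range(spec.layer_count):
        h = (a_norm @ h @ params[f"layer{l}.W"] + params[f"layer{l}.b"]).relu()
    embeddings = h
    pooled = h.mean(axis=0)
    logits = pooled @ params["head.W"] + params["head.b"]
    return logits, embeddings


def _split_flat(omega: Tensor, spec: GNNSpec) -> dict[str, Tensor]:
    out: dict[str, Tensor] = {}
    offset = 0
    for name, shape in spec.manifest():
        size = int(np.prod(shape))
        out[name] = omega[offset : offset + size].reshape(shape)
        offset += size
    return out


# ------------------------------------------------------------------ decoder


@dataclass
class DecoderState:
    """Weights of the parameter decoder z -> Omega and its sampling scales.

    Hidden layers use Sigmoid activations; the linear output is squashed by a
    final Sigmoid and affinely rescaled to (-weight_scale, weight_scale) so
    decoded GNN weights take both signs.  ``conditional_sd`` is the spread of
    q(Omega|z) around the decoded mean (0 gives a point mass per z).
    """

    weights: dict[str, np.ndarray]
    latent_dim: int
    conditional_sd: float
    weight_scale: float
    spec: GNNSpec
    hidden: tuple[int, ...] = (512, 256, 128)

    def decode_mean(self, z: np.ndarray) -> np.ndarray:
        h = np.asarray(z, dtype=np.float64)
        if h.shape != (self.latent_dim,):
            raise ValueError(f"latent must have shape ({self.latent_dim},)")
        n_hidden = len(self.hidden)
        for l in range(n_hidden):
            h = 1.0 / (1.0 + np.exp(-(h @ self.weights[f"W{l}"] + self.weights[f"b{l}"])))
        out = h @ self.weights[f"W{n_hidden}"] + self.weights[f"b{n_hidden}"]
        squashed = 1.0 / (1.0 + np.exp(-out))
        return self.weight_scale * (2.0 * squashed - 1.0)

    def sample_omega(self, rng: np.random.Generator) -> ParameterSample:
        """Draw z ~ N(0,I), decode, and add the conditional Gaussian spread."""
        z = rng.normal(size=self.latent_dim)
        mean = self.decode_mean(z)
        if self.conditional_sd > 0:
            mean = mean + rng.normal(0.0, self.conditional_sd, size=mean.shape)
        return ParameterSample(mean, self.spec.manifest())


@dataclass
class PointState:
    """Directly optimized point weights (the decoder-free ablation).

    ``dropout_rate > 0`` turns the comparator into a Monte-Carlo weight-dropout
    baseline: each weight is zeroed independently at sample time and the rest
    rescaled, so repeated draws give a crude posterior sample.
    """

    omega: np.ndarray
    spec: GNNSpec
    dropout_rate: float = 0.0

    def sample_omega(self, rng: np.random.Generator) -> ParameterSample:
        flat = np.asarray(self.omega, dtype=np.float64)
        if self.dropout_rate > 0:
            keep = rng.random(flat.shape) >= self.dropout_rate
            flat = flat * keep / (1.0 - self.dropout_rate)
        return ParameterSample(flat, self.spec.manifest())


def init_decoder(
    spec: GNNSpec,
    latent_dim: int = 16,
    hidden: tuple[int, ...] = (512, 256, 128),
    conditional_sd: float = 0.05,
    weight_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> DecoderState:
    """Xavier-initialized decoder whose output length is the GNN weight count."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dims = [latent_dim, *hidden, spec.param_count]
    weights: dict[str, np.ndarray] = {}
    for l, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights[f"W{l}"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        weights[f"b{l}"] = np.zeros(fan_out)
    return DecoderState(
        weights=weights,
        latent_dim=latent_dim,
        conditional_sd=conditional_sd,
        weight_scale=weight_scale,
        spec=spec,
        hidden=tuple(hidden),
    )


def decode_parameters(
    state: DecoderState, z: np.ndarray, sample_noise: int | None = None
) -> ParameterSample:
    """Decode a latent into a full GNN weight vector.

    Deterministic in ``(state, z)``; passing ``sample_noise`` adds the
    conditional Gaussian perturbation of sd ``state.conditional_sd`` drawn
    from that seed.
    """
    mean = state.decode_mean(np.asarray(z, dtype=np.float64))
    if sample_noise is not None and state.conditional_sd > 0:
        rng = np.random.default_rng(sample_noise)
        mean = mean + rng.normal(0.0, state.conditional_sd, size=mean.shape)
    return ParameterSample(mean, state.spec.manifest())


def _decoder_forward_ad(
    weights: dict[str, Tensor], z: np.ndarray, hidden: tuple[int, ...], scale: float
) -> Tensor:
    h: Tensor = Tensor(z)
    for l in range(len(hidden)):
        h = (h @ weights[f"W{l}"] + weights[f"b{l}"]).sigmoid()
    out = h @ weights[f"W{len(hidden)}"] + weights[f"b{len(hidden)}"]
    return out.sigmoid() * (2.0 * scale) - scale


# --------------------------------------------------------------------- loss


@dataclass
class TrainConfig:
    """Optimization settings; gamma weights the KL term of the loss."""

    gamma: float = 0.1
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.001
    mc_latents_per_step: int = 2
    mc_transforms_per_step: int = 2
    noise_sd: float | None = None  # None -> 0.1 * mean per-feature training sd
    noisy_fraction: float = 0.1
    latent_dim: int = 16
    conditional_sd: float = 0.05
    weight_scale: float = 1.0
    decoder_hidden: tuple[int, ...] = (512, 256, 128)
    eval_latents: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if min(self.epochs, self.batch_size, self.mc_latents_per_step,
               self.mc_transforms_per_step) < 1:
            raise ValueError("counts must be >= 1")


def default_noise_sd(ds: Dataset, fraction: float = 0.1) -> float:
    """Scale-free default: a fraction of the mean per-feature sd of ``ds``."""
    stacked = np.concatenate([g.features for g in ds.graphs], axis=0)
    return float(fraction * stacked.std(axis=0).mean())


def _gaussian_kl(mean_sq_norm: Tensor, sd: float, dim: int) -> Tensor:
    """KL[N(m, sd^2 I) || N(0, I)] as a function of ||m||^2.

    At sd=0 the point-mass convention drops the divergent constant and keeps
    the squared-norm penalty ||m||^2 / 2.
    """
    if sd == 0:
        return mean_sq_norm * 0.5
    const = 0.5 * dim * (sd**2 - 1.0 - 2.0 * np.log(sd))
    return mean_sq_norm * 0.5 + const


def _elbo_graph(
    graphs: Sequence[AttributedGraph],
    weights: dict[str, Tensor],
    state_template: DecoderState,
    spec: GNNSpec,
    cfg: TrainConfig,
    rng: np.random.Generator,
    noise_sd: float,
    use_transforms: bool = True,
    point_omega: Tensor | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Build the autodiff loss graph for one step; returns (loss, components)."""
    n_latent = cfg.mc_latents_per_step if point_omega is None else 1
    n_transform = cfg.mc_transforms_per_step
    p_count = spec.param_count

    # precompute normalized adjacency once per graph; permutation of the raw
    # graph permutes it identically, so the transform only reindexes it
    a_norms = [normalized_adjacency(g.adjacency) for g in graphs]

    kl_terms: list[Tensor] = []
    nll: Tensor | None = None
    for _ in range(n_latent):
        if point_omega is None:
            z = rng.normal(size=state_template.latent_dim)
            mean = _decoder_forward_ad(
                weights, z, state_template.hidden, state_template.weight_scale
            )
            kl_terms.append(
                _gaussian_kl((mean * mean).sum(), state_template.conditional_sd, p_count)
            )
            omega = mean
            if state_template.conditional_sd > 0:
                omega = mean + rng.normal(
                    0.0, state_template.conditional_sd, size=p_count
                )
        else:
            omega = point_omega
            kl_terms.append((omega * omega).sum() * 0.5)
        params = _split_flat(omega, spec)
        for k in range(n_transform):
            for g, a_norm in zip(graphs, a_norms):
                if g.label is None:
                    raise ValueError("training requires labeled graphs")
                if use_transforms:
                    t = sample_transformation(
                        g, noise_sd, cfg.noisy_fraction, rng
                    )
                    perm = t.permutation
                    x = (g.features - t.feature_noise)[perm]
                    a_n = a_norm[np.ix_(perm, perm)]
                else:
                    x, a_n = g.features, a_norm
                logits, _ = _forward_ad(Tensor(x), Tensor(a_n), params, spec)
                logp = logits.log_softmax()[g.label]
                nll = (-logp) if nll is None else nll + (-logp)

    kl_hat = kl_terms[0]
    for term in kl_terms[1:]:
        kl_hat = kl_hat + term
    kl_hat = kl_hat * (1.0 / len(kl_terms))
    nll_mean = nll * (1.0 / (n_latent * n_transform))
    loss = kl_hat * cfg.gamma + nll_mean
    comps = {
        "kl": float(kl_hat.data),
        "nll": float(nll_mean.data),
        "loss": float(kl_hat.data * cfg.gamma + nll_mean.data),
    }
    return loss, comps


def elbo_loss(
    batch: Dataset | Sequence[AttributedGraph],
    state: DecoderState,
    spec: GNNSpec,
    cfg: TrainConfig,
    step_seed: int = 0,
) -> tuple[float, dict[str, float]]:
    """Monte-Carlo loss gamma*KL_hat + NLL on a labeled batch (no gradients)."""
    graphs = list(batch.graphs if isinstance(batch, Dataset) else batch)
    rng = np.random.default_rng(step_seed)
    noise_sd = cfg.noise_sd if cfg.noise_sd is not None else default_noise_sd(
        Dataset(graphs, class_count=spec.class_count)
    )
    weights = {k: Tensor(v) for k, v in state.weights.items()}
    loss, comps = _elbo_graph(graphs, weights, state, spec, cfg, rng, noise_sd)
    return comps["loss"], comps


# ----------------------------------------------------------------- training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainResult:
    state: "DecoderState | PointState"
    log: list[dict] = field(default_factory=list)


def _accuracy(
    graphs: Sequence[AttributedGraph],
    state: "DecoderState | PointState",
    spec: GNNSpec,
    n_latent: int,
    rng: np.random.Generator,
) -> float:
    if not graphs:
        return float("nan")
    omegas = [state.sample_omega(rng) for _ in range(n_latent)]
    param_sets = [o.arrays() for o in omegas]
    correct = 0
    for g in graphs:
        a_norm = normalized_adjacency(g.adjacency)
        probs = np.mean(
            [_forward_np(g.features, a_norm, p, spec)[0] for p in param_sets], axis=0
        )
        correct += int(np.argmax(probs) == g.label)
    return correct / len(graphs)


Variant = Literal["full", "no_transform", "point"]


def train(
    ds: Dataset,
    spec: GNNSpec,
    cfg: TrainConfig,
    variant: Variant = "full",
) -> TrainResult:
    """Fit the parameter decoder (or point weights) by Adam on the MC loss.

    ``variant='no_transform'`` disables the reversible transforms during
    training; ``variant='point'`` removes the decoder and optimizes a single
    weight vector directly (a plain GNN with a Gaussian weight prior).  Fully
    reproducible from ``cfg.seed``.
    """
    if ds.split_assignment is not None:
        train_graphs = [ds.graphs[i] for i in ds.split_indices("train")]
        valid_graphs = [ds.graphs[i] for i in ds.split_indices("valid")]
    else:
        train_graphs, valid_graphs = list(ds.graphs), []
    if not train_graphs:
        raise ValueError("empty train split")

    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_init = np.random.default_rng(seeds[0])
    rng_step = np.random.default_rng(seeds[1])
    rng_eval = np.random.default_rng(seeds[2])

    noise_sd = cfg.noise_sd
    if noise_sd is None:
        noise_sd = default_noise_sd(Dataset(train_graphs, class_count=ds.class_count))

    use_transforms = variant != "no_transform"
    point_mode = variant == "point"

    state = init_decoder(
        spec,
        latent_dim=cfg.latent_dim,
        hidden=cfg.decoder_hidden,
        conditional_sd=cfg.conditional_sd,
        weight_scale=cfg.weight_scale,
        seed=rng_init,
    )
    if point_mode:
        omega0 = rng_init.normal(0.0, 0.1, size=spec.param_count)
        params: dict[str, np.ndarray] = {"omega": omega0}
    else:
        params = state.weights

    opt = _Adam(params, cfg.learning_rate)
    log: list[dict] = []
    n = len(train_graphs)
    for epoch in range(cfg.epochs):
        order = rng_step.permutation(n)
        epoch_comps = {"kl": 0.0, "nll": 0.0, "loss": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            batch = [train_graphs[i] for i in order[start : start + cfg.batch_size]]
            if point_mode:
                leaves = {"omega": Tensor(params["omega"], requires_grad=True)}
                loss, comps = _elbo_graph(
                    batch, {}, state, spec, cfg, rng_step, noise_sd,
                    use_transforms=use_transforms, point_omega=leaves["omega"],
                )
            else:
                leaves = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
                loss, comps = _elbo_graph(
                    batch, leaves, state, spec, cfg, rng_step, noise_sd,
                    use_transforms=use_transforms,
                )
            loss.backward()
            grads = {k: t.grad for k, t in leaves.items()}
            opt.step(params, grads)
            for key in epoch_comps:
                epoch_comps[key] += comps[key]
            n_batches += 1
        eval_state: DecoderState | PointState
        eval_state = PointState(params["omega"], spec) if point_mode else state
        entry = {
            "epoch": epoch,
            "loss": epoch_comps["loss"] / n_batches,
            "kl": epoch_comps["kl"] / n_batches,
            "nll": epoch_comps["nll"] / n_batches,
            "train_acc": _accuracy(train_graphs, eval_state, spec, cfg.eval_latents, rng_eval),
            "valid_acc": _accuracy(valid_graphs, eval_state, spec, cfg.eval_latents, rng_eval),
        }
        log.append(entry)

    final: DecoderState | PointState = (
        PointState(params["omega"], spec) if point_mode else state
    )
    return TrainResult(state=final, log=log)


# --------------------------------------------------------------- prediction


def predict(
    g: AttributedGraph,
    state: "DecoderState | PointState",
    spec: GNNSpec,
    J: int = 8,
    K: int = 4,
    noise_sd: float = 0.1,
    noisy_fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
    permute: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """MC-average predictive probabilities over J weight and K transform draws.

    Each sample inverts a freshly drawn transform on the observed graph before
    the forward pass.  Returns ``(mean_vector, samples)`` where ``samples`` has
    shape ``(J*K, class_count)`` and its arithmetic mean equals ``mean_vector``.
    """
    if J < 1 or K < 1:
        raise ValueError("J and K must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = np.empty((J * K, spec.class_count))
    i = 0
    for _ in range(J):
        params = state.sample_omega(rng).arrays()
        for _ in range(K):
            t = sample_transformation(g, noise_sd, noisy_fraction, rng, permute=permute)
            g_rec = invert_transform(g, t)
            probs, _, _ = _forward_np(
                g_rec.features, normalized_adjacency(g_rec.adjacency), params, spec
            )
            samples[i] = probs
            i += 1
    return samples.mean(axis=0), samples


# ------------------------------------------------------------- persistence


def save_checkpoint(state: "DecoderState | PointState", path) -> None:
    """One-file checkpoint: tensors plus a JSON manifest."""
    import json

    path = Path(path)
    if isinstance(state, DecoderState):
        meta = {
            "kind": "decoder",
            "latent_dim": state.latent_dim,
            "conditional_sd": state.conditional_sd,
            "weight_scale": state.weight_scale,
            "hidden": list(state.hidden),
            "spec": {
                "input_dim": state.spec.input_dim,
                "hidden_dims": list(state.spec.hidden_dims),
                "class_count": state.spec.class_count,
            },
        }
        np.savez(path, __meta__=json.dumps(meta), **state.weights)
    else:
        meta = {
            "kind": "point",
            "dropout_rate": state.dropout_rate,
            "spec": {
                "input_dim": state.spec.input_dim,
                "hidden_dims": list(state.spec.hidden_dims),
                "class_count": state.spec.class_count,
            },
        }
        np.savez(path, __meta__=json.dumps(meta), omega=state.omega)


def load_checkpoint(path) -> "DecoderState | PointState":
    import json

    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        spec = GNNSpec(
            input_dim=meta["spec"]["input_dim"],
            hidden_dims=tuple(meta["spec"]["hidden_dims"]),
            class_count=meta["spec"]["class_count"],
        )
        if meta["kind"] == "decoder":
            weights = {k: data[k] for k in data.files if k != "__meta__"}
            return DecoderState(
                weights=weights,
                latent_dim=meta["latent_dim"],
                conditional_sd=meta["conditional_sd"],
                weight_scale=meta["weight_scale"],
                spec=spec,
                hidden=tuple(meta["hidden"]),
            )
        return PointState(
            omega=data["omega"], spec=spec, dropout_rate=meta["dropout_rate"]
        )
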