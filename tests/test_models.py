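"""Classifier, decoder, ELBO loss, training and prediction contracts."""

import numpy as np
import pytest

import graphuq as gq
from conftest import random_graph


class TestDecoder:
    def test_output_length_matches_parameter_count(self, tiny_spec, tiny_decoder):
        z = np.zeros(tiny_decoder.latent_dim)
        omega = gq.decode_parameters(tiny_decoder, z)
        assert omega.flat_values.shape == (tiny_spec.param_count,)

    def test_zero_decoder_outputs_rescaled_output_bias(self, tiny_spec):
        state = gq.init_decoder(tiny_spec, latent_dim=3, hidden=(4, 4, 4),
                                conditional_sd=0.0, seed=0)
        for key in state.weights:
            state.weights[key] = np.zeros_like(state.weights[key])
        bias = np.full(tiny_spec.param_count, 0.7)
        state.weights["b3"] = bias
        expected = state.weight_scale * (2.0 / (1.0 + np.exp(-bias)) - 1.0)
        for z in (np.zeros(3), np.ones(3), -np.ones(3)):
            omega = gq.decode_parameters(state, z)
            assert np.allclose(omega.flat_values, expected)

    def test_deterministic_in_z_and_sensitive_to_z(self, tiny_decoder, rng):
        zs = rng.normal(size=(10, tiny_decoder.latent_dim))
        outputs = []
        for z in zs:
            a = gq.decode_parameters(tiny_decoder, z)
            b = gq.decode_parameters(tiny_decoder, z)
            assert np.array_equal(a.flat_values, b.flat_values)
            outputs.append(a.flat_values)
        for i in range(9):
            assert not np.allclose(outputs[i], outputs[i + 1])

    def test_sample_noise_reproducible(self, tiny_decoder):
        z = np.ones(tiny_decoder.latent_dim)
        a = gq.decode_parameters(tiny_decoder, z, sample_noise=5)
        b = gq.decode_parameters(tiny_decoder, z, sample_noise=5)
        c = gq.decode_parameters(tiny_decoder, z, sample_noise=6)
        assert np.array_equal(a.flat_values, b.flat_values)
        assert not np.array_equal(a.flat_values, c.flat_values)

    def test_dimension_mismatch_rejected(self, tiny_decoder):
        with pytest.raises(ValueError, match="latent"):
            gq.decode_parameters(tiny_decoder, np.zeros(99))


class TestParameterSample:
    def test_unflatten_flatten_identity(self, tiny_spec, rng):
        flat = rng.normal(size=tiny_spec.param_count)
        omega = gq.ParameterSample(flat, tiny_spec.manifest())
        back = gq.ParameterSample.from_arrays(omega.arrays(), tiny_spec)
        assert np.array_equal(back.flat_values, flat)

    def test_wrong_length_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="manifest"):
            gq.ParameterSample(np.zeros(3), tiny_spec.manifest())


class TestForward:
    def test_probabilities_normalized(self, tiny_spec, tiny_omega, rng):
        for _ in range(5):
            g = random_graph(rng, n=6, d=4)
            probs = gq.gnn_forward(g, tiny_omega, tiny_spec)
            assert (probs >= 0).all()
            assert abs(probs.sum() - 1.0) < 1e-6

    def test_permutation_invariance(self, tiny_spec, tiny_omega, rng):
        g = random_graph(rng, n=7, d=4)
        base = gq.gnn_forward(g, tiny_omega, tiny_spec)
        for seed in range(10):
            t = gq.sample_transformation(g, 0.0, 0.0, seed=seed)
            permuted = gq.apply_transform(g, t)
            assert np.abs(gq.gnn_forward(permuted, tiny_omega, tiny_spec) - base).max() < 1e-5

    def test_single_node_closed_form(self):
        """1-node, 1-layer network reduces to softmax(U^T relu(W^T x + b) + c)."""
        spec = gq.GNNSpec(input_dim=2, hidden_dims=(3,), class_count=2)
        rng = np.random.default_rng(0)
        arrays = {
            "layer0.W": rng.normal(size=(2, 3)),
            "layer0.b": rng.normal(size=3),
            "head.W": rng.normal(size=(3, 2)),
            "head.b": rng.normal(size=2),
        }
        omega = gq.ParameterSample.from_arrays(arrays, spec)
        x = np.array([[0.5, -1.0]])
        g = gq.AttributedGraph(features=x, adjacency=np.zeros((1, 1), dtype=np.int8))
        # closed form: self-loop normalization is the identity for one node
        h = np.maximum(x[0] @ arrays["layer0.W"] + arrays["layer0.b"], 0)
        logits = h @ arrays["head.W"] + arrays["head.b"]
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(gq.gnn_forward(g, omega, spec), expected, atol=1e-12)

    def test_feature_dim_mismatch_rejected(self, tiny_spec, tiny_omega, rng):
        g = random_graph(rng, n=4, d=7)
        with pytest.raises(ValueError, match="dimension"):
            gq.gnn_forward(g, tiny_omega, tiny_spec)


class TestElboLoss:
    def _constant_decoder(self, spec, value=0.0, sd=0.0):
        state = gq.init_decoder(spec, latent_dim=2, hidden=(4, 4, 4),
                                conditional_sd=sd, seed=0)
        for key in state.weights:
            state.weights[key] = np.zeros_like(state.weights[key])
        if value != 0.0:
            # invert the output squashing to hit the requested constant
            state.weights["b3"] = np.full(
                spec.param_count, np.log((1 + value) / (1 - value))
            )
        return state

    def test_zero_weights_zero_sd_gives_zero_kl(self, tiny_spec, rng):
        """Point-mass convention: decoded mean 0 gives KL_hat = 0 and the loss
        equals the uniform-prediction NLL."""
        state = self._constant_decoder(tiny_spec)
        g = random_graph(rng, n=5, d=4, label=1)
        cfg = gq.TrainConfig(gamma=0.5, noise_sd=0.0,
                             mc_latents_per_step=1, mc_transforms_per_step=1)
        loss, comps = gq.elbo_loss([g], state, tiny_spec, cfg, step_seed=0)
        assert comps["kl"] == 0.0
        # zero weights -> uniform class probabilities -> NLL = log C
        assert np.isclose(comps["nll"], np.log(2))
        assert np.isclose(loss, np.log(2))

    def test_nll_nonnegative_and_loss_decomposition_exact(self, tiny_spec,
                                                          tiny_decoder, rng):
        graphs = [random_graph(rng, n=5, d=4, label=i % 2) for i in range(3)]
        cfg = gq.TrainConfig(gamma=0.3)
        loss, comps = gq.elbo_loss(graphs, tiny_decoder, tiny_spec, cfg, step_seed=4)
        assert comps["nll"] >= 0
        assert np.isclose(loss, cfg.gamma * comps["kl"] + comps["nll"], rtol=1e-12)

    def test_single_term_oracle(self, tiny_spec, rng):
        """J=K=1, sigma=0, zero feature noise: the loss must equal
        gamma*||m(z)||^2/2 - log F(X,A,m(z))[y] with z replayed from the seed."""
        state = gq.init_decoder(tiny_spec, latent_dim=3, hidden=(6, 5, 4),
                                conditional_sd=0.0, seed=3)
        g = random_graph(rng, n=4, d=4, label=0)
        cfg = gq.TrainConfig(gamma=0.25, noise_sd=0.0, noisy_fraction=0.0,
                             mc_latents_per_step=1, mc_transforms_per_step=1)
        loss, comps = gq.elbo_loss([g], state, tiny_spec, cfg, step_seed=77)
        z = np.random.default_rng(77).normal(size=3)
        omega = gq.decode_parameters(state, z)
        expected_kl = 0.5 * float(omega.flat_values @ omega.flat_values)
        # forward pass is permutation-invariant, so the sampled permutation
        # cannot change the likelihood term
        expected_nll = -np.log(gq.gnn_forward(g, omega, tiny_spec)[0])
        assert np.isclose(comps["kl"], expected_kl, rtol=1e-10)
        assert np.isclose(comps["nll"], expected_nll, rtol=1e-10)
        assert np.isclose(loss, cfg.gamma * expected_kl + expected_nll, rtol=1e-10)

    def test_unlabeled_graph_rejected(self, tiny_spec, tiny_decoder, rng):
        g = random_graph(rng, n=4, d=4, label=None)
        with pytest.raises(ValueError, match="label"):
            gq.elbo_loss([g], tiny_decoder, tiny_spec, gq.TrainConfig(), 0)


@pytest.fixture(scope="module")
def trained_small():
    ds = gq.generate_motif_dataset(gq.SyntheticConfig(n_graphs=120, seed=21))
    gq.split_dataset(ds, seed=21)
    spec = gq.GNNSpec(input_dim=8, hidden_dims=(16, 16), class_count=2)
    cfg = gq.TrainConfig(epochs=10, seed=21)
    result = gq.train(ds, spec, cfg)
    return ds, spec, cfg, result


class TestTraining:
    def test_seeded_training_is_reproducible(self):
        ds = gq.generate_motif_dataset(gq.SyntheticConfig(n_graphs=30, seed=5))
        gq.split_dataset(ds, seed=5)
        spec = gq.GNNSpec(input_dim=8, hidden_dims=(6, 6), class_count=2)
        cfg = gq.TrainConfig(epochs=2, seed=5, decoder_hidden=(16, 8, 8), latent_dim=4)
        a = gq.train(ds, spec, cfg)
        b = gq.train(ds, spec, cfg)
        for key in a.state.weights:
            assert np.array_equal(a.state.weights[key], b.state.weights[key])
        assert a.log == b.log

    def test_learns_motif_task_above_majority(self, trained_small):
        ds, spec, cfg, result = trained_small
        labels = ds.split("valid").labels()
        majority = max(labels.mean(), 1 - labels.mean())
        assert result.log[-1]["valid_acc"] > majority

    def test_loss_decreases_on_learnable_task(self, trained_small):
        _, _, _, result = trained_small
        assert result.log[-1]["loss"] <= result.log[0]["loss"]

    def test_empty_train_split_rejected(self, rng):
        ds = gq.Dataset([random_graph(rng, n=4, d=2, label=0)])
        ds.split_assignment = {0: "test"}
        with pytest.raises(ValueError, match="train"):
            gq.train(ds, gq.GNNSpec(input_dim=2), gq.TrainConfig(epochs=1))

    def test_point_variant_trains_plain_gnn(self):
        ds = gq.generate_motif_dataset(gq.SyntheticConfig(n_graphs=30, seed=5))
        gq.split_dataset(ds, seed=5)
        spec = gq.GNNSpec(input_dim=8, hidden_dims=(6, 6), class_count=2)
        cfg = gq.TrainConfig(epochs=3, seed=5)
        result = gq.train(ds, spec, cfg, variant="point")
        assert isinstance(result.state, gq.PointState)
        assert result.state.omega.shape == (spec.param_count,)


class TestPredict:
    def test_single_sample_equals_forward(self, tiny_spec, rng):
        g = random_graph(rng, n=5, d=4, label=0)
        state = gq.init_decoder(tiny_spec, latent_dim=3, hidden=(4, 4, 4),
                                conditional_sd=0.0, seed=1)
        mean, samples = gq.predict(g, state, tiny_spec, J=1, K=1, noise_sd=0.0,
                                   noisy_fraction=0.0, seed=3, permute=False)
        z = np.random.default_rng(3).normal(size=3)
        omega = gq.decode_parameters(state, z)
        assert np.allclose(mean, gq.gnn_forward(g, omega, tiny_spec))
        assert samples.shape == (1, 2)

    def test_mean_equals_mean_of_samples(self, tiny_spec, tiny_decoder, rng):
        g = random_graph(rng, n=6, d=4)
        mean, samples = gq.predict(g, tiny_decoder, tiny_spec, J=3, K=2,
                                   noise_sd=0.2, noisy_fraction=0.5, seed=0)
        assert np.allclose(mean, samples.mean(axis=0))

    def test_two_pinned_weight_sets_average(self, tiny_spec, rng):
        """J=2, K=1 with two pinned weight vectors equals the hand average."""
        omegas = [
            gq.ParameterSample(rng.normal(size=tiny_spec.param_count),
                               tiny_spec.manifest())
            for _ in range(2)
        ]

        class PinnedState:
            def __init__(self):
                self.calls = 0

            def sample_omega(self, _rng):
                omega = omegas[self.calls % 2]
                self.calls += 1
                return omega

        g = random_graph(rng, n=2, d=4)
        mean, _ = gq.predict(g, PinnedState(), tiny_spec, J=2, K=1,
                             noise_sd=0.0, noisy_fraction=0.0, seed=0, permute=False)
        expected = 0.5 * (gq.gnn_forward(g, omegas[0], tiny_spec)
                          + gq.gnn_forward(g, omegas[1], tiny_spec))
        assert np.allclose(mean, expected)

    def test_relabeling_invariance_of_mean(self, tiny_spec, tiny_decoder, rng):
        g = random_graph(rng, n=6, d=4)
        t = gq.sample_transformation(g, 0.0, 0.0, seed=8)
        relabeled = gq.apply_transform(g, t)
        a, _ = gq.predict(g, tiny_decoder, tiny_spec, J=4, K=1, noise_sd=0.0,
                          noisy_fraction=0.0, seed=2)
        b, _ = gq.predict(relabeled, tiny_decoder, tiny_spec, J=4, K=1, noise_sd=0.0,
                          noisy_fraction=0.0, seed=2)
        assert np.abs(a - b).max() < 1e-5


def test_teacher_parameter_recovery():
    """Fitting data labeled by a fixed teacher network recovers its held-out
    behavior: predictive accuracy on confidently teacher-labeled graphs
    exceeds 90% at desk scale."""
    ds = gq.generate_motif_dataset(gq.SyntheticConfig(n_graphs=400, seed=9))
    spec = gq.GNNSpec(input_dim=8, hidden_dims=(16, 16), class_count=2)
    rng = np.random.default_rng(42)
    arrays = gq.ParameterSample(rng.normal(0, 1.0, spec.param_count),
                                spec.manifest()).arrays()
    teacher = gq.ParameterSample.from_arrays(arrays, spec)
    margins = np.array([
        gq.gnn_logits(g, teacher, spec)[1] - gq.gnn_logits(g, teacher, spec)[0]
        for g in ds.graphs
    ])
    margins = margins - np.median(margins)  # balance the two classes
    lo, hi = np.quantile(margins, [0.3, 0.7])
    kept = []
    for g, m in zip(ds.graphs, margins):
        if m <= lo or m >= hi:  # drop ambiguous near-boundary graphs
            g.label = int(m > 0)
            kept.append(g)
    student_ds = gq.Dataset(kept, class_count=2)
    gq.split_dataset(student_ds, seed=9)
    result = gq.train(student_ds, spec, gq.TrainConfig(epochs=25, seed=9, noise_sd=0.05))
    test = student_ds.split("test")
    correct = 0
    for i, g in enumerate(test.graphs):
        mean, _ = gq.predict(g, result.state, spec, J=8, K=1, noise_sd=0.0,
                             noisy_fraction=0.0, seed=np.random.default_rng([9, i]))
        correct += int(np.argmax(mean) == g.label)
    assert correct / len(test.graphs) > 0.9


def test_checkpoint_round_trip(tmp_path, tiny_spec, tiny_decoder):
    path = tmp_path / "model.npz"
    gq.save_checkpoint(tiny_decoder, path)
    back = gq.load_checkpoint(path)
    assert isinstance(back, gq.DecoderState)
    for key in tiny_decoder.weights:
        assert np.array_equal(back.weights[key], tiny_decoder.weights[key])
    assert back.spec == tiny_spec
    z = np.array([0.1, 0.2, 0.3])
    assert np.array_equal(
        gq.decode_parameters(back, z).flat_values,
        gq.decode_parameters(tiny_decoder, z).flat_values,
    )
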