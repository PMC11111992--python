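"""End-to-end planted-motif benchmark: train, predict, quantify, detect.

This is the package's reference pipeline on fully synthetic data with known
ground truth: generate the planted-motif dataset, train the variational
classifier, and measure (a) held-out accuracy against the majority rate,
(b) whether prediction uncertainty separates misclassified from correctly
classified graphs, (c) misclassification-detection AUC with a permutation
test over several scoring seeds, (d) explanation-misclassification detection
against the planted-motif masks, and (e) accuracy under increasing feature
noise.  Both the acceptance checks and the example scripts run through here.
"""

from __future__ import annotations

import numpy as np

from .evaluation import (
    auc_permutation_test,
    explanation_detection,
    misclassification_roc,
    noise_robustness_experiment,
)
from .explain import expected_explanation
from .models import GNNSpec, TrainConfig, default_noise_sd, predict, train
from .splits import split_dataset
from .synthetic import SyntheticConfig, generate_motif_dataset
from .transforms import WalkConfig
from .uncertainty import decompose_uncertainty, prediction_uncertainty

__all__ = ["run_motif_benchmark"]


def run_motif_benchmark(
    seed: int = 0,
    n_graphs: int = 500,
    epochs: int = 25,
    score_seeds: int = 10,
    explain_graphs: int = 25,
    noise_fractions: tuple[float, ...] = (0.0, 0.05, 0.10),
    noise_replicates: int = 5,
    J: int = 8,
    K: int = 2,
    verbose: bool = False,
) -> dict:
    """Run the full pipeline at desk scale; returns a flat dict of results."""
    seed = int(seed) % (2**31 - 1)
    data_cfg = SyntheticConfig(n_graphs=n_graphs, seed=seed)
    ds = generate_motif_dataset(data_cfg)
    split_dataset(ds, mode="random", ratio=(0.8, 0.1, 0.1), seed=seed)
    spec = GNNSpec(input_dim=data_cfg.feature_dim, hidden_dims=(16, 16), class_count=2)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    result = train(ds, spec, cfg)
    state = result.state
    if verbose:
        for entry in result.log:
            print(
                f"epoch {entry['epoch']:3d}  loss {entry['loss']:8.3f}  "
                f"train_acc {entry['train_acc']:.3f}  valid_acc {entry['valid_acc']:.3f}"
            )

    test_idx = ds.split_indices("test")
    test_graphs = [ds.graphs[i] for i in test_idx]
    labels = np.array([g.label for g in test_graphs])
    majority_rate = float(max(np.mean(labels), 1 - np.mean(labels)))
    noise_sd = default_noise_sd(ds.split("train"))

    # held-out predictions (fixed evaluation seed)
    predictions = np.empty(len(test_graphs), dtype=int)
    for i, g in enumerate(test_graphs):
        mean, _ = predict(
            g, state, spec, J=J, K=K, noise_sd=noise_sd, noisy_fraction=0.1,
            seed=np.random.default_rng([seed, 7, i]),
        )
        predictions[i] = int(np.argmax(mean))
    misclassified = (predictions != labels).astype(int)
    accuracy = float(1 - misclassified.mean())

    # uncertainty scores over several MC seeds
    score_matrix = np.empty((score_seeds, len(test_graphs)))
    for s in range(score_seeds):
        for i, g in enumerate(test_graphs):
            score, _ = prediction_uncertainty(
                g, state, spec, J=J, K=K, noise_sd=noise_sd, noisy_fraction=0.1,
                seed=np.random.default_rng([seed, 11, s, i]),
            )
            score_matrix[s, i] = score
    mean_scores = score_matrix.mean(axis=0)

    out: dict = {
        "n_graphs": n_graphs,
        "n_test": len(test_graphs),
        "majority_rate": majority_rate,
        "test_accuracy": accuracy,
        "n_misclassified": int(misclassified.sum()),
    }
    if 0 < misclassified.sum() < len(test_graphs):
        out["mean_uncertainty_misclassified"] = float(
            mean_scores[misclassified == 1].mean()
        )
        out["mean_uncertainty_correct"] = float(mean_scores[misclassified == 0].mean())
        per_seed_auc = [
            misclassification_roc(score_matrix[s], misclassified).area_under_curve
            for s in range(score_seeds)
        ]
        out["misclassification_auc"] = float(np.mean(per_seed_auc))
        out["misclassification_auc_sd"] = float(np.std(per_seed_auc))
        _, p_value = auc_permutation_test(
            mean_scores, misclassified, n_permutations=999, seed=seed
        )
        out["misclassification_auc_pvalue"] = float(p_value)

    # explanation detection on positive test graphs (they carry motif truth)
    positives = [g for g in test_graphs if g.label == 1][:explain_graphs]
    saliencies, reports = [], []
    for i, g in enumerate(positives):
        s_mean, _ = expected_explanation(
            g, state, spec, c=1, I=4, J=4, noise_sd=noise_sd, noisy_fraction=0.1,
            seed=np.random.default_rng([seed, 13, i]), level="node",
        )
        rep = decompose_uncertainty(
            g, state, spec, c=1, J=4, K=4, noise_sd=noise_sd, noisy_fraction=0.1,
            walk_cfg=WalkConfig(walk_count=20, walk_length=10),
            seed=int(np.random.default_rng([seed, 17, i]).integers(2**31)),
            level="node",
        )
        saliencies.append(s_mean)
        reports.append(rep)
    detection = explanation_detection(saliencies, reports, positives, "total")
    out["explanation_node_auc"] = detection["node"]["auc"]
    out["explanation_node_acc"] = detection["node"]["accuracy"]

    # robustness to feature noise on 0/5/10% of nodes
    rows = noise_robustness_experiment(
        ds, state, spec, fractions=noise_fractions,
        noise_sd=data_cfg.feature_noise_sd * 2, replicates=noise_replicates,
        seed=seed, J=J, K=K, predict_noise_sd=noise_sd,
    )
    for row in rows:
        pct = int(round(row.noise_fraction * 100))
        out[f"accuracy_noise_{pct}pct"] = row.accuracy
        out[f"auc_noise_{pct}pct"] = row.auc
        out[f"f1_noise_{pct}pct"] = row.f1
    return out
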