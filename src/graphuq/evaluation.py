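"""Experiment protocols: misclassification detection, explanation detection,
noise-robustness curves and the ablation harness.

Misclassified test graphs are treated as the positive class and ranked by a
scalar uncertainty score; ROC/AUC measures how well uncertainty flags errors.
Explanations are binarized by min-max normalizing each saliency map and
thresholding at 0.5; per-element disagreement with a ground-truth mask
defines "wrong" explanation elements, which per-element uncertainty is then
scored against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score, roc_curve

from .explain import SaliencyMap
from .graphs import AttributedGraph, Dataset
from .models import DecoderState, GNNSpec, PointState, TrainConfig, predict, train
from .uncertainty import UncertaintyReport

__all__ = [
    "RocResult",
    "MetricsRow",
    "misclassification_roc",
    "auc_permutation_test",
    "binarize_explanation",
    "explanation_detection",
    "noise_robustness_experiment",
    "ablation_experiment",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    area_under_curve: float


@dataclass
class MetricsRow:
    """One row of a robustness table: metrics at one noise fraction."""

    noise_fraction: float
    accuracy: float
    auc: float
    f1: float
    accuracy_sd: float = 0.0
    auc_sd: float = 0.0
    f1_sd: float = 0.0

    def as_dict(self) -> dict:
        return {
            "noise_fraction": self.noise_fraction,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "f1": self.f1,
            "accuracy_sd": self.accuracy_sd,
            "auc_sd": self.auc_sd,
            "f1_sd": self.f1_sd,
        }


def misclassification_roc(
    scores: Sequence[float], misclassified: Sequence[bool]
) -> RocResult:
    """ROC of an uncertainty score against misclassification (positives).

    Threshold sweep over the unique scores with trapezoidal AUC; equals the
    Mann-Whitney pairwise statistic (ties counted half).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(misclassified, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"single-class input: only class {classes[0]} present; ROC undefined"
        )
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        area_under_curve=float(roc_auc_score(labels, scores)),
    )


def auc_permutation_test(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: Literal["greater"] = "greater",
) -> tuple[float, float]:
    """Permutation p-value for AUC > 0.5 (label shuffling null)."""
    rng = np.random.default_rng(seed)
    observed = roc_auc_score(labels, scores)
    labels = np.asarray(labels)
    count = 0
    for _ in range(n_permutations):
        if roc_auc_score(rng.permutation(labels), scores) >= observed:
            count += 1
    return float(observed), (count + 1) / (n_permutations + 1)


def _above_half(values: np.ndarray) -> np.ndarray:
    """Min-max normalize and threshold at 0.5 with >= counting as positive.

    Implemented in the symmetric form (v - lo) >= (hi - v), with a relative
    tolerance of 1e-9*(hi - lo) so values at the exact midpoint are counted
    positive despite binary rounding.  Constant maps give all-False
    (degenerate convention)."""
    lo, hi = values.min(), values.max()
    if hi - lo == 0:
        return np.zeros(values.shape, dtype=bool)
    return (values - lo) >= (hi - values) - 1e-9 * (hi - lo)


def binarize_explanation(
    s: SaliencyMap, adjacency: np.ndarray | None = None
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Min-max normalize each map and threshold at 0.5 (>= counts positive).

    Constant maps binarize to all zeros.  For edge maps, when ``adjacency``
    is given only its support enters the normalization and the mask.
    Returns ``(node_mask, edge_mask)`` with ``None`` for absent maps.
    """
    node_mask = edge_mask = None
    if s.node_scores is not None:
        node_mask = _above_half(s.node_scores).astype(np.int8)
    if s.edge_scores is not None:
        edge = s.edge_scores
        n = edge.shape[0]
        edge_mask = np.zeros((n, n), dtype=np.int8)
        if adjacency is not None:
            i, j = np.nonzero(np.triu(adjacency, k=1))
        else:
            i, j = np.nonzero(np.triu(np.ones((n, n)), k=1).astype(bool))
        values = edge[i, j]
        if values.size:
            mask = _above_half(values)
            edge_mask[i[mask], j[mask]] = 1
            edge_mask = (edge_mask | edge_mask.T).astype(np.int8)
    return node_mask, edge_mask


def _detection_metrics(uncertainty: np.ndarray, wrong: np.ndarray) -> dict:
    """AUC of uncertainty vs. wrongness + ACC at the median-uncertainty cut."""
    out: dict = {"n_elements": int(wrong.size), "wrong_rate": float(wrong.mean())}
    threshold = np.median(uncertainty)
    flagged = uncertainty >= threshold
    out["accuracy"] = float(accuracy_score(wrong, flagged))
    if np.unique(wrong).size < 2:
        out["auc"] = float("nan")
    else:
        out["auc"] = float(roc_auc_score(wrong, uncertainty))
    return out


def explanation_detection(
    saliency: Sequence[SaliencyMap],
    uncertainty: Sequence[UncertaintyReport],
    truth_graphs: Sequence[AttributedGraph],
    score_source: Literal["measurement", "structural", "total"] = "total",
) -> dict:
    """Explanation-misclassification detection against ground-truth masks.

    Per element (node, and edge on the adjacency support), the binarized
    explanation "is wrong" when it disagrees with the truth mask; elements
    are pooled across graphs and the chosen per-element uncertainty is scored
    against wrongness.  Returns node and edge ACC/AUC.
    """
    if not (len(saliency) == len(uncertainty) == len(truth_graphs)):
        raise ValueError("aligned saliency/uncertainty/truth collections required")
    attr = {
        "measurement": "measurement_var",
        "structural": "structural_var",
        "total": "total_var",
    }[score_source]
    node_unc, node_wrong, edge_unc, edge_wrong = [], [], [], []
    for s, rep, g in zip(saliency, uncertainty, truth_graphs):
        node_mask, edge_mask = binarize_explanation(s, adjacency=g.adjacency)
        var = getattr(rep, attr)
        if var is None:
            raise ValueError(f"uncertainty report lacks {attr}")
        var = np.asarray(var)
        if node_mask is not None and g.node_truth is not None and var.ndim == 1:
            node_wrong.append(node_mask != g.node_truth)
            node_unc.append(var)
        if edge_mask is not None and g.edge_truth is not None and var.ndim == 2:
            i, j = np.nonzero(np.triu(g.adjacency, k=1))
            edge_wrong.append(edge_mask[i, j] != g.edge_truth[i, j])
            edge_unc.append(var[i, j])
    if not node_wrong and not edge_wrong:
        raise ValueError("no elements with ground truth to score")
    result: dict = {"score_source": score_source}
    if node_wrong:
        result["node"] = _detection_metrics(
            np.concatenate(node_unc), np.concatenate(node_wrong).astype(int)
        )
    if edge_wrong:
        result["edge"] = _detection_metrics(
            np.concatenate(edge_unc), np.concatenate(edge_wrong).astype(int)
        )
    return result


def _perturb(g: AttributedGraph, fraction: float, noise_sd: float,
             rng: np.random.Generator) -> AttributedGraph:
    out = g.copy()
    k = int(round(fraction * g.node_count))
    if k > 0 and noise_sd > 0:
        nodes = rng.choice(g.node_count, size=k, replace=False)
        out.features[nodes] += rng.normal(0.0, noise_sd, size=(k, g.feature_dim))
    return out


def _classification_metrics(
    labels: np.ndarray, positive_probs: np.ndarray
) -> tuple[float, float, float]:
    predicted = (positive_probs >= 0.5).astype(int)
    acc = float(accuracy_score(labels, predicted))
    f1 = float(f1_score(labels, predicted, zero_division=0))
    auc = float(roc_auc_score(labels, positive_probs)) if np.unique(labels).size > 1 \
        else float("nan")
    return acc, auc, f1


def noise_robustness_experiment(
    ds: Dataset,
    state: "DecoderState | PointState",
    spec: GNNSpec,
    fractions: Sequence[float] = (0.0, 0.05, 0.10),
    noise_sd: float = 0.5,
    replicates: int = 10,
    seed: int = 0,
    J: int = 8,
    K: int = 2,
    predict_noise_sd: float = 0.0,
) -> list[MetricsRow]:
    """ACC/AUC/F1 on the test split under feature noise on 0/5/10% of nodes.

    Each replicate redraws the perturbation and the prediction MC samples;
    rows report the mean and sd over replicates.  The AUC ranking score is
    the positive-class mean predictive probability.
    """
    test_graphs = [ds.graphs[i] for i in ds.split_indices("test")]
    if not test_graphs:
        raise ValueError("empty test split")
    labels = np.array([g.label for g in test_graphs])
    rows = []
    for f_idx, fraction in enumerate(fractions):
        accs, aucs, f1s = [], [], []
        for rep in range(replicates):
            rng = np.random.default_rng([seed, f_idx, rep])
            pos_probs = np.empty(len(test_graphs))
            for i, g in enumerate(test_graphs):
                g_noisy = _perturb(g, fraction, noise_sd, rng)
                mean, _ = predict(
                    g_noisy, state, spec, J=J, K=K,
                    noise_sd=predict_noise_sd, noisy_fraction=0.0, seed=rng,
                )
                pos_probs[i] = mean[1]
            acc, auc, f1 = _classification_metrics(labels, pos_probs)
            accs.append(acc)
            aucs.append(auc)
            f1s.append(f1)
        rows.append(
            MetricsRow(
                noise_fraction=float(fraction),
                accuracy=float(np.mean(accs)),
                auc=float(np.mean(aucs)),
                f1=float(np.mean(f1s)),
                accuracy_sd=float(np.std(accs)),
                auc_sd=float(np.std(aucs)),
                f1_sd=float(np.std(f1s)),
            )
        )
    return rows


def ablation_experiment(
    ds: Dataset,
    spec: GNNSpec,
    cfg: TrainConfig,
    fractions: Sequence[float] = (0.0, 0.05, 0.10),
    noise_sd: float = 0.5,
    replicates: int = 3,
    variants: Sequence[str] = ("full", "no_transform", "point"),
) -> dict[str, list[MetricsRow]]:
    """Train each variant and emit the same robustness-table schema.

    ``no_transform`` drops the reversible transforms during training;
    ``point`` replaces the decoder by directly optimized point weights.  The
    comparison is reported, not asserted.
    """
    out: dict[str, list[MetricsRow]] = {}
    for variant in variants:
        result = train(ds, spec, cfg, variant=variant)  # type: ignore[arg-type]
        out[variant] = noise_robustness_experiment(
            ds, result.state, spec, fractions=fractions, noise_sd=noise_sd,
            replicates=replicates, seed=cfg.seed,
        )
    return out
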