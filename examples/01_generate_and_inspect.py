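"""Generate the planted-motif benchmark and inspect its ground truth.

Label-1 graphs contain a small clique whose member nodes carry a feature
shift; the clique is the known-correct explanation every detection
experiment scores against.
"""

import numpy as np

import graphuq as gq

cfg = gq.SyntheticConfig(n_graphs=100, seed=0)
ds = gq.generate_motif_dataset(cfg)
gq.split_dataset(ds, mode="random", ratio=(0.8, 0.1, 0.1), seed=0)

labels = ds.labels()
positives = [g for g in ds.graphs if g.label == 1]
print(f"{len(ds)} graphs, feature dim {ds.feature_dim}")
print(f"class balance: {labels.mean():.2f} positive")
print(f"split sizes: " + ", ".join(
    f"{s}={len(ds.split_indices(s))}" for s in ("train", "valid", "test")))
g = positives[0]
print(f"one positive graph: {g.node_count} nodes, {g.edge_count} edges, "
      f"motif nodes at {np.nonzero(g.node_truth)[0].tolist()}")
# The motif nodes form a clique and are shifted on feature channel 0:
print(f"mean channel-0 feature, motif vs background: "
      f"{g.features[g.node_truth == 1, 0].mean():.2f} vs "
      f"{g.features[g.node_truth == 0, 0].mean():.2f}")
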