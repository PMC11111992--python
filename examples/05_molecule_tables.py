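"""Read a MoleculeNet-style CSV and split it by Bemis-Murcko scaffold.

Scaffold splitting keeps molecules sharing a core ring system in the same
split, so the test set probes generalization to unseen chemotypes.  The tiny
table below is written inline; real tables (e.g. blood-brain-barrier
penetration data with columns smiles,p_np) are read the same way with
preset="bbbp".
"""

import tempfile
from pathlib import Path

import graphuq as gq

csv = """smiles,p_np
c1ccccc1CCN,1
c1ccccc1CCO,1
c1ccncc1CC,0
c1ccncc1CCC,0
CCCCCC,0
CCCCCCO,1
"""
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "mols.csv"
    path.write_text(csv)
    ds = gq.read_molecule_table(path, preset="bbbp")

print(f"read {len(ds)} molecules ({ds.skipped_rows} rows skipped), "
      f"feature dim {ds.feature_dim}")
keys = gq.murcko_scaffold_keys(ds)
print("scaffold keys:", keys)
gq.split_dataset(ds, mode="by_key", ratio=(1 / 3, 1 / 3, 1 / 3), seed=0,
                 scaffold_keys=keys)
for s in ("train", "valid", "test"):
    members = ds.split_indices(s)
    print(f"  {s}: molecules {members} "
          f"(scaffolds {sorted({keys[i] for i in members})})")
print("molecules sharing a scaffold never straddle two splits")
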