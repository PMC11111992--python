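"""SMILES → attributed-graph conversion for MoleculeNet-style CSV tables.

Molecules are read as hydrogen-suppressed heavy-atom graphs: atoms become
nodes, bonds become undirected edges.  The default node encoding concatenates
a one-hot element indicator over a configurable vocabulary (with an "other"
bucket), a one-hot heavy-atom degree (capped), and the formal charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import AttributedGraph, Dataset

__all__ = [
    "AtomFeaturizer",
    "TABLE_PRESETS",
    "read_molecule_table",
    "murcko_scaffold_keys",
]

# Column-name dialects of the MoleculeNet CSV releases this package reads.
TABLE_PRESETS: dict[str, dict[str, str]] = {
    "bbbp": {"smiles_column": "smiles", "label_column": "p_np"},
    "bace": {"smiles_column": "mol", "label_column": "Class"},
    "tox21": {"smiles_column": "smiles", "label_column": "NR-ER"},
}

DEFAULT_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
MAX_DEGREE = 5


@dataclass
class AtomFeaturizer:
    """Atom → feature-vector encoding; swappable via ``read_molecule_table``."""

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    max_degree: int = MAX_DEGREE
    include_formal_charge: bool = True

    @property
    def dim(self) -> int:
        d = len(self.elements) + 1 + (self.max_degree + 1)
        return d + 1 if self.include_formal_charge else d

    def __call__(self, atom) -> np.ndarray:
        vec = np.zeros(self.dim)
        symbol = atom.GetSymbol()
        idx = self.elements.index(symbol) if symbol in self.elements else len(self.elements)
        vec[idx] = 1.0
        degree = min(atom.GetDegree(), self.max_degree)
        vec[len(self.elements) + 1 + degree] = 1.0
        if self.include_formal_charge:
            vec[-1] = float(atom.GetFormalCharge())
        return vec


def _mol_to_graph(mol, featurizer: AtomFeaturizer, label: int | None) -> AttributedGraph:
    n = mol.GetNumAtoms()
    features = np.stack([featurizer(mol.GetAtomWithIdx(i)) for i in range(n)])
    adjacency = np.zeros((n, n), dtype=np.int8)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1
    return AttributedGraph(features=features, adjacency=adjacency, label=label)


def read_molecule_table(
    path,
    smiles_column: str | None = None,
    label_column: str | None = None,
    featurizer: AtomFeaturizer | None = None,
    preset: str | None = None,
) -> Dataset:
    """Read a delimited molecule table into a :class:`Dataset`.

    Either pass explicit column names or a ``preset`` from
    :data:`TABLE_PRESETS`.  Rows whose SMILES fail to parse (or that have at
    least one atom missing) are skipped and counted in ``Dataset.skipped_rows``.
    SMILES strings are kept in ``metadata["smiles"]`` so scaffold keys can be
    derived later.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")

    if preset is not None:
        cols = TABLE_PRESETS[preset]
        smiles_column = smiles_column or cols["smiles_column"]
        label_column = label_column or cols["label_column"]
    if smiles_column is None or label_column is None:
        raise ValueError("smiles_column and label_column (or a preset) are required")

    table = pd.read_csv(path)
    for col in (smiles_column, label_column):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table (has {list(table.columns)})")

    featurizer = featurizer or AtomFeaturizer()
    graphs: list[AttributedGraph] = []
    smiles_kept: list[str] = []
    skipped = 0
    for smiles, label in zip(table[smiles_column], table[label_column]):
        mol = Chem.MolFromSmiles(str(smiles))
        if mol is None or mol.GetNumAtoms() == 0 or pd.isna(label):
            skipped += 1
            continue
        graphs.append(_mol_to_graph(mol, featurizer, int(label)))
        smiles_kept.append(str(smiles))
    if not graphs:
        raise ValueError(f"no parseable rows in {path}")
    labels = {g.label for g in graphs}
    ds = Dataset(
        graphs,
        class_count=max(2, max(labels) + 1),
        skipped_rows=skipped,
        metadata={"smiles": smiles_kept, "source": str(path)},
    )
    return ds


def murcko_scaffold_keys(dataset: Dataset) -> list[str]:
    """Bemis–Murcko scaffold SMILES for each graph, from stored SMILES."""
    from rdkit.Chem.Scaffolds.MurckoScaffold import MurckoScaffoldSmiles

    smiles = dataset.metadata.get("smiles")
    if smiles is None or len(smiles) != len(dataset):
        raise ValueError("dataset carries no SMILES; scaffold keys unavailable")
    return [MurckoScaffoldSmiles(smiles=s, includeChirality=False) for s in smiles]
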