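"""Train/valid/test splitting: seeded random, scaffold-grouped, or by key.

Default ratio is 8:1:1.  Grouped modes (``scaffold``, ``by_key``) never place
two graphs sharing a key in different splits; groups are assigned greedily,
largest first, to the split with the largest remaining deficit relative to
the target sizes, which minimizes the deviation from the target ratio for
desk-scale group structures.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .graphs import Dataset, Split

__all__ = ["split_dataset", "split_sizes"]

SplitMode = Literal["random", "scaffold", "by_key"]
SPLITS: tuple[Split, ...] = ("train", "valid", "test")


def split_sizes(n: int, ratio: Sequence[float]) -> tuple[int, int, int]:
    """Integer split sizes; remainders go to train, then valid."""
    ratio = np.asarray(ratio, dtype=float)
    if ratio.min() < 0 or ratio.sum() <= 0:
        raise ValueError("ratio entries must be nonnegative with positive sum")
    ratio = ratio / ratio.sum()
    base = np.floor(n * ratio).astype(int)
    # three floors leave at most two leftovers: train gets the first, valid the second
    for i in range(int(n - base.sum())):
        base[i] += 1
    return int(base[0]), int(base[1]), int(base[2])


def split_dataset(
    ds: Dataset,
    mode: SplitMode = "random",
    ratio: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    scaffold_keys: Sequence[str] | None = None,
) -> Dataset:
    """Assign every graph to exactly one of train/valid/test.

    ``scaffold`` derives Bemis–Murcko keys from the dataset's stored SMILES;
    ``by_key`` takes ``scaffold_keys`` directly (so grouped splitting is
    testable without a chemistry backend).
    """
    n = len(ds)
    targets = split_sizes(n, ratio)
    rng = np.random.default_rng(seed)

    if mode == "random":
        order = rng.permutation(n)
        assignment: dict[int, Split] = {}
        bounds = np.cumsum(targets)
        for pos, idx in enumerate(order):
            which = SPLITS[int(np.searchsorted(bounds, pos, side="right"))]
            assignment[int(idx)] = which
    elif mode in ("scaffold", "by_key"):
        if mode == "scaffold":
            from .molecules import murcko_scaffold_keys

            keys = murcko_scaffold_keys(ds)
        else:
            if scaffold_keys is None:
                raise ValueError("by_key mode requires scaffold_keys")
            keys = list(scaffold_keys)
        if len(keys) != n:
            raise ValueError("one key per graph required")
        groups: dict[str, list[int]] = {}
        for idx, key in enumerate(keys):
            groups.setdefault(key, []).append(idx)
        # deterministic: seeded shuffle of group order, then largest-first
        group_items = list(groups.items())
        rng.shuffle(group_items)
        group_items.sort(key=lambda kv: -len(kv[1]))
        deficits = np.asarray(targets, dtype=float)
        assignment = {}
        for _, members in group_items:
            which = SPLITS[int(np.argmax(deficits))]
            for idx in members:
                assignment[idx] = which
            deficits[SPLITS.index(which)] -= len(members)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    ds.split_assignment = assignment
    return ds
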