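"""Attacin-family alignment trimming and distance-based tree building.

Trees are neighbor-joining on p-distances with midpoint rooting -- a
reproducible, model-free stand-in for maximum-likelihood inference; topology
statements derived from it are treated qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .protein_metrics import drop_gap_columns


@dataclass
class TrimSpec:
    """Concatenation rule: N-terminal block + family-domain block.

    ``signal_block_len`` alignment columns from the start (defaults to 22:
    a 20-residue signal peptide plus two extra residues) are joined with the
    1-based inclusive ``domain_block`` column span of the C-terminal domain.
    """

    signal_block_len: int = 22
    domain_block: Tuple[int, int] = (0, 0)


def trim_attacin_alignment(alignment: Dict[str, str], spec: TrimSpec) -> Dict[str, str]:
    """Join the N-terminal and domain blocks of an aligned protein set."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    L = lengths.pop()
    ds, de = spec.domain_block
    if not (1 <= spec.signal_block_len <= L and 1 <= ds <= de <= L):
        raise ValueError(f"trim blocks outside alignment of {L} columns")
    return {
        name: seq[: spec.signal_block_len] + seq[ds - 1 : de]
        for name, seq in alignment.items()
    }


def p_distance(alignment: Dict[str, str], complete_deletion: bool = True) -> pd.DataFrame:
    """Proportion of differing sites per pair over retained columns.

    With complete deletion, every gap-containing column is dropped first.
    """
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = [alignment[n] for n in names]
    if complete_deletion:
        seqs = drop_gap_columns(seqs)
    ncol = len(seqs[0])
    if ncol == 0:
        raise ValueError("no columns retained after complete deletion")
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j])) / ncol
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def nj_tree(distances: pd.DataFrame) -> TreeNode:
    """Standard neighbor-joining; negative branch lengths clipped to zero."""
    ids = list(distances.index)
    if len(ids) == 2:  # a single edge; split at its middle
        half = float(distances.iloc[0, 1]) / 2.0
        return TreeNode.read([f"({ids[0]}:{half},{ids[1]}:{half});"])
    dm = DistanceMatrix(distances.to_numpy(), ids=list(distances.index))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) == 2:  # a single edge: split it at its middle
        half = sum(t.length or 0.0 for t in tips) / 2.0
        return TreeNode.read([f"({tips[0].name}:{half},{tips[1].name}:{half});"])
    return tree.root_at_midpoint()


def total_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse() if not n.is_root())


def _splits(tree: TreeNode, all_tips: frozenset) -> set:
    """Non-trivial bipartitions as frozensets of the smaller/canonical side."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


def bootstrap_support(
    alignment: Dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
    complete_deletion: bool = True,
    mask_below: float = 0.5,
) -> Tuple[TreeNode, Dict[frozenset, float]]:
    """Column-resampled NJ bootstrap.

    Returns the reference (full-alignment) NJ tree with per-internal-node
    ``support`` attributes, plus the split -> support map.  Supports below
    ``mask_below`` are masked to None on the tree (hidden on output), but
    kept in the map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names = list(alignment)
    seqs = [alignment[n] for n in names]
    if complete_deletion:
        seqs = drop_gap_columns(seqs)
    ncol = len(seqs[0])
    ref = nj_tree(p_distance(dict(zip(names, seqs)), complete_deletion=False))
    all_tips = frozenset(names)
    counts: Dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(ncol, size=ncol)
        rep = {n: "".join(s[c] for c in cols) for n, s in zip(names, seqs)}
        for split in _splits(nj_tree(p_distance(rep, complete_deletion=False)), all_tips):
            counts[split] = counts.get(split, 0) + 1
    support = {s: c / n_reps for s, c in counts.items()}
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=lambda s: (len(s), tuple(sorted(s))))
        val = support.get(key, 0.0)
        node.support = val if val >= mask_below else None
    return ref, support
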