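"""Fitch small parsimony: minimum substitution counts per column and per pair.

Branch lengths are ignored.  A leaf with a gap or ambiguity carries the full
state set, so gaps never force substitutions.  Multifurcations are resolved
into binary nodes with zero-length edges beforehand (this does not change the
parsimony count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TreeError
from .msa_io import ALPHABET, Alignment
from .phylo import PhyloTree

FULL_MASK = 0b1111  # {A, C, G, U}

_MASK_OF = {r: 1 << k for k, r in enumerate(ALPHABET)}


def _state_mask(state: str) -> int:
    """Bitmask of allowed states for a leaf residue; gaps/ambiguity -> full set."""
    return _MASK_OF.get(state.upper(), FULL_MASK)


@dataclass
class SubstitutionCounts:
    """Per-column Fitch counts s_i; per-pair counts default to s_i + s_j."""

    per_column: np.ndarray
    _per_pair: dict[tuple[int, int], int] = field(default_factory=dict)

    def pair_count(self, i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key in self._per_pair:
            return self._per_pair[key]
        return int(self.per_column[key[0]] + self.per_column[key[1]])

    def set_pair_count(self, i: int, j: int, s: int) -> None:
        self._per_pair[(i, j) if i < j else (j, i)] = s


def _check_leaves(tree: PhyloTree, names) -> None:
    tree_names = set(tree.leaf_names())
    if set(names) != tree_names:
        missing = set(names) - tree_names
        extra = tree_names - set(names)
        raise TreeError(
            f"tree/alignment leaf mismatch (missing from tree: {sorted(missing)}, "
            f"extra in tree: {sorted(extra)})"
        )


def _fitch_masks(tree: PhyloTree, leaf_masks: dict[str, int]) -> int:
    """Fitch pass over a binary tree given per-leaf state bitmasks."""
    count = 0
    masks: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            masks[id(node)] = leaf_masks[node.name]
        else:
            acc = None
            for child in node.children:
                cm = masks[id(child)]
                if acc is None:
                    acc = cm
                else:
                    inter = acc & cm
                    if inter:
                        acc = inter
                    else:
                        acc = acc | cm
                        count += 1
            masks[id(node)] = acc
    return count


def fitch_column(tree: PhyloTree, column: dict[str, str]) -> int:
    """Minimum number of substitutions for one column of leaf states.

    ``column`` maps leaf name -> residue character (gap/ambiguity allowed).
    """
    _check_leaves(tree, column.keys())
    btree = tree.binarized()
    leaf_masks = {name: _state_mask(state) for name, state in column.items()}
    return _fitch_masks(btree, leaf_masks)


def fitch_counts_coded(tree: PhyloTree, codes: np.ndarray, names: list[str]) -> np.ndarray:
    """Vectorised per-column Fitch counts from a coded residue matrix.

    ``codes`` is (n_seqs, L) with values 0..3 for A/C/G/U and >= 4 for
    gap/ambiguity (full state set).  ``names[r]`` labels row r.
    """
    btree = tree.binarized()
    row_of = {name: r for r, name in enumerate(names)}
    masks_matrix = np.where(codes >= 4, FULL_MASK,
                            np.left_shift(1, codes.clip(0, 3).astype(np.intp)))
    counts = np.zeros(codes.shape[1], dtype=float)
    node_masks: dict[int, np.ndarray] = {}
    for node in btree.postorder():
        if node.is_leaf:
            node_masks[id(node)] = masks_matrix[row_of[node.name]]
        else:
            acc = node_masks[id(node.children[0])]
            for child in node.children[1:]:
                cm = node_masks[id(child)]
                inter = acc & cm
                need_union = inter == 0
                acc = np.where(need_union, acc | cm, inter)
                counts += need_union
            node_masks[id(node)] = acc
    return counts.astype(int)


def substitutions(aln: Alignment, tree: PhyloTree) -> SubstitutionCounts:
    """Fitch counts for every column; pair counts are s_ij = s_i + s_j."""
    _check_leaves(tree, aln.names)
    per_column = fitch_counts_coded(tree, aln.codes(), list(aln.names))
    return SubstitutionCounts(per_column=per_column)


def joint_pair_substitutions(
    tree: PhyloTree, col_i: dict[str, str], col_j: dict[str, str]
) -> int:
    """Fitch on the 16-state product alphabet for a column pair (optional,
    more expensive alternative to s_i + s_j)."""
    _check_leaves(tree, col_i.keys())
    _check_leaves(tree, col_j.keys())
    btree = tree.binarized()
    leaf_masks: dict[str, int] = {}
    for name in col_i:
        mi = _state_mask(col_i[name])
        mj = _state_mask(col_j[name])
        mask = 0
        for a in range(4):
            if not mi >> a & 1:
                continue
            for b in range(4):
                if mj >> b & 1:
                    mask |= 1 << (4 * a + b)
        leaf_masks[name] = mask
    return _fitch_masks(btree, leaf_masks)
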