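"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: minimum substitution
counts are found by exhaustive enumeration over all labelings of internal
nodes (and of leaves whose state is unconstrained, i.e. gaps).
"""

import itertools

import numpy as np


def brute_force_min_changes(tree, leaf_states, alphabet_size=4):
    """Exhaustive minimum number of state changes on a tree.

    ``leaf_states`` maps leaf name -> state index, or None for an
    unconstrained (gap) leaf.  Vectorised over all 4^k (or 16^k) labelings.
    """
    btree = tree.binarized()
    nodes = list(btree.preorder())
    free_index = {}
    fixed = {}
    for node in nodes:
        if node.is_leaf:
            st = leaf_states[node.name]
            if st is None:
                free_index[id(node)] = len(free_index)
            else:
                fixed[id(node)] = st
        else:
            free_index[id(node)] = len(free_index)
    k = len(free_index)
    combos = np.array(
        list(itertools.product(range(alphabet_size), repeat=k)), dtype=np.int16
    )
    changes = np.zeros(len(combos), dtype=np.int32)
    for parent in nodes:
        for child in parent.children:
            pid, cid = id(parent), id(child)
            if pid in free_index and cid in free_index:
                changes += combos[:, free_index[pid]] != combos[:, free_index[cid]]
            elif pid in free_index:
                changes += combos[:, free_index[pid]] != fixed[cid]
            elif cid in free_index:
                changes += combos[:, free_index[cid]] != fixed[pid]
            else:
                changes += int(fixed[pid] != fixed[cid])
    return int(changes.min())
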