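"""Phylogenetic trees: Newick I/O, neighbor-joining, rescaling, subsampling.

The built-in tree route is neighbor-joining on Jukes–Cantor-corrected
pairwise-identity distances; an externally inferred tree may be supplied as
Newick instead.  Trees are rooted (midpoint by default for NJ trees) so that
downstream parsimony and simulation have a defined root.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError
from .msa_io import CODE_GAP, CODE_MISSING, Alignment


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # length of the edge above this node
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with branch lengths and named leaves."""

    def __init__(self, root: Node):
        self.root = root
        names = [n.name for n in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise TreeError("every leaf must carry a name")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        for node in self.preorder():
            if not (node.length >= 0.0 and math.isfinite(node.length)):
                raise TreeError(f"invalid branch length {node.length!r}")

    # -- traversal ---------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder()) - self.root.length

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            return Node(node.name, node.length, [rec(c) for c in node.children])

        return PhyloTree(rec(self.root))

    def binarized(self) -> "PhyloTree":
        """Resolve multifurcations into binary nodes with zero-length edges."""

        def rec(node: Node) -> Node:
            kids = [rec(c) for c in node.children]
            while len(kids) > 2:
                merged = Node(None, 0.0, [kids[0], kids[1]])
                kids = [merged] + kids[2:]
            return Node(node.name, node.length, kids)

        return PhyloTree(rec(self.root))

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted name pairs."""
        dists: dict[tuple[str, str], float] = {}

        def rec(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child in node.children:
                d = {k: v + child.length for k, v in rec(child).items()}
                below.append(d)
            for a, b in itertools.combinations(range(len(below)), 2):
                for x, dx in below[a].items():
                    for y, dy in below[b].items():
                        key = (x, y) if x < y else (y, x)
                        dists[key] = dx + dy
            merged: dict[str, float] = {}
            for d in below:
                merged.update(d)
            return merged

        rec(self.root)
        return dists

    def to_newick(self) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                label = _quote_label(node.name)
            else:
                label = "(" + ",".join(rec(c) for c in node.children) + ")"
            return f"{label}:{node.length:.10g}"

        inner = "(" + ",".join(rec(c) for c in self.root.children) + ")" \
            if not self.root.is_leaf else _quote_label(self.root.name)
        return inner + ";"


def _quote_label(name: str) -> str:
    if any(c in name for c in " ()[]{}:;,'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# Newick I/O via dendropy
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def rec(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        kids = [rec(c) for c in dnode.child_nodes()]
        return Node(name if not kids else None, float(length), kids)

    root = rec(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root)


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    return dendropy.Tree.get(data=tree.to_newick(), schema="newick")


def read_newick(path: str) -> PhyloTree:
    """Parse a Newick file.  Missing branch lengths default to 0; an unrooted
    trifurcating root is accepted as-is (rooted at the trifurcation)."""
    try:
        dtree = dendropy.Tree.get(
            path=path, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise TreeError(f"{path}: Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def parse_newick(text: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise TreeError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Reroot at the midpoint of the longest leaf-to-leaf path.

    Degenerate trees (zero total length) are returned unchanged: they have
    no defined midpoint and dendropy mishandles them.
    """
    if tree.total_length() <= 0:
        return tree
    dtree = _to_dendropy(tree)
    dtree.reroot_at_midpoint(update_bipartitions=False)
    out = _from_dendropy(dtree)
    if set(out.leaf_names()) != set(tree.leaf_names()):
        return tree
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def pairwise_identity_matrix(aln: Alignment) -> np.ndarray:
    """Fraction of matching residues over mutually ungapped columns, per pair.

    A pair with no mutually ungapped column gets identity 0 (with a warning).
    """
    if aln.n_seqs < 2:
        raise TreeError("need at least 2 sequences")
    codes = aln.codes()
    ok = (codes != CODE_GAP) & (codes != CODE_MISSING)
    n = aln.n_seqs
    ident = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            both = ok[a] & ok[b]
            m = int(both.sum())
            if m == 0:
                warnings.warn(
                    f"sequences {aln.names[a]!r} and {aln.names[b]!r} share no "
                    "ungapped columns; identity set to 0"
                )
                val = 0.0
            else:
                val = float((codes[a][both] == codes[b][both]).sum()) / m
            ident[a, b] = ident[b, a] = val
    return ident


def average_identity(aln: Alignment) -> float:
    """Mean pairwise identity over all off-diagonal pairs."""
    ident = pairwise_identity_matrix(aln)
    n = ident.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(ident[iu].mean())


def distance_from_identity(ident: np.ndarray, max_distance: float = 10.0) -> np.ndarray:
    """Jukes–Cantor-corrected distances from an identity matrix.

    d = -(3/4) ln(1 - (4/3) p) with p = 1 - identity, capped at
    ``max_distance`` when the correction saturates.
    """
    p = 1.0 - np.asarray(ident, dtype=float)
    arg = 1.0 - (4.0 / 3.0) * p
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.inf)
    d = np.minimum(d, max_distance)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Neighbor-joining (Saitou–Nei), deterministic tie-breaking
# ---------------------------------------------------------------------------


def nj_tree(dist: np.ndarray, names: list[str] | None = None) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch-length estimates are clamped to 0.  Ties in the Q
    criterion are broken by the smallest (row, column) index pair.  The
    returned tree is rooted at the final join (trifurcation for n >= 3).
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise TreeError("distance matrix must be square")
    if n < 2:
        raise TreeError("need at least 2 taxa")
    if not np.allclose(d, d.T):
        raise TreeError("distance matrix must be symmetric")
    if (d < 0).any():
        raise TreeError("distance matrix must be nonnegative")
    if names is None:
        names = [f"t{i}" for i in range(n)]
    if len(names) != n:
        raise TreeError("names length must match matrix size")

    nodes: list[Node] = [Node(name=nm) for nm in names]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic arg-min: smallest (row, col) among minima
        flat = np.argmin(q)
        a, b = divmod(int(flat), m)
        if a > b:
            a, b = b, a
        dij = sub[a, b]
        va = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        vb = dij - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        ia, ib = active[a], active[b]
        nodes[ia].length = va
        nodes[ib].length = vb
        parent = Node(children=[nodes[ia], nodes[ib]])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[ia, active] + d[ib, active] - dij)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        active = [x for x in active if x not in (ia, ib)] + [k]

    ia, ib = active
    dij = d[ia, ib]
    na, nb = nodes[ia], nodes[ib]
    if not (na.is_leaf and nb.is_leaf):
        # hang the remaining node off the internal one -> trifurcating root
        host, guest = (na, nb) if not na.is_leaf else (nb, na)
        guest.length = max(dij, 0.0)
        host.children.append(guest)
        host.length = 0.0
        return PhyloTree(host)
    na.length = max(0.5 * dij, 0.0)  # n == 2
    nb.length = max(0.5 * dij, 0.0)
    return PhyloTree(Node(children=[na, nb]))


def tree_from_alignment(aln: Alignment, max_distance: float = 10.0) -> PhyloTree:
    """NJ tree on JC-corrected identity distances, midpoint-rooted."""
    ident = pairwise_identity_matrix(aln)
    dist = distance_from_identity(ident, max_distance=max_distance)
    tree = nj_tree(dist, names=list(aln.names))
    if tree.n_leaves >= 3:
        tree = midpoint_root(tree)
    return tree.binarized()


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------


def rescale_branches(tree: PhyloTree, factor: float) -> PhyloTree:
    if not factor > 0:
        raise TreeError(f"scale factor must be positive, got {factor}")
    out = tree.copy()
    for node in out.preorder():
        node.length *= factor
    out.root.length = 0.0
    return out


def subsample_taxa(tree: PhyloTree, n: int, seed: int) -> PhyloTree:
    """Keep a uniformly sampled subset of n leaves; suppress unary nodes,
    summing their branch lengths (patristic distances are preserved)."""
    leaves = sorted(tree.leaf_names())
    if not 2 <= n <= len(leaves):
        raise TreeError(f"n must be in [2, {len(leaves)}], got {n}")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(leaves, size=n, replace=False).tolist())
    return restrict_to_taxa(tree, keep)


def restrict_to_taxa(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    missing = keep - set(tree.leaf_names())
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                return Node(node.name, node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += node.length
            return kids[0]
        return Node(node.name, node.length, kids)

    root = rec(tree.root)
    if root is None or root.is_leaf:
        raise TreeError("subsampled tree has fewer than 2 leaves")
    root.length = 0.0
    return PhyloTree(root)
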