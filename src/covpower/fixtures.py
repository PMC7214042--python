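"""Seed-deterministic synthetic fixtures for tests and demonstrations."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .errors import SimulationError
from .evolver import default_model, evolve_down_tree
from .msa_io import ALPHABET, Alignment, SecondaryStructure, wuss_from_pairs
from .phylo import Node, PhyloTree


def random_tree(n_leaves: int, seed: int, mean_branch: float = 0.1) -> PhyloTree:
    """Random rooted binary tree with exponential branch lengths and leaves
    named seq1..seqN."""
    if n_leaves < 2:
        raise SimulationError("need >= 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [Node(name=f"seq{k + 1}", length=float(rng.exponential(mean_branch)))
             for k in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(length=float(rng.exponential(mean_branch)),
                      children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])


def hairpin_structure(L: int, n_pairs: int, n_helices: int = 2) -> SecondaryStructure:
    """n_helices nested hairpins tiled across L columns."""
    pairs: list[tuple[int, int]] = []
    per = max(n_pairs // n_helices, 1)
    span = L // n_helices
    for h in range(n_helices):
        base = h * span
        width = span
        k = 0
        while k < per and len(pairs) < n_pairs and base + k < base + width - 1 - k - 3:
            pairs.append((base + k, base + width - 1 - k))
            k += 1
    return SecondaryStructure(pairs=pairs)


def random_root(L: int, structure: SecondaryStructure, seed: int) -> str:
    """Random root sequence whose paired positions hold canonical basepairs."""
    rng = np.random.default_rng(seed)
    chars = [ALPHABET[int(rng.integers(4))] for _ in range(L)]
    canonical = ["AU", "UA", "GC", "CG", "GU", "UG"]
    for i, j in structure.pairs:
        st = canonical[int(rng.integers(len(canonical)))]
        chars[i], chars[j] = st
    return "".join(chars)


def structural_template(
    seed: int,
    L: int = 60,
    n_pairs: int = 15,
    n_seqs: int = 25,
    mean_branch: float = 0.25,
    with_indels: bool = False,
) -> Alignment:
    """A diverse structural alignment evolved under basepair constraints."""
    rng = np.random.default_rng(seed)
    structure = hairpin_structure(L, n_pairs)
    root = random_root(L, structure, int(rng.integers(2**31)))
    tree = random_tree(n_seqs, int(rng.integers(2**31)), mean_branch=mean_branch)
    model = default_model()
    if not with_indels:
        model = replace(model, insertion_rate=0.0, deletion_rate=0.0)
    return evolve_down_tree(root, tree, model, structure, seed=int(rng.integers(2**31)))


def negative_control(
    seed: int, L: int = 60, n_seqs: int = 25, mean_branch: float = 0.25
) -> Alignment:
    """Same evolutionary depth but no pairing constraint and no SS_cons."""
    aln = structural_template(seed, L=L, n_pairs=0, n_seqs=n_seqs,
                              mean_branch=mean_branch)
    return Alignment(names=aln.names, rows=aln.rows, ss_cons=None)


def fitch_fixture() -> tuple[Alignment, str]:
    """Hand-sized alignment plus matching Newick tree for parsimony checks.

    Expected Fitch counts per column (worked by hand):
    col 0: all A -> 0; col 1: A,A,G,G on ((a,b),(c,d)) -> 1;
    col 2: A,C,G,U -> 3; col 3: gaps are free -> 0;
    col 4: A,G,A,G -> 2.
    """
    newick = "((a:0.1,b:0.1):0.05,(c:0.2,d:0.2):0.05);"
    aln = Alignment(
        names=["a", "b", "c", "d"],
        rows=["AAAGA", "AAC-G", "AGG-A", "AGUGG"],
    )
    return aln, newick


def invariant_alignment(n_seqs: int = 10, L: int = 40) -> Alignment:
    """All rows identical: no variation, zero substitutions everywhere."""
    row = ("ACGU" * ((L + 3) // 4))[:L]
    n_pairs = min(5, L // 4)
    pairs = [(k, L - 1 - k) for k in range(n_pairs)]
    return Alignment(
        names=[f"seq{k + 1}" for k in range(n_seqs)],
        rows=[row] * n_seqs,
        ss_cons=wuss_from_pairs(SecondaryStructure(pairs=pairs), L),
    )
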