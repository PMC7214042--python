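"""Evolutionary alignment simulator with basepair-aware substitution.

A root sequence is evolved down a rooted tree: unpaired columns under a
4-state reversible substitution process, paired columns jointly as 16-state
units under a pair process whose stationary distribution concentrates on
canonical basepairs, plus Poisson insertion/deletion events with geometric
lengths restricted to unpaired regions (so the annotated structure stays
valid throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import SimulationError
from .msa_io import (
    ALPHABET,
    GAP,
    Alignment,
    SecondaryStructure,
    normalize_residue,
    wuss_from_pairs,
)
from .phylo import (
    PhyloTree,
    average_identity,
    rescale_branches,
    subsample_taxa,
    tree_from_alignment,
)

PAIR_STATES = [a + b for a in ALPHABET for b in ALPHABET]
_CANONICAL = {"AU": 0.22, "UA": 0.22, "GC": 0.22, "CG": 0.22, "GU": 0.05, "UG": 0.05}


@dataclass(frozen=True)
class EvolModel:
    single_rates: np.ndarray  # 4x4, rows sum to 0
    pi: np.ndarray  # stationary composition, 4-vector
    pair_rates: np.ndarray  # 16x16 over ordered pair states
    pair_pi: np.ndarray  # stationary pair composition, 16-vector
    insertion_rate: float = 0.02
    deletion_rate: float = 0.02
    p_len: float = 0.6  # geometric length parameter (success prob of extension)

    def __post_init__(self) -> None:
        for q in (self.single_rates, self.pair_rates):
            if np.abs(q.sum(axis=1)).max() > 1e-9:
                raise SimulationError("rate matrix rows must sum to 0")
            off = q - np.diag(np.diag(q))
            if (off < -1e-12).any():
                raise SimulationError("off-diagonal rates must be nonnegative")
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise SimulationError("indel rates must be nonnegative")
        if not 0 < self.p_len < 1:
            raise SimulationError("p_len must be in (0, 1)")


def _f81_rates(pi: np.ndarray, n_sites: float) -> np.ndarray:
    """F81-style rate matrix with stationary pi, normalised so the expected
    number of state changes per unit branch length equals n_sites."""
    k = pi.size
    q = np.tile(pi, (k, 1))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float((pi * np.diag(q)).sum())
    if rate > 0:
        q = q * (n_sites / rate)
    return q


def default_model(template: Alignment | None = None) -> EvolModel:
    """Reversible defaults: F81 singles with template composition (uniform if
    absent); 16-state pair process biased toward canonical basepairs."""
    if template is None:
        pi = np.full(4, 0.25)
    else:
        counts = np.ones(4)  # pseudocount keeps pi strictly positive
        for row in template.rows:
            for ch in row:
                r = normalize_residue(ch)
                if r in ALPHABET:
                    counts[ALPHABET.index(r)] += 1
        pi = counts / counts.sum()
    pair_pi = np.empty(16)
    noncanon = (1.0 - sum(_CANONICAL.values())) / (16 - len(_CANONICAL))
    for k, st in enumerate(PAIR_STATES):
        pair_pi[k] = _CANONICAL.get(st, noncanon)
    pair_pi = pair_pi / pair_pi.sum()
    return EvolModel(
        single_rates=_f81_rates(pi, 1.0),
        pi=pi,
        pair_rates=_f81_rates(pair_pi, 2.0),  # a pair unit spans two sites
        pair_pi=pair_pi,
    )


def transition_matrix(rates: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(t Q)."""
    if t < 0:
        raise SimulationError(f"branch length must be >= 0, got {t}")
    return expm(t * np.asarray(rates, dtype=float))


# ---------------------------------------------------------------------------
# Evolution down the tree
# ---------------------------------------------------------------------------


class _ColumnRegistry:
    """Global alignment-column bookkeeping shared across lineages.

    Ancestral columns are ids 0..L-1; insertions allocate fresh ids spliced
    into a global ordering.  Each lineage holds states only for the columns
    present in it; absent columns render as gaps.
    """

    def __init__(self, L: int):
        self.order: list[int] = list(range(L))
        self.next_id = L

    def insert_after(self, anchor: int | None, count: int) -> list[int]:
        new = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        pos = 0 if anchor is None else self.order.index(anchor) + 1
        self.order[pos:pos] = new
        return new


def evolve_down_tree(
    root: str,
    tree: PhyloTree,
    model: EvolModel,
    structure: SecondaryStructure | None,
    seed: int,
) -> Alignment:
    """Evolve a root sequence down a rooted tree; returns the aligned leaves.

    Paired columns are never deleted and insertions fall in unpaired
    regions, so the structure annotation remains valid; it is re-emitted as
    SS_cons at the columns' final positions.
    """
    L = len(root)
    root_states = [normalize_residue(ch) for ch in root]
    if any(s not in ALPHABET for s in root_states):
        raise SimulationError("root sequence must be gap-free A/C/G/U")
    structure = structure or SecondaryStructure(pairs=[])
    for i, j in structure.pairs:
        if j >= L:
            raise SimulationError(f"structure pair ({i}, {j}) outside root length {L}")
    rng = np.random.default_rng(seed)
    reg = _ColumnRegistry(L)
    paired_cols = structure.paired_columns()
    pair_of = {}
    for i, j in structure.pairs:
        pair_of[i] = (i, j)

    sidx = {r: k for k, r in enumerate(ALPHABET)}
    pidx = {st: k for k, st in enumerate(PAIR_STATES)}

    root_seq: dict[int, str] = {c: root_states[c] for c in range(L)}
    leaf_seqs: dict[str, dict[int, str]] = {}

    def branch_evolve(seq: dict[int, str], t: float) -> dict[int, str]:
        out = dict(seq)
        if t > 0:
            p_single = transition_matrix(model.single_rates, t)
            p_pair = transition_matrix(model.pair_rates, t)
            cum_single = np.cumsum(p_single, axis=1)
            cum_pair = np.cumsum(p_pair, axis=1)
            for i, j in structure.pairs:
                st = pidx[out[i] + out[j]]
                new = int(np.searchsorted(cum_pair[st], rng.random(), side="right"))
                new = min(new, 15)
                out[i], out[j] = PAIR_STATES[new]
            for c in list(out):
                if c in paired_cols:
                    continue
                st = sidx[out[c]]
                new = int(np.searchsorted(cum_single[st], rng.random(), side="right"))
                out[c] = ALPHABET[min(new, 3)]
        _apply_indels(out, t)
        return out

    def _apply_indels(seq: dict[int, str], t: float) -> None:
        if t <= 0:
            return
        present = [c for c in reg.order if c in seq]
        unpaired = [c for c in present if c not in paired_cols]
        n_del = rng.poisson(model.deletion_rate * t * len(unpaired))
        for _ in range(n_del):
            unpaired = [c for c in reg.order if c in seq and c not in paired_cols]
            if not unpaired:
                break
            start = int(rng.integers(len(unpaired)))
            length = int(rng.geometric(1.0 - model.p_len))
            for c in unpaired[start : start + max(length, 1)]:
                del seq[c]
        present = [c for c in reg.order if c in seq]
        n_ins = rng.poisson(model.insertion_rate * t * max(len(present), 1))
        for _ in range(n_ins):
            present = [c for c in reg.order if c in seq]
            candidates = [None] + [c for c in present if c not in paired_cols]
            anchor = candidates[int(rng.integers(len(candidates)))]
            length = max(1, int(rng.geometric(1.0 - model.p_len)))
            new_ids = reg.insert_after(anchor, length)
            cum_pi = np.cumsum(model.pi)
            for cid in new_ids:
                seq[cid] = ALPHABET[
                    min(int(np.searchsorted(cum_pi, rng.random(), side="right")), 3)
                ]

    def walk(node, seq: dict[int, str]) -> None:
        for child in node.children:
            child_seq = branch_evolve(seq, child.length)
            if child.is_leaf:
                leaf_seqs[child.name] = child_seq
            else:
                walk(child, child_seq)

    if tree.root.is_leaf:
        leaf_seqs[tree.root.name] = root_seq
    else:
        walk(tree.root, root_seq)

    names = tree.leaf_names()
    rows = [
        "".join(leaf_seqs[nm].get(c, GAP) for c in reg.order) for nm in names
    ]
    pos_of = {c: k for k, c in enumerate(reg.order)}
    final_pairs = [(pos_of[i], pos_of[j]) for i, j in structure.pairs]
    ss = wuss_from_pairs(SecondaryStructure(pairs=final_pairs), len(reg.order))
    return Alignment(names=names, rows=rows, ss_cons=ss)


# ---------------------------------------------------------------------------
# Identity-targeted simulation from a template alignment
# ---------------------------------------------------------------------------

SCALE_LO, SCALE_HI = 1e-3, 1e2


def _root_from_template(aln: Alignment, row: int, rng: np.random.Generator) -> str:
    """Template row with gaps/ambiguities filled from column composition."""
    codes = aln.codes()
    out = []
    for c in range(aln.L):
        ch = normalize_residue(aln.rows[row][c])
        if ch in ALPHABET:
            out.append(ch)
            continue
        col = codes[:, c]
        obs = col[col < 4]
        if obs.size:
            counts = np.bincount(obs, minlength=4).astype(float)
            pi = counts / counts.sum()
        else:
            pi = np.full(4, 0.25)
        out.append(ALPHABET[int(rng.choice(4, p=pi))])
    return "".join(out)


def simulate_alignment(
    template: Alignment,
    structure: SecondaryStructure | None,
    n_taxa: int,
    target_id: float,
    seed: int,
    model: EvolModel | None = None,
    tree: PhyloTree | None = None,
    tolerance: float = 0.02,
    max_iter: int = 30,
) -> tuple[Alignment, float, float]:
    """Simulate an alignment at a target average pairwise identity.

    Builds (or takes) a tree for the template, subsamples to ``n_taxa``,
    picks a random template sequence as root, and bisection-searches the
    branch-scale factor until the simulated average identity is within
    ``tolerance`` of ``target_id``.  Returns (alignment, achieved_identity,
    scale_factor).
    """
    if not 2 <= n_taxa <= template.n_seqs:
        raise SimulationError(
            f"n_taxa must be in [2, {template.n_seqs}], got {n_taxa}"
        )
    if not 0.25 < target_id < 1.0:
        raise SimulationError(f"target identity must be in (0.25, 1), got {target_id}")
    rng = np.random.default_rng(seed)
    if structure is None:
        structure = template.structure() or SecondaryStructure(pairs=[])
    if model is None:
        model = default_model(template)
    if tree is None:
        tree = tree_from_alignment(template)
    sub = subsample_taxa(tree, n_taxa, seed=int(rng.integers(2**31)))
    root_row = int(rng.integers(template.n_seqs))
    root = _root_from_template(template, root_row, rng)

    def trial(scale: float, trial_seed: int) -> tuple[Alignment, float]:
        scaled = rescale_branches(sub, scale)
        sim = evolve_down_tree(root, scaled, model, structure, seed=trial_seed)
        return sim, average_identity(sim)

    base_seed = int(rng.integers(2**31))
    lo, hi = SCALE_LO, SCALE_HI
    _, id_lo = trial(lo, base_seed)  # small scale -> high identity
    _, id_hi = trial(hi, base_seed + 1)
    if not (id_hi - tolerance <= target_id <= id_lo + tolerance):
        raise SimulationError(
            f"target identity {target_id:.2f} unreachable; achievable range "
            f"about [{id_hi:.2f}, {id_lo:.2f}]"
        )
    best: tuple[Alignment, float, float] | None = None
    for it in range(max_iter):
        mid = (lo * hi) ** 0.5  # geometric bisection on scale
        sim, ident = trial(mid, base_seed + 2 + it)
        if best is None or abs(ident - target_id) < abs(best[1] - target_id):
            best = (sim, ident, mid)
        if abs(ident - target_id) <= tolerance:
            return sim, ident, mid
        if ident > target_id:
            lo = mid  # too similar -> need longer branches
        else:
            hi = mid
    return best  # closest achieved within max_iter


def simulate_structural(
    template: Alignment,
    n_taxa: int,
    target_id: float,
    seed: int,
    **kwargs,
) -> tuple[Alignment, float, float]:
    """Convenience wrapper using the template's own SS_cons."""
    struct = template.structure()
    if struct is None:
        raise SimulationError("template has no SS_cons structure annotation")
    return simulate_alignment(template, struct, n_taxa, target_id, seed, **kwargs)
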