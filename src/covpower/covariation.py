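"""Pairwise covariation statistics with phylogeny-aware empirical E-values.

The default statistic is the G-test; mutual information (bits) is available
as an alternative.  Statistical significance is assessed against an
empirical null built from synthetic alignments that preserve the original
alignment's composition, per-column substitution counts and phylogeny while
destroying pairwise correlations (each column is evolved independently down
the tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CovpowerError, TreeError
from .msa_io import ALPHABET, Alignment, SecondaryStructure
from .parsimony import SubstitutionCounts, fitch_counts_coded, substitutions
from .phylo import PhyloTree

_LN2 = math.log(2.0)

#: minimum mutually ungapped rows for a pair to be testable
MIN_TESTABLE_ROWS = 3


@dataclass
class CovariationResult:
    pair: tuple[int, int]
    stat: float
    pvalue: float
    evalue: float
    significant: bool
    in_structure: bool
    substitutions: int
    testable: bool = True
    power: float | None = None


@dataclass
class NullDistribution:
    """Pooled null statistic values from simulated negative-control alignments."""

    samples: np.ndarray  # sorted ascending
    n_alignments: int
    n_tests: int

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise CovpowerError("null distribution has no samples")
        if self.n_tests < 1:
            raise CovpowerError("n_tests must be >= 1")

    def survival(self, scores: np.ndarray) -> np.ndarray:
        """Add-one-smoothed empirical fraction of null samples >= score."""
        scores = np.asarray(scores, dtype=float)
        n = self.samples.size
        k = n - np.searchsorted(self.samples, scores, side="left")
        return (1.0 + k) / (1.0 + n)


# ---------------------------------------------------------------------------
# Count tables and statistics
# ---------------------------------------------------------------------------


def joint_counts(aln: Alignment, i: int, j: int) -> tuple[np.ndarray, int]:
    """4x4 joint residue counts for columns i, j over rows where both columns
    hold an unambiguous residue.  Returns (table, N)."""
    if i == j:
        raise CovpowerError("cannot pair a column with itself")
    if not (0 <= i < aln.L and 0 <= j < aln.L):
        raise CovpowerError(f"column indices ({i}, {j}) out of range for L={aln.L}")
    codes = aln.codes()
    return _counts_from_codes(codes[:, i], codes[:, j])


def _counts_from_codes(ci: np.ndarray, cj: np.ndarray) -> tuple[np.ndarray, int]:
    valid = (ci < 4) & (cj < 4)
    idx = ci[valid].astype(np.intp) * 4 + cj[valid]
    table = np.bincount(idx, minlength=16).reshape(4, 4).astype(float)
    return table, int(valid.sum())


def mutual_information(counts: np.ndarray) -> float:
    """MI in bits: sum p_xy log2(p_xy / (p_x p_y)), with 0 log 0 = 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def g_test(counts: np.ndarray) -> float:
    """G statistic 2 sum O ln(O/E), E from the independence model."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    # numerically exact identity with MI avoids separate E-table bookkeeping
    return 2.0 * n * _LN2 * mutual_information(counts)


def apc_correct(stat_matrix: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric pairwise score matrix."""
    m = np.asarray(stat_matrix, dtype=float)
    n = m.shape[0]
    if n < 2:
        return m.copy()
    off = ~np.eye(n, dtype=bool)
    mean_all = m[off].mean()
    if mean_all == 0:
        return m.copy()
    row_mean = m.sum(axis=1) / (n - 1)
    corr = m - np.outer(row_mean, row_mean) / mean_all
    corr[~off] = 0.0
    return corr


def _pair_list(L: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(L - 1) for j in range(i + 1, L)]


def _stat_fn(statistic: str):
    if statistic.upper() in ("G", "GT"):
        return g_test
    if statistic.upper() == "MI":
        return mutual_information
    raise CovpowerError(f"unknown statistic {statistic!r} (use 'GT' or 'MI')")


def pair_statistics(
    codes: np.ndarray,
    pairs: list[tuple[int, int]],
    statistic: str = "GT",
    apc: bool = False,
    L: int | None = None,
) -> np.ndarray:
    """Statistic for each listed column pair of a coded alignment.

    With ``apc=True`` the statistic is computed for all pairs, the
    average-product correction applied, and the corrected values returned
    for the requested pairs.
    """
    fn = _stat_fn(statistic)
    if not apc:
        out = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            table, n = _counts_from_codes(codes[:, i], codes[:, j])
            out[k] = fn(table) if n > 0 else 0.0
        return out
    L = codes.shape[1] if L is None else L
    mat = np.zeros((L, L))
    for i, j in _pair_list(L):
        table, n = _counts_from_codes(codes[:, i], codes[:, j])
        v = fn(table) if n > 0 else 0.0
        mat[i, j] = mat[j, i] = v
    corr = apc_correct(mat)
    return np.array([corr[i, j] for i, j in pairs])


# ---------------------------------------------------------------------------
# Null alignments
# ---------------------------------------------------------------------------


def null_alignments(
    aln: Alignment,
    tree: PhyloTree,
    subs: SubstitutionCounts,
    n: int,
    seed: int,
    calibrate: bool = True,
) -> list[Alignment]:
    """Simulate n negative-control alignments.

    Each column is evolved independently down the tree: the root state is
    drawn from the column's observed residue composition, and a number of
    substitution events close to the column's Fitch count s_i is placed on
    branches multinomially in proportion to branch length, each replacing
    the current residue with a different one drawn from the column
    composition.  Because parsimony collapses parallel and reverting
    changes, placing exactly s_i events yields simulated columns whose own
    Fitch counts fall short of s_i; a short calibration loop therefore
    inflates the per-column event counts until the simulated Fitch counts
    match the originals (which simultaneously restores the original average
    identity).  This preserves the alignment's dimensions, gap structure,
    composition, per-column substitution counts and phylogenetic
    correlation structure while destroying the coordinated residue
    identities that constitute covariation.  Gap and ambiguity characters
    are copied verbatim.
    """
    if n < 1:
        raise CovpowerError("need n >= 1 null alignments")
    if set(tree.leaf_names()) != set(aln.names):
        raise TreeError("tree leaves do not match alignment names")
    rng = np.random.default_rng(seed)
    btree = tree.binarized()
    codes = aln.codes()
    n_seqs, L = codes.shape
    row_of = {name: r for r, name in enumerate(aln.names)}

    # per-column residue composition (for drawing substitution targets)
    pis = np.full((L, 4), 0.25)
    s_col = subs.per_column.astype(int)
    for c in range(L):
        obs = codes[:, c][codes[:, c] < 4]
        if obs.size:
            counts = np.bincount(obs, minlength=4).astype(float)
            pis[c] = counts / counts.sum()

    order = [nd for nd in btree.preorder() if nd is not btree.root]
    parent = {}
    for node in btree.preorder():
        for child in node.children:
            parent[id(child)] = node
    lengths = np.array([nd.length for nd in order], dtype=float)
    if lengths.sum() <= 0:
        branch_p = np.full(len(order), 1.0 / len(order))
    else:
        # small floor so zero-length branches stay reachable
        branch_p = lengths + 1e-6 * lengths.sum() / len(order)
        branch_p = branch_p / branch_p.sum()
    leaf_nodes = btree.leaves()
    leaf_rows = [row_of[leaf.name] for leaf in leaf_nodes]
    gap_mask = codes >= 4  # cells copied verbatim from the original

    def simulate_states(counts: np.ndarray, gen: np.random.Generator) -> np.ndarray:
        """(n_seqs, L) residue codes sampled with the given per-column event
        counts; gap cells still hold placeholder states (masked later)."""
        states = np.empty((n_seqs, L), dtype=np.intp)
        node_state: dict[int, np.ndarray] = {
            id(btree.root): np.array(
                [_draw(pis[c], gen) for c in range(L)], dtype=np.intp
            )
        }
        changes_on: list[list[int]] = [[] for _ in order]  # branch -> columns
        for c in range(L):
            if counts[c] <= 0:
                continue
            placed = gen.choice(len(order), size=int(counts[c]), p=branch_p)
            for b in placed:
                changes_on[int(b)].append(c)
        for k, node in enumerate(order):
            state = node_state[id(parent[id(node)])].copy()
            for c in changes_on[k]:
                state[c] = _draw_excluding(pis[c], int(state[c]), gen)
            node_state[id(node)] = state
        for leaf, r in zip(leaf_nodes, leaf_rows):
            states[r] = node_state[id(leaf)]
        return states

    event_counts = s_col.astype(float)
    if calibrate and (s_col > 0).any():
        cal_rng = np.random.default_rng(rng.integers(2**31))
        for _ in range(3):
            placed = np.maximum(np.round(event_counts), s_col).astype(int)
            fitches = []
            for _ in range(4):
                states = simulate_states(placed, cal_rng)
                sim_codes = np.where(gap_mask, 4, states).astype(np.int8)
                fitches.append(fitch_counts_coded(tree, sim_codes, list(aln.names)))
            mean_fitch = np.mean(fitches, axis=0)
            factor = (s_col + 0.5) / (mean_fitch + 0.5)
            factor = np.clip(factor, 0.5, 2.0)
            event_counts = np.where(s_col > 0, event_counts * factor, 0.0)
    final_counts = np.maximum(np.round(event_counts), s_col).astype(int)

    out: list[Alignment] = []
    for _ in range(n):
        states = simulate_states(final_counts, rng)
        rows = []
        for r in range(n_seqs):
            orig = aln.rows[r]
            chars = [
                orig[c] if gap_mask[r, c] else ALPHABET[states[r, c]]
                for c in range(L)
            ]
            rows.append("".join(chars))
        out.append(Alignment(names=list(aln.names), rows=rows))
    return out


def _draw(pi: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(pi), rng.random(), side="right").clip(0, 3))


def _draw_excluding(pi: np.ndarray, current: int, rng: np.random.Generator) -> int:
    w = pi.copy()
    w[current] = 0.0
    total = w.sum()
    if total <= 0:
        w = np.ones(4)
        w[current] = 0.0
        total = 3.0
    w = w / total
    return int(np.searchsorted(np.cumsum(w), rng.random(), side="right").clip(0, 3))


def build_null(
    aln: Alignment,
    tree: PhyloTree,
    subs: SubstitutionCounts,
    seed: int,
    n_nulls: int = 20,
    min_null_stats: int = 100_000,
    statistic: str = "GT",
    apc: bool = False,
) -> NullDistribution:
    """Pool pair statistics across simulated negative controls.

    More alignments than ``n_nulls`` are generated if needed to reach
    ``min_null_stats`` pooled values.  Untestable pairs (fewer than
    MIN_TESTABLE_ROWS mutually ungapped rows) are excluded from the pool.
    """
    L = aln.L
    pairs = _pair_list(L)
    codes = aln.codes()
    ok = codes < 4
    testable = [
        (i, j) for i, j in pairs if int((ok[:, i] & ok[:, j]).sum()) >= MIN_TESTABLE_ROWS
    ]
    if not testable:
        raise CovpowerError("no testable column pairs (alignment too gappy)")
    per_aln = len(testable)
    n_aligns = max(n_nulls, math.ceil(min_null_stats / per_aln))
    pooled: list[np.ndarray] = []
    nulls = null_alignments(aln, tree, subs, n_aligns, seed)
    for null in nulls:
        ncodes = null.codes()
        pooled.append(pair_statistics(ncodes, testable, statistic=statistic, apc=apc))
    samples = np.concatenate(pooled)
    return NullDistribution(
        samples=samples, n_alignments=n_aligns, n_tests=L * (L - 1) // 2
    )


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------


def evalues(
    observed: np.ndarray,
    null: NullDistribution,
    n_tests: int | None = None,
    threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical E-values for observed scores against a null.

    E(x) = n_tests * survival(x) with add-one smoothing; a score is
    significant iff E < threshold.  Returns (pvalues, evalues, significant).
    """
    nt = null.n_tests if n_tests is None else n_tests
    if nt < 1:
        raise CovpowerError("n_tests must be >= 1")
    surv = null.survival(np.asarray(observed, dtype=float))
    ev = nt * surv
    return surv, ev, ev < threshold


# ---------------------------------------------------------------------------
# Test orchestration
# ---------------------------------------------------------------------------


def run_test(
    aln: Alignment,
    tree: PhyloTree,
    structure: SecondaryStructure | None = None,
    mode: str = "one_set",
    statistic: str = "GT",
    apc: bool = False,
    evalue_threshold: float = 0.05,
    n_nulls: int = 20,
    min_null_stats: int = 100_000,
    seed: int = 42,
    subs: SubstitutionCounts | None = None,
    null: NullDistribution | None = None,
) -> list[CovariationResult]:
    """Score all column pairs and assign E-values in one-set or two-set mode.

    One-set: every pair is corrected by n_tests = L(L-1)/2.  Two-set: the
    proposed basepair set is corrected by n_tests = B and its complement by
    L(L-1)/2 - B, each against the shared null.
    """
    if mode not in ("one_set", "two_set"):
        raise CovpowerError(f"unknown mode {mode!r}")
    if mode == "two_set" and structure is None:
        raise CovpowerError(
            "two_set mode requires a proposed structure "
            "(estimating alignment power needs one)"
        )
    if subs is None:
        subs = substitutions(aln, tree)
    L = aln.L
    all_pairs = _pair_list(L)
    n_all = len(all_pairs)
    codes = aln.codes()
    ok = codes < 4
    testable_mask = np.array(
        [int((ok[:, i] & ok[:, j]).sum()) >= MIN_TESTABLE_ROWS for i, j in all_pairs]
    )
    stats = np.zeros(n_all)
    idx_testable = np.nonzero(testable_mask)[0]
    tested_pairs = [all_pairs[k] for k in idx_testable]
    stats[idx_testable] = pair_statistics(codes, tested_pairs, statistic=statistic, apc=apc)

    if null is None:
        null = build_null(
            aln, tree, subs, seed=seed, n_nulls=n_nulls,
            min_null_stats=min_null_stats, statistic=statistic, apc=apc,
        )

    in_struct = np.zeros(n_all, dtype=bool)
    if structure is not None:
        struct_set = set(structure.pairs)
        in_struct = np.array([p in struct_set for p in all_pairs])

    if mode == "one_set":
        set_ntests = np.full(n_all, n_all)
    else:
        B = int(in_struct.sum())
        set_ntests = np.where(in_struct, max(B, 1), max(n_all - B, 1))

    results: list[CovariationResult] = []
    surv = null.survival(stats)
    for k, (i, j) in enumerate(all_pairs):
        nt = int(set_ntests[k])
        if testable_mask[k]:
            pv = float(surv[k])
            ev = nt * pv
        else:
            pv, ev = 1.0, float(nt)
        results.append(
            CovariationResult(
                pair=(i, j),
                stat=float(stats[k]),
                pvalue=pv,
                evalue=ev,
                significant=bool(testable_mask[k] and ev < evalue_threshold),
                in_structure=bool(in_struct[k]),
                substitutions=subs.pair_count(i, j),
                testable=bool(testable_mask[k]),
            )
        )
    return results
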