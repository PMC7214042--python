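import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from covpower.covariation import (
    NullDistribution,
    apc_correct,
    build_null,
    evalues,
    g_test,
    joint_counts,
    mutual_information,
    null_alignments,
    run_test,
)
from covpower.errors import CovpowerError
from covpower.fixtures import structural_template
from covpower.msa_io import Alignment
from covpower.phylo import average_identity, tree_from_alignment
from covpower.parsimony import substitutions


def covarying_alignment(n=8):
    """Half the rows A-U, half G-C at columns 0 and 3."""
    rows = ["AXXU".replace("X", "C") for _ in range(n // 2)]
    rows += ["GXXC".replace("X", "C") for _ in range(n - n // 2)]
    return Alignment(names=[f"s{k}" for k in range(n)], rows=rows)


class TestJointCounts:
    def test_two_cells_of_four(self):
        aln = covarying_alignment(8)
        table, n = joint_counts(aln, 0, 3)
        assert n == 8
        assert table[0, 3] == 4  # A-U
        assert table[2, 1] == 4  # G-C

    def test_self_pair_rejected(self):
        with pytest.raises(CovpowerError):
            joint_counts(covarying_alignment(), 1, 1)

    def test_gapped_rows_excluded(self):
        aln = Alignment(names=["a", "b", "c"], rows=["AU", "A-", "GC"])
        table, n = joint_counts(aln, 0, 1)
        assert n == 2
        assert table.sum() == 2


class TestMutualInformation:
    def test_perfect_covariation_one_bit(self):
        table, _ = joint_counts(covarying_alignment(8), 0, 3)
        assert mutual_information(table) == pytest.approx(1.0)

    def test_independent_columns_zero_bits(self):
        # A-U, A-C, G-U, G-C equally frequent
        rows = ["AU", "AC", "GU", "GC"] * 2
        aln = Alignment(names=[f"s{k}" for k in range(8)], rows=rows)
        table, _ = joint_counts(aln, 0, 1)
        assert mutual_information(table) == pytest.approx(0.0)

    def test_invariant_pair_zero(self):
        rows = ["AU"] * 6
        aln = Alignment(names=[f"s{k}" for k in range(6)], rows=rows)
        table, _ = joint_counts(aln, 0, 1)
        assert mutual_information(table) == 0.0

    def test_nonnegative_and_bounded_by_entropy(self, rng):
        for _ in range(50):
            table = rng.integers(0, 10, size=(4, 4)).astype(float)
            if table.sum() == 0:
                continue
            mi = mutual_information(table)
            p = table / table.sum()
            hx = -sum(q * math.log2(q) for q in p.sum(axis=1) if q > 0)
            hy = -sum(q * math.log2(q) for q in p.sum(axis=0) if q > 0)
            assert -1e-12 <= mi <= min(hx, hy) + 1e-9


class TestGTest:
    def test_independent_table_zero(self):
        table = np.outer([4, 4, 0, 0], [2, 6, 0, 0]) / 8.0
        assert g_test(table) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_covariation_value(self):
        table, _ = joint_counts(covarying_alignment(8), 0, 3)
        assert g_test(table) == pytest.approx(2 * 8 * math.log(2))

    def test_matches_scipy_loglikelihood_ratio(self, rng):
        for _ in range(30):
            table = rng.integers(1, 12, size=(2, 2)).astype(float)
            g_mine = g_test(_embed(table))
            g_scipy = chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            )[0]
            assert g_mine == pytest.approx(g_scipy, rel=1e-9)

    def test_identity_with_mi(self, rng):
        for _ in range(30):
            table = rng.integers(0, 9, size=(4, 4)).astype(float)
            n = table.sum()
            if n == 0:
                continue
            assert g_test(table) == pytest.approx(
                2 * n * math.log(2) * mutual_information(table), abs=1e-9
            )


def _embed(t22):
    out = np.zeros((4, 4))
    out[:2, :2] = t22
    return out


class TestAPC:
    def test_constant_matrix_zeroed(self):
        m = np.full((5, 5), 2.0)
        np.fill_diagonal(m, 0.0)
        corr = apc_correct(m)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(corr[off], 0.0)

    def test_symmetry_preserved(self, rng):
        m = rng.random((6, 6))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        corr = apc_correct(m)
        assert np.allclose(corr, corr.T)

    def test_single_hot_pair_stays_maximal(self):
        m = np.zeros((6, 6))
        m[1, 4] = m[4, 1] = 5.0
        corr = apc_correct(m)
        assert corr[1, 4] == corr.max()

    def test_all_zero_unchanged(self):
        m = np.zeros((4, 4))
        assert np.allclose(apc_correct(m), m)


class TestNullAlignments:
    def test_invariant_column_copied(self, template_tree, template_aln,
                                     template_subs):
        nulls = null_alignments(template_aln, template_tree, template_subs,
                                2, seed=5)
        codes = template_aln.codes()
        for c in range(template_aln.L):
            obs = set(codes[:, c][codes[:, c] < 4].tolist())
            if len(obs) <= 1:
                for null in nulls:
                    assert [r[c] for r in null.rows] == [
                        r[c] for r in template_aln.rows
                    ]

    def test_dimensions_and_gaps_preserved(self, template_aln, template_tree,
                                           template_subs):
        (null,) = null_alignments(template_aln, template_tree, template_subs,
                                  1, seed=6)
        assert null.L == template_aln.L
        assert null.names == template_aln.names
        for orig, sim in zip(template_aln.rows, null.rows):
            for a, b in zip(orig, sim):
                assert (a == "-") == (b == "-")

    def test_fitch_counts_match(self, template_aln, template_tree,
                                template_subs):
        nulls = null_alignments(template_aln, template_tree, template_subs,
                                50, seed=7)
        mat = np.array([
            substitutions(n, template_tree).per_column for n in nulls
        ])
        mean_fitch = mat.mean(axis=0)
        s = template_subs.per_column
        sel = s >= 5
        assert sel.any()
        ratios = mean_fitch[sel] / s[sel]
        assert (np.abs(ratios - 1.0) <= 0.25).all()

    def test_identity_preserved(self, template_aln, template_tree,
                                template_subs):
        nulls = null_alignments(template_aln, template_tree, template_subs,
                                10, seed=8)
        orig = average_identity(template_aln)
        null_id = np.mean([average_identity(n) for n in nulls])
        assert abs(null_id - orig) <= 0.03


class TestEvalues:
    def _null(self):
        return NullDistribution(samples=np.arange(100.0), n_alignments=1,
                                n_tests=45)

    def test_low_score_never_significant(self):
        null = self._null()
        _, ev, sig = evalues(np.array([-5.0]), null)
        assert ev[0] == pytest.approx(45.0 * 101 / 101)
        assert not sig[0]

    def test_high_score_smoothing_bound(self):
        null = self._null()
        _, ev, _ = evalues(np.array([1e9]), null)
        assert ev[0] == pytest.approx(45.0 / 101)
        assert ev[0] <= 45 / (1 + 100)

    def test_monotone_nonincreasing_in_score(self):
        null = self._null()
        scores = np.linspace(-10, 110, 50)
        _, ev, _ = evalues(scores, null)
        assert (np.diff(ev) <= 1e-12).all()

    def test_two_set_evalues_smaller_for_basepairs(self):
        null = self._null()
        scores = np.array([50.0])
        _, ev_small, _ = evalues(scores, null, n_tests=4)
        _, ev_big, _ = evalues(scores, null, n_tests=41)
        assert ev_small[0] < ev_big[0]

    def test_small_sample_calibration(self, template_aln, template_tree,
                                      template_subs):
        # pure-null observed data: mean significant count per one-set test
        # should not exceed the threshold (plus smoothing slack)
        null = build_null(template_aln, template_tree, template_subs, seed=21,
                          n_nulls=10, min_null_stats=40_000)
        obs = null_alignments(template_aln, template_tree, template_subs,
                              30, seed=77)
        counts = []
        for o in obs:
            res = run_test(o, template_tree, mode="one_set", seed=1,
                           subs=template_subs, null=null)
            counts.append(sum(r.significant for r in res))
        assert np.mean(counts) <= 0.05 * 1.5 + 0.2


class TestRunTest:
    def test_one_set_counts_all_pairs(self, template_aln, template_tree,
                                      template_subs):
        aln = structural_template(seed=30, L=10, n_pairs=2, n_seqs=8)
        tree = tree_from_alignment(aln)
        res = run_test(aln, tree, mode="one_set", seed=2, n_nulls=2,
                       min_null_stats=500)
        assert len(res) == 45

    def test_two_set_requires_structure(self, template_aln, template_tree):
        with pytest.raises(CovpowerError, match="structure"):
            run_test(template_aln, template_tree, mode="two_set")

    def test_two_set_correction_factors(self, template_aln, template_tree,
                                        template_subs):
        structure = template_aln.structure()
        res = run_test(template_aln, template_tree, structure=structure,
                       mode="two_set", seed=3, n_nulls=3, min_null_stats=2000,
                       subs=template_subs)
        n_all = template_aln.L * (template_aln.L - 1) // 2
        bp = [r for r in res if r.in_structure]
        nonbp = [r for r in res if not r.in_structure]
        assert len(bp) == structure.B
        assert len(nonbp) == n_all - structure.B
        # E = n_tests * survival: basepair set uses the smaller factor
        for r in bp:
            if r.testable:
                assert r.evalue == pytest.approx(structure.B * r.pvalue)

    def test_positive_control_detects_structure(self, template_aln,
                                                template_tree, template_subs):
        structure = template_aln.structure()
        res = run_test(template_aln, template_tree, structure=structure,
                       mode="two_set", seed=4, min_null_stats=30_000,
                       subs=template_subs)
        sig_bp = sum(r.significant for r in res if r.in_structure)
        assert sig_bp >= structure.B * 0.5
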