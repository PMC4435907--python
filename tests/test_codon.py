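"""Codon models: translation, conservation, rate matrices, pruning, fits, LRTs."""

import numpy as np
import pytest

import hibtarget as ht
from hibtarget.codonmodel import (
    BranchLikelihood,
    CodonModelParams,
    N_CODONS,
    SENSE_CODONS,
    _EigenQ,
    f3x4_frequencies,
    fit_branch_model,
    gy94_rate_matrix,
    substitution_split,
)
from hibtarget.phylo import parse_labeled_tree
from hibtarget.simulate import simulate_codon_alignment


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [("ATGAAA", "MK"), ("ATG---", "M-"), ("ATGAAATAA", "MK"), ("TTTTGG", "FW")],
    )
    def test_examples(self, cds, protein):
        assert ht.translate(cds) == protein

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ht.translate("ATGTAAAAA")

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError):
            ht.translate("ATGA")


class TestConservation:
    def test_all_identical(self):
        aln = {"a": "MKV", "b": "MKV"}
        s = ht.conservation_summary(aln)
        assert s.percent_identity == 100.0 and s.n_variable == 0

    def test_gap_does_not_break_identity(self):
        aln = {"a": "MKV", "b": "M-V"}
        assert ht.conservation_summary(aln).n_identical == 3

    def test_group_classification_matches_per_column_logic(self):
        # columns: 0 identical everywhere; 1 conserved in A, variable in B;
        # 2 conserved in both but for different residues; 3 variable in A only
        aln = {
            "a1": "MKLV",
            "a2": "MKLI",
            "b1": "MRAV",
            "b2": "MSAV",
        }
        s = ht.conservation_summary(aln, groups=(["a1", "a2"], ["b1", "b2"]))
        assert s.n_identical == 1
        assert s.conserved_in_a_diff_in_b == [2, 3]
        assert s.conserved_in_b_diff_in_a == [3, 4]

    def test_region_subsetting(self):
        aln = {"a": "AAAB", "b": "AAAC"}
        s = ht.conservation_summary(aln, region=(1, 3))
        assert s.n_columns == 3 and s.n_variable == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ht.conservation_summary({"a": "MK", "b": "MK"}, groups=([], ["a", "b"]))


class TestRateMatrix:
    def test_detailed_balance(self):
        pi = np.random.default_rng(0).dirichlet(np.ones(N_CODONS))
        Q = gy94_rate_matrix(3.0, 0.2, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rows_sum_to_zero_and_unit_rate(self):
        pi = np.full(N_CODONS, 1 / N_CODONS)
        Q = gy94_rate_matrix(2.0, 0.5, pi)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_neutral_uniform_rates_equal(self):
        pi = np.full(N_CODONS, 1 / N_CODONS)
        Q = gy94_rate_matrix(1.0, 1.0, pi, scale=False)
        off = Q[Q > 0]
        assert np.allclose(off, off[0])

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_transition_matrix_stochastic(self, t):
        pi = np.random.default_rng(1).dirichlet(np.ones(N_CODONS))
        P = _EigenQ(2.0, 0.3, pi).transition(t)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-10)

    def test_substitution_split_partitions_unit_rate(self):
        pi = np.full(N_CODONS, 1 / N_CODONS)
        rho_n, rho_s = substitution_split(2.0, 0.3, pi)
        assert rho_n + rho_s == pytest.approx(1.0)
        # more nonsynonymous flux when omega rises
        rho_n2, _ = substitution_split(2.0, 1.0, pi)
        assert rho_n2 > rho_n


def _random_alignment(taxa, n_codons, seed):
    rng = np.random.default_rng(seed)
    return ht.CodonAlignment(
        list(taxa),
        [
            "".join(SENSE_CODONS[i] for i in rng.integers(0, N_CODONS, n_codons))
            for _ in taxa
        ],
    )


class TestPruning:
    def test_single_taxon_closed_form(self):
        tree, _ = parse_labeled_tree("A;")
        aln = _random_alignment("A", 8, seed=2)
        pi = np.full(N_CODONS, 1 / N_CODONS)
        eng = BranchLikelihood(tree, aln, pi=pi)
        ll = eng.log_likelihood(2.0, {0: 0.5}, np.zeros(0))
        expected = sum(np.log(pi[i]) for i in aln.codon_matrix()[0])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_pairwise_oracle(self):
        tree, _ = parse_labeled_tree("(A:0.12,B:0.27);")
        aln = _random_alignment("AB", 10, seed=3)
        pi = f3x4_frequencies(aln)
        eng = BranchLikelihood(tree, aln, pi=pi)
        ll = eng.log_likelihood(2.0, {0: 0.4}, eng.edge_length0[eng.edge_nodes])
        # reversibility: pair likelihood = sum_i pi_i P(t1)_ia P(t2)_ib
        e = _EigenQ(2.0, 0.4, pi)
        PA, PB = e.transition(0.12), e.transition(0.27)
        mat = aln.codon_matrix()
        direct = sum(
            np.log((pi * PA[:, a] * PB[:, b]).sum()) for a, b in zip(mat[0], mat[1])
        )
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_three_taxon_bruteforce_marginalization(self):
        tree, _ = parse_labeled_tree("((A:0.1,B:0.2):0.15,C:0.3);")
        aln = _random_alignment("ABC", 6, seed=4)
        pi = f3x4_frequencies(aln)
        eng = BranchLikelihood(tree, aln, pi=pi)
        ll = eng.log_likelihood(1.7, {0: 0.6}, eng.edge_length0[eng.edge_nodes])
        e = _EigenQ(1.7, 0.6, pi)
        PU, PA, PB, PC = (e.transition(t) for t in (0.15, 0.1, 0.2, 0.3))
        mat = aln.codon_matrix()
        brute = 0.0
        for a, b, c in mat.T:
            inner = (PU * (PA[:, a] * PB[:, b])[None, :]).sum(axis=1)
            brute += np.log((pi * inner * PC[:, c]).sum())
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_rerooting_invariance(self):
        aln = _random_alignment("ABCD", 15, seed=5)
        pi = f3x4_frequencies(aln)
        t1, _ = parse_labeled_tree("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.05);")
        t2, _ = parse_labeled_tree("(A:0.1,(B:0.2,(C:0.3,D:0.1):0.1):0.0);")
        e1 = BranchLikelihood(t1, aln, pi=pi)
        e2 = BranchLikelihood(t2, aln, pi=pi)
        ll1 = e1.log_likelihood(2.0, {0: 0.4}, e1.edge_length0[e1.edge_nodes])
        ll2 = e2.log_likelihood(2.0, {0: 0.4}, e2.edge_length0[e2.edge_nodes])
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_gap_codons_treated_as_missing(self):
        tree, _ = parse_labeled_tree("(A:0.1,B:0.2);")
        aln_full = ht.CodonAlignment(["A", "B"], ["ATGAAA", "ATGAAG"])
        aln_gap = ht.CodonAlignment(["A", "B"], ["ATG---", "ATGAAG"])
        pi = np.full(N_CODONS, 1 / N_CODONS)
        ef = BranchLikelihood(tree, aln_full, pi=pi)
        eg = BranchLikelihood(tree, aln_gap, pi=pi)
        bl = ef.edge_length0[ef.edge_nodes]
        # gapped column contributes only the single-sequence marginal
        assert eg.log_likelihood(2.0, {0: 0.5}, bl) > ef.log_likelihood(
            2.0, {0: 0.5}, bl
        )


@pytest.fixture(scope="module")
def small_sim():
    from hibtarget.phylo import pure_birth_tree

    tree = pure_birth_tree(6, seed=17)
    for e in tree.preorder_edge_iter():
        if e.length:
            e.length *= 0.4
    params = CodonModelParams(
        kappa=2.0, omegas={0: 0.3}, pi=np.full(N_CODONS, 1 / N_CODONS)
    )
    aln = simulate_codon_alignment(tree, params, 120, seed=19)
    return tree, aln


class TestBranchModelFits:
    def test_np_accounting_and_nesting(self, small_sim):
        tree, aln = small_sim
        one = fit_branch_model(tree, aln, "one_ratio", seed=1, n_restarts=1)
        fixed = fit_branch_model(
            tree,
            aln,
            "fixed_omega1",
            seed=1,
            n_restarts=1,
            init={"kappa": one.kappa, "branch_lengths": one.branch_lengths},
        )
        free = fit_branch_model(tree, aln, "free_ratio", seed=1, n_restarts=1)
        assert fixed.np_ == one.np_ - 1
        assert free.np_ == one.np_ + len(free.branches) - 1
        assert free.lnl >= one.lnl - 1e-3
        assert one.lnl >= fixed.lnl - 1e-3

    def test_two_ratio_requires_label(self, small_sim):
        tree, aln = small_sim
        with pytest.raises(ValueError):
            fit_branch_model(tree, aln, "two_ratio", seed=1)

    def test_two_ratio_labeled_foreground(self):
        tree, classes = parse_labeled_tree(
            "((A:0.2,B:0.2)#1:0.2,(C:0.2,D:0.2):0.2);"
        )
        assert 1 in classes.values()
        params = CodonModelParams(
            kappa=2.0, omegas={0: 0.5}, pi=np.full(N_CODONS, 1 / N_CODONS)
        )
        aln = simulate_codon_alignment(tree, params, 80, seed=23)
        fit = fit_branch_model(
            tree, aln, "two_ratio", branch_classes=classes, seed=1, n_restarts=1
        )
        assert set(fit.omegas) == {0, 1}
        one = fit_branch_model(tree, aln, "one_ratio", seed=1, n_restarts=1)
        assert fit.np_ == one.np_ + 1
        assert fit.lnl >= one.lnl - 1e-3

    def test_branch_report_decomposition(self, small_sim):
        tree, aln = small_sim
        fit = fit_branch_model(tree, aln, "one_ratio", seed=1, n_restarts=1)
        for b in fit.branches:
            total = b.n_dn + b.s_ds
            assert total == pytest.approx(b.length * aln.n_codons, rel=1e-6)
            assert b.omega == pytest.approx(fit.omegas[0])


class TestLRT:
    def test_identical_fits_degenerate(self):
        res = ht.lrt((-100.0, 10), (-100.0, 11))
        assert res.stat == 0.0 and res.pvalue == 1.0

    def test_negative_statistic_beyond_tolerance_raises(self):
        with pytest.raises(ValueError):
            ht.lrt((-100.0, 10), (-101.0, 11))

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            ht.lrt((-100.0, 11), (-99.0, 11))


class TestCodonAlignmentContainer:
    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ht.CodonAlignment(["a"], ["ATGTAAAAA"])

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            ht.CodonAlignment(["a", "b"], ["ATGAAA", "ATG"])

    def test_fasta_roundtrip(self, tmp_path):
        aln = ht.CodonAlignment(["a", "b"], ["ATGAAA", "ATGAAG"])
        p = tmp_path / "aln.fa"
        aln.to_fasta(p)
        back = ht.CodonAlignment.from_fasta(p)
        assert back.taxa == aln.taxa and back.sequences == aln.sequences
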