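import numpy as np
import pytest

from _oracles import brute_force_loglik
from redking.alignment import Alignment, CodonAlignment, translate
from redking.likelihood import BindingError, loglikelihood, tip_partials
from redking.models import (
    CODON_INDEX,
    CodonModelParams,
    EmpiricalAAModel,
    GTRParams,
    N_CODONS,
    SENSE_CODONS,
    SpectralQ,
    blosum62_exchangeabilities,
    build_aa_Q,
    build_codon_Q,
    build_gtr_Q,
    discrete_gamma,
)
from redking.trees import CladeTree, LICHENIZED, NON_LICHENIZED, OUTGROUP


def _three_tip_tree(ta, tb, tc):
    parent = np.array([3, 3, 3, -1])
    blens = np.array([ta, tb, tc, 0.0])
    cmap = {"X": LICHENIZED, "Y": NON_LICHENIZED, "Z": OUTGROUP}
    return CladeTree(parent, blens, ["X", "Y", "Z"], cmap)


class TestClosedForms:
    def test_identical_sequences_zero_lengths_jc(self):
        tree = _three_tip_tree(0.0, 0.0, 0.0)
        aln = Alignment(["X", "Y", "Z"], ["ACGTAC"] * 3)
        res = loglikelihood(aln, tree, GTRParams.jukes_cantor())
        assert res.loglik == pytest.approx(6 * np.log(0.25), abs=1e-10)

    def test_two_taxon_jc_closed_form(self):
        # Z is attached with a zero branch, so the model reduces to a
        # two-taxon JC comparison at distance t
        t = 0.3
        tree = _three_tip_tree(t, 0.0, 0.0)
        aln = Alignment(["X", "Y", "Z"], ["AAGC", "ACGC", "ACGC"])
        n_same, n_diff = 3, 1
        p_same = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
        p_diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))
        expected = n_same * np.log(p_same) + n_diff * np.log(p_diff)
        res = loglikelihood(aln, tree, GTRParams.jukes_cantor())
        assert res.loglik == pytest.approx(expected, abs=1e-10)


class TestBruteForceOracle:
    def test_nucleotide_pruning_matches_enumeration(self, four_taxon_tree):
        rng = np.random.default_rng(0)
        gtr = GTRParams(rng.uniform(0.5, 3, 6), rng.dirichlet(np.ones(4) * 8))
        seqs = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(4)]
        aln = Alignment(["A", "B", "C", "D"], seqs)
        sq = SpectralQ(build_gtr_Q(gtr), gtr.base_freqs)
        P = {e: sq.transition_matrix(four_taxon_tree.branch_lengths[e])
             for e in four_taxon_tree.edges}
        states = np.array([["ACGT".index(c) for c in s] for s in seqs])
        expected = brute_force_loglik(four_taxon_tree, states, P, gtr.base_freqs)
        got = loglikelihood(aln, four_taxon_tree, gtr).loglik
        assert got == pytest.approx(expected, abs=1e-8)

    def test_codon_pruning_matches_enumeration(self, four_taxon_tree, uniform_codon_model):
        rng = np.random.default_rng(1)
        codons = rng.integers(0, N_CODONS, size=(4, 3))
        seqs = ["".join(SENSE_CODONS[c] for c in row) for row in codons]
        aln = CodonAlignment(["A", "B", "C", "D"], seqs)
        omega = 0.4
        sq = SpectralQ(build_codon_Q(uniform_codon_model, omega),
                       uniform_codon_model.codon_freqs)
        P = {e: sq.transition_matrix(four_taxon_tree.branch_lengths[e])
             for e in four_taxon_tree.edges}
        expected = brute_force_loglik(four_taxon_tree, codons, P,
                                      uniform_codon_model.codon_freqs)
        got = loglikelihood(
            aln, four_taxon_tree, uniform_codon_model,
            omega_by_edge={e: omega for e in four_taxon_tree.edges},
        ).loglik
        assert got == pytest.approx(expected, abs=1e-8)


class TestMixturesAndMissingData:
    def test_gamma_mixture_equals_manual_average(self, four_taxon_tree):
        rng = np.random.default_rng(3)
        gtr = GTRParams(rng.uniform(0.5, 3, 6), rng.dirichlet(np.ones(4) * 8))
        aln = Alignment(["A", "B", "C", "D"],
                        ["".join(rng.choice(list("ACGT"), 20)) for _ in range(4)])
        mix = discrete_gamma(0.5, 4)
        got = loglikelihood(aln, four_taxon_tree, gtr, mixture=mix).loglik
        # manual average of per-category site likelihoods
        per_cat = []
        for r in mix.rates:
            scaled = four_taxon_tree.with_branch_lengths(four_taxon_tree.branch_lengths * r)
            per_cat.append(loglikelihood(aln, scaled, gtr).site_loglik)
        site = np.log(np.mean(np.exp(np.stack(per_cat)), axis=0))
        res = loglikelihood(aln, four_taxon_tree, gtr)
        assert got == pytest.approx(float(site @ res.pattern_weights), abs=1e-8)

    def test_missing_data_never_decreases_site_likelihood(self, four_taxon_tree):
        rng = np.random.default_rng(4)
        gtr = GTRParams.jukes_cantor()
        base = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(4)]
        aln = Alignment(["A", "B", "C", "D"], base)
        full = loglikelihood(aln, four_taxon_tree, gtr)
        masked = [s if i else "N" + s[1:] for i, s in enumerate(base)]
        aln2 = Alignment(["A", "B", "C", "D"], masked)
        part = loglikelihood(aln2, four_taxon_tree, gtr)
        assert part.loglik >= full.loglik - 1e-12

    def test_pattern_compression_changes_nothing(self, four_taxon_tree):
        rng = np.random.default_rng(5)
        cols = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(6)]
        expanded = cols * 5  # 30 columns, 6 distinct patterns
        seqs = ["".join(col[i] for col in expanded) for i in range(4)]
        aln = Alignment(["A", "B", "C", "D"], seqs)
        res = loglikelihood(aln, four_taxon_tree, GTRParams.jukes_cantor())
        assert len(res.pattern_weights) == len(set(cols))
        seqs1 = ["".join(col[i] for col in cols) for i in range(4)]
        res1 = loglikelihood(Alignment(["A", "B", "C", "D"], seqs1),
                             four_taxon_tree, GTRParams.jukes_cantor())
        assert res.loglik == pytest.approx(5 * res1.loglik, abs=1e-10)


class TestRootPlacementInvariance:
    def test_reversible_likelihood_invariant_to_rerooting(self):
        # same unrooted tree described with the basal trifurcation at
        # either internal vertex of ((A,B),(C,D))
        ta, tb, tc, td, tm = 0.11, 0.27, 0.05, 0.4, 0.19
        cmap = {"A": OUTGROUP, "B": OUTGROUP, "C": LICHENIZED, "D": NON_LICHENIZED}
        tree1 = CladeTree(np.array([5, 5, 4, 4, 5, -1]),
                          np.array([ta, tb, tc, td, tm, 0.0]),
                          ["A", "B", "C", "D"], cmap)
        tree2 = CladeTree(np.array([4, 4, 5, 5, 5, -1]),
                          np.array([ta, tb, tc, td, tm, 0.0]),
                          ["A", "B", "C", "D"], cmap)
        rng = np.random.default_rng(6)
        gtr = GTRParams(rng.uniform(0.5, 3, 6), rng.dirichlet(np.ones(4) * 8))
        aln = Alignment(["A", "B", "C", "D"],
                        ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)])
        l1 = loglikelihood(aln, tree1, gtr).loglik
        l2 = loglikelihood(aln, tree2, gtr).loglik
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestAminoAcidAndErrors:
    def test_aa_pruning_matches_enumeration(self, four_taxon_tree):
        rng = np.random.default_rng(7)
        freqs = rng.dirichlet(np.ones(20) * 10)
        model = EmpiricalAAModel(blosum62_exchangeabilities(), freqs)
        from redking.models import AA

        states = rng.integers(0, 20, size=(4, 3))
        seqs = ["".join(AA[i] for i in row) for row in states]
        aln = Alignment(["A", "B", "C", "D"], seqs, alphabet="aa")
        sq = SpectralQ(build_aa_Q(model), freqs)
        P = {e: sq.transition_matrix(four_taxon_tree.branch_lengths[e])
             for e in four_taxon_tree.edges}
        expected = brute_force_loglik(four_taxon_tree, states, P, freqs)
        got = loglikelihood(aln, four_taxon_tree, model).loglik
        assert got == pytest.approx(expected, abs=1e-8)

    def test_taxon_mismatch_raises(self, four_taxon_tree):
        aln = Alignment(["A", "B", "C", "E"], ["ACGT"] * 4)
        with pytest.raises(BindingError):
            loglikelihood(aln, four_taxon_tree, GTRParams.jukes_cantor())

    def test_ambiguity_codes_enter_as_partial_observations(self):
        part, w = tip_partials(Alignment(["a"], ["RN-"]))
        assert np.all(part[0, :, :].sum(axis=0) > 1)  # each pattern ambiguous
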