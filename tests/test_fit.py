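import numpy as np
import pandas as pd
import pytest

from redking.alignment import Alignment, CodonAlignment, PartitionScheme, split_codon_positions
from redking.fit import (
    FitResult,
    ModelSpec,
    branch_dn_ds,
    fit,
    fit_codon,
    fit_nested,
    fit_nucleotide,
    fit_partitioned,
    omega_class_of_edges,
    synonymous_site_fraction,
)
from redking.models import (
    CODON_NONSYN,
    CODON_DIFF1,
    CodonModelParams,
    N_CODONS,
    build_codon_Q,
    discrete_gamma,
)
from redking.simulate import DEFAULT_GTR, simulate_codon, simulate_nucleotide
from redking.trees import LICHENIZED, NON_LICHENIZED, OUTGROUP


class TestFitNucleotide:
    def test_identical_sequences_shrink_branches(self, small_tree):
        aln = Alignment(small_tree.tip_labels, ["ACGTACGTACGTACGTACGT"] * 5)
        res = fit_nucleotide(aln, small_tree, n_starts=1)
        assert np.all(res.tree.branch_lengths[res.tree.edges] <= 1e-6)

    def test_optimizer_determinism(self, small_tree):
        aln = simulate_nucleotide(small_tree, DEFAULT_GTR, discrete_gamma(0.5, 10), 400, 21)
        r1 = fit_nucleotide(aln, small_tree, n_starts=2, seed=3)
        r2 = fit_nucleotide(aln, small_tree, n_starts=2, seed=3)
        assert r1.lnL == r2.lnL
        assert np.array_equal(r1.tree.branch_lengths, r2.tree.branch_lengths)


class TestFitPartitioned:
    def test_single_partition_equals_plain_fit(self, small_tree):
        aln = simulate_nucleotide(small_tree, DEFAULT_GTR, discrete_gamma(0.5, 10), 300, 31)
        scheme = PartitionScheme([("all", np.arange(1, 301))])
        part = fit_partitioned(aln, small_tree, scheme, ModelSpec("NUC_GTRG"), n_starts=1)
        plain = fit_nucleotide(aln, small_tree, n_starts=1)
        assert part.lnL == pytest.approx(plain.lnL, abs=1e-6)

    def test_locus_names_preserved_in_order(self, small_tree):
        aln = simulate_nucleotide(small_tree, DEFAULT_GTR, None, 90, 32)
        scheme = PartitionScheme(
            [("18S", np.arange(1, 31)), ("ITS", np.arange(31, 61)), ("28S", np.arange(61, 91))]
        )
        part = fit_partitioned(aln, small_tree, scheme, ModelSpec("NUC_GTRG"), n_starts=1)
        assert part.partition_names == ["18S", "ITS", "28S"]
        assert len(part.fits) == 3

    def test_third_position_rate_ratio_recovered(self, small_tree):
        # simulate positions 1,2 at rate 1 and position 3 at rate 3 by
        # splicing two simulations, then refit per position
        slow = simulate_nucleotide(small_tree, DEFAULT_GTR, None, 2000, 41)
        fast_tree = small_tree.with_branch_lengths(small_tree.branch_lengths * 3.0)
        fast = simulate_nucleotide(fast_tree, DEFAULT_GTR, None, 1000, 42)
        mat = np.empty((5, 3000), dtype="<U1")
        mat[:, 0::3] = slow.matrix[:, :1000]
        mat[:, 1::3] = slow.matrix[:, 1000:]
        mat[:, 2::3] = fast.matrix
        caln = Alignment(slow.taxa, ["".join(r) for r in mat])
        scheme = PartitionScheme(
            [(f"pos{k+1}", np.arange(k + 1, 3001, 3)) for k in range(3)]
        )
        part = fit_partitioned(caln, small_tree, scheme, ModelSpec("NUC_GTRG"), n_starts=1)
        tls = [f.tree.branch_lengths.sum() for f in part.fits]
        assert tls[2] / tls[0] == pytest.approx(3.0, rel=0.25)
        assert tls[1] / tls[0] == pytest.approx(1.0, rel=0.25)


class TestCodonBranchModels:
    def test_omega_class_layouts(self, small_tree):
        m0, n0 = omega_class_of_edges(small_tree, "CODON_M0")
        b2, n2 = omega_class_of_edges(small_tree, "CODON_B2")
        b3, n3 = omega_class_of_edges(small_tree, "CODON_B3")
        fb, nf = omega_class_of_edges(small_tree, "CODON_FB")
        assert (n0, n2, n3, nf) == (1, 2, 3, len(small_tree.edges))
        assert set(m0.values()) == {0}
        out_edges = small_tree.clade_edges(OUTGROUP)
        assert all(b2[e] == 1 for e in out_edges)
        assert all(b3[e] == 2 for e in out_edges)

    def test_nesting_chain_of_likelihoods(self, small_tree, uniform_codon_model):
        omega = {LICHENIZED: 0.02, NON_LICHENIZED: 0.06, OUTGROUP: 0.06}
        aln = simulate_codon(small_tree, uniform_codon_model, omega, 400, 51)
        m0 = fit_codon(aln, small_tree, ModelSpec("CODON_M0"), n_starts=1)
        b2 = fit_codon(aln, small_tree, ModelSpec("CODON_B2"), n_starts=1, warm=m0)
        b3 = fit_codon(aln, small_tree, ModelSpec("CODON_B3"), n_starts=1, warm=b2)
        fb = fit_codon(aln, small_tree, ModelSpec("CODON_FB"), n_starts=1, warm=b3)
        tol = 1e-4
        assert b2.lnL >= m0.lnL - tol
        assert b3.lnL >= b2.lnL - tol
        assert fb.lnL >= b3.lnL - tol

    def test_fit_nested_escalates_to_satisfy_nesting(self, small_tree, uniform_codon_model):
        omega = {LICHENIZED: 0.05, NON_LICHENIZED: 0.05, OUTGROUP: 0.05}
        aln = simulate_codon(small_tree, uniform_codon_model, omega, 250, 52)
        null, alt = fit_nested(aln, small_tree, ModelSpec("CODON_M0"), ModelSpec("CODON_B3"),
                               n_starts=1)
        assert alt.lnL >= null.lnL - 1e-4


class TestBranchSitePower:
    def test_positive_selection_detected_above_null_rate(self, uniform_codon_model):
        # omega2 = 4 on ~10% of sites in the foreground clade: the
        # bsA-vs-bsA1 LRT must reject far more often than its nominal size
        from redking import TwoCladeDesign, make_two_clade_topology
        from redking.models import BranchSiteParams
        from redking.simulate import simulate_branch_site
        from redking.stats import lrt
        from redking.fit import fit_branch_site

        design = TwoCladeDesign(3, 3, True, 0.12, 1.0, seed=3)
        tree = make_two_clade_topology(design)
        params = BranchSiteParams(p0=0.65, p1=0.25, omega0=0.1, omega2=4.0,
                                  foreground=LICHENIZED)
        hits = 0
        n_genes = 5
        for g in range(n_genes):
            aln, _ = simulate_branch_site(tree, params, uniform_codon_model,
                                          300, [3, g])
            null = fit_branch_site(aln, tree, LICHENIZED, alternative=False,
                                   n_starts=1, seed=g)
            alt = fit_branch_site(aln, tree, LICHENIZED, alternative=True,
                                  n_starts=1, seed=g, warm=null)
            res = lrt(null.lnL, max(alt.lnL, null.lnL), df=1)
            if res.p < 0.05:
                hits += 1
                assert alt.params["omega2"] > 1.0
        assert hits >= 2  # power clearly above the 5% size


class TestBranchDnDs:
    def _neutral_fit(self, tree, codon_model):
        omega_by_edge = {e: 1.0 for e in tree.edges}
        return FitResult(
            spec="CODON_FB", lnL=0.0,
            params={"kappa": codon_model.kappa, "codon_freqs": codon_model.codon_freqs,
                    "omega_by_edge": omega_by_edge, "omegas": np.ones(len(tree.edges))},
            tree=tree, branch_stats=None, convergence={},
        )

    def test_neutral_omega_identity(self, small_tree, uniform_codon_model):
        stats = branch_dn_ds(self._neutral_fit(small_tree, uniform_codon_model))
        assert np.allclose(stats["omega"], 1.0, atol=1e-8)

    def test_zero_length_branch_has_zero_dn_ds(self, small_tree, uniform_codon_model):
        tree = small_tree.with_branch_lengths(np.zeros(small_tree.n_nodes))
        stats = branch_dn_ds(self._neutral_fit(tree, uniform_codon_model))
        assert np.all(stats["dN"] == 0) and np.all(stats["dS"] == 0)

    def test_flow_partition_matches_stochastic_mapping(self, uniform_codon_model):
        # classify jumps of the embedded chain: the non-synonymous fraction
        # of substitutions must match the generator's flow partition
        omega = 0.3
        Q = build_codon_Q(uniform_codon_model, omega)
        pi = uniform_codon_model.codon_freqs
        flow = pi[:, None] * Q
        total = flow[CODON_DIFF1].sum()
        rho_N = flow[CODON_NONSYN].sum() / total
        rng = np.random.default_rng(17)
        jump = Q.copy()
        np.fill_diagonal(jump, 0.0)
        jump /= jump.sum(axis=1, keepdims=True)
        n_events, nonsyn = 50_000, 0
        state = rng.choice(N_CODONS, p=pi)
        for _ in range(n_events):
            nxt = rng.choice(N_CODONS, p=jump[state])
            nonsyn += int(CODON_NONSYN[state, nxt])
            state = nxt
        p_hat = nonsyn / n_events
        se = np.sqrt(rho_N * (1 - rho_N) / n_events)
        # the embedded chain is not started in the flow-weighted state
        # distribution; allow a small extra slack beyond 3 SE
        assert abs(p_hat - rho_N) < 3 * se + 0.01

    def test_site_counts_sum_to_three(self, uniform_codon_model):
        N, S = synonymous_site_fraction(uniform_codon_model)
        assert N + S == pytest.approx(3.0)
        assert 0 < S < N  # most random single-base changes are non-synonymous
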