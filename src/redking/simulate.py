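"""Synthetic two-clade gene sets with known evolutionary parameters.

Emulates the study design: a lichenized clade and a non-lichenized sister
clade of equal size plus an outgroup tip, joined at a basal trifurcation.
Branch lengths are drawn from an exponential law; all lichenized-clade
branches (including the stem) are multiplied by a clade-level rate
multiplier, so a multiplier below 1 makes the lichenized clade the slower
one.  Gene sets share one topology; per-gene rate spread is modelled by a
mean-preserving lognormal rescaling of all branch lengths.

Every simulated gene carries a ground-truth record (model, parameters,
derived child seed) so downstream estimators can be validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, CodonAlignment, write_fasta
from .models import (
    BranchSiteParams,
    CodonModelParams,
    GammaMixture,
    GTRParams,
    ModelError,
    N_CODONS,
    NT,
    SENSE_CODONS,
    SpectralQ,
    build_codon_Q,
    build_gtr_Q,
    discrete_gamma,
)
from .trees import CladeTree, LICHENIZED, NON_LICHENIZED, OUTGROUP


class DesignError(ValueError):
    """Invalid synthetic-study design."""


@dataclass
class TwoCladeDesign:
    """Shape and rates of the synthetic two-clade study.

    clade_rate_multiplier scales every lichenized-clade branch length; the
    paper-style comparison uses equal tip counts in the two clades to avoid
    node-density artefacts.
    """

    n_lichen_tips: int = 5
    n_nonlichen_tips: int = 5
    include_outgroup: bool = True
    branch_length_mean: float = 0.1
    clade_rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lichen_tips < 2 or self.n_nonlichen_tips < 2:
            raise DesignError("each clade needs at least 2 tips")
        if self.clade_rate_multiplier <= 0:
            raise DesignError("clade_rate_multiplier must be positive")
        if self.branch_length_mean <= 0:
            raise DesignError("branch_length_mean must be positive")
        if not self.include_outgroup:
            raise DesignError(
                "the two-clade design requires the outgroup tip (the basal "
                "trifurcation joins outgroup, lichenized and non-lichenized clades)"
            )


def make_two_clade_topology(design: TwoCladeDesign, rng: np.random.Generator | None = None) -> CladeTree:
    """Build the constrained two-clade topology with random branch lengths.

    Each clade is a pectinate (ladder) subtree; the basal node joins the
    outgroup tip (if present), the lichenized clade and the non-lichenized
    clade as a trifurcation.  Branch lengths are iid Exponential with mean
    ``branch_length_mean``.  When the two clades have equal tip counts
    (the study's balanced design), the lichenized clade inherits the
    mirrored branch-length draws of its sister clade, so the
    ``clade_rate_multiplier`` (applied to every lichenized-clade branch,
    stem included) is the only systematic rate difference between the two
    clades; with unequal tip counts the draws are independent.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    nl, nn = design.n_lichen_tips, design.n_nonlichen_tips
    tip_labels = [f"L{i+1}" for i in range(nl)] + [f"N{i+1}" for i in range(nn)]
    if design.include_outgroup:
        tip_labels.append("OUT")
    n_tips = len(tip_labels)
    # internal nodes: clade roots and ladder nodes; root is the last index
    parent_links: dict[int, int] = {}
    next_idx = [n_tips]

    def build_clade(tips: list[int]) -> tuple[int, list[int]]:
        """Pectinate subtree over ``tips``; returns (root, edge order:
        pendant edges in tip order, then ladder internals root-last —
        the clade root's own edge is the stem)."""
        node = tips[0]
        created: list[int] = []
        for t in tips[1:]:
            anc = next_idx[0]
            next_idx[0] += 1
            parent_links[node] = anc
            parent_links[t] = anc
            created.append(anc)
            node = anc
        return node, list(tips) + created

    lichen_root, lichen_edges = build_clade(list(range(nl)))
    nonlichen_root, nonlichen_edges = build_clade(list(range(nl, nl + nn)))
    root = next_idx[0]
    next_idx[0] += 1
    parent_links[lichen_root] = root
    parent_links[nonlichen_root] = root
    parent_links[n_tips - 1] = root  # outgroup tip

    n_nodes = next_idx[0]
    parent = np.full(n_nodes, -1, dtype=int)
    for child, anc in parent_links.items():
        parent[child] = anc
    blens = rng.exponential(design.branch_length_mean, size=n_nodes)
    if nl == nn:
        # balanced design: mirror the sister clade's draws branch-for-branch
        for le, ne in zip(lichen_edges, nonlichen_edges):
            blens[le] = blens[ne]
    blens[root] = 0.0
    for e in lichen_edges:
        blens[e] *= design.clade_rate_multiplier
    clade_map = {t: (LICHENIZED if t.startswith("L") else NON_LICHENIZED) for t in tip_labels}
    if design.include_outgroup:
        clade_map["OUT"] = OUTGROUP
    return CladeTree(parent, blens, tip_labels, clade_map)


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve(tree: CladeTree, P_by_edge_and_group, root_freqs: np.ndarray,
            group_of_site: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Simulate states down the tree.

    ``P_by_edge_and_group[(edge, g)]`` is the transition matrix used on
    ``edge`` for sites in group ``g`` (rate category or site class).
    Returns (n_nodes, n_sites) integer states; rows for internal nodes are
    intermediate states, tips are the output.
    """
    n_sites = len(group_of_site)
    n_states = len(root_freqs)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(n_states, size=n_sites, p=root_freqs)
    for v in tree.preorder:
        if v == tree.root:
            continue
        parent_states = states[tree.parent[v]]
        out = np.empty(n_sites, dtype=np.int64)
        for g in np.unique(group_of_site):
            mask = group_of_site == g
            P = P_by_edge_and_group[(v, int(g))]
            cum = np.cumsum(P[parent_states[mask]], axis=1)
            u = rng.random(mask.sum())
            out[mask] = (u[:, None] > cum).sum(axis=1)
        states[v] = out
    return states


def simulate_nucleotide(
    tree: CladeTree,
    gtr: GTRParams,
    gamma: GammaMixture | None,
    n_sites: int,
    seed: int | list[int],
) -> Alignment:
    """Evolve a nucleotide alignment under GTR(+discrete-gamma).

    Each site draws a gamma rate category, a root state from the stationary
    frequencies, and then evolves along every branch by the category-scaled
    transition matrices.  Deterministic for a fixed seed.
    """
    if n_sites < 1:
        raise DesignError("n_sites must be >= 1")
    if np.any(tree.branch_lengths[tree.edges] < 0):
        raise ModelError("tree has negative branch lengths")
    rng = np.random.default_rng(seed)
    sq = SpectralQ(build_gtr_Q(gtr), gtr.base_freqs)
    rates = gamma.rates if gamma is not None else np.ones(1)
    weights = gamma.weights if gamma is not None else np.ones(1)
    cats = rng.choice(len(rates), size=n_sites, p=weights)
    P = {
        (e, g): sq.transition_matrix(rates[g] * tree.branch_lengths[e])
        for e in tree.edges
        for g in range(len(rates))
    }
    states = _evolve(tree, P, gtr.base_freqs, cats, rng)
    seqs = ["".join(NT[s] for s in states[i]) for i in range(tree.n_tips)]
    return Alignment(tree.tip_labels, seqs, alphabet="nt")


def _omega_by_edge_from_map(tree: CladeTree, branch_omega) -> dict[int, float]:
    """Accept either an edge->omega dict or a clade->omega dict."""
    if all(isinstance(k, str) for k in branch_omega):
        edge_clades = tree.edge_clades()
        missing = sorted(set(edge_clades.values()) - set(branch_omega))
        if missing:
            raise DesignError(f"clades without omega assignment: {missing}")
        return {e: float(branch_omega[c]) for e, c in edge_clades.items()}
    out = {int(e): float(w) for e, w in branch_omega.items()}
    missing = [e for e in tree.edges if e not in out]
    if missing:
        raise DesignError(f"edges without omega assignment: {missing}")
    return out


def simulate_codon(
    tree: CladeTree,
    codon_model: CodonModelParams,
    branch_omega,
    n_codons: int,
    seed: int | list[int],
) -> CodonAlignment:
    """Evolve a codon alignment under a GY94-type model with per-branch
    omega (``branch_omega`` maps edges, or clade names, to omega)."""
    if n_codons < 1:
        raise DesignError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    omega_by_edge = _omega_by_edge_from_map(tree, branch_omega)
    spectral = {}
    P = {}
    for e in tree.edges:
        om = omega_by_edge[e]
        if om not in spectral:
            spectral[om] = SpectralQ(build_codon_Q(codon_model, om), codon_model.codon_freqs)
        P[(e, 0)] = spectral[om].transition_matrix(tree.branch_lengths[e])
    states = _evolve(tree, P, codon_model.codon_freqs, np.zeros(n_codons, dtype=int), rng)
    seqs = ["".join(SENSE_CODONS[s] for s in states[i]) for i in range(tree.n_tips)]
    return CodonAlignment(tree.tip_labels, seqs)


def simulate_branch_site(
    tree: CladeTree,
    params: BranchSiteParams,
    codon_model: CodonModelParams,
    n_codons: int,
    seed: int | list[int],
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment under the branch-site mixture.

    Each codon column draws a latent site class (0, 1, 2a, 2b) iid;
    foreground branches use the class's foreground omega, background
    branches the background omega.  All classes of a branch share the
    mixture-averaged rate scale, so a branch length is the expected number
    of substitutions per codon averaged over site classes.  Returns the
    alignment and the per-column class labels (the simulation truth).
    """
    if n_codons < 1:
        raise DesignError("n_codons must be >= 1")
    fg = set(tree.clade_edges(params.foreground, include_stem=True))
    if not fg:
        raise DesignError(f"foreground clade {params.foreground!r} has no branches")
    rng = np.random.default_rng(seed)
    props = params.proportions
    classes = rng.choice(4, size=n_codons, p=props)
    from .models import branch_site_scales

    scale_fg, scale_bg = branch_site_scales(codon_model, props,
                                            params.omega0, params.omega2)
    spectral = {}

    def sq(om: float) -> SpectralQ:
        if om not in spectral:
            spectral[om] = SpectralQ(
                build_codon_Q(codon_model, om, normalize=False),
                codon_model.codon_freqs,
            )
        return spectral[om]

    P = {}
    omegas = params.class_omegas()
    for e in tree.edges:
        scale = scale_fg if e in fg else scale_bg
        for g, (bg_om, fg_om) in enumerate(omegas):
            om = fg_om if e in fg else bg_om
            P[(e, g)] = sq(om).transition_matrix(tree.branch_lengths[e] / scale)
    states = _evolve(tree, P, codon_model.codon_freqs, classes, rng)
    seqs = ["".join(SENSE_CODONS[s] for s in states[i]) for i in range(tree.n_tips)]
    return CodonAlignment(tree.tip_labels, seqs), classes


# ---------------------------------------------------------------------------
# gene sets


DEFAULT_GTR = GTRParams(
    exchangeabilities=np.array([1.5, 4.0, 1.0, 1.2, 4.5, 1.0]),
    base_freqs=np.array([0.27, 0.23, 0.24, 0.26]),
)
DEFAULT_ALPHA = 0.5


def child_seed(root_seed: int, gene_index: int) -> list[int]:
    """Per-gene RNG seed derived from the root seed by a fixed splitting
    rule (seed sequence [root_seed, gene_index])."""
    return [int(root_seed), int(gene_index)]


def simulate_gene_set(
    design: TwoCladeDesign,
    n_genes: int,
    mean_sites: int = 900,
    model: str = "nucleotide",
    gtr: GTRParams | None = None,
    alpha: float = DEFAULT_ALPHA,
    codon_model: CodonModelParams | None = None,
    clade_omega: dict[str, float] | None = None,
    rate_spread_sigma: float = 0.3,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[CladeTree, dict[str, Alignment], pd.DataFrame]:
    """Simulate a set of independent gene alignments on one shared topology.

    Per-gene rate variation: all branch lengths are rescaled by a
    mean-preserving lognormal factor exp(N(-sigma^2/2, sigma^2)).  Gene
    lengths are drawn uniformly in [0.75, 1.25] * mean_sites (rounded to
    whole codons for codon models).  Returns the base tree, a gene ->
    alignment dict and the ground-truth table; optionally writes FASTA
    files, the annotated Newick tree, a truth TSV and a JSON manifest.
    """
    if n_genes < 1:
        raise DesignError("n_genes must be >= 1")
    root_seed = design.seed if seed is None else seed
    rng = np.random.default_rng([root_seed, 990001])
    tree = make_two_clade_topology(design, rng)
    gtr = gtr or DEFAULT_GTR
    if model == "codon":
        if codon_model is None:
            freqs = np.full(N_CODONS, 1.0 / N_CODONS)
            codon_model = CodonModelParams(kappa=2.5, codon_freqs=freqs)
        clade_omega = clade_omega or {
            LICHENIZED: 0.05, NON_LICHENIZED: 0.05, OUTGROUP: 0.05,
        }
    gamma = discrete_gamma(alpha, 10) if model == "nucleotide" else None
    alignments: dict[str, Alignment] = {}
    truth_rows = []
    for g in range(n_genes):
        gene = f"gene{g+1:04d}"
        cseed = child_seed(root_seed, g)
        grng = np.random.default_rng(cseed + [7])
        scale = float(np.exp(grng.normal(-rate_spread_sigma**2 / 2, rate_spread_sigma)))
        gtree = tree.with_branch_lengths(tree.branch_lengths * scale)
        if model == "nucleotide":
            n_sites = int(grng.integers(int(0.75 * mean_sites), int(1.25 * mean_sites) + 1))
            n_sites -= n_sites % 3
            aln = simulate_nucleotide(gtree, gtr, gamma, n_sites, cseed + [11])
            params = {"alpha": alpha, "scale": scale}
            length = n_sites
        elif model == "codon":
            n_cod = max(1, int(grng.integers(int(0.75 * mean_sites), int(1.25 * mean_sites) + 1)) // 3)
            aln = simulate_codon(gtree, codon_model, clade_omega, n_cod, cseed + [11])
            params = {"kappa": codon_model.kappa, "scale": scale, **{f"omega_{k}": v for k, v in clade_omega.items()}}
            length = n_cod
        else:
            raise DesignError(f"unknown model {model!r}")
        alignments[gene] = aln
        truth_rows.append(
            {
                "gene_id": gene,
                "model": model,
                "length": length,
                "seed": ":".join(map(str, cseed)),
                "tree_scale": scale,
                "true_params": json.dumps(params, sort_keys=True),
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "alignments").mkdir(exist_ok=True)
        for gene, aln in alignments.items():
            write_fasta(aln, out / "alignments" / f"{gene}.fasta")
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        pd.DataFrame(
            [{"tip": t, "clade": c} for t, c in tree.clade_map.items()]
        ).to_csv(out / "clade_map.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest = {
            "design": {
                "n_lichen_tips": design.n_lichen_tips,
                "n_nonlichen_tips": design.n_nonlichen_tips,
                "branch_length_mean": design.branch_length_mean,
                "clade_rate_multiplier": design.clade_rate_multiplier,
            },
            "n_genes": n_genes,
            "model": model,
            "seed": root_seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return tree, alignments, truth
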