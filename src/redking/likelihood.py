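"""Phylogenetic likelihood by the pruning algorithm.

Supports nucleotide, amino-acid and codon state spaces, discrete-gamma rate
mixtures, branch-heterogeneous codon generators (per-branch omega classes),
branch-site mixtures and IUPAC/gap missing-data states.  Likelihoods are
computed on compressed site patterns with per-pattern max-scaling, so the
log-likelihood is finite for any valid input.

The tree is evaluated with its virtual root at the basal trifurcation; for
the reversible models used here the result is independent of that choice
(pulley principle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, CodonAlignment, MISSING_CODON
from .models import (
    AA,
    AA_AMBIG,
    AA_INDEX,
    CODON_INDEX,
    GammaMixture,
    IUPAC_NT,
    N_CODONS,
    NT,
    NT_INDEX,
    SpectralQ,
)
from .trees import CladeTree


class BindingError(ValueError):
    """Alignment and tree do not match."""


def tip_partials(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Tip partial-likelihood tensor on compressed site patterns.

    Returns (partials, weights): partials has shape
    (n_taxa, n_states, n_patterns) with 1.0 for every state compatible with
    the observed symbol (all ones for fully missing data), and weights the
    multiplicity of each pattern.
    """
    if isinstance(aln, CodonAlignment):
        codons = aln.codon_matrix()
        n_states = N_CODONS
        cols, weights = np.unique(codons, axis=1, return_counts=True)
        part = np.zeros((aln.n_taxa, n_states, cols.shape[1]))
        for ti in range(aln.n_taxa):
            for pi_, codon in enumerate(cols[ti]):
                if codon == MISSING_CODON:
                    part[ti, :, pi_] = 1.0
                else:
                    part[ti, CODON_INDEX[codon], pi_] = 1.0
        return part, weights.astype(float)

    if aln.alphabet == "nt":
        symbols, ambig, index, n_states = NT, IUPAC_NT, NT_INDEX, 4
    else:
        symbols, ambig, index, n_states = AA, AA_AMBIG, AA_INDEX, 20
    cols, weights = np.unique(aln.matrix, axis=1, return_counts=True)
    part = np.zeros((aln.n_taxa, n_states, cols.shape[1]))
    for ti in range(aln.n_taxa):
        for pi_, sym in enumerate(cols[ti]):
            if sym in index:
                part[ti, index[sym], pi_] = 1.0
            else:
                for s in ambig[sym]:
                    part[ti, index[s], pi_] = 1.0
    return part, weights.astype(float)


def _check_binding(aln: Alignment, tree: CladeTree) -> list[int]:
    """Map tree tip index -> alignment row."""
    rows = {t: i for i, t in enumerate(aln.taxa)}
    missing = [t for t in tree.tip_labels if t not in rows]
    extra = [t for t in aln.taxa if t not in set(tree.tip_labels)]
    if missing or extra:
        raise BindingError(
            f"tree/alignment taxa mismatch (missing from alignment: {missing}; "
            f"not in tree: {extra})"
        )
    return [rows[t] for t in tree.tip_labels]


def prune_patterns(
    tree: CladeTree,
    tip_part: np.ndarray,
    P_by_edge: dict[int, np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihood for one rate/site class.

    ``P_by_edge`` maps each non-root node index to the transition matrix of
    the edge above it.  Uses per-pattern max scaling in log space.
    """
    n_states, n_pat = tip_part.shape[1], tip_part.shape[2]
    partial = np.empty((tree.n_nodes, n_states, n_pat))
    logscale = np.zeros(n_pat)
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            partial[v] = tip_part[v]
            continue
        acc = np.ones((n_states, n_pat))
        for c in kids:
            acc *= P_by_edge[c] @ partial[c]
        smax = acc.max(axis=0)
        smax[smax == 0.0] = 1.0  # impossible pattern; log(0) surfaces at root
        acc /= smax
        logscale += np.log(smax)
        partial[v] = acc
    site_like = pi @ partial[tree.root]
    with np.errstate(divide="ignore"):
        return np.log(site_like) + logscale


def _mixture_loglik(
    tree: CladeTree,
    tip_part: np.ndarray,
    weights: np.ndarray,
    components: list[tuple[float, dict[int, np.ndarray]]],
    pi: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Log-likelihood of an equal-alphabet mixture (gamma categories or
    branch-site classes), combined per pattern with logsumexp."""
    logs = np.stack(
        [np.log(w) + prune_patterns(tree, tip_part, P, pi) for w, P in components]
    )
    m = logs.max(axis=0)
    site_logl = m + np.log(np.exp(logs - m).sum(axis=0))
    return float(site_logl @ weights), site_logl


@dataclass
class LikelihoodResult:
    loglik: float
    site_loglik: np.ndarray  # per pattern
    pattern_weights: np.ndarray


def loglikelihood(
    aln: Alignment,
    tree: CladeTree,
    model,
    mixture: GammaMixture | None = None,
    omega_by_edge: dict[int, float] | None = None,
    branch_site=None,
) -> LikelihoodResult:
    """Total and per-pattern log-likelihood.

    ``model`` is a GTRParams, EmpiricalAAModel, or CodonModelParams (codon
    models additionally need ``omega_by_edge`` or ``branch_site``);
    ``mixture`` adds discrete-gamma rate heterogeneity (nucleotide /
    amino-acid data).
    """
    from .models import (
        CodonModelParams,
        EmpiricalAAModel,
        GTRParams,
        build_aa_Q,
        build_codon_Q,
        build_gtr_Q,
    )

    order = _check_binding(aln, tree)
    part, weights = tip_partials(aln)
    part = part[order]

    if isinstance(model, CodonModelParams):
        pi = model.codon_freqs
        if branch_site is not None:
            from .models import branch_site_scales

            fg = set(tree.clade_edges(branch_site.foreground, include_stem=True))
            props = branch_site.proportions
            scale_fg, scale_bg = branch_site_scales(
                model, props, branch_site.omega0, branch_site.omega2
            )
            spectral: dict[float, SpectralQ] = {}

            def sq(omega: float) -> SpectralQ:
                if omega not in spectral:
                    spectral[omega] = SpectralQ(
                        build_codon_Q(model, omega, normalize=False), pi
                    )
                return spectral[omega]

            components = []
            for w, (bg_om, fg_om) in zip(props, branch_site.class_omegas()):
                if w <= 0:
                    continue
                P = {
                    e: sq(fg_om if e in fg else bg_om).transition_matrix(
                        tree.branch_lengths[e]
                        / (scale_fg if e in fg else scale_bg)
                    )
                    for e in tree.edges
                }
                components.append((w, P))
            total, site = _mixture_loglik(tree, part, weights, components, pi)
            return LikelihoodResult(total, site, weights)

        if omega_by_edge is None:
            raise ValueError("codon likelihood needs omega_by_edge or branch_site")
        missing = [e for e in tree.edges if e not in omega_by_edge]
        if missing:
            raise ValueError(f"edges without omega assignment: {missing}")
        spectral = {}
        P_by_edge = {}
        for e in tree.edges:
            om = float(omega_by_edge[e])
            if om not in spectral:
                spectral[om] = SpectralQ(build_codon_Q(model, om), pi)
            P_by_edge[e] = spectral[om].transition_matrix(tree.branch_lengths[e])
        site = prune_patterns(tree, part, P_by_edge, pi)
        return LikelihoodResult(float(site @ weights), site, weights)

    if isinstance(model, GTRParams):
        pi = model.base_freqs
        Q = build_gtr_Q(model)
    elif isinstance(model, EmpiricalAAModel):
        pi = model.aa_freqs
        Q = build_aa_Q(model)
    else:
        raise TypeError(f"unsupported model type: {type(model).__name__}")
    sq_ = SpectralQ(Q, pi)
    if mixture is None or mixture.ncat == 1:
        P = {e: sq_.transition_matrix(tree.branch_lengths[e]) for e in tree.edges}
        site = prune_patterns(tree, part, P, pi)
        return LikelihoodResult(float(site @ weights), site, weights)
    components = []
    for r, w in zip(mixture.rates, mixture.weights):
        P = {e: sq_.transition_matrix(r * tree.branch_lengths[e]) for e in tree.edges}
        components.append((w, P))
    total, site = _mixture_loglik(tree, part, weights, components, pi)
    return LikelihoodResult(total, site, weights)
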