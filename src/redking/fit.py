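"""Maximum-likelihood model fitting on the constrained topology.

All fits keep the topology fixed and jointly maximize branch lengths and
the global model parameters by bounded quasi-Newton (L-BFGS-B) on
log/logit-transformed parameters, with a configurable multi-start policy.
Model menu:

==============  ============================================================
NUC_GTRG        GTR + discrete-gamma(10) nucleotide model, observed
                base frequencies, alpha estimated
AA_EMP          empirical amino-acid model (BLOSUM62-derived
                exchangeabilities, observed "+F" frequencies)
CODON_M0        one omega for the whole tree
CODON_B2        two omegas: both study clades share one, outgroup the other
CODON_B3        three omegas: lichenized / non-lichenized / outgroup
CODON_FB        free-ratio: one omega per branch
CODON_BSA       branch-site model A (foreground omega2 >= 1 free)
CODON_BSA1      its null (omega2 fixed at 1)
==============  ============================================================

Codon frequencies are F3X4-estimated from each gene and held fixed; kappa
is estimated by ML.  Codon branch lengths are in expected substitutions per
codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .alignment import (
    Alignment,
    CodonAlignment,
    PartitionScheme,
    aa_counts,
    base_counts,
    position_nucleotide_counts,
)
from .likelihood import _check_binding, tip_partials
from .models import (
    CODON_NONSYN,
    CodonModelParams,
    EmpiricalAAModel,
    GTRParams,
    SpectralQ,
    blosum62_exchangeabilities,
    build_codon_Q,
    discrete_gamma,
    f3x4_frequencies,
)
from .trees import CladeTree, LICHENIZED, NON_LICHENIZED, OUTGROUP

NUC_SPECS = ("NUC_GTRG",)
AA_SPECS = ("AA_EMP",)
CODON_BRANCH_SPECS = ("CODON_M0", "CODON_B2", "CODON_B3", "CODON_FB")
BRANCH_SITE_SPECS = ("CODON_BSA", "CODON_BSA1")

LOG_BL_BOUNDS = (np.log(1e-8), np.log(50.0))
LOG_OMEGA_BOUNDS = (np.log(1e-6), np.log(999.0))
LOG_KAPPA_BOUNDS = (np.log(1e-3), np.log(100.0))
LOG_ALPHA_BOUNDS = (np.log(0.02), np.log(100.0))
LOG_EXCH_BOUNDS = (np.log(1e-4), np.log(1e4))


class OptimizationError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Which model to fit; branch-site specs need a foreground clade."""

    name: str
    foreground: str | None = None

    def __post_init__(self):
        known = NUC_SPECS + AA_SPECS + CODON_BRANCH_SPECS + BRANCH_SITE_SPECS
        if self.name not in known:
            raise ValueError(f"unknown model spec {self.name!r}")
        if self.name in BRANCH_SITE_SPECS and self.foreground is None:
            raise ValueError(f"{self.name} requires a foreground clade")


@dataclass
class FitResult:
    spec: str
    lnL: float
    params: dict
    tree: CladeTree
    branch_stats: pd.DataFrame | None
    convergence: dict

    def omega_by_edge(self) -> dict[int, float] | None:
        return self.params.get("omega_by_edge")


@dataclass
class PartitionedFitResult:
    partition_names: list[str]
    fits: list[FitResult]

    @property
    def lnL(self) -> float:
        return sum(f.lnL for f in self.fits)


def omega_class_of_edges(tree: CladeTree, spec_name: str) -> tuple[dict[int, int], int]:
    """Edge -> omega-class index for the codon branch models."""
    edge_clades = tree.edge_clades()
    if spec_name == "CODON_M0":
        return {e: 0 for e in tree.edges}, 1
    if spec_name == "CODON_B2":
        cls = {LICHENIZED: 0, NON_LICHENIZED: 0, OUTGROUP: 1}
        return {e: cls[c] for e, c in edge_clades.items()}, 2
    if spec_name == "CODON_B3":
        cls = {LICHENIZED: 0, NON_LICHENIZED: 1, OUTGROUP: 2}
        return {e: cls[c] for e, c in edge_clades.items()}, 3
    if spec_name == "CODON_FB":
        return {e: i for i, e in enumerate(tree.edges)}, len(tree.edges)
    raise ValueError(f"{spec_name} is not a codon branch model")


# ---------------------------------------------------------------------------
# shared pruning internals on pre-encoded data


def _prune_batch(tree: CladeTree, tip_part: np.ndarray, P_by_edge: dict[int, np.ndarray],
                 pi: np.ndarray) -> np.ndarray:
    """Per-component, per-pattern log-likelihood.

    tip_part: (n_tips, n_states, n_pat); P_by_edge[e]: (n_comp, n_states,
    n_states).  Components (rate categories or site classes) are pruned in
    one batched pass.
    """
    n_comp = next(iter(P_by_edge.values())).shape[0]
    n_states, n_pat = tip_part.shape[1], tip_part.shape[2]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros((n_comp, n_pat))
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            partial[v] = np.broadcast_to(tip_part[v], (n_comp, n_states, n_pat))
            continue
        acc = P_by_edge[kids[0]] @ partial[kids[0]]
        del partial[kids[0]]
        for c in kids[1:]:
            acc *= P_by_edge[c] @ partial[c]
            del partial[c]
        smax = acc.max(axis=1)
        smax[smax == 0.0] = 1.0
        acc = acc / smax[:, None, :]
        logscale += np.log(smax)
        partial[v] = acc
    site = np.einsum("s,csp->cp", pi, partial[tree.root])
    with np.errstate(divide="ignore"):
        return np.log(site) + logscale


def _mix_logsumexp(comp_logl: np.ndarray, weights: np.ndarray) -> np.ndarray:
    logw = np.log(weights)[:, None] + comp_logl
    m = logw.max(axis=0)
    safe = np.where(np.isfinite(m), m, 0.0)  # all-(-inf) column stays -inf
    with np.errstate(divide="ignore"):
        return safe + np.log(np.exp(logw - safe).sum(axis=0))


class _EncodedData:
    """Alignment bound to a tree, pattern-compressed once for many evals."""

    def __init__(self, aln: Alignment, tree: CladeTree):
        order = _check_binding(aln, tree)
        part, weights = tip_partials(aln)
        self.tip_part = part[order]
        self.weights = weights
        self.n_states = part.shape[1]
        self.n_sites = int(weights.sum())


def _heuristic_branch_init(data: _EncodedData, tree: CladeTree) -> np.ndarray:
    """Rough starting branch lengths from average pairwise mismatch."""
    # expected mismatch fraction between two random rows of the tip partials
    tp = data.tip_part
    n = tp.shape[0]
    dots = []
    for i in range(n):
        for j in range(i + 1, n):
            pi_ = tp[i] / tp[i].sum(axis=0, keepdims=True)
            pj_ = tp[j] / tp[j].sum(axis=0, keepdims=True)
            same = (pi_ * pj_).sum(axis=0)
            dots.append(float(1.0 - same @ data.weights / data.weights.sum()))
    mean_p = float(np.mean(dots)) if dots else 0.1
    init = max(1e-3, mean_p / max(2, int(np.log2(max(2, n)))))
    return np.full(len(tree.edges), init)


def _run_starts(objective, starts, bounds, maxiter=500):
    best = None
    reports = []
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        reports.append(
            {"lnL": -float(res.fun), "iterations": int(res.nit), "success": bool(res.success)}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise OptimizationError(f"non-finite likelihood at all starts: {reports}")
    convergence = {"starts": reports, "n_evals": None}
    return best, convergence


# ---------------------------------------------------------------------------
# nucleotide GTR + gamma


def fit_nucleotide(
    aln: Alignment,
    tree: CladeTree,
    ncat: int = 10,
    n_starts: int = 3,
    seed: int = 0,
    warm: FitResult | None = None,
) -> FitResult:
    """Fit GTR + discrete-gamma: branch lengths, 5 exchangeabilities
    (GT fixed at 1) and alpha; base frequencies observed from the data."""
    data = _EncodedData(aln, tree)
    edges = tree.edges
    ne = len(edges)
    counts = base_counts(aln)
    if counts.sum() == 0:
        raise OptimizationError("alignment has no unambiguous bases")
    freqs = np.maximum(counts / counts.sum(), 1e-6)
    freqs /= freqs.sum()

    def unpack(x):
        bl = np.exp(x[:ne])
        exch = np.concatenate([np.exp(x[ne : ne + 5]), [1.0]])
        alpha = float(np.exp(x[ne + 5]))
        return bl, exch, alpha

    sq_cache: dict[tuple, SpectralQ] = {}
    mix_cache: dict[float, object] = {}

    def objective(x):
        bl, exch, alpha = unpack(x)
        try:
            key = tuple(exch)
            if key not in sq_cache:
                from .models import build_gtr_Q

                sq_cache.clear() if len(sq_cache) > 64 else None
                sq_cache[key] = SpectralQ(build_gtr_Q(GTRParams(exch, freqs)), freqs)
            sq = sq_cache[key]
            if alpha not in mix_cache:
                if len(mix_cache) > 64:
                    mix_cache.clear()
                mix_cache[alpha] = discrete_gamma(alpha, ncat)
            mix = mix_cache[alpha]
        except Exception:
            return np.inf
        P = {
            e: sq.transition_matrices(bl[i] * mix.rates)
            for i, e in enumerate(edges)
        }
        comp = _prune_batch(tree, data.tip_part, P, freqs)
        site = _mix_logsumexp(comp, mix.weights)
        val = float(site @ data.weights)
        return -val if np.isfinite(val) else np.inf

    bounds = [LOG_BL_BOUNDS] * ne + [LOG_EXCH_BOUNDS] * 5 + [LOG_ALPHA_BOUNDS]
    bl0 = np.log(_heuristic_branch_init(data, tree))
    starts = [np.concatenate([bl0, np.zeros(5), [np.log(0.5)]])]
    if warm is not None:
        starts.insert(0, warm.convergence["x"])
    rng = np.random.default_rng(seed)
    if n_starts >= 2:
        starts.append(np.concatenate([np.full(ne, np.log(0.1)), np.zeros(5), [np.log(1.0)]]))
    while len(starts) < n_starts:
        starts.append(
            np.concatenate(
                [
                    np.log(rng.uniform(0.01, 0.5, ne)),
                    np.log(rng.uniform(0.3, 3.0, 5)),
                    [np.log(rng.uniform(0.2, 2.0))],
                ]
            )
        )
    best, conv = _run_starts(objective, starts, bounds)
    bl, exch, alpha = unpack(best.x)
    conv["x"] = best.x
    fitted = tree.with_branch_lengths(_edge_lengths_to_nodes(tree, bl))
    return FitResult(
        spec="NUC_GTRG",
        lnL=-float(best.fun),
        params={"alpha": alpha, "exchangeabilities": exch, "base_freqs": freqs},
        tree=fitted,
        branch_stats=None,
        convergence=conv,
    )


def _edge_lengths_to_nodes(tree: CladeTree, bl: np.ndarray) -> np.ndarray:
    out = np.zeros(tree.n_nodes)
    for i, e in enumerate(tree.edges):
        out[e] = bl[i]
    return out


# ---------------------------------------------------------------------------
# empirical amino-acid model


def fit_aa(
    aln: Alignment,
    tree: CladeTree,
    n_starts: int = 2,
    seed: int = 0,
) -> FitResult:
    """Fit branch lengths under the empirical amino-acid model
    (exchangeabilities fixed, "+F" observed frequencies, no gamma)."""
    data = _EncodedData(aln, tree)
    edges = tree.edges
    ne = len(edges)
    counts = aa_counts(aln)
    if counts.sum() == 0:
        raise OptimizationError("alignment has no unambiguous residues")
    freqs = np.maximum(counts / counts.sum(), 1e-6)
    freqs /= freqs.sum()
    model = EmpiricalAAModel(blosum62_exchangeabilities(), freqs)
    from .models import build_aa_Q

    sq = SpectralQ(build_aa_Q(model), freqs)

    def objective(x):
        bl = np.exp(x)
        P = {e: sq.transition_matrices(np.array([bl[i]])) for i, e in enumerate(edges)}
        comp = _prune_batch(tree, data.tip_part, P, freqs)
        val = float(comp[0] @ data.weights)
        return -val if np.isfinite(val) else np.inf

    bounds = [LOG_BL_BOUNDS] * ne
    starts = [np.log(_heuristic_branch_init(data, tree))]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(np.log(rng.uniform(0.01, 0.5, ne)))
    best, conv = _run_starts(objective, starts, bounds)
    conv["x"] = best.x
    fitted = tree.with_branch_lengths(_edge_lengths_to_nodes(tree, np.exp(best.x)))
    return FitResult(
        spec="AA_EMP",
        lnL=-float(best.fun),
        params={"aa_freqs": freqs},
        tree=fitted,
        branch_stats=None,
        convergence=conv,
    )


# ---------------------------------------------------------------------------
# codon branch models


def fit_codon(
    aln: CodonAlignment,
    tree: CladeTree,
    spec: ModelSpec,
    n_starts: int = 3,
    seed: int = 0,
    warm: FitResult | None = None,
) -> FitResult:
    """Fit a GY94 branch model (M0 / two-omega / three-omega / free-ratio).

    Branch lengths, kappa and one omega per branch class are free; F3X4
    codon frequencies are estimated from the alignment and held fixed.
    """
    if spec.name not in CODON_BRANCH_SPECS:
        raise ValueError(f"{spec.name} is not a codon branch model")
    data = _EncodedData(aln, tree)
    edges = tree.edges
    ne = len(edges)
    class_of, n_classes = omega_class_of_edges(tree, spec.name)
    freqs = f3x4_frequencies(position_nucleotide_counts(aln))
    edge_class = np.array([class_of[e] for e in edges])

    def unpack(x):
        bl = np.exp(x[:ne])
        kappa = float(np.exp(x[ne]))
        omegas = np.exp(x[ne + 1 : ne + 1 + n_classes])
        return bl, kappa, omegas

    sq_cache: dict[tuple, SpectralQ] = {}

    def spectral(kappa: float, om: float) -> SpectralQ:
        key = (kappa, om)
        if key not in sq_cache:
            if len(sq_cache) > 128:
                sq_cache.clear()
            sq_cache[key] = SpectralQ(build_codon_Q(CodonModelParams(kappa, freqs), om), freqs)
        return sq_cache[key]

    def objective(x):
        bl, kappa, omegas = unpack(x)
        try:
            sqs = [spectral(kappa, om) for om in omegas]
        except Exception:
            return np.inf
        P = {
            e: sqs[edge_class[i]].transition_matrices(bl[i : i + 1])
            for i, e in enumerate(edges)
        }
        comp = _prune_batch(tree, data.tip_part, P, freqs)
        val = float(comp[0] @ data.weights)
        return -val if np.isfinite(val) else np.inf

    bounds = (
        [LOG_BL_BOUNDS] * ne + [LOG_KAPPA_BOUNDS] + [LOG_OMEGA_BOUNDS] * n_classes
    )
    bl0 = np.log(_heuristic_branch_init(data, tree))
    starts = [np.concatenate([bl0, [np.log(2.0)], np.full(n_classes, np.log(0.2))])]
    if warm is not None:
        starts.insert(0, _expand_codon_warm(warm, tree, spec, ne, n_classes, class_of))
    rng = np.random.default_rng(seed)
    if n_starts >= 2:
        starts.append(
            np.concatenate([np.full(ne, np.log(0.1)), [np.log(2.0)], np.full(n_classes, np.log(0.5))])
        )
    while len(starts) < n_starts:
        starts.append(
            np.concatenate(
                [
                    np.log(rng.uniform(0.01, 0.5, ne)),
                    [np.log(rng.uniform(0.5, 5.0))],
                    np.log(rng.uniform(0.02, 2.0, n_classes)),
                ]
            )
        )
    best, conv = _run_starts(objective, starts, bounds)
    bl, kappa, omegas = unpack(best.x)
    conv["x"] = best.x
    fitted = tree.with_branch_lengths(_edge_lengths_to_nodes(tree, bl))
    omega_by_edge = {e: float(omegas[class_of[e]]) for e in edges}
    params = {
        "kappa": kappa,
        "omegas": omegas,
        "omega_by_edge": omega_by_edge,
        "codon_freqs": freqs,
    }
    result = FitResult(spec.name, -float(best.fun), params, fitted, None, conv)
    result.branch_stats = branch_dn_ds(result)
    return result


def _expand_codon_warm(warm: FitResult, tree: CladeTree, spec: ModelSpec,
                       ne: int, n_classes: int, class_of: dict[int, int]) -> np.ndarray:
    """Map a restricted codon fit into the parameter vector of a richer
    model (shared branch lengths and kappa; class omegas inherited from the
    restricted fit's per-edge omegas)."""
    edges = tree.edges
    bl = np.array([warm.tree.branch_lengths[e] for e in edges])
    kappa = warm.params["kappa"]
    prev = warm.params["omega_by_edge"]
    omegas = np.empty(n_classes)
    for cls in range(n_classes):
        vals = [prev[e] for e in edges if class_of[e] == cls]
        omegas[cls] = np.mean(vals) if vals else 0.2
    return np.concatenate(
        [np.log(np.maximum(bl, 1e-8)), [np.log(kappa)], np.log(np.maximum(omegas, 1e-6))]
    )


# ---------------------------------------------------------------------------
# branch-site models


def fit_branch_site(
    aln: CodonAlignment,
    tree: CladeTree,
    foreground: str,
    alternative: bool,
    n_starts: int = 2,
    seed: int = 0,
    warm: FitResult | None = None,
) -> FitResult:
    """Fit branch-site model A (``alternative=True``) or its null.

    Site classes 0/1/2a/2b with proportions driven by (p0, p1); foreground
    branches take omega2 (free and >= 1 in the alternative, fixed at 1 in
    the null) in classes 2a/2b.  Shared branch lengths across classes.
    """
    data = _EncodedData(aln, tree)
    edges = tree.edges
    ne = len(edges)
    freqs = f3x4_frequencies(position_nucleotide_counts(aln))
    fg = set(tree.clade_edges(foreground, include_stem=True))
    if not fg:
        raise ValueError(f"foreground clade {foreground!r} has no branches")
    fg_mask = np.array([e in fg for e in edges])

    # x = [log bl (ne), log kappa, a, b, logit(omega0), (log(omega2-1))]
    def unpack(x):
        bl = np.exp(x[:ne])
        kappa = float(np.exp(x[ne]))
        a, b = x[ne + 1], x[ne + 2]
        z = np.exp([a, b, 0.0])
        z /= z.sum()
        p0, p1 = float(z[0]), float(z[1])
        omega0 = float(1.0 / (1.0 + np.exp(-x[ne + 3])))
        omega2 = float(1.0 + np.exp(x[ne + 4])) if alternative else 1.0
        return bl, kappa, p0, p1, omega0, omega2

    sq_cache: dict[tuple, SpectralQ] = {}

    def spectral(kappa: float, om: float) -> SpectralQ:
        # unnormalized generator: site classes share a per-branch
        # mixture-averaged scale instead of per-class normalization
        key = (kappa, om)
        if key not in sq_cache:
            if len(sq_cache) > 128:
                sq_cache.clear()
            sq_cache[key] = SpectralQ(
                build_codon_Q(CodonModelParams(kappa, freqs), om, normalize=False),
                freqs,
            )
        return sq_cache[key]

    def objective(x):
        bl, kappa, p0, p1, omega0, omega2 = unpack(x)
        try:
            sqs = {om: spectral(kappa, om) for om in {omega0, 1.0, omega2}}
        except Exception:
            return np.inf
        p2 = max(0.0, 1.0 - p0 - p1)
        denom = p0 + p1
        props = np.array([p0, p1, p2 * p0 / denom, p2 * p1 / denom])
        mus = {om: -float(freqs @ np.diag(sq.Q)) for om, sq in sqs.items()}
        scale_fg = (props[0] * mus[omega0] + props[1] * mus[1.0]
                    + (props[2] + props[3]) * mus[omega2])
        scale_bg = ((props[0] + props[2]) * mus[omega0]
                    + (props[1] + props[3]) * mus[1.0])
        scale = np.where(fg_mask, scale_fg, scale_bg)
        omega_pairs = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
        # per distinct omega, transition matrices for all edges in one batch
        P_om = {om: sq.transition_matrices(bl / scale) for om, sq in sqs.items()}
        P = {}
        for i, e in enumerate(edges):
            mats = [
                P_om[fg_om if fg_mask[i] else bg_om][i]
                for bg_om, fg_om in omega_pairs
            ]
            P[e] = np.stack(mats)
        comp = _prune_batch(tree, data.tip_part, P, freqs)
        keep = props > 0
        site = _mix_logsumexp(comp[keep], props[keep])
        val = float(site @ data.weights)
        return -val if np.isfinite(val) else np.inf

    bounds = (
        [LOG_BL_BOUNDS] * ne
        + [LOG_KAPPA_BOUNDS]
        + [(-15.0, 15.0)] * 2
        + [(-15.0, 8.0)]
        + ([(np.log(1e-6), np.log(998.0))] if alternative else [])
    )

    bl0 = np.log(_heuristic_branch_init(data, tree))
    base = np.concatenate(
        [bl0, [np.log(2.0)], [np.log(0.7 / 0.2), np.log(0.2 / 0.1)], [np.log(0.1 / 0.9)]]
    )
    starts = [np.concatenate([base, [np.log(1.0)]]) if alternative else base]
    if warm is not None:
        wx = np.array(warm.convergence["x"], dtype=float)
        if alternative and len(wx) == ne + 4:
            wx = np.concatenate([wx, [np.log(1e-3)]])  # omega2 just above 1
        elif not alternative and len(wx) == ne + 5:
            wx = wx[: ne + 4]
        starts.insert(0, wx)
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts + (1 if warm is not None else 0):
        extra = np.concatenate(
            [
                np.log(rng.uniform(0.01, 0.5, ne)),
                [np.log(rng.uniform(0.5, 5.0))],
                rng.normal(0, 1.5, 2),
                [rng.normal(-2, 1)],
            ]
        )
        if alternative:
            extra = np.concatenate([extra, [np.log(rng.uniform(0.1, 3.0))]])
        starts.append(extra)
    best, conv = _run_starts(objective, starts, bounds)
    bl, kappa, p0, p1, omega0, omega2 = unpack(best.x)
    conv["x"] = best.x
    fitted = tree.with_branch_lengths(_edge_lengths_to_nodes(tree, bl))
    params = {
        "kappa": kappa,
        "p0": p0,
        "p1": p1,
        "omega0": omega0,
        "omega2": omega2,
        "foreground": foreground,
        "codon_freqs": freqs,
    }
    name = "CODON_BSA" if alternative else "CODON_BSA1"
    return FitResult(name, -float(best.fun), params, fitted, None, conv)


# ---------------------------------------------------------------------------
# dispatch / partitioned / dN-dS


def fit(aln, tree: CladeTree, spec: ModelSpec, **kwargs) -> FitResult:
    """Fit any model of the menu (dispatch by spec name)."""
    if spec.name in NUC_SPECS:
        return fit_nucleotide(aln, tree, **kwargs)
    if spec.name in AA_SPECS:
        return fit_aa(aln, tree, **kwargs)
    if spec.name in CODON_BRANCH_SPECS:
        return fit_codon(aln, tree, spec, **kwargs)
    if spec.name in BRANCH_SITE_SPECS:
        return fit_branch_site(
            aln, tree, spec.foreground, alternative=(spec.name == "CODON_BSA"), **kwargs
        )
    raise ValueError(f"unknown spec {spec.name!r}")


def fit_partitioned(
    aln, tree: CladeTree, partitions: PartitionScheme, spec: ModelSpec, **kwargs
) -> PartitionedFitResult:
    """Independent fits per partition on the shared topology (separate
    branch lengths and alpha per partition)."""
    partitions.validate(aln.n_columns)
    fits = []
    for name, cols in partitions.partitions:
        idx = np.asarray(cols, int) - 1
        sub = Alignment(
            aln.taxa, ["".join(row) for row in aln.matrix[:, idx]], alphabet=aln.alphabet
        )
        fits.append(fit(sub, tree, spec, **kwargs))
    return PartitionedFitResult([name for name, _ in partitions.partitions], fits)


def fit_nested(aln, tree: CladeTree, null_spec: ModelSpec, alt_spec: ModelSpec,
               max_escalations: int = 2, **kwargs) -> tuple[FitResult, FitResult]:
    """Fit a nested model pair, warm-starting the general model from the
    restricted optimum and escalating restarts until lnL(alt) >= lnL(null)
    (up to optimizer tolerance)."""
    null = fit(aln, tree, null_spec, **kwargs)
    alt = fit(aln, tree, alt_spec, warm=null, **kwargs)
    seed = kwargs.pop("seed", 0)
    tries = 0
    while alt.lnL < null.lnL - 1e-4 and tries < max_escalations:
        tries += 1
        alt2 = fit(aln, tree, alt_spec, warm=null, seed=seed + 1000 + tries,
                   n_starts=2 + tries, **{k: v for k, v in kwargs.items() if k != "n_starts"})
        if alt2.lnL > alt.lnL:
            alt = alt2
    return null, alt


def synonymous_site_fraction(params: CodonModelParams) -> tuple[float, float]:
    """(N, S) mutational-opportunity site counts per codon, from the
    neutral (omega=1) version of the fitted process."""
    Q1 = build_codon_Q(params, 1.0)
    pi = params.codon_freqs
    flow = pi[:, None] * Q1
    total = -float(pi @ np.diag(Q1))
    rho_N = float(flow[CODON_NONSYN].sum()) / total
    N = 3.0 * rho_N
    return N, 3.0 - N


def branch_dn_ds(fit_result: FitResult) -> pd.DataFrame:
    """Per-branch t, dN, dS, omega from a fitted codon branch model.

    The fitted generator of each branch is partitioned into synonymous and
    non-synonymous flow; expected counts are divided by the mutational-
    opportunity site counts (computed from the neutral process).  dS = 0
    yields an infinite omega sentinel.
    """
    params = CodonModelParams(fit_result.params["kappa"], fit_result.params["codon_freqs"])
    omega_by_edge = fit_result.params["omega_by_edge"]
    tree = fit_result.tree
    N, S = synonymous_site_fraction(params)
    rows = []
    rho_cache: dict[float, float] = {}
    for e in tree.edges:
        om = omega_by_edge[e]
        if om not in rho_cache:
            Q = build_codon_Q(params, om)
            flow = params.codon_freqs[:, None] * Q
            total = -float(params.codon_freqs @ np.diag(Q))
            rho_cache[om] = float(flow[CODON_NONSYN].sum()) / total
        rho_N = rho_cache[om]
        t = float(tree.branch_lengths[e])
        n_subs = t * rho_N
        s_subs = t * (1.0 - rho_N)
        dN = n_subs / N
        dS = s_subs / S
        omega = dN / dS if dS > 0 else (np.inf if dN > 0 else 0.0)
        rows.append({"edge": e, "t": t, "dN": dN, "dS": dS, "omega": omega})
    return pd.DataFrame(rows)
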