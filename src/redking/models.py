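"""Substitution models: GTR, empirical amino-acid, and GY94-type codon models.

All generators Q are time-reversible and scaled so that one unit of branch
length equals one expected substitution per site (per codon for codon
models).  Transition probabilities are computed through the symmetrized
eigendecomposition, which is numerically stable for reversible chains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

NT = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NT)}

#: IUPAC nucleotide ambiguity codes -> compatible bases.
IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT", ".": "ACGT",
}

AA = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA)}
AA_AMBIG = {
    "B": "ND", "Z": "QE", "J": "IL",
    "X": AA, "-": AA, "?": AA, ".": AA, "*": AA,
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
#: the 61 sense codons of the standard genetic code, in TCAG order
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("TCAG", repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA = {c: _STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS}

N_CODONS = len(SENSE_CODONS)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _codon_structure():
    """Static single-nucleotide-move structure of the sense-codon space.

    Returns boolean (61, 61) arrays: single-difference mask, transition mask
    (among single differences) and non-synonymous mask.
    """
    n = N_CODONS
    diff1 = np.zeros((n, n), dtype=bool)
    is_ts = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            diff1[i, j] = True
            is_ts[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            nonsyn[i, j] = CODON_TO_AA[ci] != CODON_TO_AA[cj]
    return diff1, is_ts, nonsyn


CODON_DIFF1, CODON_TS, CODON_NONSYN = _codon_structure()

_GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


class ModelError(ValueError):
    """Invalid model parameters."""


@dataclass
class GTRParams:
    """General time-reversible nucleotide model.

    exchangeabilities: symmetric rates for (AC, AG, AT, CG, CT, GT); the GT
    rate is conventionally fixed to 1.  base_freqs: stationary frequencies
    of A, C, G, T.
    """

    exchangeabilities: np.ndarray
    base_freqs: np.ndarray

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ModelError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ModelError("need 4 positive base frequencies")
        if not np.isclose(self.base_freqs.sum(), 1.0):
            raise ModelError("base frequencies must sum to 1")

    @classmethod
    def jukes_cantor(cls) -> "GTRParams":
        return cls(np.ones(6), np.full(4, 0.25))


@dataclass
class GammaMixture:
    """Discrete-gamma among-site rate variation (equal-probability bins)."""

    alpha: float
    rates: np.ndarray
    weights: np.ndarray

    @property
    def ncat(self) -> int:
        return len(self.rates)


@dataclass
class CodonModelParams:
    """Global parameters of a GY94-type codon model (omega is supplied per
    branch class when the generator is built)."""

    kappa: float
    codon_freqs: np.ndarray

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ModelError("kappa must be positive")
        if self.codon_freqs.shape != (N_CODONS,):
            raise ModelError(f"need {N_CODONS} sense-codon frequencies")
        if np.any(self.codon_freqs < 0) or not np.isclose(self.codon_freqs.sum(), 1.0):
            raise ModelError("codon frequencies must be non-negative and sum to 1")


@dataclass
class EmpiricalAAModel:
    """Empirical amino-acid model: fixed exchangeabilities + frequencies."""

    exchangeability_matrix: np.ndarray
    aa_freqs: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.exchangeability_matrix, dtype=float)
        f = np.asarray(self.aa_freqs, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ModelError("exchangeability matrix must be symmetric 20x20")
        if f.shape != (20,) or np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ModelError("need 20 positive frequencies summing to 1")
        self.exchangeability_matrix = s
        self.aa_freqs = f


@dataclass
class BranchSiteParams:
    """Branch-site mixture (model A parameterisation).

    Site classes: 0 (omega0 everywhere), 1 (neutral everywhere), 2a
    (background omega0, foreground omega2), 2b (background 1, foreground
    omega2).  p0, p1 are the class-0/1 proportions; classes 2a/2b split the
    remainder in proportion p0:p1.  The null model fixes omega2 = 1.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float
    foreground: str = "lichenized"

    def __post_init__(self):
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ModelError("class proportions must lie in [0,1] and p0+p1<=1")
        if not (0 < self.omega0 < 1):
            raise ModelError("omega0 must lie in (0,1)")
        if self.omega2 < 1:
            raise ModelError("omega2 must be >= 1")

    @property
    def proportions(self) -> np.ndarray:
        """Proportions of classes (0, 1, 2a, 2b)."""
        p0, p1 = self.p0, self.p1
        p2 = max(0.0, 1.0 - p0 - p1)
        if p0 + p1 <= 0:
            # all sites in class 2; split evenly
            return np.array([0.0, 0.0, p2 / 2, p2 / 2])
        return np.array([p0, p1, p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)])

    def class_omegas(self) -> list[tuple[float, float]]:
        """(background, foreground) omega for classes 0, 1, 2a, 2b."""
        return [
            (self.omega0, self.omega0),
            (1.0, 1.0),
            (self.omega0, self.omega2),
            (1.0, self.omega2),
        ]


def build_gtr_Q(params: GTRParams) -> np.ndarray:
    """GTR generator with q_ij = s_ij * pi_j, scaled to 1 substitution/site."""
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(params.exchangeabilities, _GTR_PAIRS):
        Q[i, j] = s * params.base_freqs[j]
        Q[j, i] = s * params.base_freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return _normalize_Q(Q, params.base_freqs)


def build_codon_Q(params: CodonModelParams, omega: float, normalize: bool = True) -> np.ndarray:
    """GY94-type 61x61 generator for a given omega.

    Single-nucleotide moves only; rate to codon j is proportional to pi_j,
    multiplied by kappa for transitions and by omega for non-synonymous
    changes.  With ``normalize`` (branch models), scaled so branch lengths
    count expected substitutions per codon; unnormalized generators are
    used by the branch-site mixture, whose site classes share a
    mixture-averaged scale per branch.
    """
    if omega < 0:
        raise ModelError("omega must be non-negative")
    pi = params.codon_freqs
    R = np.where(CODON_DIFF1, 1.0, 0.0)
    R = R * np.where(CODON_TS, params.kappa, 1.0)
    R = R * np.where(CODON_NONSYN, omega, 1.0)
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return _normalize_Q(Q, pi) if normalize else Q


def codon_mean_rate(params: CodonModelParams, omega: float) -> float:
    """Expected substitutions per codon per unit time of the unnormalized
    GY94 generator (the per-class weight in the branch-site scale)."""
    Q = build_codon_Q(params, omega, normalize=False)
    return -float(params.codon_freqs @ np.diag(Q))


def branch_site_scales(params: CodonModelParams, props: np.ndarray,
                       omega0: float, omega2: float) -> tuple[float, float]:
    """(foreground, background) mixture-averaged rate scales.

    All site classes of a branch share one scale, so a branch length is the
    expected number of substitutions per codon averaged over site classes
    and sites under a positively selected class genuinely evolve faster.
    Classes (0, 1, 2a, 2b) use foreground omegas (w0, 1, w2, w2) and
    background omegas (w0, 1, w0, 1).
    """
    mu0 = codon_mean_rate(params, omega0)
    mu1 = codon_mean_rate(params, 1.0)
    mu2 = codon_mean_rate(params, omega2)
    fg = props[0] * mu0 + props[1] * mu1 + (props[2] + props[3]) * mu2
    bg = (props[0] + props[2]) * mu0 + (props[1] + props[3]) * mu1
    return fg, bg


def build_aa_Q(model: EmpiricalAAModel) -> np.ndarray:
    Q = model.exchangeability_matrix * model.aa_freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return _normalize_Q(Q, model.aa_freqs)


def _normalize_Q(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    return Q / mu


def blosum62_exchangeabilities() -> np.ndarray:
    """Symmetric amino-acid exchangeabilities derived from the BLOSUM62
    log-odds matrix.

    BLOSUM62 scores are half-bit log-odds S_ij = 2*log2(q_ij / (p_i p_j));
    inverting gives target/background odds 2**(S_ij/2), which serve as the
    exchangeabilities of a reversible empirical model (frequencies are
    supplied separately, typically observed from the data, the "+F"
    convention).
    """
    blosum = substitution_matrices.load("BLOSUM62")
    s = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            if i != j:
                s[i, j] = 2.0 ** (blosum[a, b] / 2.0)
    return s


def f3x4_frequencies(codon_counts_by_position: np.ndarray) -> np.ndarray:
    """F3X4 codon frequencies from per-position nucleotide counts.

    codon_counts_by_position: (3, 4) array of A,C,G,T counts at codon
    positions 1..3.  Stop codons are removed and the rest renormalized.
    """
    counts = np.asarray(codon_counts_by_position, dtype=float)
    if counts.shape != (3, 4):
        raise ModelError("expected (3, 4) position-specific nucleotide counts")
    if np.any(counts.sum(axis=1) == 0):
        raise ModelError("a codon position has no unambiguous bases")
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    # floor to keep the chain irreducible when a base is absent at a position
    pos_freqs = np.maximum(pos_freqs, 1e-6)
    pos_freqs /= pos_freqs.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, NT_INDEX[c[0]]]
            * pos_freqs[1, NT_INDEX[c[1]]]
            * pos_freqs[2, NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return freqs / freqs.sum()


def discrete_gamma(alpha: float, ncat: int = 10) -> GammaMixture:
    """Equal-probability discrete-gamma mixture with bin-mean category rates.

    The continuous Gamma(alpha, alpha) density (mean 1) is cut at the
    i/ncat quantiles; each category's rate is the conditional mean of the
    density over its bin, renormalized so the mixture mean is exactly 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape alpha must be positive")
    if ncat < 1:
        raise ModelError("ncat must be >= 1")
    if ncat == 1:
        return GammaMixture(alpha, np.ones(1), np.ones(1))
    probs = np.arange(1, ncat) / ncat
    # quantile boundaries of Gamma(shape=alpha, rate=alpha)
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X ; a<X<b] for Gamma(alpha, alpha) via the regularized incomplete
    # gamma of shape alpha+1
    cdf_hi = np.where(np.isinf(upper), 1.0, gammainc(alpha + 1, upper * alpha))
    cdf_lo = gammainc(alpha + 1, lower * alpha)
    rates = ncat * (cdf_hi - cdf_lo)
    weights = np.full(ncat, 1.0 / ncat)
    rates = rates / (rates @ weights)
    return GammaMixture(alpha, rates, weights)


class SpectralQ:
    """Reversible generator with cached symmetric eigendecomposition.

    Exploits reversibility: B = D^{1/2} Q D^{-1/2} is symmetric for
    D = diag(pi), so P(t) = D^{-1/2} U exp(L t) U' D^{1/2} with (U, L)
    from a symmetric eigenproblem.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = np.asarray(Q, float)
        self.pi = np.asarray(pi, float)
        sqrt_pi = np.sqrt(self.pi)
        B = (self.Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        evals, U = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = U / sqrt_pi[:, None]      # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U' D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ModelError("branch length must be non-negative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths, shape (len(ts), n, n)."""
        ts = np.asarray(ts, float)
        if np.any(ts < 0):
            raise ModelError("branch length must be non-negative")
        E = np.exp(np.outer(ts, self._evals))  # (m, n)
        P = (self._left[None, :, :] * E[:, None, :]) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible generator (rows sum to 1)."""
    if pi is None:
        # stationary distribution from the left null vector of Q
        evals, evecs = np.linalg.eig(Q.T)
        k = int(np.argmin(np.abs(evals)))
        pi = np.real(evecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
    return SpectralQ(Q, pi).transition_matrix(t)
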