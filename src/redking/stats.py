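"""Statistical layer: paired Wilcoxon tests, distribution-free median CIs,
likelihood-ratio tests, positive-selection screening and summary tables.

The Wilcoxon signed-rank test here follows the matched-pairs convention
used throughout the analysis: zero differences are dropped (their count is
reported), midranks handle ties, the exact null distribution is enumerated
by rank-polynomial convolution for small samples and a tie- and
continuity-corrected normal approximation is used above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class InsufficientDataError(ValueError):
    pass


@dataclass
class WilcoxonResult:
    n_pairs: int
    n_zero_diffs: int
    W: float
    p_two_sided: float
    mode: str  # "exact" | "normal-approx" | "degenerate"


@dataclass
class MedianCI:
    median: float
    ci_low: float
    ci_high: float
    level: float
    method: str = "order-statistic"


@dataclass
class LRTResult:
    lnL_null: float
    lnL_alt: float
    df: int
    statistic: float
    p: float
    clamped: bool = False


def wilcoxon_signed_rank(
    x, y=None, exact_threshold: int = 25, zero_policy: str = "drop"
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    With ``zero_policy="drop"`` (the classic treatment) zero differences
    are removed before ranking; ``"pratt"`` ranks them but excludes them
    from both sums.  W is min(W+, W-).  Exact p-values (by convolution of
    the signed-rank generating polynomial, valid under ties) are used for
    n <= ``exact_threshold`` non-zero pairs.
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    n_total = len(d)
    zeros = d == 0
    n_zero = int(zeros.sum())
    if zero_policy == "drop":
        d = d[~zeros]
    elif zero_policy != "pratt":
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    n = len(d)
    if n - (n_zero if zero_policy == "pratt" else 0) == 0 or np.all(d == 0):
        return WilcoxonResult(n_total, n_zero, 0.0, 1.0, "degenerate")
    if n - (n_zero if zero_policy == "pratt" else 0) < 2:
        raise InsufficientDataError("need >= 2 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    if zero_policy == "pratt":
        w_plus = float(ranks[(d > 0)].sum())
        w_minus = float(ranks[(d < 0)].sum())
    else:
        w_plus = float(ranks[d > 0].sum())
        w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    n_eff = int((d != 0).sum())
    if n_eff <= exact_threshold:
        p = _exact_signed_rank_p(ranks[d != 0] if zero_policy == "pratt" else ranks,
                                 min(w_plus, w_minus))
        mode = "exact"
    else:
        # normal approximation with tie and continuity corrections
        rr = ranks if zero_policy == "drop" else ranks[d != 0]
        mu = rr.sum() / 2.0
        # Var(W+) = sum r_i^2 / 4 under random signs; midranks make this
        # the tie-corrected variance automatically
        var = rr @ rr / 4.0
        z = (W - mu + 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
        mode = "normal-approx"
    return WilcoxonResult(n_total, n_zero, W, p, mode)


def _exact_signed_rank_p(ranks: np.ndarray, w_min: float) -> float:
    """P(2 * min tail) by convolution over all 2^n sign assignments.

    Midranks are multiples of 1/2, so doubling makes them integers and the
    distribution of 2*W+ is a polynomial convolution; the null distribution
    is symmetric, hence two-sided p = min(1, 2*P(W+ <= w_min)).
    """
    r2 = np.rint(2.0 * np.asarray(ranks, float)).astype(int)
    total = int(r2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = 0.5 * (poly + shifted)
    w2 = int(np.floor(2.0 * w_min + 1e-9))
    return float(min(1.0, 2.0 * poly[: w2 + 1].sum()))


def median_ci(values, level: float = 0.95) -> MedianCI:
    """Distribution-free order-statistic confidence interval for the median.

    Chooses the symmetric order-statistic pair (k, n+1-k) with the smallest
    coverage >= ``level`` under Binomial(n, 1/2); if no symmetric pair
    reaches the level, the widest possible pair (sample min/max) is
    returned.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)
    if n < 6:
        raise InsufficientDataError("need n >= 6 for a median CI")
    med = float(np.median(v))
    best_k = None
    for k in range(n // 2, 0, -1):
        # coverage of (X_(k), X_(n+1-k)): P(k <= B < n+1-k), B ~ Bin(n, 1/2)
        cover = sps.binom.cdf(n - k, n, 0.5) - sps.binom.cdf(k - 1, n, 0.5)
        if cover >= level:
            best_k = k
            break
    if best_k is None:
        best_k = 1
    return MedianCI(med, float(v[best_k - 1]), float(v[n - best_k]), level)


def lrt(lnL_null: float, lnL_alt: float, df: int, tol: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of nested models via the chi-square upper tail.

    A slightly negative 2*Delta-lnL (optimizer noise within ``tol``) is
    clamped to zero; a larger violation raises, signalling that the general
    model needs refitting.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL_alt - lnL_null)
    clamped = False
    if stat < 0:
        if stat < -2.0 * tol:
            raise ValueError(
                f"lnL(alt)={lnL_alt:.6f} < lnL(null)={lnL_null:.6f}: refit needed"
            )
        stat, clamped = 0.0, True
    p = float(sps.chi2.sf(stat, df))
    return LRTResult(lnL_null, lnL_alt, df, stat, p, clamped)


def normality_check(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K^2, p)."""
    v = np.asarray(values, float)
    if len(v) < 20:
        raise InsufficientDataError("need n >= 20 for the omnibus test")
    if np.ptp(v) == 0:
        raise InsufficientDataError("degenerate (constant) sample")
    k2, p = sps.normaltest(v)
    return float(k2), float(p)


# ---------------------------------------------------------------------------
# positive-selection screening


def selection_screen(
    bs_results: pd.DataFrame,
    alpha: float = 0.05,
    neutral_boundary: float = 1.0 + 1e-3,
) -> pd.DataFrame:
    """Classify genes by the branch-site LRT.

    ``bs_results`` needs one row per (gene_id, foreground) with columns
    lnL_null, lnL_alt, omega2.  Adds: p (bsA vs bsA1, df=1), significant,
    class ("positive_sites" if omega2 > the neutral boundary else
    "neutral_boundary"), and exclusive (significant for this foreground
    only).
    """
    req = {"gene_id", "foreground", "lnL_null", "lnL_alt", "omega2"}
    missing = req - set(bs_results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = bs_results.copy()
    out["p"] = [
        lrt(r.lnL_null, r.lnL_alt, df=1).p for r in out.itertuples()
    ]
    out["significant"] = out["p"] < alpha
    out["classification"] = np.where(
        out["omega2"] > neutral_boundary, "positive_sites", "neutral_boundary"
    )
    sig = out[out["significant"]]
    sig_by_fg = {
        fg: set(grp["gene_id"]) for fg, grp in sig.groupby("foreground")
    }
    def exclusive(row):
        if not row.significant:
            return False
        others = [g for fg, g in sig_by_fg.items() if fg != row.foreground]
        return all(row.gene_id not in g for g in others)
    out["exclusive"] = [exclusive(r) for r in out.itertuples()]
    return out


def background_consistency(list_a, list_b) -> dict:
    """Overlap of two significant-gene lists obtained with different
    background clades (Jaccard overlap plus per-list recovery)."""
    a, b = set(list_a), set(list_b)
    if not a and not b:
        return {"jaccard": float("nan"), "recovered_from_a": float("nan"),
                "recovered_from_b": float("nan"), "defined": False}
    inter = len(a & b)
    return {
        "jaccard": inter / len(a | b),
        "recovered_from_a": inter / len(a) if a else float("nan"),
        "recovered_from_b": inter / len(b) if b else float("nan"),
        "defined": True,
    }


# ---------------------------------------------------------------------------
# summary table


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return ""


def build_summary_table(measure_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Summary table of clade medians, CIs, Wilcoxon stars and
    percent-faster rows.

    ``measure_tables`` maps a measure name (e.g. "nucleotide rate",
    "dN", "GC content") to a per-gene wide table with columns
    gene_id, <value>_lichenized, <value>_non_lichenized (any value prefix).
    Rows with too few genes are emitted as NA.
    """
    from .rates import percent_faster
    from .trees import LICHENIZED, NON_LICHENIZED

    rows = []
    for measure, table in measure_tables.items():
        cols = [c for c in table.columns if c != "gene_id"]
        lich = next((c for c in cols if c.endswith(LICHENIZED) and not c.endswith(NON_LICHENIZED)), None)
        non = next((c for c in cols if c.endswith(NON_LICHENIZED)), None)
        if lich is None or non is None or len(table) < 6:
            rows.append({"measure": measure, "n": len(table) if table is not None else 0,
                         "lichenized": "NA", "non_lichenized": "NA",
                         "p": np.nan, "stars": "", "percent_faster": np.nan})
            continue
        x = table[lich].to_numpy(float)
        y = table[non].to_numpy(float)
        wres = wilcoxon_signed_rank(x, y)
        ci_l = median_ci(x)
        ci_n = median_ci(y)
        pf = percent_faster(
            table.rename(columns={lich: f"v_{LICHENIZED}", non: f"v_{NON_LICHENIZED}"}),
            value="v",
        )
        rows.append(
            {
                "measure": measure,
                "n": len(table),
                "lichenized": f"{ci_l.median:.4g} [{ci_l.ci_low:.4g}, {ci_l.ci_high:.4g}]",
                "non_lichenized": f"{ci_n.median:.4g} [{ci_n.ci_low:.4g}, {ci_n.ci_high:.4g}]",
                "p": wres.p_two_sided,
                "stars": significance_stars(wres.p_two_sided),
                "percent_faster": pf["percent_faster"],
            }
        )
    return pd.DataFrame(rows)
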