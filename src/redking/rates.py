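"""Per-gene, per-clade tip-to-root rate statistics and the strict
saturation filter.

The clade rate of a fitted tree is the mean, over the clade's tips, of the
summed branch lengths on the path from each tip to the clade's most recent
common ancestor.  Because every tip-to-MRCA path spans the same timespan,
the comparison between sister clades needs no absolute calibration; with
equal tip counts per clade the two clades aggregate the same number of tip
paths, avoiding node-density bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import CladeTree, LICHENIZED, NON_LICHENIZED, TreeStructureError


def tip_to_root_rate(tree: CladeTree, clade: str) -> float:
    """Mean tip -> clade-MRCA path length over the clade's tips.

    Shared internal branches are counted once per tip path.  A single-tip
    clade contributes its pendant branch length.
    """
    tips = tree.clade_tip_indices(clade)
    if not tips:
        raise TreeStructureError(f"clade {clade!r} has no tips")
    if len(tips) == 1:
        return float(tree.branch_lengths[tips[0]])
    mrca = tree.mrca(tips)
    return float(np.mean([tree.path_to_ancestor(t, mrca) for t in tips]))


def clade_codon_stats(
    tree: CladeTree,
    branch_stats: pd.DataFrame,
    clade: str,
    omega_mode: str = "ratio_of_means",
) -> tuple[float, float, float]:
    """Clade (dN, dS, omega) by tip-to-root averaging of per-branch dN/dS.

    Per-branch dN and dS (from a free-ratio codon fit) are summed along each
    tip -> MRCA path and averaged over tips, exactly like the branch-length
    rate.  omega is the ratio of the aggregated dN to dS by default
    (robust to near-zero branch dS); ``omega_mode="mean_of_ratios"``
    averages per-branch omegas along the paths instead.
    """
    tips = tree.clade_tip_indices(clade)
    if not tips:
        raise TreeStructureError(f"clade {clade!r} has no tips")
    by_edge = branch_stats.set_index("edge")
    mrca = tree.mrca(tips) if len(tips) > 1 else None

    def path_edges(tip: int) -> list[int]:
        if mrca is None:
            return [tip]
        out, v = [], tip
        while v != mrca:
            out.append(v)
            v = int(tree.parent[v])
        return out

    paths = [path_edges(t) for t in tips]
    dn = float(np.mean([sum(by_edge.loc[e, "dN"] for e in p) for p in paths]))
    ds = float(np.mean([sum(by_edge.loc[e, "dS"] for e in p) for p in paths]))
    if omega_mode == "ratio_of_means":
        omega = dn / ds if ds > 0 else (np.inf if dn > 0 else 0.0)
    elif omega_mode == "mean_of_ratios":
        all_edges = sorted({e for p in paths for e in p})
        omega = float(np.mean([by_edge.loc[e, "omega"] for e in all_edges]))
    else:
        raise ValueError(f"unknown omega_mode {omega_mode!r}")
    return dn, ds, omega


def strict_filter(
    records: pd.DataFrame,
    ds_max: float = 3.0,
    omega_max: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Saturation filter on per-gene clade statistics.

    A gene is retained iff every compared clade has dS <= ds_max and
    omega <= omega_max (both boundaries inclusive).  Returns (retained
    records, per-gene report with reason codes).
    """
    rows = []
    keep_genes = []
    for gene, grp in records.groupby("gene_id", sort=False):
        reasons = []
        if grp[["dS", "omega"]].isna().any().any() or len(grp["clade"].unique()) < 2:
            reasons.append("incomplete")
        if (grp["dS"] > ds_max).any():
            reasons.append(f"dS>{ds_max:g}")
        if (grp["omega"] > omega_max).any():
            reasons.append(f"omega>{omega_max:g}")
        ok = not reasons
        if ok:
            keep_genes.append(gene)
        rows.append({"gene_id": gene, "retained": ok, "reason": ";".join(reasons)})
    report = pd.DataFrame(rows)
    report.attrs["n_input"] = records["gene_id"].nunique()
    report.attrs["n_retained"] = len(keep_genes)
    retained = records[records["gene_id"].isin(keep_genes)].copy()
    return retained, report


def percent_faster(paired: pd.DataFrame, value: str = "rate") -> dict:
    """Percentage of genes whose lichenized-clade value exceeds the
    non-lichenized one (ties counted as not-faster, reported separately).

    ``paired`` must have one row per gene with columns
    ``{value}_lichenized`` and ``{value}_non_lichenized``.
    """
    if len(paired) == 0:
        raise ValueError("no paired records: percent-faster undefined")
    x = paired[f"{value}_{LICHENIZED}"].to_numpy(float)
    y = paired[f"{value}_{NON_LICHENIZED}"].to_numpy(float)
    faster = int((x > y).sum())
    ties = int((x == y).sum())
    n = len(paired)
    return {
        "percent_faster": 100.0 * faster / n,
        "percent_ties": 100.0 * ties / n,
        "n": n,
    }


def pivot_rates(records: pd.DataFrame, value: str = "rate") -> pd.DataFrame:
    """Wide per-gene table with one column per clade for ``value``; genes
    missing either compared clade are dropped."""
    wide = records.pivot_table(
        index="gene_id", columns="clade", values=value, aggfunc="first"
    )
    wide = wide.reindex(columns=[LICHENIZED, NON_LICHENIZED])
    wide = wide.dropna()
    wide.columns = [f"{value}_{c}" for c in wide.columns]
    return wide.reset_index()
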