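"""End-to-end orchestration: load -> filter -> fit -> clade rates ->
strict filter -> paired statistics -> summary table.

Genes are independent: each gene's fits are cached as a JSON file keyed by
a config hash, failures are collected in a ledger without aborting the
run, and re-running with the same config skips completed genes.
"""

from __future__ import annotations

import hashlib
import json
import traceback
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    CodonAlignment,
    filter_by_length,
    gc_content,
    read_alignment,
    split_codon_positions,
    translate,
)
from .fit import ModelSpec, fit_aa, fit_branch_site, fit_codon, fit_nucleotide
from .rates import clade_codon_stats, percent_faster, pivot_rates, strict_filter, tip_to_root_rate
from .stats import build_summary_table, selection_screen, wilcoxon_signed_rank
from .trees import CladeTree, LICHENIZED, NON_LICHENIZED

COMPARED_CLADES = (LICHENIZED, NON_LICHENIZED)


@dataclass
class RunConfig:
    alignment_dir: str
    tree_file: str
    clade_map_file: str
    out_dir: str
    models: tuple = ("NUC_GTRG", "AA_EMP", "CODON_FB")
    by_codon_position: bool = False
    branch_site: bool = False
    min_codons: int = 300
    ds_max: float = 3.0
    omega_max: float = 10.0
    selection_alpha: float = 0.05
    n_starts: int = 2
    ncat: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.min_codons <= 0 or self.ds_max <= 0 or self.omega_max <= 0:
            raise ValueError("filter thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["models"] = tuple(raw.get("models", cls.models))
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_inputs(config: RunConfig):
    clade_map_df = pd.read_csv(config.clade_map_file, sep="\t")
    clade_map = dict(zip(clade_map_df["tip"], clade_map_df["clade"]))
    tree = CladeTree.from_newick(Path(config.tree_file).read_text(), clade_map)
    aln_dir = Path(config.alignment_dir)
    paths = sorted(
        p for p in aln_dir.iterdir()
        if p.suffix.lower() in (".fasta", ".fa", ".fna", ".phy", ".phylip")
    )
    codon_models = {"AA_EMP", "CODON_M0", "CODON_B2", "CODON_B3", "CODON_FB"}
    alphabet = (
        "codon"
        if (codon_models & set(config.models)) or config.branch_site
        else "nt"
    )
    alignments = {}
    read_failures = []
    for p in paths:
        try:
            alignments[p.stem] = read_alignment(p, alphabet=alphabet)
        except Exception as exc:
            read_failures.append(
                {"gene": p.stem, "error": f"{type(exc).__name__}: {exc}",
                 "traceback": traceback.format_exc()}
            )
    return tree, alignments, read_failures


def _analyze_gene(gene: str, aln: CodonAlignment, tree: CladeTree, config: RunConfig) -> dict:
    """All per-gene fits and clade statistics, as a JSON-serializable dict."""
    out: dict = {"gene": gene, "n_codons": aln.n_columns // 3, "gc": gc_content(aln)}
    gene_key = zlib.crc32(gene.encode()) % (2**31)
    seed = int(
        np.random.SeedSequence([config.seed, gene_key]).generate_state(1)[0] % (2**31)
    )
    clade_rows = {c: {"gene_id": gene, "clade": c} for c in COMPARED_CLADES}
    if "NUC_GTRG" in config.models:
        nt_fit = fit_nucleotide(aln, tree, ncat=config.ncat, n_starts=config.n_starts, seed=seed)
        out["lnL_nuc"] = nt_fit.lnL
        out["alpha"] = nt_fit.params["alpha"]
        for c in COMPARED_CLADES:
            clade_rows[c]["rate"] = tip_to_root_rate(nt_fit.tree, c)
        if config.by_codon_position:
            scheme, _ = split_codon_positions(aln)
            from .fit import fit_partitioned

            part = fit_partitioned(
                aln, tree, scheme, ModelSpec("NUC_GTRG"),
                ncat=config.ncat, n_starts=config.n_starts, seed=seed,
            )
            for name, f in zip(part.partition_names, part.fits):
                for c in COMPARED_CLADES:
                    clade_rows[c][f"rate_{name}"] = tip_to_root_rate(f.tree, c)
    if "AA_EMP" in config.models:
        aa_fit = fit_aa(translate(aln), tree, n_starts=config.n_starts, seed=seed)
        out["lnL_aa"] = aa_fit.lnL
        for c in COMPARED_CLADES:
            clade_rows[c]["rate_aa"] = tip_to_root_rate(aa_fit.tree, c)
    if "CODON_FB" in config.models:
        fb = fit_codon(aln, tree, ModelSpec("CODON_FB"), n_starts=config.n_starts, seed=seed)
        out["lnL_fb"] = fb.lnL
        out["kappa"] = fb.params["kappa"]
        for c in COMPARED_CLADES:
            dn, ds, om = clade_codon_stats(fb.tree, fb.branch_stats, c)
            clade_rows[c].update(
                rate_codon=tip_to_root_rate(fb.tree, c), dN=dn, dS=ds, omega=om
            )
    if config.branch_site:
        bs_rows = []
        for fg in COMPARED_CLADES:
            null = fit_branch_site(aln, tree, fg, alternative=False,
                                   n_starts=config.n_starts, seed=seed)
            alt = fit_branch_site(aln, tree, fg, alternative=True,
                                  n_starts=config.n_starts, seed=seed, warm=null)
            bs_rows.append(
                {
                    "gene_id": gene,
                    "foreground": fg,
                    "lnL_null": null.lnL,
                    "lnL_alt": max(alt.lnL, null.lnL),
                    "omega2": alt.params["omega2"],
                }
            )
        out["branch_site"] = bs_rows
    out["clade_rows"] = list(clade_rows.values())
    return out


def run_pipeline(config: RunConfig) -> Path:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache_dir = out_dir / "cache"
    cache_dir.mkdir(exist_ok=True)
    chash = config.config_hash()

    tree, alignments, failures = load_inputs(config)
    kept, dropped, length_report = filter_by_length(alignments, min_codons=config.min_codons)
    length_report.to_csv(out_dir / "length_filter.tsv", sep="\t", index=False)

    gene_results = []
    for gene, aln in kept.items():
        cache_file = cache_dir / f"{gene}.json"
        if cache_file.exists():
            cached = json.loads(cache_file.read_text())
            if cached.get("config_hash") == chash:
                gene_results.append(cached["result"])
                continue
        try:
            result = _analyze_gene(gene, aln, tree, config)
        except Exception as exc:  # per-gene isolation
            failures.append(
                {"gene": gene, "error": f"{type(exc).__name__}: {exc}",
                 "traceback": traceback.format_exc()}
            )
            continue
        cache_file.write_text(
            json.dumps({"config_hash": chash, "result": result}, sort_keys=True)
        )
        gene_results.append(result)

    records = pd.DataFrame(
        [row for res in gene_results for row in res["clade_rows"]]
    )
    if not records.empty:
        records.to_csv(out_dir / "gene_rates.tsv", sep="\t", index=False)

    measure_tables: dict[str, pd.DataFrame] = {}
    value_cols = [
        ("rate", "nucleotide rate"),
        ("rate_aa", "amino-acid rate"),
        ("rate_codon", "codon rate"),
        ("dN", "dN"),
        ("dS", "dS"),
        ("omega", "omega"),
        ("rate_pos1", "codon position 1 rate"),
        ("rate_pos2", "codon position 2 rate"),
        ("rate_pos3", "codon position 3 rate"),
    ]
    for col, label in value_cols:
        if col in records.columns:
            wide = pivot_rates(records, value=col)
            wide = wide.replace([np.inf, -np.inf], np.nan).dropna()
            measure_tables[label] = wide
    if "dS" in records.columns:
        retained, filter_report = strict_filter(
            records.dropna(subset=["dS", "omega"]),
            ds_max=config.ds_max, omega_max=config.omega_max,
        )
        filter_report.to_csv(out_dir / "strict_filter.tsv", sep="\t", index=False)
        for col, label in value_cols:
            if col in retained.columns and retained[col].notna().any():
                wide = pivot_rates(retained, value=col)
                wide = wide.replace([np.inf, -np.inf], np.nan).dropna()
                measure_tables[f"{label} (filtered)"] = wide

    summary = build_summary_table(measure_tables)
    summary.to_csv(out_dir / "summary_table.tsv", sep="\t", index=False)

    stats_json: dict = {"n_genes_analyzed": len(gene_results), "n_failed": len(failures)}
    if "nucleotide rate" in measure_tables and len(measure_tables["nucleotide rate"]) >= 2:
        t = measure_tables["nucleotide rate"]
        w = wilcoxon_signed_rank(t["rate_lichenized"], t["rate_non_lichenized"])
        stats_json["wilcoxon_nucleotide"] = {"W": w.W, "p": w.p_two_sided, "n": w.n_pairs}
        stats_json["percent_faster_nucleotide"] = percent_faster(t)

    bs_rows = [row for res in gene_results for row in res.get("branch_site", [])]
    if bs_rows:
        screen = selection_screen(pd.DataFrame(bs_rows), alpha=config.selection_alpha)
        screen.to_csv(out_dir / "selection_screen.tsv", sep="\t", index=False)
        stats_json["selection"] = {
            fg: int(((screen["foreground"] == fg) & screen["significant"]).sum())
            for fg in COMPARED_CLADES
        }

    (out_dir / "stats.json").write_text(json.dumps(stats_json, indent=2, sort_keys=True, default=float))
    manifest = {
        "config": asdict(config),
        "config_hash": chash,
        "version": __version__,
        "n_genes_input": len(alignments),
        "n_genes_kept": len(kept),
        "n_genes_failed": len(failures),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    if failures:
        (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
    return out_dir
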