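"""Alignment containers, format I/O, filtering and composition statistics.

Nucleotide and amino-acid alignments are thin wrappers over a character
matrix; codon alignments additionally enforce frame (length divisible by 3)
and the absence of resolved in-frame stop codons.  Partially ambiguous or
gapped codons are treated as missing codon states while the underlying
nucleotides are retained, so reading and writing round-trips losslessly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .models import (
    AA,
    AA_AMBIG,
    CODON_TO_AA,
    IUPAC_NT,
    NT,
    STOP_CODONS,
)

MISSING_CODON = "---"
MISSING_AA = "X"


class AlignmentError(ValueError):
    """Malformed or invalid alignment input."""


class Alignment:
    """Equal-length sequences over a nucleotide or amino-acid alphabet."""

    def __init__(self, taxa: list[str], sequences: list[str], alphabet: str = "nt"):
        if alphabet not in ("nt", "aa"):
            raise AlignmentError(f"unknown alphabet {alphabet!r}")
        if len(taxa) != len(sequences):
            raise AlignmentError("taxa/sequence count mismatch")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxa: {dupes}")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        self.taxa = list(taxa)
        self.alphabet = alphabet
        seqs = [s.upper() for s in sequences]
        valid = set(IUPAC_NT) if alphabet == "nt" else set(AA) | set(AA_AMBIG)
        for taxon, s in zip(taxa, seqs):
            bad = set(s) - valid
            if bad:
                col = min(s.index(b) for b in bad) + 1
                raise AlignmentError(
                    f"invalid symbol {sorted(bad)[0]!r} for {taxon} at column {col}"
                )
        self.matrix = np.array([list(s) for s in seqs], dtype="<U1") if seqs else np.empty((0, 0), dtype="<U1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1] if self.matrix.size else 0

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and self.matrix.shape == other.matrix.shape
            and bool(np.all(self.matrix == other.matrix))
        )


class CodonAlignment(Alignment):
    """In-frame coding alignment over the 61 sense codons + missing states."""

    def __init__(self, taxa: list[str], sequences: list[str]):
        super().__init__(taxa, sequences, alphabet="nt")
        if self.n_columns % 3 != 0:
            raise AlignmentError(
                f"nucleotide length {self.n_columns} not divisible by 3"
            )
        for ti, taxon in enumerate(self.taxa):
            seq = "".join(self.matrix[ti])
            for c in range(self.n_codons):
                codon = seq[3 * c : 3 * c + 3]
                if codon in STOP_CODONS:
                    raise AlignmentError(
                        f"in-frame stop codon {codon} for {taxon} at codon column {c + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def codon_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) array of codon strings; unresolved codons
        (any gap/ambiguity) are mapped to the missing codon state."""
        out = np.full((self.n_taxa, self.n_codons), MISSING_CODON, dtype="<U3")
        resolved = set("ACGT")
        for ti in range(self.n_taxa):
            seq = "".join(self.matrix[ti])
            for c in range(self.n_codons):
                codon = seq[3 * c : 3 * c + 3]
                if set(codon) <= resolved:
                    out[ti, c] = codon
        return out


@dataclass
class PartitionScheme:
    """Named, disjoint, covering sets of 1-based alignment columns."""

    partitions: list[tuple[str, np.ndarray]]

    def validate(self, n_columns: int) -> None:
        seen: set[int] = set()
        for name, cols in self.partitions:
            cols = np.asarray(cols, int)
            if np.any(cols < 1) or np.any(cols > n_columns):
                raise AlignmentError(f"partition {name!r} has out-of-range columns")
            s = set(cols.tolist())
            if seen & s:
                raise AlignmentError(f"partition {name!r} overlaps another partition")
            seen |= s
        if seen != set(range(1, n_columns + 1)):
            raise AlignmentError("partitions do not cover all columns")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.partitions]


# ---------------------------------------------------------------------------
# reading / writing


def _sniff_format(path: str | os.PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "phylip"
    raise AlignmentError(f"empty alignment file: {path}")


def read_alignment(path: str | os.PathLike, alphabet: str = "nt") -> Alignment | CodonAlignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    alphabet: "nt", "aa" or "codon" (codon mode enforces frame and
    stop-codon rules).
    """
    fmt = _sniff_format(path)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    else:
        records = None
        for schema in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                aln = AlignIO.read(str(path), schema)
                records = list(aln)
                break
            except Exception:
                continue
        if records is None:
            raise AlignmentError(f"could not parse PHYLIP alignment: {path}")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    try:
        if alphabet == "codon":
            return CodonAlignment(taxa, seqs)
        return Alignment(taxa, seqs, alphabet=alphabet)
    except AlignmentError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc


def write_fasta(aln: Alignment, path: str | os.PathLike, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for ti, taxon in enumerate(aln.taxa):
            fh.write(f">{taxon}\n")
            seq = "".join(aln.matrix[ti])
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_phylip(aln: Alignment, path: str | os.PathLike) -> None:
    """Relaxed sequential PHYLIP with a PAML-style `ntaxa ncols` header."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.n_columns}\n")
        for ti, taxon in enumerate(aln.taxa):
            fh.write(f"{taxon}  {''.join(aln.matrix[ti])}\n")


# ---------------------------------------------------------------------------
# filtering & partitioning


def filter_by_length(
    alignments: dict[str, Alignment],
    min_codons: int = 300,
    strict_greater: bool = False,
) -> tuple[dict[str, Alignment], dict[str, Alignment], pd.DataFrame]:
    """Keep alignments long enough for rate estimation.

    The default keeps genes with >= ``min_codons`` codon columns (>= 3x that
    in nucleotide columns; >= ``min_codons`` residues for amino-acid data).
    ``strict_greater`` switches the boundary to a strict > comparison.
    """
    kept: dict[str, Alignment] = {}
    dropped: dict[str, Alignment] = {}
    rows = []
    for name, aln in alignments.items():
        if isinstance(aln, CodonAlignment):
            units, threshold = aln.n_codons, min_codons
        elif aln.alphabet == "aa":
            units, threshold = aln.n_columns, min_codons
        else:
            units, threshold = aln.n_columns, 3 * min_codons
        ok = units > threshold if strict_greater else units >= threshold
        (kept if ok else dropped)[name] = aln
        rows.append({"gene": name, "length": units, "kept": ok})
    return kept, dropped, pd.DataFrame(rows, columns=["gene", "length", "kept"])


def split_codon_positions(aln: Alignment) -> tuple[PartitionScheme, list[Alignment]]:
    """Extract codon positions 1, 2, 3 into three nucleotide alignments.

    Accepts any in-frame nucleotide alignment (length divisible by 3).
    """
    if aln.alphabet != "nt" or aln.n_columns % 3 != 0:
        raise AlignmentError("codon-position split needs an in-frame nucleotide alignment")
    n = aln.n_columns
    parts = []
    subs = []
    for pos in range(3):
        cols = np.arange(pos + 1, n + 1, 3)
        parts.append((f"pos{pos + 1}", cols))
        sub = Alignment(
            aln.taxa,
            ["".join(row) for row in aln.matrix[:, pos::3]],
            alphabet="nt",
        )
        subs.append(sub)
    scheme = PartitionScheme(parts)
    scheme.validate(n)
    return scheme, subs


def merge_codon_positions(subs: list[Alignment]) -> Alignment:
    """Inverse of :func:`split_codon_positions` (codon-interleave 3 tracks)."""
    if len(subs) != 3:
        raise AlignmentError("need exactly three codon-position alignments")
    n = subs[0].n_columns
    mat = np.empty((subs[0].n_taxa, 3 * n), dtype="<U1")
    for pos, sub in enumerate(subs):
        mat[:, pos::3] = sub.matrix
    return Alignment(subs[0].taxa, ["".join(r) for r in mat], alphabet="nt")


# ---------------------------------------------------------------------------
# composition & translation


def gc_content(aln: Alignment) -> float:
    """(G+C)/(A+C+G+T) pooled over all sequences; gaps and ambiguity codes
    are excluded from both numerator and denominator."""
    if aln.alphabet != "nt":
        raise AlignmentError("GC content requires a nucleotide alignment")
    flat = aln.matrix.ravel()
    gc = np.isin(flat, ["G", "C"]).sum()
    atgc = np.isin(flat, list(NT)).sum()
    if atgc == 0:
        raise AlignmentError("no unambiguous bases: GC content undefined")
    return float(gc) / float(atgc)


def base_counts(aln: Alignment) -> np.ndarray:
    """Counts of A, C, G, T over the whole alignment (ambiguities excluded)."""
    flat = aln.matrix.ravel()
    return np.array([(flat == b).sum() for b in NT], dtype=float)


def aa_counts(aln: Alignment) -> np.ndarray:
    """Counts of the 20 amino acids over the whole alignment."""
    flat = aln.matrix.ravel()
    return np.array([(flat == a).sum() for a in AA], dtype=float)


def position_nucleotide_counts(aln: CodonAlignment) -> np.ndarray:
    """(3, 4) counts of A,C,G,T at codon positions 1..3 (for F3X4)."""
    out = np.zeros((3, 4))
    for pos in range(3):
        sub = aln.matrix[:, pos::3].ravel()
        out[pos] = [(sub == b).sum() for b in NT]
    return out


def translate(aln: CodonAlignment) -> Alignment:
    """Codon-wise translation under the standard genetic code; missing
    codons become missing residues."""
    codons = aln.codon_matrix()
    out = []
    for ti in range(aln.n_taxa):
        out.append(
            "".join(
                CODON_TO_AA.get(c, MISSING_AA) for c in codons[ti]
            )
        )
    return Alignment(aln.taxa, out, alphabet="aa")
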