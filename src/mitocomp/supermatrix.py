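"""Concatenated phylogenetic data matrices from per-gene alignments.

Builds the usual supermatrix variants consumed by tree-inference programs:
all sites of the protein-coding genes, their first+second codon positions,
protein-coding genes plus rRNAs, and the amino-acid translation.  The
module consumes ready-made alignments; producing them (aligners, column
trimming) is outside its scope, though a column mask can be recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .codons import GeneticCode, get_code
from .genomes import Alignment

log = logging.getLogger(__name__)

__all__ = ["SuperMatrix", "concatenate", "codon_subset", "translate_matrix",
           "write_phylip", "write_partitions"]


@dataclass
class SuperMatrix:
    alignment: Alignment
    partitions: dict  # gene -> (start, end, kind), 1-based inclusive, tiling
    alphabet: str = "DNA"  # or "AA"
    column_mask: dict = field(default_factory=dict)  # gene -> removed columns, optional

    def __post_init__(self):
        pos = 1
        for gene, (s, e, _kind) in self.partitions.items():
            if s != pos:
                raise ValueError(f"partitions do not tile: {gene} starts at {s}, expected {pos}")
            if e < s:
                raise ValueError(f"empty partition {gene}")
            pos = e + 1
        if self.partitions and pos - 1 != self.alignment.length:
            raise ValueError(
                f"partitions cover {pos - 1} columns but matrix has {self.alignment.length}")

    @property
    def taxa(self) -> list[str]:
        return self.alignment.ids

    def block(self, gene: str) -> Alignment:
        s, e, _ = self.partitions[gene]
        return Alignment(self.alignment.ids,
                         [row[s - 1:e] for row in self.alignment.rows])


def concatenate(gene_alignments: dict, order: list | None = None,
                kinds: dict | None = None) -> SuperMatrix:
    """Concatenate per-gene alignments into one partitioned matrix.

    Taxa are the union over genes; a taxon missing from a gene is padded
    with gaps for that block (logged).  Row order follows first appearance.
    """
    if not gene_alignments:
        raise ValueError("no alignments given")
    order = list(order) if order is not None else list(gene_alignments)
    unknown = [g for g in order if g not in gene_alignments]
    if unknown:
        raise KeyError(f"order names absent from alignments: {unknown}")
    taxa: list[str] = []
    for g in order:
        for t in gene_alignments[g].ids:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    partitions: dict = {}
    pos = 1
    for g in order:
        aln = gene_alignments[g]
        L = aln.length
        by_id = dict(zip(aln.ids, aln.rows))
        for t in taxa:
            if t in by_id:
                rows[t].append(by_id[t])
            else:
                log.warning("taxon %s missing from gene %s; padded with gaps", t, g)
                rows[t].append("-" * L)
        kind = (kinds or {}).get(g, "DNA")
        partitions[g] = (pos, pos + L - 1, kind)
        pos += L
    matrix = Alignment(taxa, ["".join(rows[t]) for t in taxa])
    return SuperMatrix(matrix, partitions)


def codon_subset(matrix: SuperMatrix, positions) -> SuperMatrix:
    """Keep only the requested codon positions (subset of {1,2,3}) of every
    partition; all blocks must be in-frame (length divisible by 3)."""
    positions = sorted(set(positions))
    if not positions or not set(positions) <= {1, 2, 3}:
        raise ValueError(f"positions must be a nonempty subset of {{1,2,3}}, got {positions}")
    if matrix.alphabet != "DNA":
        raise ValueError("codon positions are defined on nucleotide matrices only")
    new_rows = ["" for _ in matrix.taxa]
    partitions: dict = {}
    pos = 1
    for gene, (s, e, kind) in matrix.partitions.items():
        L = e - s + 1
        if L % 3:
            raise ValueError(f"gene {gene} block length {L} is not a multiple of 3")
        keep = [i for i in range(L) if (i % 3) + 1 in positions]
        for r, row in enumerate(matrix.alignment.rows):
            block = row[s - 1:e]
            new_rows[r] += "".join(block[i] for i in keep)
        partitions[gene] = (pos, pos + len(keep) - 1, kind)
        pos += len(keep)
    return SuperMatrix(Alignment(list(matrix.taxa), new_rows), partitions)


def translate_matrix(matrix: SuperMatrix, code: GeneticCode | None = None,
                     stop_handling: str = "remove") -> SuperMatrix:
    """Codon-wise translation of an in-frame nucleotide matrix.

    A gap codon ``---`` becomes ``-``; a codon with any other gap or an
    ambiguous base becomes ``X``.  Stop codons translate to ``*`` and are
    then handled per ``stop_handling``: ``remove`` drops every amino-acid
    column containing a stop (the common practice before tree inference),
    ``X`` masks them, ``keep`` leaves the asterisks.
    """
    if stop_handling not in ("remove", "X", "keep"):
        raise ValueError(f"unknown stop_handling {stop_handling!r}")
    code = code or get_code(5)
    if matrix.alphabet != "DNA":
        raise ValueError("matrix is already amino-acid")
    aa_rows = []
    for row in matrix.alignment.rows:
        chars = []
        for k in range(0, len(row), 3):
            codon = row[k:k + 3]
            if codon == "---":
                chars.append("-")
            elif code.is_stop(codon):
                chars.append("*")
            else:
                aa = code.aa(codon)
                chars.append(aa if aa is not None else "X")
        aa_rows.append("".join(chars))
    # partition bounds in amino-acid coordinates
    partitions: dict = {}
    for gene, (s, e, _kind) in matrix.partitions.items():
        L = e - s + 1
        if L % 3:
            raise ValueError(f"gene {gene} block length {L} is not a multiple of 3")
        partitions[gene] = ((s - 1) // 3 + 1, e // 3, "AA")

    if stop_handling != "keep":
        drop = set()
        for r in aa_rows:
            drop.update(i for i, ch in enumerate(r) if ch == "*")
        if stop_handling == "X":
            aa_rows = [r.replace("*", "X") for r in aa_rows]
        else:
            keep = [i for i in range(len(aa_rows[0])) if i not in drop]
            aa_rows = ["".join(r[i] for i in keep) for r in aa_rows]
            new_parts: dict = {}
            pos = 1
            for gene, (s, e, kind) in partitions.items():
                n_kept = sum(1 for i in keep if s - 1 <= i <= e - 1)
                if n_kept == 0:
                    log.warning("gene %s vanished after stop-column removal", gene)
                    continue
                new_parts[gene] = (pos, pos + n_kept - 1, kind)
                pos += n_kept
            partitions = new_parts
    out_alphabet = "AA"
    aa_aln = _aa_alignment(list(matrix.taxa), aa_rows)
    return SuperMatrix(aa_aln, partitions, out_alphabet)


class _AAAlignment(Alignment):
    """Alignment whose rows are amino acids; skips the DNA alphabet check."""

    def __post_init__(self):  # noqa: D105
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        self.rows = [r.upper() for r in self.rows]
        if self.rows:
            L = len(self.rows[0])
            for i, r in enumerate(self.rows):
                if len(r) != L:
                    raise ValueError(f"row {self.ids[i]!r} has length {len(r)}, expected {L}")


def _aa_alignment(ids, rows) -> Alignment:
    return _AAAlignment(ids, rows)


def write_phylip(matrix: SuperMatrix, path) -> None:
    """Relaxed PHYLIP: name, two spaces, full row; header 'ntaxa ncols'."""
    aln = matrix.alignment
    with open(path, "w") as fh:
        fh.write(f"{aln.n} {aln.length}\n")
        for name, row in aln:
            fh.write(f"{name}  {row}\n")


def write_partitions(matrix: SuperMatrix, path) -> None:
    """RAxML-style partition file: 'KIND, gene = start-end' per block."""
    with open(path, "w") as fh:
        for gene, (s, e, kind) in matrix.partitions.items():
            fh.write(f"{kind if matrix.alphabet == 'DNA' else 'PROT'}, {gene} = {s}-{e}\n")
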