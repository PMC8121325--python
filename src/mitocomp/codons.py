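"""Codon counting and relative synonymous codon usage (RSCU).

RSCU of a codon is its observed count divided by the count expected if all
codons for the same amino acid were used equally:

    RSCU(c) = k_a * n_c / sum_{c' in family(a)} n_c'

where ``k_a`` is the synonymous-family size.  Under the invertebrate
mitochondrial code (NCBI translation table 5) AGA/AGG encode Ser, AUA Met
and UGA Trp, so Leu is a 6-codon family and Ser an 8-codon family; the two
stop codons UAA/UAG form their own 2-member family, reported separately
from the sense total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .genomes import AnnotatedGenome, extract_feature_sequence

log = logging.getLogger(__name__)

__all__ = [
    "GeneticCode",
    "CodonCountTable",
    "RSCUTable",
    "count_codons",
    "rscu",
    "preferred_codons",
]

_BASES = "TCAG"


def _dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


class GeneticCode:
    """A genetic code by NCBI translation-table id (default 5, invertebrate
    mitochondrial).  Codons are held as DNA triplets internally; lookups
    accept RNA spelling too."""

    def __init__(self, table_id: int = 5):
        try:
            tbl = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise ValueError(f"unknown NCBI translation table {table_id}") from exc
        self.id = table_id
        self.name = tbl.names[0] if tbl.names else str(table_id)
        self._aa = dict(tbl.forward_table)
        self.stop_codons = frozenset(tbl.stop_codons)
        self.sense_codons = frozenset(self._aa)
        fams: dict[str, list[str]] = {}
        for codon, aa in self._aa.items():
            fams.setdefault(aa, []).append(codon)
        self.families = {aa: tuple(sorted(cs)) for aa, cs in fams.items()}

    def aa(self, codon: str) -> str | None:
        """One-letter amino acid, '*' for stop, None for ambiguous codons."""
        c = _dna(codon)
        if c in self.stop_codons:
            return "*"
        return self._aa.get(c)

    def is_stop(self, codon: str) -> bool:
        return _dna(codon) in self.stop_codons

    def family(self, codon: str) -> tuple[str, ...]:
        c = _dna(codon)
        if c in self.stop_codons:
            return tuple(sorted(self.stop_codons))
        return self.families[self._aa[c]]

    def family_size(self, codon: str) -> int:
        return len(self.family(codon))

    def __repr__(self):
        return f"GeneticCode(id={self.id})"


@lru_cache(maxsize=8)
def get_code(table_id: int = 5) -> GeneticCode:
    return GeneticCode(table_id)


@dataclass
class CodonCountTable:
    counts: dict  # DNA codon -> count, sense codons only
    stop_counts: dict  # DNA stop codon -> count
    code: GeneticCode
    internal_stops: list = field(default_factory=list)  # (gene, codon_index)

    @property
    def total_sense(self) -> int:
        return sum(self.counts.values())

    @property
    def total_stops(self) -> int:
        return sum(self.stop_counts.values())

    @property
    def total_codons(self) -> int:
        return self.total_sense + self.total_stops

    def count(self, codon: str) -> int:
        c = _dna(codon)
        if c in self.code.stop_codons:
            return self.stop_counts.get(c, 0)
        return self.counts.get(c, 0)

    @classmethod
    def from_counts(cls, counts: dict, code: GeneticCode | None = None) -> "CodonCountTable":
        """Build from a plain codon->count mapping (RNA or DNA spelling)."""
        code = code or get_code(5)
        sense: dict[str, int] = {}
        stops: dict[str, int] = {}
        for codon, n in counts.items():
            c = _dna(codon)
            if code.is_stop(c):
                stops[c] = stops.get(c, 0) + int(n)
            elif c in code.sense_codons:
                sense[c] = sense.get(c, 0) + int(n)
            else:
                raise ValueError(f"not a codon under table {code.id}: {codon!r}")
        return cls(sense, stops, code)


def count_codons(genome: AnnotatedGenome, code: GeneticCode | None = None) -> CodonCountTable:
    """Pool in-frame codon counts over all protein-coding genes.

    Each CDS is read on its coding strand from position 1; a trailing
    incomplete codon (length not a multiple of 3) is dropped.  Stop codons
    are tallied separately from the sense total; an in-frame stop before
    the final codon is logged with its position but not fatal, because real
    annotations contain read-through edge cases.
    """
    code = code or get_code(5)
    sense: dict[str, int] = {}
    stops: dict[str, int] = {}
    internal: list[tuple[str, int]] = []
    for f in genome.pcgs:
        seq = extract_feature_sequence(genome, f)
        n_codons = len(seq) // 3
        for i in range(n_codons):
            codon = seq[3 * i:3 * i + 3]
            if code.is_stop(codon):
                stops[codon] = stops.get(codon, 0) + 1
                if i < n_codons - 1:
                    internal.append((f.name, i))
                    log.warning("in-frame stop %s at codon %d of %s", codon, i + 1, f.name)
            elif codon in code.sense_codons:
                sense[codon] = sense.get(codon, 0) + 1
            # codons containing N are skipped silently
    return CodonCountTable(sense, stops, code, internal)


@dataclass
class RSCUTable:
    rscu: dict  # DNA codon -> ratio; includes the stop family
    family_size: dict  # amino acid (one-letter, '*') -> int
    code: GeneticCode
    missing_families: tuple = ()

    def value(self, codon: str) -> float | None:
        return self.rscu.get(_dna(codon))

    def as_rna(self) -> dict:
        return {_rna(c): v for c, v in self.rscu.items()}


def rscu(counts: CodonCountTable) -> RSCUTable:
    """RSCU per codon, with Leu and Ser pooled into single families.

    Families whose total count is zero have no defined RSCU and are listed
    in ``missing_families``.  The stop pair is treated as a 2-member family
    of its own.
    """
    code = counts.code
    values: dict[str, float] = {}
    fam_sizes: dict[str, int] = {}
    missing: list[str] = []
    for aa, fam in sorted(code.families.items()):
        fam_sizes[aa] = len(fam)
        total = sum(counts.counts.get(c, 0) for c in fam)
        if total == 0:
            missing.append(aa)
            continue
        for c in fam:
            values[c] = len(fam) * counts.counts.get(c, 0) / total
    stop_fam = tuple(sorted(code.stop_codons))
    fam_sizes["*"] = len(stop_fam)
    stop_total = sum(counts.stop_counts.get(c, 0) for c in stop_fam)
    if stop_total > 0:
        for c in stop_fam:
            values[c] = len(stop_fam) * counts.stop_counts.get(c, 0) / stop_total
    else:
        missing.append("*")
    return RSCUTable(values, fam_sizes, code, tuple(missing))


def preferred_codons(rscu_table: RSCUTable, counts: CodonCountTable, k: int):
    """Top-``k`` sense codons by RSCU.

    Ties are broken by raw count, then alphabetically (a fully tied input is
    flagged).  Also reports whether every returned codon ends in A or U,
    the hallmark of AT-rich third positions.
    """
    sense = [(c, v) for c, v in rscu_table.rscu.items()
             if not rscu_table.code.is_stop(c)]
    if k > len(sense):
        raise ValueError(f"k={k} exceeds {len(sense)} sense codons with defined RSCU")
    ranked = sorted(sense, key=lambda cv: (-cv[1], -counts.counts.get(cv[0], 0), cv[0]))
    top = [_rna(c) for c, _ in ranked[:k]]
    tied = len({round(v, 12) for _, v in sense}) == 1 and k > 0
    ends_au = all(c[-1] in "AU" for c in top) if top else False
    return {"codons": top, "all_end_AU": ends_au, "tied": tied}
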