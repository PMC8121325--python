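"""Annotated mitogenome and alignment containers plus flat-file I/O.

The in-memory model is deliberately small: an :class:`AnnotatedGenome` is a
DNA string plus an ordered list of :class:`GeneFeature` records with 1-based
inclusive coordinates, exactly as a curator would type them from a genome
organisation table.  Insect mitogenomes are circular, so a feature may wrap
the sequence origin (``end < start``); the control region is stored as an
explicit feature and never inferred.

Strand convention: ``H`` is the deposited (majority) strand, ``L`` the
complement.  Gene names are normalised to a compact vocabulary
(``cox1..3``, ``nad1..6``, ``nad4L``, ``atp6/8``, ``cytb``, ``trnX``,
``12S``, ``16S``, ``CR``) because public records label the same genes in
many dialects (``COI``, ``ND5``, ``s-rRNA`` ...).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "Alignment",
    "normalize_gene_name",
    "read_genbank",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "extract_feature_sequence",
    "reverse_complement",
]

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")

_DNA_OK = set("ACGTN")
_ALN_OK = set("ACGTN-")

#: Canonical spellings for the 37 + 1 mitochondrial features.  Keys are
#: upper-cased, punctuation-stripped labels as found in public flatfiles.
_NAME_TABLE = {
    "COI": "cox1", "CO1": "cox1", "COX1": "cox1", "COXI": "cox1",
    "COII": "cox2", "CO2": "cox2", "COX2": "cox2", "COXII": "cox2",
    "COIII": "cox3", "CO3": "cox3", "COX3": "cox3", "COXIII": "cox3",
    "ND1": "nad1", "NAD1": "nad1", "NADH1": "nad1",
    "ND2": "nad2", "NAD2": "nad2", "NADH2": "nad2",
    "ND3": "nad3", "NAD3": "nad3", "NADH3": "nad3",
    "ND4": "nad4", "NAD4": "nad4", "NADH4": "nad4",
    "ND4L": "nad4L", "NAD4L": "nad4L", "NADH4L": "nad4L",
    "ND5": "nad5", "NAD5": "nad5", "NADH5": "nad5",
    "ND6": "nad6", "NAD6": "nad6", "NADH6": "nad6",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASE 6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASE 8": "atp8",
    "CYTB": "cytb", "COB": "cytb", "CYB": "cytb",
    "SRRNA": "12S", "S-RRNA": "12S", "RRNS": "12S", "12S": "12S",
    "12S RRNA": "12S", "12S RIBOSOMAL RNA": "12S", "SMALL SUBUNIT RIBOSOMAL RNA": "12S",
    "LRRNA": "16S", "L-RRNA": "16S", "RRNL": "16S", "16S": "16S",
    "16S RRNA": "16S", "16S RIBOSOMAL RNA": "16S", "LARGE SUBUNIT RIBOSOMAL RNA": "16S",
    "D-LOOP": "CR", "DLOOP": "CR", "CONTROL REGION": "CR", "CR": "CR",
    "AT RICH REGION": "CR", "A+T RICH REGION": "CR",
}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def normalize_gene_name(raw: str) -> str:
    """Map a heterogeneous gene label onto the canonical vocabulary.

    tRNAs become ``trn`` + one-letter amino-acid code, keeping a trailing
    ``1``/``2`` isoacceptor index when present (``tRNA-Leu(UUR)`` and
    ``trnL2`` both normalise to ``trnL2``; a bare ``tRNA-Leu`` stays
    ``trnL``).  Unknown labels are returned stripped but otherwise intact.
    """
    label = raw.strip()
    key = re.sub(r"[_*]", "", label).upper()
    if key in _NAME_TABLE:
        return _NAME_TABLE[key]
    m = re.match(r"^TRNA[-_ ]?([A-Z]{3})\s*(\d?)\s*(?:\((\w{3})\))?$", key)
    if not m:
        m = re.match(r"^TRN([A-Z])(\d?)$", key)
        if m:
            return f"trn{m.group(1)}{m.group(2)}"
        return label
    aa3, idx, anticodon = m.groups()
    one = _AA3_TO_1.get(aa3)
    if one is None:
        return label
    if not idx and anticodon:
        # the two Leu/Ser isoacceptors carry their codon family in brackets
        if one == "L":
            idx = "2" if anticodon in ("UUR", "TAA", "UAA") else "1"
        elif one == "S":
            idx = "1" if anticodon in ("AGN", "GCT", "GCU", "UCU", "TCT") else "2"
    return f"trn{one}{idx}"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: name, class, 1-based inclusive span, strand."""

    name: str
    gclass: str
    start: int
    end: int
    strand: str = "H"

    def __post_init__(self):
        if not self.name:
            raise ValueError("feature name must be nonempty")
        if self.gclass not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gclass!r}; expected one of {GENE_CLASSES}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates are 1-based; got {self.start}..{self.end}")

    def length(self, genome_length: int | None = None) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"feature {self.name} wraps the origin; genome length required")
        return genome_length - self.start + 1 + self.end

    @property
    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    taxon: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - _DNA_OK
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValueError(f"feature {f.name} ({f.start}..{f.end}) outside genome of length {n}")
            if f.wraps and not self.circular:
                raise ValueError(f"feature {f.name} has end < start on a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_class(self, gclass: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gclass == gclass]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_of_class("PCG")


@dataclass
class Alignment:
    """Equal-length gapped sequences with identifiers."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        self.rows = [r.upper() for r in self.rows]
        if self.rows:
            L = len(self.rows[0])
            for i, r in enumerate(self.rows):
                if len(r) != L:
                    raise ValueError(f"row {self.ids[i]!r} has length {len(r)}, expected {L}")
                bad = set(r) - _ALN_OK
                if bad:
                    raise ValueError(f"row {self.ids[i]!r} contains {sorted(bad)}")
        if len(set(self.ids)) != len(self.ids):
            dups = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dups}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(zip(self.ids, self.rows))

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in recs], [str(r.seq) for r in recs])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# readers / writers

def _classify(ftype: str, name: str) -> str | None:
    if name == "CR":
        return "CR"
    if ftype == "CDS":
        return "PCG"
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "rRNA":
        return "rRNA"
    if name.startswith("trn"):
        return "tRNA"
    if name in ("12S", "16S"):
        return "rRNA"
    if name in ("cox1", "cox2", "cox3", "cytb", "atp6", "atp8",
                "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"):
        return "PCG"
    return None


def read_genbank(path) -> AnnotatedGenome:
    """Read an annotated mitogenome from a GenBank flatfile.

    One :class:`GeneFeature` is emitted per annotated gene; ``CDS``, ``tRNA``,
    ``rRNA``, ``D-loop`` and ``misc_feature`` entries take precedence over
    bare ``gene`` features covering the same span.  Names are normalised via
    :func:`normalize_gene_name`.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"malformed GenBank flatfile {path}: {exc}") from exc
    seq = str(record.seq).upper()
    circular = record.annotations.get("topology", "circular") == "circular"

    feats: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    preferred = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature")
    ordered = [f for f in record.features if f.type in preferred] + \
              [f for f in record.features if f.type == "gene"]
    for f in ordered:
        quals = f.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        if f.type == "D-loop" and not label:
            label = "CR"
        name = normalize_gene_name(label)
        gclass = _classify(f.type, name)
        if gclass is None:
            continue
        loc = f.location
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[0].start) == 0 and int(parts[-1].end) == len(seq):
            # join() across the circular origin
            start, end = int(parts[-1].start) + 1, int(parts[0].end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        key = (name, start, end)
        if key in seen:
            continue
        seen.add(key)
        strand = "H" if (loc.strand or 1) >= 0 else "L"
        feats.append(GeneFeature(name, gclass, start, end, strand))
    if not feats:
        raise ValueError(f"no gene features found in {path}")
    feats.sort(key=lambda f: f.start)
    taxon = {"species": record.annotations.get("organism", record.id)}
    genome = AnnotatedGenome(record.id, seq, circular, feats, taxon)
    return genome


_TABLE_COLUMNS = ("gene", "class", "start", "end", "strand")


def read_gene_table(seq_path, table_path, circular: bool = True,
                    taxon: dict | None = None) -> AnnotatedGenome:
    """Build a genome from a FASTA sequence and a gene-table TSV.

    The TSV mirrors a genome-organisation table: columns ``gene``, ``class``,
    ``start``, ``end``, ``strand`` with 1-based inclusive coordinates.
    """
    recs = list(SeqIO.parse(str(seq_path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"expected exactly one sequence in {seq_path}, found {len(recs)}")
    seq = str(recs[0].seq).upper()

    feats: list[GeneFeature] = []
    file_taxon: dict = {}
    with open(table_path) as fh:
        lines = []
        for line in fh:
            if line.startswith("#taxon\t"):
                _, key, value = line.rstrip("\n").split("\t", 2)
                file_taxon[key] = value
            elif not line.startswith("#"):
                lines.append(line)
        reader = csv.DictReader(lines, delimiter="\t")
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"gene table {table_path} lacks columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                feat = GeneFeature(
                    normalize_gene_name(row["gene"]),
                    row["class"].strip(),
                    int(row["start"]),
                    int(row["end"]),
                    row["strand"].strip(),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{table_path}:{lineno}: {exc}") from exc
            if feat.start > len(seq) or feat.end > len(seq):
                raise ValueError(
                    f"{table_path}:{lineno}: {feat.name} coordinates "
                    f"{feat.start}..{feat.end} outside sequence of length {len(seq)}")
            if feat.wraps and not circular:
                raise ValueError(f"{table_path}:{lineno}: {feat.name} has start > end on a linear genome")
            feats.append(feat)
    names = [f.name for f in feats]
    dups = sorted({n for n in names if names.count(n) > 1})
    if dups:
        raise ValueError(f"duplicate gene names in {table_path}: {dups}")
    return AnnotatedGenome(recs[0].id, seq, circular, feats, taxon or file_taxon)


def write_gene_table(genome: AnnotatedGenome, table_path, seq_path=None) -> None:
    with open(table_path, "w") as fh:
        for key, value in genome.taxon.items():
            fh.write(f"#taxon\t{key}\t{value}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write(f"{f.name}\t{f.gclass}\t{f.start}\t{f.end}\t{f.strand}\n")
    if seq_path is not None:
        write_fasta(seq_path, [(genome.id, genome.sequence)])


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def extract_feature_sequence(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Return the coding-strand sequence of a feature.

    Strand ``H`` gives the deposited-strand substring, strand ``L`` its
    reverse complement.  A feature with ``end < start`` on a circular genome
    wraps the origin.
    """
    n = len(genome.sequence)
    if feature.start > n or feature.end > n:
        raise ValueError(f"feature {feature.name} out of bounds for genome of length {n}")
    if feature.wraps:
        if not genome.circular:
            raise ValueError(f"feature {feature.name} wraps origin of a linear genome")
        sub = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        sub = genome.sequence[feature.start - 1:feature.end]
    return reverse_complement(sub) if feature.strand == "L" else sub
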