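"""Gene-order accounting: intergenic spacers, overlaps, start/stop codons.

The spacer between consecutive features on the deposited strand is
``start(next) - end(previous) - 1``; a negative value is an overlap, the
sign convention used in genome-organisation tables.  Mitochondrial CDSs may
end on an incomplete stop codon (a trailing ``T`` or ``TA`` completed to
``UAA`` by polyadenylation), which is reported as such rather than an
error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genomes import AnnotatedGenome, extract_feature_sequence

log = logging.getLogger(__name__)

__all__ = ["LayoutRow", "LayoutTotals", "spacers_and_overlaps", "start_stop_codons"]


@dataclass(frozen=True)
class LayoutRow:
    gene: str
    start: int
    end: int
    strand: str
    length: int
    spacer_to_previous: int | None  # None for the first feature of a linear genome


@dataclass(frozen=True)
class LayoutTotals:
    n_spacer_regions: int
    total_spacer_bp: int
    n_overlap_pairs: int
    total_overlap_bp: int
    includes_origin_pair: bool


def spacers_and_overlaps(genome: AnnotatedGenome):
    """Per-gene spacer/overlap rows plus totals.

    Returns ``(rows, totals_with_origin, totals_without_origin)``.  Features
    are sorted by start on the deposited strand (with a warning if the input
    order differed); a feature nested inside its predecessor is reported and
    excluded from pair accounting.  For circular genomes the wrap-around
    pair (last feature back to the first) is included in the first totals
    object and excluded from the second, since published totals do not
    always state which rule they used.
    """
    feats = [f for f in genome.features if not f.wraps]
    wrapped = [f for f in genome.features if f.wraps]
    if wrapped:
        log.warning("genome %s: %d origin-wrapping feature(s) excluded from spacer rows: %s",
                    genome.id, len(wrapped), [f.name for f in wrapped])
    ordered = sorted(feats, key=lambda f: (f.start, f.end))
    if [f.name for f in ordered] != [f.name for f in feats]:
        log.warning("genome %s: features were not sorted by start; sorted internally", genome.id)

    rows: list[LayoutRow] = []
    spacers: list[int] = []
    prev_end = None
    max_end_seen = 0
    for f in ordered:
        spacer = None
        if prev_end is not None:
            if f.end <= max_end_seen:
                log.warning("genome %s: feature %s nested within a previous feature; "
                            "excluded from pair accounting", genome.id, f.name)
                rows.append(LayoutRow(f.name, f.start, f.end, f.strand,
                                      f.length(len(genome)), None))
                continue
            spacer = f.start - prev_end - 1
            spacers.append(spacer)
        rows.append(LayoutRow(f.name, f.start, f.end, f.strand, f.length(len(genome)), spacer))
        prev_end = f.end
        max_end_seen = max(max_end_seen, f.end)

    def _totals(vals, with_origin):
        pos = [v for v in vals if v > 0]
        neg = [v for v in vals if v < 0]
        return LayoutTotals(len(pos), sum(pos), len(neg), -sum(neg), with_origin)

    totals_no_origin = _totals(spacers, False)
    if genome.circular and len(ordered) >= 2:
        origin_spacer = (ordered[0].start + len(genome)) - max_end_seen - 1
        totals_with_origin = _totals(spacers + [origin_spacer], True)
    else:
        totals_with_origin = _totals(spacers, True)
    return rows, totals_with_origin, totals_no_origin


def start_stop_codons(genome: AnnotatedGenome) -> dict[str, dict]:
    """Start and stop codons of every protein-coding gene.

    The start codon is the first three coding-strand bases; the stop codon
    is the trailing full triplet when the length is a multiple of 3,
    otherwise the trailing partial codon (``T`` or ``TA``) flagged as
    incomplete.  Starts other than ATN/TTG/GTG are flagged unusual.
    """
    out: dict[str, dict] = {}
    for f in genome.pcgs:
        seq = extract_feature_sequence(genome, f)
        if len(seq) < 6:
            raise ValueError(f"PCG {f.name} is only {len(seq)} nt; too short for start+stop")
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            stop, incomplete = seq[-3:], False
        else:
            stop, incomplete = seq[-rem:], True
        out[f.name] = {
            "start_codon": start,
            "stop_codon": stop,
            "incomplete_stop": incomplete,
            "atn_start": start[:2] == "AT",
            "unusual_start": not (start[:2] == "AT" or start in ("TTG", "GTG")),
            "length": len(seq),
        }
    return out
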