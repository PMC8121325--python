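"""Base composition and strand-skew statistics.

Strand asymmetry of a mitogenome is summarised by

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed either from raw counts of a sequence or from already-tabulated
percentages.  Region summaries split the genome the way comparative
mitogenomics tables do: whole deposited strand, concatenated protein-coding
genes and their three codon positions, pooled tRNAs, the two rRNAs and the
control region.  ``N`` (and gap) characters never enter numerator or
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genomes import AnnotatedGenome, extract_feature_sequence

log = logging.getLogger(__name__)

__all__ = [
    "CompositionSummary",
    "base_composition",
    "skew_from_fractions",
    "region_composition",
    "group_summary",
    "REGION_ORDER",
]

REGION_ORDER = (
    "Whole", "PCGs", "1st codon position", "2nd codon position",
    "3rd codon position", "tRNA", "16S", "12S", "CR",
)


@dataclass(frozen=True)
class CompositionSummary:
    countA: int
    countC: int
    countG: int
    countT: int

    @property
    def length(self) -> int:
        return self.countA + self.countC + self.countG + self.countT

    @property
    def pctA(self) -> float:
        return 100.0 * self.countA / self.length

    @property
    def pctC(self) -> float:
        return 100.0 * self.countC / self.length

    @property
    def pctG(self) -> float:
        return 100.0 * self.countG / self.length

    @property
    def pctT(self) -> float:
        return 100.0 * self.countT / self.length

    @property
    def pctAT(self) -> float:
        return self.pctA + self.pctT

    @property
    def at_skew(self) -> float:
        return (self.countA - self.countT) / (self.countA + self.countT)

    @property
    def gc_skew(self) -> float:
        return (self.countG - self.countC) / (self.countG + self.countC)

    def as_dict(self) -> dict:
        return {
            "A%": self.pctA, "C%": self.pctC, "G%": self.pctG, "T%": self.pctT,
            "A+T%": self.pctAT, "AT-skew": self.at_skew, "GC-skew": self.gc_skew,
            "Length(bp)": self.length,
        }


def base_composition(seq: str) -> CompositionSummary:
    """Counts, percentages and skews of a DNA string; N and ``-`` ignored."""
    s = seq.upper()
    summary = CompositionSummary(s.count("A"), s.count("C"), s.count("G"), s.count("T"))
    if summary.length == 0:
        raise ValueError("no countable bases (sequence empty or all N)")
    return summary


def skew_from_fractions(a: float, t: float, g: float, c: float) -> tuple[float, float]:
    """Skews straight from tabulated base percentages (no sequence needed)."""
    if a + t <= 0:
        raise ValueError("A + T fraction must be positive")
    if g + c <= 0:
        raise ValueError("G + C fraction must be positive")
    return (a - t) / (a + t), (g - c) / (g + c)


def _codon_position_slices(pcg_seqs: list[str]) -> tuple[str, str, str]:
    """Split each coding sequence by reading-frame position, then pool.

    Trailing partial codons keep their bases (a gene of length 3k+1
    contributes k+1 first positions), matching how per-position totals in
    published organisation tables sum to the full coding length.
    """
    pos = ["", "", ""]
    for seq in pcg_seqs:
        for i in range(3):
            pos[i] += seq[i::3]
    return tuple(pos)


def region_composition(genome: AnnotatedGenome) -> dict[str, CompositionSummary]:
    """Per-region composition table for one genome.

    Regions: whole deposited strand; all PCGs concatenated on their coding
    strands; the three codon positions of that concatenation (frame-aware per
    gene); pooled tRNAs; 16S; 12S; control region.  Regions with no members
    are omitted with a warning.
    """
    out: dict[str, CompositionSummary] = {}
    out["Whole"] = base_composition(genome.sequence)

    pcg_seqs = [extract_feature_sequence(genome, f) for f in genome.pcgs]
    if pcg_seqs:
        out["PCGs"] = base_composition("".join(pcg_seqs))
        slices = _codon_position_slices(pcg_seqs)
        for i, name in enumerate(("1st codon position", "2nd codon position", "3rd codon position")):
            out[name] = base_composition(slices[i])
    else:
        log.warning("genome %s: no PCG features; codon-position rows omitted", genome.id)

    trna = [extract_feature_sequence(genome, f) for f in genome.features_of_class("tRNA")]
    if trna:
        out["tRNA"] = base_composition("".join(trna))
    else:
        log.warning("genome %s: no tRNA features", genome.id)

    for rname in ("16S", "12S"):
        hits = [f for f in genome.features if f.name == rname]
        if hits:
            out[rname] = base_composition("".join(extract_feature_sequence(genome, f) for f in hits))
        else:
            log.warning("genome %s: no %s feature", genome.id, rname)

    cr = genome.features_of_class("CR")
    if cr:
        out["CR"] = base_composition("".join(extract_feature_sequence(genome, f) for f in cr))
    else:
        log.warning("genome %s: no control region feature", genome.id)
    return out


def group_summary(genomes: list[AnnotatedGenome], group_key: str = "subfamily",
                  mode: str = "mean_percent") -> "pandas.DataFrame":
    """Whole-genome composition aggregated by a taxon field.

    ``mean_percent`` (default) averages per-species base percentages within
    each group and recomputes the skews from the mean percentages;
    ``pooled`` sums raw counts across members first.  The two agree to
    printed precision whenever group members have similar genome sizes.
    """
    import pandas as pd

    if mode not in ("mean_percent", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    groups: dict[str, list[AnnotatedGenome]] = {}
    for g in genomes:
        if group_key not in g.taxon:
            raise KeyError(f"genome {g.id} has no taxon field {group_key!r}")
        groups.setdefault(g.taxon[group_key], []).append(g)

    rows = []
    for name, members in groups.items():
        summaries = [base_composition(g.sequence) for g in members]
        if mode == "pooled":
            pooled = CompositionSummary(
                sum(s.countA for s in summaries), sum(s.countC for s in summaries),
                sum(s.countG for s in summaries), sum(s.countT for s in summaries))
            a, c, gg, t = pooled.pctA, pooled.pctC, pooled.pctG, pooled.pctT
        else:
            k = len(summaries)
            a = sum(s.pctA for s in summaries) / k
            c = sum(s.pctC for s in summaries) / k
            gg = sum(s.pctG for s in summaries) / k
            t = sum(s.pctT for s in summaries) / k
        at_skew, gc_skew = skew_from_fractions(a, t, gg, c)
        rows.append({group_key: name, "n": len(members), "A%": a, "C%": c,
                     "G%": gg, "T%": t, "A+T%": a + t,
                     "AT-skew": at_skew, "GC-skew": gc_skew})
    return pd.DataFrame(rows).set_index(group_key)
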