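"""Seeded generators for every input the pipeline consumes.

The genome generator emulates an AT-rich (~75-80% A+T) circular insect
mitogenome: 13 protein-coding genes, 22 tRNAs, 2 rRNAs laid out on two
strands with small spacers, a control region that may carry a planted
tandem-repeat array, ATN/TTG start and TAA/TAG (or incomplete T) stop
codons.  Bases are drawn i.i.d. from the composition implied by the target
A+T fraction and strand skews, so measured composition converges on the
targets by the law of large numbers.

The codon-alignment generator evolves sequences from a random ancestor
along a star tree; proposed single-nucleotide codon changes are accepted
with relative probability 1 when synonymous and ``omega`` when
nonsynonymous (stop-creating changes rejected), which makes the realised
nonsynonymous/synonymous rate ratio equal the requested omega.  Everything
is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import GeneticCode, get_code
from .genomes import Alignment, AnnotatedGenome, GeneFeature, reverse_complement

__all__ = [
    "GenomeSpec", "AlignmentSpec", "RepeatSpec",
    "generate_genome", "generate_codon_alignment", "generate_nucleotide_alignment",
]

_PCG_NAMES = ("nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
              "nad5", "nad4", "nad4L", "nad6", "cytb", "nad1")
# typical leafhopper-scale gene lengths (multiples of 3)
_PCG_LENGTHS = (972, 1536, 678, 153, 651, 780, 354, 1671, 1326, 279, 483, 1137, 942)
_TRNA_NAMES = ("trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
               "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
               "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV")
_RRNA_NAMES = ("16S", "12S")
_RRNA_LENGTHS = (1188, 727)
# minority-strand genes, mirroring the usual insect arrangement
_L_STRAND = {"trnQ", "trnC", "trnY", "trnF", "nad5", "trnH", "nad4", "nad4L",
             "trnP", "nad1", "trnL1", "16S", "trnV", "12S"}


@dataclass(frozen=True)
class RepeatSpec:
    period: int
    copies: float
    identity: float = 1.0


@dataclass
class GenomeSpec:
    length: int = 15000
    target_at: float = 77.9       # % A+T, the across-subfamily average
    target_at_skew: float = 0.08
    target_gc_skew: float = -0.10
    n_pcg: int = 13
    n_trna: int = 22
    n_rrna: int = 2
    cr_length: int = 525
    repeat_spec: RepeatSpec | None = None
    n_incomplete_stops: int = 0   # PCGs ending on a trailing 'T'
    seed: int = 0
    species: str | None = None
    subfamily: str = "Simulatinae"
    tribe: str | None = None

    def base_probs(self) -> dict:
        at = self.target_at / 100.0
        gc = 1.0 - at
        p = {
            "A": at * (1 + self.target_at_skew) / 2,
            "T": at * (1 - self.target_at_skew) / 2,
            "G": gc * (1 + self.target_gc_skew) / 2,
            "C": gc * (1 - self.target_gc_skew) / 2,
        }
        if any(v <= 0 for v in p.values()):
            raise ValueError("infeasible composition: skews must lie strictly inside (-1, 1)")
        return p


def _gene_lengths(spec: GenomeSpec) -> tuple[list, list, list]:
    pcg = [(_PCG_NAMES[i % 13], _PCG_LENGTHS[i % 13]) for i in range(spec.n_pcg)]
    trna = [(_TRNA_NAMES[i % 22], 66) for i in range(spec.n_trna)]
    rrna = [(_RRNA_NAMES[i % 2], _RRNA_LENGTHS[i % 2]) for i in range(spec.n_rrna)]
    return pcg, trna, rrna


def _layout(spec: GenomeSpec):
    """Deterministic feature order: tRNA punctuation between PCGs, rRNAs
    near the end, control region last (ending at the genome end)."""
    pcg, trna, rrna = _gene_lengths(spec)
    order: list[tuple[str, str, int]] = []
    ti = 0
    for name, ln in pcg:
        if ti < len(trna):
            order.append((trna[ti][0], "tRNA", trna[ti][1]))
            ti += 1
        order.append((name, "PCG", ln))
    for name, ln in rrna:
        if ti < len(trna):
            order.append((trna[ti][0], "tRNA", trna[ti][1]))
            ti += 1
        order.append((name, "rRNA", ln))
    while ti < len(trna):
        order.append((trna[ti][0], "tRNA", trna[ti][1]))
        ti += 1
    return order


def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Simulate one annotated circular mitogenome from a :class:`GenomeSpec`."""
    rng = np.random.default_rng(spec.seed)
    probs = spec.base_probs()

    order = _layout(spec)
    total_genes = sum(ln for _, _, ln in order) + spec.cr_length
    slack = spec.length - total_genes
    if slack < 0:
        raise ValueError(
            f"infeasible spec: features need {total_genes} bp but genome length is {spec.length}")
    n_gaps = len(order) + 1  # before each feature and before the CR
    gaps = [slack // n_gaps] * n_gaps
    for i in range(slack - sum(gaps)):
        gaps[i % n_gaps] += 1

    bases = np.array(list("ATGC"))
    pvec = np.array([probs[b] for b in "ATGC"])
    seq = list(rng.choice(bases, size=spec.length, p=pvec))

    features: list[GeneFeature] = []
    pos = 1
    for gi, (name, gclass, ln) in enumerate(order):
        pos += gaps[gi]
        strand = "L" if name in _L_STRAND else "H"
        features.append(GeneFeature(name, gclass, pos, pos + ln - 1, strand))
        pos += ln
    pos += gaps[-1]
    cr_start = spec.length - spec.cr_length + 1
    features.append(GeneFeature("CR", "CR", cr_start, spec.length, "H"))

    # give PCGs proper start/stop codons on their coding strands
    starts = ("ATG", "ATT", "ATA", "TTG")
    incomplete_left = spec.n_incomplete_stops
    feats_out = []
    for f in features:
        if f.gclass != "PCG":
            feats_out.append(f)
            continue
        start_codon = starts[0] if f.name not in ("nad5", "atp8") else "TTG"
        stop_codon = "TAA" if rng.random() < 0.8 else "TAG"
        s, e = f.start, f.end
        if incomplete_left > 0:
            # shorten at the coding 3' end: length mod 3 becomes 1
            if f.strand == "H":
                e -= 2
            else:
                s += 2
            incomplete_left -= 1
            stop_codon = "T"
        _write_codon(seq, s, e, f.strand, start_codon, stop_codon)
        feats_out.append(GeneFeature(f.name, "PCG", s, e, f.strand))
    features = feats_out

    if spec.repeat_spec is not None:
        _plant_repeat(seq, features[-1], spec.repeat_spec, probs, rng)

    taxon = {"species": spec.species or f"sim_sp{spec.seed}",
             "subfamily": spec.subfamily}
    if spec.tribe:
        taxon["tribe"] = spec.tribe
    return AnnotatedGenome(f"sim{spec.seed}", "".join(seq), True, features, taxon)


def _write_codon(seq: list, start: int, end: int, strand: str,
                 start_codon: str, stop_codon: str) -> None:
    if strand == "H":
        seq[start - 1:start + 2] = list(start_codon)
        seq[end - len(stop_codon):end] = list(stop_codon)
    else:
        rc_start = reverse_complement(start_codon)
        rc_stop = reverse_complement(stop_codon)
        seq[end - 3:end] = list(rc_start)
        seq[start - 1:start - 1 + len(rc_stop)] = list(rc_stop)


def _plant_repeat(seq: list, cr: GeneFeature, rep: RepeatSpec, probs: dict,
                  rng: np.random.Generator) -> None:
    span = int(round(rep.period * rep.copies))
    if span > cr.end - cr.start + 1:
        raise ValueError(f"repeat span {span} exceeds control region length "
                         f"{cr.end - cr.start + 1}")
    bases = np.array(list("ATGC"))
    pvec = np.array([probs[b] for b in "ATGC"])
    unit = rng.choice(bases, size=rep.period, p=pvec)
    array = np.tile(unit, int(np.ceil(rep.copies)))[:span]
    n_mut = int(round((1 - rep.identity) * (span - rep.period)))
    if n_mut > 0:
        # mutate interior positions of the final copy only, so each mutation
        # costs exactly one position of copy-to-copy identity
        interior = np.arange(span - rep.period + 1, span - 1)
        sites = rng.choice(interior, size=min(n_mut, interior.size), replace=False)
        for s in sites:
            cur = array[s]
            array[s] = rng.choice([b for b in "ATGC" if b != cur])
    max_off = (cr.end - cr.start + 1) - span
    off = int(rng.integers(0, max_off + 1)) if max_off > 0 else 0
    p0 = cr.start - 1 + off
    seq[p0:p0 + span] = list(array)


# ---------------------------------------------------------------------------
# alignments

@dataclass
class AlignmentSpec:
    n_taxa: int = 20
    n_codons: int = 500
    divergence: float = 0.2   # expected pairwise substitutions per nucleotide site
    omega: float = 0.4
    code_id: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")
        if self.n_taxa < 2 or self.n_codons < 1:
            raise ValueError("need at least 2 taxa and 1 codon")


def generate_codon_alignment(spec: AlignmentSpec) -> Alignment:
    """Evolve codon sequences from a random ancestor along a star tree.

    Each tip receives a Poisson number of accepted substitutions targeting
    ``divergence / 2`` per site per branch, so the expected tip-to-tip
    divergence matches the spec.  Synonymous proposals are always accepted,
    nonsynonymous ones with probability ``omega``; proposals creating a
    stop codon are rejected outright.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_code(spec.code_id)
    sense = sorted(code.sense_codons)
    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=spec.n_codons)]
    L = 3 * spec.n_codons
    rows = []
    for t in range(spec.n_taxa):
        codons = list(ancestor)
        target = rng.poisson(spec.divergence / 2 * L)
        accepted = 0
        guard = 0
        while accepted < target:
            guard += 1
            if guard > 200 * (target + 10):
                raise RuntimeError("substitution sampler failed to converge")
            site = int(rng.integers(0, L))
            ci, cp = divmod(site, 3)
            old = codons[ci]
            new_base = "ACGT"[int(rng.integers(0, 4))]
            if new_base == old[cp]:
                continue
            new = old[:cp] + new_base + old[cp + 1:]
            if code.is_stop(new):
                continue
            if code.aa(new) != code.aa(old) and rng.random() >= spec.omega:
                continue
            codons[ci] = new
            accepted += 1
        rows.append("".join(codons))
    return Alignment([f"taxon{t + 1}" for t in range(spec.n_taxa)], rows)


def generate_nucleotide_alignment(n_taxa: int, length: int, divergence: float,
                                  hotspot: tuple | None = None,
                                  seed: int = 0) -> Alignment:
    """Star-tree nucleotide alignment for diversity tests.

    Every site of every tip mutates independently with probability
    ``divergence / 2`` (doubled inside the optional ``(start, end, factor)``
    hotspot, 1-based inclusive, rate multiplied by ``factor``) to a
    uniformly chosen different base.  Under this model two tips differ at a
    site with probability ``2 m (1 - m) + (2/3) m**2`` for per-branch rate
    ``m``.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ancestor = rng.integers(0, 4, size=length)
    rate = np.full(length, divergence / 2.0)
    if hotspot is not None:
        s, e, factor = hotspot
        rate[s - 1:e] = np.minimum(1.0, rate[s - 1:e] * factor)
    rows = []
    for t in range(n_taxa):
        mut = rng.random(length) < rate
        shift = rng.integers(1, 4, size=length)
        tip = np.where(mut, (ancestor + shift) % 4, ancestor)
        rows.append("".join(bases[tip]))
    return Alignment([f"taxon{t + 1}" for t in range(n_taxa)], rows)
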