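"""Pairwise Ka/Ks by the Nei–Gojobori (1986) pathway-counting method.

For each codon, synonymous site counts are the per-position fractions of
the nine single-nucleotide neighbours that preserve the amino acid
(changes to stop codons count as nonsynonymous), so syn + nonsyn = 3
exactly.  Observed differences between a codon pair are classified by
averaging equally over all minimal substitution pathways (1, 2 or 6
orderings for 1/2/3 differing positions); pathways passing through a stop
codon are excluded and the rest reweighted.  Proportions are corrected
with the Jukes–Cantor formula

    K = -(3/4) * ln(1 - 4p/3)

and omega = Ka/Ks whenever Ks > 0.  An omega below 1 indicates purifying
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations
from math import log as _ln

from .codons import GeneticCode, get_code
from .genomes import Alignment

log = logging.getLogger(__name__)

__all__ = ["PairwiseRates", "ng86_site_counts", "ng86_pair", "gene_omega", "jukes_cantor"]

_BASES = "ACGT"


def ng86_site_counts(codon: str, code: GeneticCode | None = None) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    code = code or get_code(5)
    c = codon.upper().replace("U", "T")
    if code.is_stop(c):
        raise ValueError(f"{codon} is a stop codon under table {code.id}")
    aa = code.aa(c)
    if aa is None:
        raise ValueError(f"{codon!r} is not an unambiguous codon")
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == c[pos]:
                continue
            mut = c[:pos] + b + c[pos + 1:]
            # stops count as nonsynonymous changes
            if not code.is_stop(mut) and code.aa(mut) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon
    pair, or None when every minimal pathway crosses a stop codon."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    n_valid = 0
    for order in permutations(diff):
        cur = c1
        path_syn = path_nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.aa(nxt) == code.aa(cur):
                path_syn += 1
            else:
                path_nonsyn += 1
            cur = nxt
        if blocked:
            continue
        syn_total += path_syn
        nonsyn_total += path_nonsyn
        n_valid += 1
    if n_valid == 0:
        return None
    return syn_total / n_valid, nonsyn_total / n_valid


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor distance; None when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * _ln(1 - 4 * p / 3)


@dataclass(frozen=True)
class PairwiseRates:
    seq_pair: tuple
    n_codons: int  # codon pairs actually compared
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    omega: float | None
    n_skipped: int  # codon pairs skipped (gaps/N/stops/blocked pathways)


def ng86_pair(seq1: str, seq2: str, code: GeneticCode | None = None,
              ids: tuple = ("seq1", "seq2")) -> PairwiseRates:
    """Nei–Gojobori rates for one pair of in-frame gapless codon sequences.

    Codon pairs containing gaps, N, a stop codon, or connected only through
    stop-codon pathways are skipped (and counted).  Expected site counts are
    averaged between the two sequences, as in the original method.
    """
    code = code or get_code(5)
    s1 = seq1.upper().replace("U", "T")
    s2 = seq2.upper().replace("U", "T")
    if len(s1) != len(s2):
        raise ValueError(f"sequence lengths differ: {len(s1)} vs {len(s2)}")
    if len(s1) % 3:
        raise ValueError(f"length {len(s1)} is not a multiple of 3")

    site_cache: dict[str, tuple[float, float]] = {}
    path_cache: dict[tuple[str, str], tuple[float, float] | None] = {}
    S = N = Sd = Nd = 0.0
    n_codons = n_skipped = 0
    for k in range(0, len(s1), 3):
        c1, c2 = s1[k:k + 3], s2[k:k + 3]
        if c1 not in code.sense_codons or c2 not in code.sense_codons:
            n_skipped += 1
            continue
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        if key not in path_cache:
            path_cache[key] = _pathway_counts(*key, code=code)
        counts = path_cache[key]
        if counts is None:
            log.warning("codon pair %s/%s at position %d connected only via stops; skipped",
                        c1, c2, k + 1)
            n_skipped += 1
            continue
        for c in (c1, c2):
            if c not in site_cache:
                site_cache[c] = ng86_site_counts(c, code)
        S += (site_cache[c1][0] + site_cache[c2][0]) / 2
        N += (site_cache[c1][1] + site_cache[c2][1]) / 2
        Sd += counts[0]
        Nd += counts[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    pS, pN = Sd / S, Nd / N
    Ks, Ka = jukes_cantor(pS), jukes_cantor(pN)
    omega = (Ka / Ks) if (Ka is not None and Ks is not None and Ks > 0) else None
    return PairwiseRates(tuple(ids), n_codons, S, N, Sd, Nd, pS, pN, Ks, Ka, omega, n_skipped)


def gene_omega(alignment: Alignment, code: GeneticCode | None = None) -> dict:
    """Average pairwise Ka, Ks and omega over all unordered pairs of an
    in-frame alignment.

    Pairs with undefined omega (Ks = 0 or saturated proportions) are
    excluded from the omega mean but counted; the gene-level omega is
    missing (None) when no pair defines one.  Classification is
    "purifying" for 0 < omega < 1, "neutral" at 1, "positive" above.
    """
    code = code or get_code(5)
    if alignment.n < 2:
        raise ValueError("need at least 2 sequences")
    pairs = []
    for i, j in combinations(range(alignment.n), 2):
        pairs.append(ng86_pair(alignment.rows[i], alignment.rows[j], code,
                               ids=(alignment.ids[i], alignment.ids[j])))
    omegas = [p.omega for p in pairs if p.omega is not None]
    kas = [p.Ka for p in pairs if p.Ka is not None]
    kss = [p.Ks for p in pairs if p.Ks is not None]
    mean_omega = sum(omegas) / len(omegas) if omegas else None
    if mean_omega is None:
        selection = "undefined"
    elif mean_omega < 1:
        selection = "purifying"
    elif mean_omega == 1:
        selection = "neutral"
    else:
        selection = "positive"
    return {
        "n_pairs": len(pairs),
        "n_undefined": len(pairs) - len(omegas),
        "mean_Ka": sum(kas) / len(kas) if kas else None,
        "mean_Ks": sum(kss) / len(kss) if kss else None,
        "mean_omega": mean_omega,
        "selection": selection,
        "pairs": pairs,
    }
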