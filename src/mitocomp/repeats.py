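"""Tandem-repeat detection in control regions and the size/repeat correlation.

The detector is a deterministic shift-identity scanner: for each candidate
period ``p`` it compares the sequence with itself shifted by ``p`` bases; a
maximal stretch where the running identity stays at or above the threshold
marks a tandem array spanning the stretch plus one extra period.  It is
parameter-transparent (period range, minimum copies, minimum identity) and
does not emulate any particular alignment-scoring automaton.  Fractional
trailing copies are reported as span/period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["RepeatAnnotation", "CorrelationResult", "find_tandem_repeats",
           "cr_repeat_correlation"]


@dataclass(frozen=True)
class RepeatAnnotation:
    unit: str
    period: int
    copies: float
    start: int  # 1-based inclusive
    end: int
    identity: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _segments(match: np.ndarray, min_identity: float, min_len: int):
    """Maximal high-identity stretches of a boolean match array.

    Runs of consecutive matches are merged across a mismatch gap only when
    the bridge improves the local identity score (next run contributes more
    than the gap costs at the threshold) and the merged stretch keeps its
    overall identity at or above the threshold.  Segments therefore always
    start and end on a match and do not creep into random flanking
    sequence.
    """
    idx = np.flatnonzero(match)
    if idx.size == 0:
        return
    # runs of consecutive matches as (start, end) half-open
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    ones = np.concatenate(([0], np.cumsum(match)))
    strict = (1 + min_identity) / 2  # boundary chunks must clear this

    def ident(s, e):
        return (ones[e] - ones[s]) / (e - s)

    def emit(members):
        # trim boundary runs whose bridge (run plus the gap separating it
        # from the rest) falls below the strict threshold: random flanking
        # matches merged into an array are removed here
        while len(members) > 1:
            (s0, e0), (s1, _) = members[0], members[1]
            if ident(s0, s1) < strict:
                members = members[1:]
                continue
            (sl, el) = members[-1]
            (_, ep) = members[-2]
            if ident(ep, el) < strict:
                members = members[:-1]
                continue
            break
        s, e = members[0][0], members[-1][1]
        if e - s >= min_len and ident(s, e) >= min_identity:
            return int(s), int(e), float(ident(s, e))
        return None

    members = [(int(run_starts[0]), int(run_ends[0]))]
    for rs, re in zip(run_starts[1:], run_ends[1:]):
        gap = rs - members[-1][1]
        bridge_ok = (re - rs) * (1 - min_identity) > gap * min_identity
        if bridge_ok and ident(members[0][0], re) >= min_identity:
            members.append((int(rs), int(re)))
        else:
            seg = emit(members)
            if seg:
                yield seg
            members = [(int(rs), int(re))]
    seg = emit(members)
    if seg:
        yield seg


def _consensus_unit(seq: str, start0: int, span: int, period: int) -> str:
    full = span // period
    cols = []
    for j in range(period):
        votes: dict[str, int] = {}
        for k in range(max(full, 1)):
            pos = start0 + k * period + j
            if pos < start0 + span:
                b = seq[pos]
                votes[b] = votes.get(b, 0) + 1
        cols.append(max(sorted(votes), key=votes.get))
    return "".join(cols)


def find_tandem_repeats(seq: str, min_period: int = 10, max_period: int = 300,
                        min_copies: float = 2.0, min_identity: float = 0.8
                        ) -> list[RepeatAnnotation]:
    """Detect tandem repeat arrays in a DNA string.

    For each period the self-alignment shifted by that period is scanned for
    high-identity stretches; a stretch of length m implies an array of span
    m + period and copies (m + period)/period.  Overlapping candidates from
    different periods are resolved by keeping the largest span, then the
    highest identity, then the smallest period; surviving annotations are
    returned in order of start position.
    """
    s = seq.upper()
    L = len(s)
    if L == 0:
        raise ValueError("empty sequence")
    if max_period > L // 2:
        log.warning("max_period %d exceeds half the sequence length; clamped to %d",
                    max_period, L // 2)
        max_period = L // 2
    if min_period < 1 or min_period > max_period:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: list[RepeatAnnotation] = []
    for p in range(min_period, max_period + 1):
        match = arr[:-p] == arr[p:]
        min_len = int(np.ceil((min_copies - 1) * p))
        for seg_s, seg_e, ident in _segments(match, min_identity, min_len):
            span = seg_e - seg_s + p
            copies = span / p
            if copies + 1e-9 < min_copies:
                continue
            unit = _consensus_unit(s, seg_s, span, p)
            candidates.append(RepeatAnnotation(unit, p, copies, seg_s + 1,
                                               seg_s + span, ident))
    candidates.sort(key=lambda r: (-r.span, -r.identity, r.period, r.start))
    kept: list[RepeatAnnotation] = []
    for cand in candidates:
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept


def cr_repeat_correlation(records) -> CorrelationResult:
    """Pearson correlation between control-region length and repeat count.

    ``records`` is a sequence of (cr_length, repeat_units) pairs, one per
    species; species are treated as independent points (no phylogenetic
    correction).  The p-value is the two-sided t-test on n-2 degrees of
    freedom.
    """
    x = np.asarray([r[0] for r in records], dtype=float)
    y = np.asarray([r[1] for r in records], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 records")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variable: zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
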