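"""Nucleotide diversity (Pi) per alignment and in sliding windows.

Pi is the mean pairwise proportion of differing sites among aligned
sequences.  Columns containing any gap or N are removed globally before
computation (complete deletion, the default of the classical population
genetics tools); a pairwise-deletion mode is available for sensitivity
analysis.  Window coordinates refer to the filtered alignment, since that
is the matrix a sliding-window figure is drawn on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genomes import Alignment

log = logging.getLogger(__name__)

__all__ = ["WindowSeries", "pi", "sliding_window_pi", "per_gene_pi", "filter_columns"]

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


def _matrix(alignment: Alignment) -> np.ndarray:
    return np.frombuffer("".join(alignment.rows).encode(), dtype=np.uint8).reshape(
        alignment.n, alignment.length)


def filter_columns(alignment: Alignment) -> np.ndarray:
    """Byte matrix of the alignment after complete deletion of gap/N columns."""
    m = _matrix(alignment)
    keep = np.isin(m, _VALID).all(axis=0)
    return m[:, keep]


def _pi_of_matrix(m: np.ndarray) -> float:
    n, L = m.shape
    if L == 0:
        raise ValueError("no usable sites after gap/N filtering")
    total = 0.0
    for i, j in combinations(range(n), 2):
        total += np.count_nonzero(m[i] != m[j]) / L
    return total / (n * (n - 1) / 2)


def pi(alignment: Alignment, deletion: str = "complete") -> float:
    """Average pairwise p-distance over all unordered sequence pairs."""
    if alignment.n < 2:
        raise ValueError("Pi needs at least 2 sequences")
    if deletion == "complete":
        return _pi_of_matrix(filter_columns(alignment))
    if deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    m = _matrix(alignment)
    ok = np.isin(m, _VALID)
    total = 0.0
    npairs = 0
    for i, j in combinations(range(alignment.n), 2):
        both = ok[i] & ok[j]
        sites = int(both.sum())
        if sites == 0:
            raise ValueError(f"no comparable sites between {alignment.ids[i]} and {alignment.ids[j]}")
        total += np.count_nonzero((m[i] != m[j]) & both) / sites
        npairs += 1
    return total / npairs


@dataclass(frozen=True)
class WindowSeries:
    window: int
    step: int
    midpoints: tuple  # 1-based positions on the filtered alignment
    pi_values: tuple
    filtered_length: int

    def __len__(self):
        return len(self.midpoints)

    def argmax_span(self) -> tuple[int, int]:
        """1-based span of the window with the highest Pi."""
        i = int(np.argmax(self.pi_values))
        start = 1 + i * self.step
        return start, start + self.window - 1


def sliding_window_pi(alignment: Alignment, window: int = 200, step: int = 20,
                      deletion: str = "complete") -> WindowSeries:
    """Pi in sliding windows over the gap-filtered alignment.

    The number of windows is ``floor((L_used - window)/step) + 1``; a final
    partial window is dropped.  Midpoint of a window starting at ``s``
    (1-based) is ``s + window/2 - 1``.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if deletion != "complete":
        raise ValueError("sliding windows are defined on the complete-deletion matrix")
    m = filter_columns(alignment)
    L = m.shape[1]
    if L < window:
        raise ValueError(f"usable length {L} shorter than window {window}")
    nwin = (L - window) // step + 1
    mids, vals = [], []
    for w in range(nwin):
        s = w * step
        vals.append(_pi_of_matrix(m[:, s:s + window]))
        mids.append(s + 1 + window / 2 - 1)
    return WindowSeries(window, step, tuple(mids), tuple(vals), L)


def per_gene_pi(gene_alignments: dict, deletion: str = "complete"):
    """Pi per gene, as a DataFrame sorted by descending diversity.

    Genes whose alignment fails (too few sequences, no usable sites) are
    listed in the ``error`` column rather than aborting the table.
    """
    import pandas as pd

    rows = []
    for gene, aln in gene_alignments.items():
        try:
            rows.append({"gene": gene, "length": aln.length,
                         "pi": pi(aln, deletion=deletion), "error": ""})
        except ValueError as exc:
            log.warning("gene %s: %s", gene, exc)
            rows.append({"gene": gene, "length": getattr(aln, "length", 0),
                         "pi": float("nan"), "error": str(exc)})
    df = pd.DataFrame(rows)
    return df.sort_values("pi", ascending=False, kind="stable").reset_index(drop=True)
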