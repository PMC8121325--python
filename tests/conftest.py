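"""Shared fixtures: the typed-in leafhopper gene table, printed codon-usage
counts, and small synthetic genomes/alignments."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pytest

from mitocomp import (
    AnnotatedGenome,
    GeneFeature,
    GenomeSpec,
    RepeatSpec,
    generate_genome,
)

DATA = Path(__file__).parent / "data"

# Gene organisation of the E. wengangensis mitogenome (14,830 bp), typed in
# from the published table: (gene, class, start, end, strand).  Only the
# internally consistent coordinate/strand columns are used.
EWEN_GENES = [
    ("trnI", "tRNA", 1, 63, "H"),
    ("trnQ", "tRNA", 61, 129, "L"),
    ("trnM", "tRNA", 138, 207, "H"),
    ("nad2", "PCG", 208, 1179, "H"),
    ("trnW", "tRNA", 1178, 1242, "H"),
    ("trnC", "tRNA", 1235, 1296, "L"),
    ("trnY", "tRNA", 1302, 1368, "L"),
    ("cox1", "PCG", 1370, 2905, "H"),
    ("trnL2", "tRNA", 2906, 2971, "H"),
    ("cox2", "PCG", 2972, 3650, "H"),
    ("trnK", "tRNA", 3651, 3721, "H"),
    ("trnD", "tRNA", 3721, 3784, "H"),
    ("atp8", "PCG", 3784, 3936, "H"),
    ("atp6", "PCG", 3930, 4580, "H"),
    ("cox3", "PCG", 4583, 5362, "H"),
    ("trnG", "tRNA", 5363, 5424, "H"),
    ("nad3", "PCG", 5425, 5778, "H"),
    ("trnA", "tRNA", 5783, 5845, "H"),
    ("trnR", "tRNA", 5848, 5913, "H"),
    ("trnN", "tRNA", 5912, 5976, "H"),
    ("trnS1", "tRNA", 5973, 6032, "H"),
    ("trnE", "tRNA", 6041, 6107, "H"),
    ("trnF", "tRNA", 6112, 6177, "L"),
    ("nad5", "PCG", 6178, 7849, "L"),
    ("trnH", "tRNA", 7850, 7912, "L"),
    ("nad4", "PCG", 7912, 9237, "L"),
    ("nad4L", "PCG", 9231, 9509, "L"),
    ("trnT", "tRNA", 9512, 9575, "H"),
    ("trnP", "tRNA", 9576, 9639, "L"),
    ("nad6", "PCG", 9642, 10124, "H"),
    ("cytb", "PCG", 10132, 11268, "H"),
    ("trnS2", "tRNA", 11267, 11329, "H"),
    ("nad1", "PCG", 11320, 12261, "L"),
    ("trnL1", "tRNA", 12262, 12326, "L"),
    ("16S", "rRNA", 12327, 13514, "L"),
    ("trnV", "tRNA", 13515, 13578, "L"),
    ("12S", "rRNA", 13579, 14305, "L"),
    ("CR", "CR", 14306, 14830, "H"),
]
EWEN_LENGTH = 14830


@pytest.fixture(scope="session")
def ewen_genome() -> AnnotatedGenome:
    """E. wengangensis gene layout over a reproducible random sequence.

    Coordinates and strands are the published ones; the sequence itself is
    synthetic (layout statistics do not depend on base content)."""
    rng = np.random.default_rng(20210501)
    seq = "".join(rng.choice(list("ACGT"), p=[0.42, 0.13, 0.10, 0.35], size=EWEN_LENGTH))
    feats = [GeneFeature(*row) for row in EWEN_GENES]
    return AnnotatedGenome("EWEN", seq, True, feats,
                           {"species": "E_wengangensis", "subfamily": "Typhlocybinae",
                            "tribe": "Erythroneurini"})


@pytest.fixture(scope="session")
def table6():
    """Printed codon counts and RSCU of the two leafhopper mitogenomes."""
    rows = []
    with open(DATA / "table6_printed.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append({"aa": row["aa"], "codon": row["codon"],
                         "count_w": int(row["count_w"]), "rscu_w": row["rscu_w"],
                         "count_g": int(row["count_g"]), "rscu_g": row["rscu_g"]})
    return rows


@pytest.fixture(scope="session")
def sim_genome() -> AnnotatedGenome:
    return generate_genome(GenomeSpec(seed=42, repeat_spec=RepeatSpec(50, 3.0, 1.0)))


@pytest.fixture()
def tmp_gene_table(tmp_path, ewen_genome):
    """The session genome written out as FASTA + TSV for reader tests."""
    from mitocomp import write_gene_table

    fa, tsv = tmp_path / "ewen.fasta", tmp_path / "ewen.tsv"
    write_gene_table(ewen_genome, tsv, seq_path=fa)
    return fa, tsv
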