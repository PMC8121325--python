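"""End-to-end report: publication-style tables from a set of genomes.

Emits the comparative tables a mitogenome paper prints — per-region
composition, group composition, gene layout, RSCU, per-gene and windowed
nucleotide diversity, Ka/Ks, control-region repeats and the CR-size /
repeat-count correlation — as TSVs with fixed column order plus a
machine-readable JSON summary.  Every output carries the configuration
hash and tool version so bundles are diffable and reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codons import count_codons, get_code, rscu
from .composition import group_summary, region_composition
from .diversity import per_gene_pi, sliding_window_pi
from .genomes import AnnotatedGenome, Alignment, extract_feature_sequence
from .layout import spacers_and_overlaps, start_stop_codons
from .repeats import cr_repeat_correlation, find_tandem_repeats
from .selection import gene_omega

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_report"]

SKEW_DECIMALS = 3
RSCU_DECIMALS = 2


@dataclass
class RunConfig:
    genome_tables: list = field(default_factory=list)  # (fasta, tsv) pairs
    genbank_files: list = field(default_factory=list)
    alignment_dir: str | None = None  # per-gene FASTA alignments (in-frame)
    code_id: int = 5
    window: int = 200
    step: int = 20
    min_period: int = 10
    max_period: int = 300
    min_copies: float = 2.0
    min_identity: float = 0.8
    group_by: str = "subfamily"
    outdir: str = "mitocomp_report"
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        # where the bundle is written (and how verbosely) does not change
        # what is computed, so those fields stay out of the hash
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("outdir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stamp(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mitocomp {__version__} config={cfg.digest()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_genomes(cfg: RunConfig) -> list[AnnotatedGenome]:
    from .genomes import read_gene_table, read_genbank

    genomes: list[AnnotatedGenome] = []
    for fa, tsv in cfg.genome_tables:
        genomes.append(read_gene_table(fa, tsv))
    for gb in cfg.genbank_files:
        genomes.append(read_genbank(gb))
    return genomes


def run_full_report(cfg: RunConfig, genomes: list[AnnotatedGenome] | None = None,
                    gene_alignments: dict | None = None) -> dict:
    """Run every pipeline stage and write the table bundle to ``cfg.outdir``.

    Genomes and per-gene alignments may be passed in memory or loaded from
    the config paths.  Per-genome failures are isolated and logged; the
    run fails only if every genome fails.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = _load_genomes(cfg)
    if not genomes:
        raise ValueError("no input genomes")
    code = get_code(cfg.code_id)

    summary: dict = {"version": __version__, "config": cfg.digest(),
                     "n_genomes": len(genomes), "genomes": {}, "failures": {}}
    region_rows, layout_rows, codon_rows, cr_rows = [], [], [], []
    cr_points = []
    ok = 0
    for g in genomes:
        try:
            regions = region_composition(g)
            for name, s in regions.items():
                region_rows.append({"genome": g.id, "region": name, **{
                    k: round(v, SKEW_DECIMALS) if "skew" in k.lower() else v
                    for k, v in s.as_dict().items()},
                    "countA": s.countA, "countC": s.countC,
                    "countG": s.countG, "countT": s.countT})
            rows, tot_o, tot_no = spacers_and_overlaps(g)
            codons_tbl = start_stop_codons(g)
            for r in rows:
                extra = codons_tbl.get(r.gene, {})
                layout_rows.append({
                    "genome": g.id, "gene": r.gene, "start": r.start, "end": r.end,
                    "size": r.length, "intergenic": r.spacer_to_previous,
                    "start_codon": extra.get("start_codon", ""),
                    "stop_codon": extra.get("stop_codon", ""),
                    "strand": r.strand})
            counts = count_codons(g, code)
            table = rscu(counts)
            for codon, val in sorted(table.as_rna().items()):
                codon_rows.append({"genome": g.id, "codon": codon,
                                   "aa": code.aa(codon),
                                   "count": counts.count(codon),
                                   "rscu": round(val, RSCU_DECIMALS)})
            crs = g.features_of_class("CR")
            n_units = 0
            for cr in crs:
                cr_seq = extract_feature_sequence(g, cr)
                reps = find_tandem_repeats(cr_seq, cfg.min_period, cfg.max_period,
                                           cfg.min_copies, cfg.min_identity)
                for rep in reps:
                    cr_rows.append({"genome": g.id, "cr_length": len(cr_seq),
                                    "unit": rep.unit, "period": rep.period,
                                    "copies": round(rep.copies, 2),
                                    "start": rep.start, "end": rep.end,
                                    "identity": round(rep.identity, 3)})
                n_units += sum(int(r.copies) for r in reps)
                cr_points.append((len(cr_seq), len(reps)))
            summary["genomes"][g.id] = {
                "length": len(g), "n_features": len(g.features),
                "total_codons": counts.total_codons,
                "spacer_bp": tot_o.total_spacer_bp, "overlap_bp": tot_o.total_overlap_bp,
                "spacer_bp_no_origin": tot_no.total_spacer_bp,
                "n_repeat_types": cr_points[-1][1] if crs else None,
                "total_repeat_units": n_units if crs else None,
            }
            ok += 1
        except Exception as exc:
            log.error("genome %s failed: %s", g.id, exc)
            summary["failures"][g.id] = str(exc)
    if ok == 0:
        raise RuntimeError("all genomes failed; see log")

    _stamp(out / "composition_regions.tsv", pd.DataFrame(region_rows), cfg)
    _stamp(out / "gene_layout.tsv", pd.DataFrame(layout_rows), cfg)
    _stamp(out / "rscu.tsv", pd.DataFrame(codon_rows), cfg)
    _stamp(out / "cr_repeats.tsv", pd.DataFrame(cr_rows), cfg)

    key = cfg.group_by
    if all(key in g.taxon for g in genomes):
        df = group_summary(genomes, key).reset_index()
        for col in ("AT-skew", "GC-skew"):
            df[col] = df[col].round(SKEW_DECIMALS)
        _stamp(out / "composition_groups.tsv", df, cfg)

    if len(cr_points) >= 3:
        try:
            corr = cr_repeat_correlation(cr_points)
            summary["cr_correlation"] = {"r": corr.r, "p": corr.p, "n": corr.n}
        except ValueError as exc:
            log.warning("CR correlation skipped: %s", exc)

    if gene_alignments is None and cfg.alignment_dir:
        gene_alignments = {p.stem: Alignment.from_fasta(p)
                           for p in sorted(Path(cfg.alignment_dir).glob("*.fasta"))}
    if gene_alignments:
        pi_df = per_gene_pi(gene_alignments)
        _stamp(out / "per_gene_pi.tsv", pi_df, cfg)
        win_rows, omega_rows = [], []
        for gene, aln in gene_alignments.items():
            try:
                series = sliding_window_pi(aln, cfg.window, cfg.step)
                win_rows += [{"gene": gene, "midpoint": m, "pi": round(v, 5)}
                             for m, v in zip(series.midpoints, series.pi_values)]
            except ValueError as exc:
                log.warning("windows for %s skipped: %s", gene, exc)
            if aln.length % 3 == 0:
                try:
                    res = gene_omega(aln, code)
                    omega_rows.append({
                        "gene": gene,
                        "mean_Ka": res["mean_Ka"], "mean_Ks": res["mean_Ks"],
                        "mean_omega": res["mean_omega"], "selection": res["selection"],
                        "n_pairs": res["n_pairs"], "n_undefined": res["n_undefined"]})
                except ValueError as exc:
                    log.warning("Ka/Ks for %s skipped: %s", gene, exc)
        _stamp(out / "window_pi.tsv", pd.DataFrame(win_rows), cfg)
        _stamp(out / "kaks.tsv", pd.DataFrame(omega_rows), cfg)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
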