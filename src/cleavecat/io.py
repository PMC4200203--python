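"""Readers and writers for the standard formats the pipeline consumes.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention on read/write; BED and bedGraph are native 0-based
half-open. Only the attributes the pipeline relies on (gene_id,
transcript_id, optional biotype) are preserved. All writers emit records
in deterministic genomic order so a fixed seed yields byte-identical
files.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from pyfaidx import Fasta

from .tracks import ConservationTrack, CoverageTrack, IntervalTrack
from .transcripts import TranscriptModel, sort_transcripts

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


# --- GTF ------------------------------------------------------------------

def read_gtf(path) -> List[TranscriptModel]:
    """Read exon records from a GTF file into TranscriptModels."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, tuple] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: exon without transcript_id")
            exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
            meta[tid] = (attrs.get("gene_id", tid), f[0], f[6],
                         attrs.get("biotype"))
    out = []
    for tid, ex in exons.items():
        gene_id, chrom, strand, biotype = meta[tid]
        strand = strand if strand in "+-" else "."
        out.append(TranscriptModel(tid, gene_id, chrom, strand,
                                   tuple(sorted(ex)), biotype=biotype))
    return sort_transcripts(out)


def write_gtf(transcripts: Sequence[TranscriptModel], path,
              source: str = "cleavecat") -> None:
    with open(path, "w") as fh:
        for t in sort_transcripts(transcripts):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype:
                attrs += f' biotype "{t.biotype}";'
            fh.write(f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t"
                     f"{t.end}\t.\t{t.strand}\t.\t{attrs}\n")
            for a, b in t.exons:
                fh.write(f"{t.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t"
                         f"{t.strand}\t.\t{attrs}\n")


# --- BED12 ----------------------------------------------------------------

def write_bed12(transcripts: Sequence[TranscriptModel], path) -> None:
    """Catalog export in BED12 (block-structured transcript annotation)."""
    with open(path, "w") as fh:
        for t in sort_transcripts(transcripts):
            sizes = ",".join(str(b - a) for a, b in t.exons) + ","
            starts = ",".join(str(a - t.start) for a, _ in t.exons) + ","
            fh.write("\t".join(map(str, (
                t.chrom, t.start, t.end, t.transcript_id, 0,
                t.strand if t.strand in "+-" else ".",
                t.start, t.end, "0,0,0", t.n_exons, sizes, starts))) + "\n")


# --- bedGraph -------------------------------------------------------------

def read_bedgraph(path, kind: str = "coverage") -> IntervalTrack:
    cls = CoverageTrack if kind == "coverage" else ConservationTrack
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            ivs.append((chrom, int(start), int(end), float(value)))
    return cls.from_intervals(ivs)


def write_bedgraph(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            for start, end, value in track.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# --- FASTA ----------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Genome sequences as a plain chrom → string mapping."""
    fa = Fasta(str(path))
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- expression / metadata TSV -------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Feature × sample FPKM table (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="transcript_id",
                float_format="%.6g")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


# --- simulation bundle ----------------------------------------------------

def write_simulation(sim, outdir) -> None:
    """Write every emitted file of a SimulatedData bundle to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome, out / "genome.fa")
    for name, refs in sim.reference_sets.items():
        write_gtf(refs, out / f"reference_{name}.gtf")
    write_gtf(sim.lnc_db, out / "lnc_db.gtf")
    write_gtf(sim.truth_transcripts, out / "truth.gtf")
    asm = out / "assembly"
    asm.mkdir(exist_ok=True)
    for label, sets in (("A", sim.assembler_a), ("B", sim.assembler_b)):
        for sample, ts in sets.items():
            write_gtf(ts, asm / f"assembler{label}_{sample}.gtf")
    covdir = out / "coverage"
    covdir.mkdir(exist_ok=True)
    for sample, track in sim.coverage.items():
        write_bedgraph(track, covdir / f"{sample}.bedgraph")
    write_bedgraph(sim.phastcons, out / "phastcons.bedgraph")
    write_bedgraph(sim.phylop, out / "phylop.bedgraph")
    write_expression(sim.expression, out / "expression.tsv")
    write_metadata(sim.metadata, out / "metadata.tsv")
    _write_truth(sim.truth, out / "ground_truth.tsv")


def _write_truth(truth, path) -> None:
    ids = sorted(set(truth.module_labels)
                 | truth.true_lncRNA_ids | truth.noise_tx_ids)
    with open(path, "w") as fh:
        fh.write("transcript_id\tis_lncRNA\tis_novel\tis_known\tis_db\t"
                 "module\tis_noise\twell_reconstructed\tgapped\n")
        for tid in ids:
            fh.write("\t".join(map(str, (
                tid,
                int(tid in truth.true_lncRNA_ids),
                int(tid in truth.true_novel_ids),
                int(tid in truth.known_lnc_ids),
                int(tid in truth.db_lnc_ids),
                truth.module_labels.get(tid, 0),
                int(tid in truth.noise_tx_ids),
                int(tid in truth.well_reconstructed_ids),
                int(tid in truth.gapped_ids)))) + "\n")
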