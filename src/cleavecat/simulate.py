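"""Synthetic-data generator with planted ground truth.

Emulates every input the discovery pipeline consumes — genome sequence,
reference/known annotations, two assemblers' per-sample transcript sets,
per-sample read-coverage tracks, two conservation tracks, and a staged
24-sample expression matrix — so that every downstream stage is testable
without any external download.

What is planted, and which pipeline stage it exercises:

* coding genes and "known" lncRNAs → reference annotation removal;
* lncRNAs present only in a lncRNA-database annotation → database split;
* novel lncRNAs (ATG-free sequence, canonical GT..AG introns) → the
  surviving catalog;
* per-(assembler, sample) dropout and junction-breaking fragmentation →
  the two-assembler/two-sample consensus rule;
* recurrent low-depth noise loci → the coverage threshold;
* "gapped" transcripts covered over only 60% of their exonic bases → the
  integrity filter;
* single-exon and <200 nt decoys → the basic length/exon filters;
* novel coding decoys (long ORFs, absent from references) → the
  coding-potential filter;
* six stage-linked co-expression modules, divergent promoter pairs with
  correlated expression, and stage-restricted lncRNA profiles → the
  network, neighbour and specificity analyses.

Detection uses common random numbers: the per-(transcript, sample,
assembler) uniforms are drawn independently of the dropout rate and
compared against it, so raising the rate yields a nested (strictly smaller)
detection set under the same seed. All randomness flows from one seed
through deterministically spawned sub-streams, one per output kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .filters import DEFAULT_COVERAGE_THRESHOLD
from .tracks import ConservationTrack, CoverageTrack
from .transcripts import TranscriptModel, revcomp, structure_key

BASES = np.frombuffer(b"ACGT", dtype="S1")
_NON_STOP_CODONS = [a + b + c
                    for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in ("TAA", "TAG", "TGA")]

#: Minimum intron length for planted transcripts; leaves room for the
#: slot-coded junction-break offsets of fragments (max 150 + margin).
MIN_INTRON = 160


class SizingError(ValueError):
    """The requested genes do not fit on the requested chromosomes."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 4_000_000
    n_coding_genes: int = 900
    n_lncRNA_genes: int = 600
    coding_length_mean: float = 3162.0
    coding_exons_mean: float = 11.0
    lnc_length_mean: float = 550.0
    lnc_exons_mean: float = 3.7
    n_samples: int = 24
    stage_design: Tuple[Tuple[str, str, int], ...] = (
        ("oocyte", "WT", 2), ("oocyte", "dicerKO", 2),
        ("2cell", "WT", 8), ("4cell", "WT", 6), ("8cell", "WT", 6))
    n_modules: int = 6
    module_cor: float = 0.8
    assembler_dropout: float = 0.1
    fragmentation_rate: float = 0.1
    noise_tx_rate: float = 0.1
    coverage_depth_expressed: float = 20.0
    coverage_depth_noise: float = 0.8
    conservation_missing_rate: float = 0.1
    # planted-category knobs
    divergent_pair_fraction: float = 0.3
    neighbor_pair_cor: float = 0.6
    known_lnc_fraction: float = 0.25
    db_lnc_fraction: float = 0.08
    gapped_fraction: float = 0.04
    single_exon_decoy_fraction: float = 0.05   # of n_lncRNA_genes
    short_decoy_fraction: float = 0.05         # of n_lncRNA_genes
    coding_decoy_fraction: float = 0.05        # of n_coding_genes
    detection_min_fpkm: float = 1.0
    coverage_floor: float = DEFAULT_COVERAGE_THRESHOLD

    def validate(self) -> "SimulationConfig":
        for name in ("assembler_dropout", "fragmentation_rate",
                     "noise_tx_rate", "conservation_missing_rate",
                     "divergent_pair_fraction", "known_lnc_fraction",
                     "db_lnc_fraction", "gapped_fraction",
                     "single_exon_decoy_fraction", "short_decoy_fraction",
                     "coding_decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not a probability")
        for name in ("n_chromosomes", "chrom_length", "n_coding_genes",
                     "n_lncRNA_genes", "n_samples", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.module_cor < 1.0:
            raise ValueError("module_cor must be in (0,1)")
        if sum(n for _, _, n in self.stage_design) != self.n_samples:
            raise ValueError("stage_design must sum to n_samples")
        return self

    @property
    def sample_ids(self) -> List[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    true_lncRNA_ids: Set[str] = field(default_factory=set)
    true_novel_ids: Set[str] = field(default_factory=set)
    known_lnc_ids: Set[str] = field(default_factory=set)
    db_lnc_ids: Set[str] = field(default_factory=set)
    module_labels: Dict[str, int] = field(default_factory=dict)
    noise_tx_ids: Set[str] = field(default_factory=set)
    well_reconstructed_ids: Set[str] = field(default_factory=set)
    gapped_ids: Set[str] = field(default_factory=set)
    decoy_single_exon_ids: Set[str] = field(default_factory=set)
    decoy_short_ids: Set[str] = field(default_factory=set)
    decoy_coding_ids: Set[str] = field(default_factory=set)
    pair_map: Dict[str, str] = field(default_factory=dict)  # lnc → coding
    stage_specific_lnc_ids: Set[str] = field(default_factory=set)
    broad_mrna_ids: Set[str] = field(default_factory=set)
    consensus_ok_ids: Set[str] = field(default_factory=set)
    covered_ids: Set[str] = field(default_factory=set)


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: Dict[str, str]
    truth_transcripts: List[TranscriptModel]       # all planted loci
    reference_sets: Dict[str, List[TranscriptModel]]
    lnc_db: List[TranscriptModel]
    assembler_a: Dict[str, List[TranscriptModel]]  # sample → transcripts
    assembler_b: Dict[str, List[TranscriptModel]]
    coverage: Dict[str, CoverageTrack]
    phastcons: ConservationTrack
    phylop: ConservationTrack
    expression: pd.DataFrame                       # transcripts × samples
    metadata: pd.DataFrame                         # sample, stage, genotype…
    truth: GroundTruth

    @property
    def transcripts_by_id(self) -> Dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.truth_transcripts}


# --------------------------------------------------------------------------
# gene structure sampling

def _sample_exon_lengths(rng, total: int, k: int, min_exon: int = 40
                         ) -> List[int]:
    if k * min_exon >= total:
        min_exon = max(10, total // (2 * k))
    props = rng.dirichlet(np.full(k, 2.0))
    lengths = np.maximum(min_exon, np.round(props * total).astype(int))
    lengths[-1] += total - lengths.sum()
    if lengths[-1] < min_exon:
        lengths[-1] = min_exon
    return [int(x) for x in lengths]


def _gene_structure(rng, kind: str, cfg: SimulationConfig
                    ) -> Tuple[List[int], List[int]]:
    """(exon lengths, intron lengths) for a gene of the given kind."""
    if kind == "coding" or kind == "coding_decoy":
        mean_ex = cfg.coding_exons_mean if kind == "coding" else 5.0
        k = 2 + int(rng.poisson(max(0.1, mean_ex - 2)))
        total = int(np.clip(rng.lognormal(np.log(
            cfg.coding_length_mean if kind == "coding" else 1400), 0.25),
            600, 12_000))
        introns = [int(rng.integers(MIN_INTRON, 800)) for _ in range(k - 1)]
    elif kind == "lnc":
        k = 2 + int(rng.poisson(max(0.1, cfg.lnc_exons_mean - 2)))
        total = int(np.clip(rng.lognormal(np.log(cfg.lnc_length_mean), 0.35),
                            220, 4_000))
        introns = [int(rng.integers(MIN_INTRON, 600)) for _ in range(k - 1)]
    elif kind == "short_decoy":
        k, total = 2, int(rng.integers(100, 160))
        introns = [int(rng.integers(MIN_INTRON, 400))]
    elif kind == "single_exon_decoy":
        k, total = 1, int(rng.integers(400, 1500))
        introns = []
    elif kind == "noise_multi":
        k, total = 2 + int(rng.integers(0, 2)), int(rng.integers(250, 900))
        introns = [int(rng.integers(MIN_INTRON, 400)) for _ in range(k - 1)]
    elif kind == "noise_single":
        k, total = 1, int(rng.integers(200, 1200))
        introns = []
    else:
        raise ValueError(kind)
    return _sample_exon_lengths(rng, total, k), introns


def _coding_cdna(rng, length: int) -> str:
    """cDNA with an intact ORF covering ~85% of the transcript."""
    n_codons = max(12, int(length * 0.85) // 3)
    n_internal = n_codons - 2
    codons = rng.choice(len(_NON_STOP_CODONS), size=n_internal)
    orf = "ATG" + "".join(_NON_STOP_CODONS[i] for i in codons) + "TAA"
    rest = length - len(orf)
    utr5 = _random_seq(rng, max(0, rest // 2))
    utr3 = _random_seq(rng, max(0, rest - len(utr5)))
    return utr5 + orf + utr3


def _noncoding_cdna(rng, length: int) -> str:
    """ATG-free cDNA: no start codon ⇒ no ORF on the sense strand."""
    return _random_seq(rng, length).replace("ATG", "ACG")


def _random_seq(rng, length: int) -> str:
    if length <= 0:
        return ""
    return rng.choice(BASES, size=length).tobytes().decode()


# --------------------------------------------------------------------------
# genome layout

@dataclass
class _Locus:
    transcript_id: str
    kind: str            # coding | lnc | *_decoy | noise_*
    exon_lengths: List[int]
    intron_lengths: List[int]
    strand: str
    partner_of: Optional[str] = None   # coding partner for divergent lncs
    tss_gap: int = 0                   # planted TSS separation (divergent)
    chrom: str = ""
    exons: Tuple[Tuple[int, int], ...] = ()

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def to_transcript(self, biotype: str) -> TranscriptModel:
        return TranscriptModel(self.transcript_id, "g_" + self.transcript_id,
                               self.chrom, self.strand, self.exons,
                               biotype=biotype)


def _place(locus: _Locus, chrom: str, left: int) -> int:
    """Assign exon coordinates starting at ``left``; returns right edge."""
    pos = left
    exons = []
    for i, el in enumerate(locus.exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(locus.intron_lengths):
            pos += locus.intron_lengths[i]
    locus.chrom = chrom
    locus.exons = tuple(exons)
    return pos


def generate_genome(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Lay out all planted loci and synthesise the genome sequence.

    Returns (genome dict, list of _Locus in genomic order). Coding genes
    carry an intact ORF; lncRNAs and decoys are ATG-free on the sense
    strand; every planted intron reads GT..AG on its strand. Divergent
    head-to-head lncRNA:coding pairs are planted with TSS separations drawn
    mostly from 0–400 bases.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed)
                                    .spawn(6)[0])
    n_div = round(config.divergent_pair_fraction * config.n_lncRNA_genes)
    n_se = round(config.single_exon_decoy_fraction * config.n_lncRNA_genes)
    n_sh = round(config.short_decoy_fraction * config.n_lncRNA_genes)
    n_cd = round(config.coding_decoy_fraction * config.n_coding_genes)
    n_noise = round(config.noise_tx_rate *
                    (config.n_coding_genes + config.n_lncRNA_genes))

    loci: List[_Locus] = []

    def new_locus(tid, kind, partner=None, gap=0):
        ex, intr = _gene_structure(rng, kind if kind in (
            "coding", "lnc", "coding_decoy", "short_decoy",
            "single_exon_decoy", "noise_multi", "noise_single") else "lnc",
            config)
        strand = "+" if rng.random() < 0.5 else "-"
        return _Locus(tid, kind, ex, intr, strand, partner, gap)

    coding = [new_locus(f"cod{i:04d}", "coding")
              for i in range(config.n_coding_genes)]
    lncs = [new_locus(f"lnc{i:04d}", "lnc")
            for i in range(config.n_lncRNA_genes)]
    decoys = ([new_locus(f"dse{i:03d}", "single_exon_decoy")
               for i in range(n_se)]
              + [new_locus(f"dsh{i:03d}", "short_decoy")
                 for i in range(n_sh)]
              + [new_locus(f"dcd{i:03d}", "coding_decoy")
                 for i in range(n_cd)])
    noise = [_Locus(f"noise{i:04d}", kind := ("noise_single"
                                              if rng.random() < 0.7
                                              else "noise_multi"),
                    *_gene_structure(rng, kind, config),
                    strand=".")
             for i in range(n_noise)]

    # blocks: divergent (lnc_i, cod_i) pairs for i < n_div; everything else
    # is a standalone block; order shuffled for genomic mixing.
    blocks: List[List[_Locus]] = []
    for i in range(n_div):
        lnc, cod = lncs[i], coding[i]
        gap = int(abs(rng.normal(150, 110))) if rng.random() < 0.8 \
            else int(rng.integers(400, 2000))
        gap = min(gap, 400) if rng.random() < 0.85 else gap
        lnc.partner_of = cod.transcript_id
        lnc.tss_gap = gap
        lnc.strand = "-" if cod.strand == "+" else "+"
        blocks.append([lnc, cod])
    for locus in coding[n_div:] + lncs[n_div:] + decoys + noise:
        blocks.append([locus])
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # sequential placement with intergenic gaps
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_idx, cursor = 0, 2000
    placed: List[_Locus] = []
    for block in blocks:
        if len(block) == 2:
            lnc, cod = block
            width = lnc.span + lnc.tss_gap + cod.span + 100
        else:
            width = block[0].span
        # gaps exceed the 2 kb run-on window so planted novel loci are not
        # in the polymerase-run-on shadow of an upstream reference gene
        gap_after = int(rng.integers(2100, 3600))
        if cursor + width + gap_after > config.chrom_length - 2000:
            chrom_idx += 1
            cursor = 2000
            if chrom_idx >= config.n_chromosomes:
                raise SizingError(
                    "chromosomes too short for requested gene count: "
                    f"need more than {config.n_chromosomes} × "
                    f"{config.chrom_length} bases")
        chrom = chrom_names[chrom_idx]
        if len(block) == 2:
            lnc, cod = block
            if cod.strand == "+":
                # lnc (on '-') extends leftwards; TSSs separated by tss_gap
                _place(lnc, chrom, cursor)
                cod_start = lnc.exons[-1][1] + lnc.tss_gap
                _place(cod, chrom, cod_start)
                cursor = cod.exons[-1][1]
            else:
                # coding on '-' (TSS at right end), lnc on '+' to its right
                _place(cod, chrom, cursor)
                lnc_start = cod.exons[-1][1] + lnc.tss_gap
                _place(lnc, chrom, lnc_start)
                cursor = lnc.exons[-1][1]
            placed.extend(block)
        else:
            cursor = _place(block[0], chrom, cursor)
            placed.append(block[0])
        cursor += gap_after

    # genome sequence
    genome_arr = {c: rng.choice(BASES, size=config.chrom_length)
                  for c in chrom_names}
    for locus in placed:
        if locus.kind.startswith("noise"):
            continue  # background sequence; junctions stay non-canonical
        length = sum(locus.exon_lengths)
        if locus.kind in ("coding", "coding_decoy"):
            cdna = _coding_cdna(rng, length)
        else:
            cdna = _noncoding_cdna(rng, length)
        _write_transcript(genome_arr[locus.chrom], locus, cdna)
    genome = {c: genome_arr[c].tobytes().decode() for c in chrom_names}
    return genome, placed


def _write_transcript(arr: np.ndarray, locus: _Locus, cdna: str):
    """Write a strand-oriented cDNA into the genome and set splice motifs."""
    seq = cdna if locus.strand == "+" else revcomp(cdna)
    off = 0
    for a, b in locus.exons:
        arr[a:b] = np.frombuffer(seq[off:off + (b - a)].encode(), dtype="S1")
        off += b - a
    donor, acceptor = ("GT", "AG") if locus.strand == "+" else ("CT", "AC")
    for (_, b0), (a1, _) in zip(locus.exons, locus.exons[1:]):
        arr[b0:b0 + 2] = np.frombuffer(donor.encode(), dtype="S1")
        arr[a1 - 2:a1] = np.frombuffer(acceptor.encode(), dtype="S1")


# --------------------------------------------------------------------------
# expression

def _stage_vectors(config: SimulationConfig):
    """Sample metadata arrays and the planted module latent profiles."""
    stages, genotypes, time_index = [], [], []
    stage_order: List[str] = []
    for stage, genotype, n in config.stage_design:
        if stage not in stage_order:
            stage_order.append(stage)
        stages += [stage] * n
        genotypes += [genotype] * n
        time_index += [stage_order.index(stage)] * n
    stages = np.array(stages)
    genotypes = np.array(genotypes)
    time_index = np.array(time_index)

    profiles: List[np.ndarray] = []
    masks: List[np.ndarray] = []
    groups = list(dict.fromkeys(zip(stages, genotypes)))
    for stage, genotype in groups:
        ind = ((stages == stage) & (genotypes == genotype)).astype(float)
        profiles.append(ind)
        masks.append(ind > 0)
    # final module follows the whole developmental time course
    profiles.append(time_index.astype(float))
    masks.append(np.ones(len(stages), dtype=bool))
    while len(profiles) < config.n_modules:
        k = len(profiles)
        ind = (time_index >= (k % len(stage_order))).astype(float)
        profiles.append(ind)
        masks.append(np.ones(len(stages), dtype=bool))
    profiles = profiles[:config.n_modules]
    masks = masks[:config.n_modules]
    z = [(p - p.mean()) / p.std() for p in profiles]
    return stages, genotypes, time_index, z, masks


def generate_expression(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None,
                        ) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Staged FPKM matrix with planted modules, pairs and specific lncRNAs.

    Returns (expression features × samples, sample metadata, a GroundTruth
    carrying module labels, pair map and the specificity/broad groups).
    Gene ids are deterministic (``cod0000``…, ``lnc0000``…, decoys), so the
    matrix aligns with :func:`generate_genome` output for the same config.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed)
                                    .spawn(6)[1])
    n_cod, n_lnc = config.n_coding_genes, config.n_lncRNA_genes
    n_div = round(config.divergent_pair_fraction * n_lnc)
    n_mod = config.n_modules
    c_m = max(2, int((n_cod - n_div) * 0.75) // n_mod)
    l_m = max(1, int((n_lnc - n_div) * 0.55) // n_mod)

    stages, genotypes, time_index, z_mod, masks = _stage_vectors(config)
    S = config.n_samples
    a = math.sqrt(config.module_cor)
    b = math.sqrt(1.0 - config.module_cor)

    truth = GroundTruth()
    rows: Dict[str, np.ndarray] = {}

    def lognorm_base(mu, sd):
        return float(rng.lognormal(np.log(mu), sd))

    cod_y: Dict[str, np.ndarray] = {}
    for i in range(n_cod):
        tid = f"cod{i:04d}"
        if n_div <= i < n_div + n_mod * c_m:
            m = (i - n_div) // c_m
            y = a * z_mod[m] + b * rng.standard_normal(S)
            truth.module_labels[tid] = m + 1
        else:
            y = rng.standard_normal(S)
            truth.module_labels[tid] = 0
            if i >= n_div + n_mod * c_m:
                truth.broad_mrna_ids.add(tid)
        cod_y[tid] = y
        rows[tid] = lognorm_base(25.0, 0.5) * np.exp(0.9 * y)

    rho = config.neighbor_pair_cor
    for i in range(n_lnc):
        tid = f"lnc{i:04d}"
        truth.true_lncRNA_ids.add(tid)
        if i < n_div:
            partner = f"cod{i:04d}"
            truth.pair_map[tid] = partner
            zp = cod_y[partner]
            zp = (zp - zp.mean()) / zp.std()
            y = rho * zp + math.sqrt(1 - rho ** 2) * rng.standard_normal(S)
            fpkm = lognorm_base(10.0, 0.4) * np.exp(0.9 * y)
            truth.module_labels[tid] = 0
        elif i < n_div + n_mod * l_m:
            m = (i - n_div) // l_m
            y = a * z_mod[m] + b * rng.standard_normal(S)
            fpkm = lognorm_base(8.0, 0.4) * np.exp(0.9 * y)
            fpkm = np.where(masks[m], fpkm, 0.0)
            truth.module_labels[tid] = m + 1
            truth.stage_specific_lnc_ids.add(tid)
        else:
            k = int(rng.integers(1, 4))
            on = rng.choice(S, size=k, replace=False)
            fpkm = np.zeros(S)
            fpkm[on] = lognorm_base(8.0, 0.4) * \
                np.exp(0.5 * rng.standard_normal(k))
            truth.module_labels[tid] = 0
            truth.stage_specific_lnc_ids.add(tid)
        rows[tid] = fpkm

    n_se = round(config.single_exon_decoy_fraction * n_lnc)
    n_sh = round(config.short_decoy_fraction * n_lnc)
    n_cd = round(config.coding_decoy_fraction * n_cod)
    for prefix, n, bucket in (("dse", n_se, truth.decoy_single_exon_ids),
                              ("dsh", n_sh, truth.decoy_short_ids),
                              ("dcd", n_cd, truth.decoy_coding_ids)):
        for i in range(n):
            tid = f"{prefix}{i:03d}"
            bucket.add(tid)
            truth.module_labels[tid] = 0
            rows[tid] = lognorm_base(20.0, 0.3) * \
                np.exp(0.8 * rng.standard_normal(S))

    expr = pd.DataFrame(rows, index=config.sample_ids).T
    meta = pd.DataFrame({"sample": config.sample_ids, "stage": stages,
                         "genotype": genotypes, "time_index": time_index}
                        ).set_index("sample")
    return expr, meta, truth


# --------------------------------------------------------------------------
# assembler outputs, coverage, conservation

def _fragment(locus: _Locus, slot: int, rng) -> Optional[TranscriptModel]:
    """A junction-broken fragment of a planted transcript.

    One terminal exon is dropped and the intron adjacent to the cut is
    shifted by a slot-coded offset (5 + 3·slot + r bases), so two fragments
    of the same parent from different (assembler, sample) slots can never
    share an intron chain — assembler misassembly that the consensus rule
    is meant to reject. Two-exon parents yield single-exon fragments.
    """
    exons = list(locus.exons)
    if len(exons) < 2:
        return None
    drop_last = rng.random() < 0.5
    exons = exons[:-1] if drop_last else exons[1:]
    if len(exons) >= 2:
        # break the junction adjacent to the cut by a slot-coded offset:
        # the terminal exon is extended into its neighbouring intron
        # (introns are >= MIN_INTRON, so the shift always stays inside)
        delta = 5 + 3 * slot + int(rng.integers(0, 3))
        if drop_last:
            a, b = exons[-1]
            prev_end = exons[-2][1]
            delta = min(delta, a - prev_end - 5)
            exons[-1] = (a - delta, b)
        else:
            a, b = exons[0]
            next_start = exons[1][0]
            delta = min(delta, next_start - b - 5)
            exons[0] = (a, b + delta)
    tid = f"{locus.transcript_id}|frag{slot}"
    try:
        return TranscriptModel(tid, "g_" + locus.transcript_id, locus.chrom,
                               ".", tuple(exons))
    except ValueError:
        return None


def generate_assembler_outputs(loci: Sequence[_Locus],
                               expression: pd.DataFrame,
                               config: SimulationConfig,
                               rng: Optional[np.random.Generator] = None,
                               ) -> Tuple[Dict[str, List[TranscriptModel]],
                                          Dict[str, List[TranscriptModel]],
                                          Dict[str, Set[Tuple[str, str]]],
                                          GroundTruth]:
    """Per-sample transcript sets for two assemblers, with provenance.

    Returns (assembler A sets, assembler B sets, transcript id → set of
    (assembler, sample) slots where the *intact* structure was emitted,
    partial GroundTruth holding noise ids and consensus bookkeeping).
    Emitted strands are unknown (non-strand-specific libraries); terminal
    exon ends are jittered by a few bases.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed)
                                    .spawn(6)[2])
    samples = config.sample_ids
    truth = GroundTruth()
    sets_a: Dict[str, List[TranscriptModel]] = {s: [] for s in samples}
    sets_b: Dict[str, List[TranscriptModel]] = {s: [] for s in samples}
    intact_slots: Dict[str, Set[Tuple[str, str]]] = {}

    planted = [l for l in loci if not l.kind.startswith("noise")]
    noise = [l for l in loci if l.kind.startswith("noise")]

    # common random numbers: uniforms drawn independently of the rates
    u_detect = rng.random((len(planted), len(samples), 2))
    u_frag = rng.random((len(planted), len(samples), 2))

    for i, locus in enumerate(planted):
        tid = locus.transcript_id
        fpkm = expression.loc[tid].to_numpy(dtype=float) \
            if tid in expression.index else np.zeros(len(samples))
        intact_slots[tid] = set()
        for s_idx, sample in enumerate(samples):
            if fpkm[s_idx] < config.detection_min_fpkm:
                continue
            for a_idx, (label, dest) in enumerate(
                    (("A", sets_a), ("B", sets_b))):
                if u_detect[i, s_idx, a_idx] < config.assembler_dropout:
                    continue
                slot = s_idx * 2 + a_idx
                if u_frag[i, s_idx, a_idx] < config.fragmentation_rate:
                    frag = _fragment(locus, slot, rng)
                    if frag is not None:
                        dest[sample].append(frag)
                    continue
                exons = list(locus.exons)
                # terminal-end imprecision accompanies fragmentation noise;
                # at fragmentation_rate 0 the assemblers are exact
                jmax = 16 if config.fragmentation_rate > 0 else 1
                j5 = int(rng.integers(0, jmax))
                j3 = int(rng.integers(0, jmax))
                if exons[0][1] - exons[0][0] > j5 + 10:
                    exons[0] = (exons[0][0] + j5, exons[0][1])
                if exons[-1][1] - exons[-1][0] > j3 + 10:
                    exons[-1] = (exons[-1][0], exons[-1][1] - j3)
                dest[sample].append(TranscriptModel(
                    f"{tid}|{label}|{sample}", "g_" + tid, locus.chrom, ".",
                    tuple(exons)))
                intact_slots[tid].add((label, sample))

    for locus in noise:
        tid = locus.transcript_id
        truth.noise_tx_ids.add(tid)
        n_slots = int(rng.integers(1, 5))
        slots = rng.choice(len(samples) * 2, size=n_slots, replace=False)
        intact_slots[tid] = set()
        for slot in np.sort(slots):
            s_idx, a_idx = int(slot) // 2, int(slot) % 2
            label, dest = ("A", sets_a) if a_idx == 0 else ("B", sets_b)
            sample = samples[s_idx]
            exons = [(a + int(rng.integers(0, 8)), b - int(rng.integers(0, 8)))
                     if (b - a) > 30 else (a, b) for a, b in locus.exons]
            dest[sample].append(TranscriptModel(
                f"{tid}|{label}|{sample}", "g_" + tid, locus.chrom, ".",
                tuple(exons)))
            intact_slots[tid].add((label, sample))

    for tid, slots in intact_slots.items():
        by_sample: Dict[str, set] = {}
        by_asm: Dict[str, set] = {}
        for label, sample in slots:
            by_sample.setdefault(sample, set()).add(label)
            by_asm.setdefault(label, set()).add(sample)
        if any(len(v) == 2 for v in by_sample.values()) or \
                any(len(v) >= 2 for v in by_asm.values()):
            truth.consensus_ok_ids.add(tid)
    return sets_a, sets_b, intact_slots, truth


def generate_coverage(loci: Sequence[_Locus], expression: pd.DataFrame,
                      config: SimulationConfig,
                      intact_slots: Mapping[str, Set[Tuple[str, str]]],
                      rng: Optional[np.random.Generator] = None,
                      ) -> Tuple[Dict[str, CoverageTrack], Set[str],
                                 Set[str], Set[str]]:
    """Per-sample coverage tracks.

    Exonic depth is piecewise-constant and proportional to FPKM with mean
    ``coverage_depth_expressed`` over expressed entries; "gapped"
    transcripts are covered over only the first 60% of each exon (integrity
    < 0.75 by construction); noise loci get ``coverage_depth_noise``.
    Returns (tracks, gapped ids, covered ids = planted transcripts whose
    best assembled-sample depth ≥ the coverage floor, well-reconstructed
    ids = ungapped planted transcripts reaching depth ≥ 1 in some sample).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed)
                                    .spawn(6)[3])
    samples = config.sample_ids
    planted = [l for l in loci if not l.kind.startswith("noise")]
    noise = [l for l in loci if l.kind.startswith("noise")]

    fpkm = expression.reindex([l.transcript_id for l in planted]).fillna(0.0)
    nonzero = fpkm.to_numpy()[fpkm.to_numpy() > 0]
    scale = config.coverage_depth_expressed / nonzero.mean() if nonzero.size \
        else 1.0

    gapped = {l.transcript_id for l in planted
              if rng.random() < config.gapped_fraction}

    per_sample_ivs: Dict[str, List[Tuple[str, int, int, float]]] = \
        {s: [] for s in samples}
    covered: Set[str] = set()
    well: Set[str] = set()
    for locus in planted:
        tid = locus.transcript_id
        depths = fpkm.loc[tid].to_numpy(dtype=float) * scale
        best = 0.0
        for s_idx, sample in enumerate(samples):
            d = depths[s_idx]
            if d <= 0:
                continue
            for a, b in locus.exons:
                end = a + int(0.6 * (b - a)) if tid in gapped else b
                per_sample_ivs[sample].append((locus.chrom, a, end, d))
            if any(lab_sample[1] == sample for lab_sample in
                   intact_slots.get(tid, ())):
                best = max(best, d)
        if best >= config.coverage_floor:
            covered.add(tid)
        if tid not in gapped and depths.max(initial=0.0) >= 1.0:
            well.add(tid)
    for locus in noise:
        for label, sample in intact_slots.get(locus.transcript_id, ()):
            for a, b in locus.exons:
                per_sample_ivs[sample].append(
                    (locus.chrom, a, b, config.coverage_depth_noise))

    tracks = {s: CoverageTrack.from_intervals(ivs)
              for s, ivs in per_sample_ivs.items()}
    return tracks, gapped, covered, well


def generate_conservation(loci: Sequence[_Locus], config: SimulationConfig,
                          rng: Optional[np.random.Generator] = None,
                          segment: int = 50,
                          ) -> Tuple[ConservationTrack, ConservationTrack]:
    """phastCons-like ([0,1]) and phyloP-like (unbounded) tracks.

    Coding exon bases come from a high-score distribution, lncRNA (and
    decoy) exon bases from a low one; a ``conservation_missing_rate``
    fraction of segments carries no score. Noise loci are unscored.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed)
                                    .spawn(6)[4])
    pc_ivs, pp_ivs = [], []
    for locus in loci:
        if locus.kind.startswith("noise"):
            continue
        high = locus.kind in ("coding", "coding_decoy")
        for a, b in locus.exons:
            for s in range(a, b, segment):
                e = min(s + segment, b)
                if rng.random() < config.conservation_missing_rate:
                    continue
                if high:
                    pc = rng.beta(8, 2)
                    pp = rng.normal(1.5, 0.5)
                else:
                    pc = rng.beta(2, 8)
                    pp = rng.normal(0.0, 0.5)
                pc_ivs.append((locus.chrom, s, e, float(pc)))
                pp_ivs.append((locus.chrom, s, e, float(pp)))
    return (ConservationTrack.from_intervals(pc_ivs),
            ConservationTrack.from_intervals(pp_ivs))


# --------------------------------------------------------------------------
# orchestration

def simulate(config: SimulationConfig) -> SimulatedData:
    """Run every generator and assemble consistent ground truth."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]

    genome, loci = generate_genome(config, rngs[0])
    expr, meta, truth = generate_expression(config, rngs[1])
    sets_a, sets_b, intact_slots, asm_truth = generate_assembler_outputs(
        loci, expr, config, rngs[2])
    coverage, gapped, covered, well = generate_coverage(
        loci, expr, config, intact_slots, rngs[3])
    phastcons, phylop = generate_conservation(loci, config, rngs[4])

    truth.noise_tx_ids = asm_truth.noise_tx_ids
    truth.consensus_ok_ids = asm_truth.consensus_ok_ids
    truth.gapped_ids = gapped
    truth.covered_ids = covered

    # known / database membership of lncRNAs (deterministic sub-stream)
    rng_cat = rngs[5]
    n_lnc = config.n_lncRNA_genes
    u = rng_cat.random(n_lnc)
    for i in range(n_lnc):
        tid = f"lnc{i:04d}"
        if u[i] < config.known_lnc_fraction:
            truth.known_lnc_ids.add(tid)
        elif u[i] < config.known_lnc_fraction + config.db_lnc_fraction:
            truth.db_lnc_ids.add(tid)

    by_id = {l.transcript_id: l for l in loci}
    biotype = {}
    for l in loci:
        if l.kind in ("coding", "coding_decoy"):
            biotype[l.transcript_id] = "protein_coding"
        elif l.kind.startswith("noise"):
            biotype[l.transcript_id] = "noise"
        else:
            biotype[l.transcript_id] = "lncRNA"
    truth_transcripts = [l.to_transcript(biotype[l.transcript_id])
                         for l in loci if not l.kind.startswith("noise")]

    # reference annotation: all coding genes + known lncRNAs; a second
    # source holds a coding subset (multi-source removal must still work)
    ref_main = [t for t in truth_transcripts
                if t.transcript_id.startswith("cod")
                or t.transcript_id in truth.known_lnc_ids]
    ref_second = [t for t in truth_transcripts
                  if t.transcript_id.startswith("cod")
                  and int(t.transcript_id[3:]) % 2 == 0]
    lnc_db = [by_id[tid].to_transcript("lncRNA")
              for tid in sorted(truth.db_lnc_ids)]

    # the planted novel catalog: novel lncRNAs that survive every stage
    # under the realized draws
    for i in range(n_lnc):
        tid = f"lnc{i:04d}"
        locus = by_id[tid]
        t = locus.to_transcript("lncRNA")
        if tid in truth.known_lnc_ids or tid in truth.db_lnc_ids:
            continue
        if tid not in truth.consensus_ok_ids or tid not in truth.covered_ids:
            continue
        if tid in gapped:
            continue
        if t.n_exons < 2 or t.length < 200:
            continue
        truth.true_novel_ids.add(tid)

    # well-reconstructed: integrity ≥ 0.75 at depth ≥ 1 in some sample
    truth.well_reconstructed_ids = well

    return SimulatedData(config, genome, truth_transcripts,
                         {"refseq": ref_main, "second": ref_second},
                         lnc_db, sets_a, sets_b, coverage, phastcons, phylop,
                         expr, meta, truth)


def match_catalog(catalog: Sequence[TranscriptModel],
                  sim: SimulatedData) -> Tuple[Set[str], Set[str], int]:
    """Match catalog entries to planted transcripts by intron chain.

    Returns (matched planted ids, matched novel-truth ids, count of catalog
    entries matching no planted structure).
    """
    truth_keys = {structure_key(t): t.transcript_id
                  for t in sim.truth_transcripts}
    matched, novel_matched, unmatched = set(), set(), 0
    for t in catalog:
        tid = truth_keys.get(structure_key(t))
        if tid is None:
            unmatched += 1
        else:
            matched.add(tid)
            if tid in sim.truth.true_novel_ids:
                novel_matched.add(tid)
    return matched, novel_matched, unmatched


def precision_recall(catalog: Sequence[TranscriptModel], sim: SimulatedData
                     ) -> Tuple[float, float]:
    """Precision/recall of a catalog against the planted novel lncRNA set."""
    matched, novel_matched, unmatched = match_catalog(catalog, sim)
    n_pred = len(catalog)
    false_pos = unmatched + len(matched - novel_matched)
    precision = (n_pred - false_pos) / n_pred if n_pred else 1.0
    truth_n = len(sim.truth.true_novel_ids)
    recall = len(novel_matched) / truth_n if truth_n else 1.0
    return precision, recall
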