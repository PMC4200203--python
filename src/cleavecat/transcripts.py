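"""Transcript data model and interval algebra.

All coordinates are 0-based, half-open, genome-forward. GTF conversion
(1-based, inclusive) happens only at I/O boundaries (:mod:`cleavecat.io`).

A :class:`TranscriptModel` is the unit that flows through every pipeline
stage: a chromosome, a strand (``+``, ``-`` or ``.`` for unknown — the
assemblies come from non-strand-specific libraries, so unknown is a
first-class value), and an ordered list of exon intervals. The intron
chain — the ordered gaps between consecutive exons — is the identity of a
spliced transcript throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

Interval = Tuple[int, int]

STRAND_UNKNOWN = "."
_VALID_STRANDS = {"+", "-", STRAND_UNKNOWN}

#: Canonical splice motifs on the transcribed strand.
DONOR = "GT"
ACCEPTOR = "AG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A transcript span falls outside the available genome sequence."""


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron intervals of a spliced transcript on one chromosome.

    Empty for single-exon transcripts; uniquely determined by the exon
    structure of a :class:`TranscriptModel`.
    """

    chrom: str
    introns: Tuple[Interval, ...]

    def __len__(self) -> int:
        return len(self.introns)


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    biotype: Optional[str] = None
    source: Optional[Tuple[str, str]] = None  # (assembler label, sample label)

    def __post_init__(self):
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        if not exons:
            raise ValueError("transcript must have at least one exon")
        for a, b in exons:
            if b <= a:
                raise ValueError(f"empty or inverted exon ({a},{b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise ValueError("exons must be non-overlapping and "
                                 "separated by at least one intronic base")
        object.__setattr__(self, "exons", exons)

    # --- derived geometry -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exonic) length in bases."""
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """5' position of the transcript (start for +, end for -).

        For unknown strand the leftmost coordinate is returned.
        """
        return self.end if self.strand == "-" else self.start

    def introns(self) -> Tuple[Interval, ...]:
        return tuple((b0, a1) for (_, b0), (a1, _)
                     in zip(self.exons, self.exons[1:]))

    def with_strand(self, strand: str) -> "TranscriptModel":
        return replace(self, strand=strand)

    def overlaps_span(self, other: "TranscriptModel") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def intron_chain(t: TranscriptModel) -> IntronChain:
    """Intron chain of ``t``: exactly the gaps between consecutive exons."""
    return IntronChain(t.chrom, t.introns())


def strands_compatible(a: str, b: str) -> bool:
    """Unknown strand is compatible with either orientation."""
    return a == STRAND_UNKNOWN or b == STRAND_UNKNOWN or a == b


def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Number of exonic bases shared by two transcripts (0 if none)."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for xa, xb in a.exons:
        for ya, yb in b.exons:
            total += max(0, min(xb, yb) - max(xa, ya))
    return total


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Strand-oriented spliced (cDNA) sequence of ``t``.

    For unknown strand the genome-forward splice is returned.
    """
    try:
        chrom_seq = genome[t.chrom]
    except KeyError:
        raise CoordinateError(f"chromosome {t.chrom!r} not in genome")
    if t.end > len(chrom_seq) or t.start < 0:
        raise CoordinateError(
            f"{t.transcript_id}: span ({t.start},{t.end}) outside "
            f"{t.chrom} (length {len(chrom_seq)})")
    seq = "".join(chrom_seq[a:b] for a, b in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


def infer_strand(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Infer strand from splice-junction dinucleotides.

    Every intron reading GT..AG on the forward strand ⇒ ``+``; every intron
    reading CT..AC (GT..AG on the reverse strand) ⇒ ``-``; single-exon,
    mixed or non-canonical junctions ⇒ unknown.
    """
    introns = t.introns()
    if not introns:
        return STRAND_UNKNOWN
    try:
        chrom_seq = genome[t.chrom]
    except KeyError:
        raise CoordinateError(f"chromosome {t.chrom!r} not in genome")
    if t.end > len(chrom_seq):
        raise CoordinateError(f"{t.transcript_id}: span outside {t.chrom}")
    fwd = rev = True
    for a, b in introns:
        left = chrom_seq[a:a + 2].upper()
        right = chrom_seq[b - 2:b].upper()
        if not (left == DONOR and right == ACCEPTOR):
            fwd = False
        if not (left == "CT" and right == "AC"):
            rev = False
        if not fwd and not rev:
            return STRAND_UNKNOWN
    if fwd and not rev:
        return "+"
    if rev and not fwd:
        return "-"
    return STRAND_UNKNOWN


def structure_key(t: TranscriptModel) -> tuple:
    """Hashable identity of a spliced structure.

    Multi-exon transcripts are identified by their intron chain; single-exon
    transcripts by their exon interval (end slack is handled upstream by the
    consensus grouping, not here).
    """
    if t.n_exons >= 2:
        return (t.chrom, "J", t.introns())
    return (t.chrom, "S", t.exons[0])


def sort_transcripts(ts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Deterministic genomic ordering (chrom, start, end, id)."""
    return sorted(ts, key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
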