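"""Coding-potential assessment from ORF features, plus a pluggable
protein-homology filter.

The score mimics the decision surface of SVM-based coding potential
classifiers (presence, size, coverage and integrity of the longest ORF) on
the same scale and orientation: negative scores indicate non-coding, and
the classification cutoff is strictly ``score < -0.5`` ⇒ non-coding (so a
score of exactly −0.5 is on the coding side). The trained SVM and its
protein-database features are deliberately not reproduced — homology
evidence enters instead through a pluggable oracle honouring the E-value
cutoff (default 1e-4, any of the two tool classes).

Functional form of the score (fixed, documented):

    score = 1.2·tanh((3·L − 150)/120) + 0.8·C + 0.15·start + 0.15·stop − 0.8

with L the longest ORF length in codons (stop codon included), C the
fraction of the transcript covered by that ORF, and start/stop the ORF
integrity flags. It is monotone in L, C and integrity; a transcript with no
ORF scores −1.82 (≤ −1) and an intact ORF covering >90% of a ≥300 nt
transcript scores ≥ +1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .transcripts import revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
E_VALUE_CUTOFF = 1e-4
CODING_SCORE_CUTOFF = -0.5
DEFAULT_MIN_ORF = 30  # codons

_VALID_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class OrfFeatures:
    longest_orf_length: int      # codons, stop included when present
    orf_coverage: float          # fraction of transcript in the longest ORF
    has_start: bool
    has_stop: bool
    frame_count_ge_min: int      # frames containing an ORF ≥ min_orf


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    e_value: float
    tool: str                    # "protein-db" | "profile-db"

    def __post_init__(self):
        if not self.e_value > 0:
            raise ValueError(f"E-value must be positive, got {self.e_value}")


def _scan_frames(seq: str, min_orf: int) -> Tuple[int, int, bool, bool, int]:
    """Scan 3 forward frames for ORFs.

    Returns (longest length in codons, longest length in nt, has_start,
    has_stop, count of frames with an ORF ≥ min_orf codons). ORF = ATG..stop
    inclusive; an ATG-initiated run hitting the sequence end without a stop
    is recorded as an integrity-deficient ORF. Codons containing N never
    match ATG or a stop.
    """
    best_codons, best_nt = 0, 0
    best_start = best_stop = False
    frames_ge_min = 0
    n = len(seq)
    for frame in range(3):
        frame_best = 0
        i = frame
        orf_start = None
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in STOP_CODONS:
                codons = (i + 3 - orf_start) // 3
                frame_best = max(frame_best, codons)
                if codons > best_codons:
                    best_codons = codons
                    best_nt = i + 3 - orf_start
                    best_start, best_stop = True, True
                orf_start = None
            i += 3
        if orf_start is not None:  # stop-less run to sequence end
            codons = (n - orf_start) // 3
            frame_best = max(frame_best, codons)
            if codons > best_codons:
                best_codons = codons
                best_nt = codons * 3
                best_start, best_stop = True, False
        if frame_best >= min_orf:
            frames_ge_min += 1
    return best_codons, best_nt, best_start, best_stop, frames_ge_min


def extract_orf_features(sequence: str, min_orf: int = DEFAULT_MIN_ORF,
                         both_strands: bool = False) -> OrfFeatures:
    """ORF features of a (strand-oriented) transcript sequence.

    ``both_strands=True`` scans the reverse complement too and keeps the
    better orientation — used for transcripts whose strand stayed unknown.
    Sequences shorter than one codon yield all-zero features.
    """
    seq = sequence.upper()
    if not _VALID_RE.match(seq):
        raise ValueError("sequence contains characters other than ACGTN")
    if len(seq) < 3:
        return OrfFeatures(0, 0.0, False, False, 0)
    results = [_scan_frames(seq, min_orf)]
    if both_strands:
        results.append(_scan_frames(revcomp(seq), min_orf))
    codons, nt, start, stop, frames = max(results)
    coverage = nt / len(seq)
    return OrfFeatures(codons, coverage, start, stop, frames)


def coding_score(features: OrfFeatures, transcript_length: int) -> float:
    """Coding-potential score; negative ⇒ non-coding, cutoff −0.5."""
    L = features.longest_orf_length
    C = features.orf_coverage
    return (1.2 * float(np.tanh((3 * L - 150) / 120.0))
            + 0.8 * C
            + 0.15 * features.has_start
            + 0.15 * features.has_stop
            - 0.8)


def is_noncoding(score: float, cutoff: float = CODING_SCORE_CUTOFF) -> bool:
    """Strictly ``score < cutoff`` ⇒ non-coding (cutoff itself is coding)."""
    return score < cutoff


NullOracle: Callable[[str], List[HomologyHit]] = lambda query_id: []


def homology_filter(candidate_ids: Sequence[str],
                    oracle: Callable[[str], List[HomologyHit]] = NullOracle,
                    e_cut: float = E_VALUE_CUTOFF,
                    ) -> Tuple[List[str], List[str]]:
    """Split candidates into (coding, retained non-coding) by homology.

    A candidate is coding iff any hit from either tool has E-value < e_cut.
    The packaged default oracle returns no hits (identity on candidates).
    """
    coding, noncoding = [], []
    for cid in candidate_ids:
        hits = oracle(cid)
        for h in hits:
            if not h.e_value > 0:
                raise ValueError(f"{cid}: malformed hit with E={h.e_value}")
        if any(h.e_value < e_cut for h in hits):
            coding.append(cid)
        else:
            noncoding.append(cid)
    return coding, noncoding


def read_hits_tsv(path) -> Callable[[str], List[HomologyHit]]:
    """Adapter: tabular hit file (query, subject, evalue, tool) → oracle.

    Lets real blastp/profile-search results replace the null oracle without
    code changes.
    """
    hits: Dict[str, List[HomologyHit]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            q, s, e, tool = line.split("\t")[:4]
            hits.setdefault(q, []).append(HomologyHit(q, s, float(e), tool))
    return lambda query_id: hits.get(query_id, [])
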