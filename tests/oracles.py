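"""Independent brute-force oracles used by the test suite.

These deliberately use the most literal, slowest possible formulation of
each rule (nested loops, per-base counting, exhaustive enumeration) and
share no code with the package implementation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cleavecat.transcripts import TranscriptModel

PRIORITY = "=cjeospixu"  # helper order (real ranking given in rank())


def rank(code: str) -> int:
    return ("=", "c", "j", "e", "o", "s", "i", "p", "x", "u").index(code)


def _introns(t: TranscriptModel) -> List[Tuple[int, int]]:
    out = []
    for k in range(len(t.exons) - 1):
        out.append((t.exons[k][1], t.exons[k + 1][0]))
    return out


def _compat(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def _exonic_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    for qa, qb in q.exons:
        for ra, rb in r.exons:
            if qa < rb and ra < qb:
                return True
    return False


def oracle_pair_code(q: TranscriptModel, r: TranscriptModel) -> Optional[str]:
    """Literal rule-by-rule class code for one query/reference pair."""
    if q.chrom != r.chrom:
        return None
    if max(q.start - r.end, r.start - q.end) >= 2000:
        return None
    qi, ri = _introns(q), _introns(r)
    compat = _compat(q.strand, r.strand)

    if compat:
        # "=": identical intron chains (single-exon pair: identical exon)
        if qi and qi == ri:
            return "="
        if not qi and not ri and q.exons[0] == r.exons[0]:
            return "="
        # "c": contiguous proper sub-chain, inside reference span
        if qi and len(qi) < len(ri):
            for off in range(len(ri) - len(qi) + 1):
                if ri[off:off + len(qi)] == qi:
                    if q.start >= r.start and q.end <= r.end:
                        return "c"
        # "j": at least one shared intron
        if any(i in ri for i in qi):
            return "j"
        if len(q.exons) == 1 and _exonic_overlap(q, r):
            return "e"
        if _exonic_overlap(q, r):
            return "o"
    else:
        for qa, qb in qi:
            for ra, rb in ri:
                if qa < rb and ra < qb:
                    return "s"
        if _exonic_overlap(q, r):
            return "x"
    for ra, rb in ri:
        if q.start >= ra and q.end <= rb:
            return "i"
    if not _exonic_overlap(q, r):
        if r.strand == "+" and 0 <= q.start - r.end < 2000:
            return "p"
        if r.strand == "-" and 0 <= r.start - q.end < 2000:
            return "p"
    return "u"


def oracle_classify(q: TranscriptModel,
                    refs: Sequence[TranscriptModel]) -> str:
    best = "u"
    for r in refs:
        code = oracle_pair_code(q, r)
        if code is not None and rank(code) < rank(best):
            best = code
    return best


def oracle_consensus_keep(slots: set) -> bool:
    """Literal consensus rule over a set of (assembler, sample) slots."""
    samples = {s for _, s in slots}
    for s in samples:
        if ("A", s) in slots and ("B", s) in slots:
            return True
    for asm in ("A", "B"):
        if len({s for a, s in slots if a == asm}) >= 2:
            return True
    return False


def oracle_integrity(t: TranscriptModel, depth_of, min_depth=1.0) -> float:
    """Per-base integrity via explicit base counting.

    ``depth_of(chrom, pos)`` returns the depth at one base.
    """
    covered = total = 0
    for a, b in t.exons:
        for pos in range(a, b):
            total += 1
            if depth_of(t.chrom, pos) >= min_depth:
                covered += 1
    return covered / total


def oracle_youden_partition(scores, labels):
    """Exhaustive threshold scan maximising sensitivity + specificity - 1
    for the rule score >= threshold (smallest threshold wins ties)."""
    best_t, best_j = None, -np.inf
    labels = np.asarray(labels, dtype=bool)
    for c in sorted(set(np.asarray(scores, dtype=float))):
        pred = scores >= c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = c, j
    return best_t


def random_transcript(rng: np.random.Generator, tid: str,
                      lo: int = 0, hi: int = 3000,
                      max_exons: int = 4) -> TranscriptModel:
    """Small random transcript for fuzzing (dense coordinate range)."""
    n_ex = int(rng.integers(1, max_exons + 1))
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_ex,
                              replace=False))
    exons = []
    for k in range(n_ex):
        a, b = int(cuts[2 * k]), int(cuts[2 * k + 1])
        if b <= a:
            b = a + 1
        exons.append((a, b))
    # enforce >= 1 intronic base between exons
    fixed = [exons[0]]
    for a, b in exons[1:]:
        if a <= fixed[-1][1]:
            a = fixed[-1][1] + 1
        if b <= a:
            b = a + 1
        fixed.append((a, b))
    strand = rng.choice(["+", "-", "."])
    return TranscriptModel(tid, "g" + tid, "chrT", str(strand), tuple(fixed))
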