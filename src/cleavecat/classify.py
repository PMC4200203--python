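"""Cuffcompare-style class codes relating a query transcript to a reference set.

The codes and their meaning (query vs. one reference):

====  ==========================================================everything
``=``  complete match of the intron chain (single-exon pair: identical exon)
``c``  contained — the query's intron chain is a contiguous proper sub-chain
       of the reference's and the query lies within the reference span
``j``  at least one splice junction shared with the reference
``e``  single-exon query overlapping a reference exon
``o``  other exonic overlap on a compatible strand
``s``  an intron of the query overlaps a reference intron on the opposite
       strand (both strands must be set)
``i``  query fully contained within a reference intron
``p``  possible polymerase run-on: query within 2 kb downstream of a
       reference 3' end, no exonic overlap
``x``  exonic overlap on the opposite strand (both strands set)
``u``  unknown / intergenic — no reference within 2 kb
====  ==========================================================

Exactly one code is returned per (query, reference-set) comparison, the
highest-priority one over all nearby references, with priority
``= > c > j > e > o > s > i > p > x > u``. Unknown strand is compatible with
either orientation (non-strand-specific assemblies must not spuriously
trigger the antisense codes ``s``/``x``).
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Optional, Sequence, Tuple

from .transcripts import (TranscriptModel, strands_compatible)

#: Highest priority first.
CODE_PRIORITY = ("=", "c", "j", "e", "o", "s", "i", "p", "x", "u")
_RANK = {c: i for i, c in enumerate(CODE_PRIORITY)}

#: Window used both for the "p" (run-on) code and the "u" neighbourhood.
RUNON_WINDOW = 2000


def _is_sub_chain(sub: Sequence, full: Sequence) -> bool:
    """True if ``sub`` is a contiguous, non-empty, proper sub-list of ``full``."""
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return False
    for i in range(m - n + 1):
        if tuple(full[i:i + n]) == tuple(sub):
            return True
    return False


def classify_pair(query: TranscriptModel, ref: TranscriptModel) -> Optional[str]:
    """Class code of ``query`` against a single reference, or None if the
    reference is farther than :data:`RUNON_WINDOW` from the query span."""
    if query.chrom != ref.chrom:
        return None
    gap = max(query.start - ref.end, ref.start - query.end)
    if gap >= RUNON_WINDOW:
        return None

    compat = strands_compatible(query.strand, ref.strand)
    q_introns = query.introns()
    r_introns = ref.introns()
    overlap = _exon_overlap(query, ref)

    if compat:
        if q_introns and q_introns == r_introns:
            return "="
        if (query.n_exons == 1 and ref.n_exons == 1
                and query.exons[0] == ref.exons[0]):
            return "="
        if (_is_sub_chain(q_introns, r_introns)
                and query.start >= ref.start and query.end <= ref.end):
            return "c"
        if q_introns and r_introns and set(q_introns) & set(r_introns):
            return "j"
        if query.n_exons == 1 and overlap > 0:
            return "e"
        if overlap > 0:
            return "o"
    else:
        # both strands set, opposite
        if q_introns and r_introns and any(
                qa < rb and ra < qb
                for qa, qb in q_introns for ra, rb in r_introns):
            return "s"
        if overlap > 0:
            return "x"

    # no exonic overlap past this point (or opposite strand, no overlap)
    for ra, rb in r_introns:
        if query.start >= ra and query.end <= rb:
            return "i"
    if overlap == 0:
        if ref.strand == "+" and query.start >= ref.end \
                and query.start - ref.end < RUNON_WINDOW:
            return "p"
        if ref.strand == "-" and query.end <= ref.start \
                and ref.start - query.end < RUNON_WINDOW:
            return "p"
    return "u"


def _exon_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for xa, xb in a.exons:
        for ya, yb in b.exons:
            total += max(0, min(xb, yb) - max(xa, ya))
    return total


class ReferenceIndex:
    """Chromosome-indexed reference set for fast neighbourhood lookup.

    References are binned per chromosome and sorted by start; candidates for
    a query are the references whose span comes within
    :data:`RUNON_WINDOW` of the query span.
    """

    def __init__(self, references: Iterable[TranscriptModel]):
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for r in references:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._by_chrom = {}
        for chrom, refs in by_chrom.items():
            refs.sort(key=lambda t: (t.start, t.end, t.transcript_id))
            starts = [t.start for t in refs]
            max_len = max((t.end - t.start) for t in refs)
            self._by_chrom[chrom] = (starts, refs, max_len)

    def candidates(self, query: TranscriptModel) -> list[TranscriptModel]:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, refs, max_len = entry
        lo_coord = query.start - RUNON_WINDOW - max_len
        hi = bisect_right(starts, query.end + RUNON_WINDOW)
        out = []
        for r in refs[:hi]:
            if r.start < lo_coord:
                continue
            out.append(r)
        return out


def classify(query: TranscriptModel,
             references: "ReferenceIndex | Iterable[TranscriptModel]",
             ) -> Tuple[str, Optional[str]]:
    """Highest-priority class code of ``query`` over all nearby references.

    Returns ``(code, transcript_id of the best reference or None)``. A query
    on a chromosome absent from the references is ``u``.
    """
    index = references if isinstance(references, ReferenceIndex) \
        else ReferenceIndex(references)
    best_code = "u"
    best_ref: Optional[str] = None
    for ref in index.candidates(query):
        code = classify_pair(query, ref)
        if code is None or code == "u":
            continue
        if _RANK[code] < _RANK[best_code]:
            best_code, best_ref = code, ref.transcript_id
        if best_code == "=":
            break
    return best_code, best_ref
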