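"""Per-base numeric signal tracks (read coverage, conservation).

Tracks are stored as sorted non-overlapping half-open intervals with a
constant value per interval — the natural in-memory form of a bedGraph.
Coverage queries outside covered intervals return 0; conservation has
missing values instead (bases outside scored intervals carry no score and
are ignored when averaging, which is the convention for phastCons/phyloP
style tracks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .transcripts import TranscriptModel


@dataclass
class _ChromIntervals:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray    # int64
    values: np.ndarray  # float64


class IntervalTrack:
    """Piecewise-constant signal over chromosomes."""

    def __init__(self):
        self._chroms: Dict[str, _ChromIntervals] = {}

    #: Whether overlapping input records are summed and zero-valued pieces
    #: dropped (coverage semantics) or records are kept verbatim so that an
    #: explicit 0 still counts as "scored" (conservation semantics).
    _additive = True

    @classmethod
    def from_intervals(cls, intervals: Iterable[Tuple[str, int, int, float]]
                       ) -> "IntervalTrack":
        """Build from (chrom, start, end, value) records."""
        track = cls()
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if end > start:
                by_chrom.setdefault(chrom, []).append((int(start), int(end),
                                                       float(value)))
        for chrom, ivs in by_chrom.items():
            if cls._additive:
                track._chroms[chrom] = _flatten(ivs)
            else:
                ivs.sort()
                track._chroms[chrom] = _ChromIntervals(
                    np.array([s for s, _, _ in ivs], dtype=np.int64),
                    np.array([e for _, e, _ in ivs], dtype=np.int64),
                    np.array([v for _, _, v in ivs], dtype=float))
        return track

    def chromosomes(self) -> List[str]:
        return sorted(self._chroms)

    def intervals(self, chrom: str) -> Iterable[Tuple[int, int, float]]:
        ci = self._chroms.get(chrom)
        if ci is None:
            return []
        return zip(ci.starts.tolist(), ci.ends.tolist(), ci.values.tolist())

    # --- per-exon queries -------------------------------------------------
    def _clip(self, chrom: str, start: int, end: int
              ) -> Tuple[np.ndarray, np.ndarray]:
        """(covered base counts, values) of track pieces inside [start,end)."""
        ci = self._chroms.get(chrom)
        if ci is None or end <= start:
            return np.empty(0, dtype=np.int64), np.empty(0)
        lo = np.searchsorted(ci.ends, start, side="right")
        hi = np.searchsorted(ci.starts, end, side="left")
        if hi <= lo:
            return np.empty(0, dtype=np.int64), np.empty(0)
        s = np.maximum(ci.starts[lo:hi], start)
        e = np.minimum(ci.ends[lo:hi], end)
        widths = e - s
        keep = widths > 0
        return widths[keep], ci.values[lo:hi][keep]

    def max_value(self, t: TranscriptModel) -> float:
        """Maximum per-base value over the transcript's exons (0 if none)."""
        best = 0.0
        for a, b in t.exons:
            _, vals = self._clip(t.chrom, a, b)
            if vals.size:
                best = max(best, float(vals.max()))
        return best

    def covered_fraction(self, t: TranscriptModel,
                         min_value: float = 1.0) -> float:
        """Fraction of exonic bases with value ≥ ``min_value``."""
        covered = 0
        for a, b in t.exons:
            widths, vals = self._clip(t.chrom, a, b)
            covered += int(widths[vals >= min_value].sum())
        return covered / t.length

    def mean_value(self, t: TranscriptModel) -> Optional[float]:
        """Mean value over scored exonic bases; None when no base is scored."""
        total = 0.0
        n = 0
        for a, b in t.exons:
            widths, vals = self._clip(t.chrom, a, b)
            total += float((widths * vals).sum())
            n += int(widths.sum())
        return total / n if n else None


class CoverageTrack(IntervalTrack):
    """Read depth per base (non-negative; 0 outside intervals)."""


class ConservationTrack(IntervalTrack):
    """Per-base conservation score; bases outside intervals are unscored.

    Input intervals must be disjoint (bedGraph contract); a score of 0 is a
    real score, not a missing value.
    """

    _additive = False


def _flatten(ivs: List[Tuple[int, int, float]]) -> _ChromIntervals:
    """Sum overlapping intervals into sorted disjoint pieces."""
    edges: Dict[int, float] = {}
    for s, e, v in ivs:
        edges[s] = edges.get(s, 0.0) + v
        edges[e] = edges.get(e, 0.0) - v
    pos = np.array(sorted(edges), dtype=np.int64)
    deltas = np.array([edges[p] for p in pos])
    levels = np.cumsum(deltas)
    starts, ends, values = [], [], []
    for i in range(len(pos) - 1):
        if abs(levels[i]) > 1e-12:
            starts.append(pos[i])
            ends.append(pos[i + 1])
            values.append(levels[i])
    return _ChromIntervals(np.array(starts, dtype=np.int64),
                           np.array(ends, dtype=np.int64),
                           np.array(values, dtype=float))


# --- transcript-level operations -----------------------------------------

def transcript_integrity(t: TranscriptModel, cov: CoverageTrack,
                         min_depth: float = 1.0) -> float:
    """Fraction of exonic bases covered at depth ≥ ``min_depth`` (in [0,1])."""
    return cov.covered_fraction(t, min_depth)


def max_coverage(t: TranscriptModel, cov: CoverageTrack) -> float:
    """Maximum per-base read depth over the transcript's exons."""
    return cov.max_value(t)


def transcript_conservation(t: TranscriptModel, track: ConservationTrack
                            ) -> Optional[float]:
    """Mean conservation over scored exonic bases; None if none scored."""
    return track.mean_value(t)
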