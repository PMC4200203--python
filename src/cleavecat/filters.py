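"""Catalog filters: coverage threshold learning, annotation removal,
length/exon filters.

The coverage threshold separates well-reconstructed transcripts from
fragmentary/background ones. It is learned per reference class (coding and
non-coding) from the ROC of max per-base coverage against the
well-reconstructed label (exonic integrity ≥ 0.75), taking the cutoff that
maximises Youden's J; the final threshold is the mean of the two class
thresholds. When learning is skipped the pipeline constant is
3.77881 reads/base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .classify import ReferenceIndex, classify
from .tracks import CoverageTrack, max_coverage, transcript_integrity
from .transcripts import TranscriptModel

log = logging.getLogger(__name__)

#: Pipeline default when threshold learning is skipped (reads per base).
DEFAULT_COVERAGE_THRESHOLD = 3.77881

#: Class codes marking a candidate as a known/overlapping annotation.
REMOVED_CODES = frozenset("=cjeops")

#: Coordinate-overlap codes used for the lncRNA-database comparison.
DB_MATCH_CODES = frozenset("=cjeo")

DEFAULT_INTEGRITY_CUT = 0.75
MIN_LENGTH = 200


class ThresholdLearningError(ValueError):
    """A reference class has only one well-reconstructed label present."""


@dataclass
class ThresholdResult:
    threshold_coding: float
    threshold_noncoding: float
    final: float
    auc_coding: float
    auc_noncoding: float


@dataclass
class FilterReport:
    """Transcript/locus counts through the pipeline cascade, in stage order."""
    stages: List[Tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, n_loci: int):
        if n_out > n_in:
            raise ValueError(f"stage {name}: out ({n_out}) > in ({n_in})")
        self.stages.append((name, n_in, n_out, n_loci))

    def to_rows(self) -> List[dict]:
        return [{"stage": s, "n_in": a, "n_out": b, "n_loci_out": c}
                for s, a, b, c in self.stages]


def youden_threshold(scores: np.ndarray, labels: np.ndarray
                     ) -> Tuple[float, float]:
    """(threshold, AUC) maximising Youden's J for rule ``score ≥ threshold``.

    Candidate thresholds are the sorted unique scores; ties in J are broken
    toward the smaller threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ThresholdLearningError("need both labels present")
    candidates = np.unique(scores)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    # sensitivity/specificity for "score >= c" via sorted cumulative counts
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # for each candidate, positives with score >= c
    idx = np.searchsorted(s_sorted, candidates, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(l_sorted)])
    pos_ge = n_pos - cum_pos[idx]
    neg_ge = (scores.size - idx) - pos_ge
    sens = pos_ge / n_pos
    spec = 1.0 - neg_ge / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns first maximum = smallest c
    auc = float(roc_auc_score(labels, scores))
    return float(candidates[best]), auc


def learn_coverage_threshold(
        coding_refs: Sequence[TranscriptModel],
        noncoding_refs: Sequence[TranscriptModel],
        coverage_by_sample: Mapping[str, CoverageTrack],
        integrity_cut: float = DEFAULT_INTEGRITY_CUT,
        min_depth: float = 1.0,
        default: float = DEFAULT_COVERAGE_THRESHOLD,
        ) -> ThresholdResult:
    """Learn the minimal coverage threshold from reference transcripts.

    Per class, each reference transcript contributes its best max-coverage
    over samples as the score and "integrity ≥ ``integrity_cut`` in the best
    sample" as the label. A class in which learning is impossible (single
    label) falls back to ``default`` with a warning.
    """
    results = []
    for refs in (coding_refs, noncoding_refs):
        if not refs:
            raise ThresholdLearningError("empty reference set")
        scores, labels = [], []
        for t in refs:
            best_cov = max((max_coverage(t, cov)
                            for cov in coverage_by_sample.values()),
                           default=0.0)
            best_int = max((transcript_integrity(t, cov, min_depth)
                            for cov in coverage_by_sample.values()),
                           default=0.0)
            scores.append(best_cov)
            labels.append(best_int >= integrity_cut)
        try:
            thr, auc = youden_threshold(np.array(scores), np.array(labels))
        except ThresholdLearningError:
            log.warning("coverage threshold: class with a single label; "
                        "falling back to default %.5f", default)
            thr, auc = default, float("nan")
        results.append((thr, auc))
    (thr_c, auc_c), (thr_nc, auc_nc) = results
    return ThresholdResult(thr_c, thr_nc, (thr_c + thr_nc) / 2.0,
                           auc_c, auc_nc)


def basic_filters(transcripts: Iterable[TranscriptModel],
                  min_length: int = MIN_LENGTH,
                  require_multiexon: bool = True) -> List[TranscriptModel]:
    """Drop short (< ``min_length`` spliced nt) and single-exon transcripts."""
    return [t for t in transcripts
            if t.length >= min_length
            and (not require_multiexon or t.n_exons >= 2)]


def remove_known(candidates: Sequence[TranscriptModel],
                 reference_sets: Mapping[str, Sequence[TranscriptModel]],
                 removed_codes: frozenset = REMOVED_CODES,
                 ) -> Tuple[List[TranscriptModel], Dict[str, Dict[str, str]],
                            Dict[str, int]]:
    """Remove candidates matching any reference annotation source.

    A candidate is removed when its class code against *any* source is in
    ``removed_codes``. Returns (retained, per-candidate per-source codes,
    per-code removal counts).
    """
    indexes = {name: ReferenceIndex(refs)
               for name, refs in reference_sets.items()}
    retained: List[TranscriptModel] = []
    codes: Dict[str, Dict[str, str]] = {}
    removal_counts: Dict[str, int] = {}
    for t in candidates:
        per_source = {name: classify(t, idx)[0]
                      for name, idx in indexes.items()}
        codes[t.transcript_id] = per_source
        hit = [c for c in per_source.values() if c in removed_codes]
        if hit:
            worst = min(hit, key=lambda c: "=cjeops".index(c))
            removal_counts[worst] = removal_counts.get(worst, 0) + 1
        else:
            retained.append(t)
    return retained, codes, removal_counts


def known_lncRNA_annotate(candidates: Sequence[TranscriptModel],
                          lnc_db: Sequence[TranscriptModel],
                          match_codes: frozenset = DB_MATCH_CODES,
                          ) -> Tuple[List[TranscriptModel],
                                     List[TranscriptModel]]:
    """Split candidates into (database-matched, novel) by coordinate overlap
    with a lncRNA database annotation."""
    idx = ReferenceIndex(lnc_db) if lnc_db else None
    matched, novel = [], []
    for t in candidates:
        code = classify(t, idx)[0] if idx is not None else "u"
        (matched if code in match_codes else novel).append(t)
    return matched, novel
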