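"""The lncRNA discovery cascade, end to end.

Stage order: deduplicate → two-assembler/two-sample consensus → minimal
coverage threshold → exonic integrity → splice-junction strand inference →
length/exon filters → removal of known annotations → lncRNA-database
split → coding-potential and homology filters. Every stage records
(transcripts in, transcripts out, loci out) into a FilterReport.

Coverage and integrity are evaluated per structure as the best value over
the samples in which that structure was assembled: single-cell tracks are
sparse, and assembly evidence is pooled across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .classify import ReferenceIndex, classify
from .coding import (CODING_SCORE_CUTOFF, DEFAULT_MIN_ORF, E_VALUE_CUTOFF,
                     HomologyHit, NullOracle, coding_score,
                     extract_orf_features, homology_filter, is_noncoding)
from .consensus import (SINGLE_EXON_SLACK, group_structures, merge_group,
                        n_loci)
from .filters import (DB_MATCH_CODES, DEFAULT_COVERAGE_THRESHOLD,
                      DEFAULT_INTEGRITY_CUT, MIN_LENGTH, REMOVED_CODES,
                      FilterReport, basic_filters, known_lncRNA_annotate,
                      learn_coverage_threshold, remove_known)
from .tracks import CoverageTrack, max_coverage, transcript_integrity
from .transcripts import (STRAND_UNKNOWN, TranscriptModel, infer_strand,
                          sort_transcripts, spliced_sequence)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    learn_threshold: bool = False
    integrity_cut: float = DEFAULT_INTEGRITY_CUT
    min_depth: float = 1.0
    min_length: int = MIN_LENGTH
    require_multiexon: bool = True
    removed_codes: frozenset = REMOVED_CODES
    db_match_codes: frozenset = DB_MATCH_CODES
    min_orf: int = DEFAULT_MIN_ORF
    coding_cutoff: float = CODING_SCORE_CUTOFF
    e_value_cutoff: float = E_VALUE_CUTOFF
    single_exon_slack: int = SINGLE_EXON_SLACK


@dataclass
class PipelineResult:
    catalog: List[TranscriptModel]
    report: FilterReport
    coverage_threshold: float
    class_codes: Dict[str, Dict[str, str]] = field(default_factory=dict)
    db_matched: List[TranscriptModel] = field(default_factory=list)
    coding_scores: Dict[str, float] = field(default_factory=dict)

    def catalog_table(self) -> pd.DataFrame:
        rows = []
        for t in self.catalog:
            rows.append({
                "transcript_id": t.transcript_id, "chrom": t.chrom,
                "start": t.start, "end": t.end, "strand": t.strand,
                "length": t.length, "n_exons": t.n_exons,
                "coding_score": self.coding_scores.get(t.transcript_id),
            })
        return pd.DataFrame(rows)


def run_pipeline(assembler_a: Mapping[str, Sequence[TranscriptModel]],
                 assembler_b: Mapping[str, Sequence[TranscriptModel]],
                 coverage: Mapping[str, CoverageTrack],
                 genome: Mapping[str, str],
                 reference_sets: Mapping[str, Sequence[TranscriptModel]],
                 lnc_db: Sequence[TranscriptModel] = (),
                 config: Optional[PipelineConfig] = None,
                 homology_oracle: Callable[[str], List[HomologyHit]] = NullOracle,
                 coding_refs: Optional[Sequence[TranscriptModel]] = None,
                 noncoding_refs: Optional[Sequence[TranscriptModel]] = None,
                 ) -> PipelineResult:
    """Run the full discovery cascade and return the final lncRNA catalog.

    ``assembler_a``/``assembler_b`` map sample label → per-sample transcript
    sets. With ``config.learn_threshold`` the coverage threshold is learned
    from ``coding_refs``/``noncoding_refs`` (AUC/Youden), otherwise the
    pipeline constant applies. Any stage error aborts with the stage named.
    """
    cfg = config or PipelineConfig()
    report = FilterReport()
    result = PipelineResult([], report, cfg.coverage_threshold)

    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError(name, exc) from exc

    # -- dedup + consensus (provenance-aware) ------------------------------
    tagged: List[TranscriptModel] = []
    for label, sets in (("A", assembler_a), ("B", assembler_b)):
        for sample, ts in sets.items():
            for t in ts:
                tagged.append(TranscriptModel(
                    t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons,
                    biotype=t.biotype, source=(label, sample)))
    n_records = len(tagged)

    groups = run_stage("dedup", group_structures, tagged,
                       cfg.single_exon_slack)
    dedup = [merge_group(g) for g in groups]
    report.add("dedup", n_records, len(dedup), n_loci(dedup))
    if not dedup:
        report.add("consensus", 0, 0, 0)
        return result

    retained: List[Tuple[TranscriptModel, Set[str]]] = []
    for g in groups:
        by_sample: Dict[str, set] = {}
        by_asm: Dict[str, set] = {}
        for t in g:
            a, s = t.source
            by_sample.setdefault(s, set()).add(a)
            by_asm.setdefault(a, set()).add(s)
        if any(len(v) == 2 for v in by_sample.values()) or \
                any(len(v) >= 2 for v in by_asm.values()):
            retained.append((merge_group(g), set(by_sample)))
    current = sort_with_samples(retained)
    report.add("consensus", len(dedup), len(current),
               n_loci([t for t, _ in current]))

    # -- coverage threshold ------------------------------------------------
    threshold = cfg.coverage_threshold
    if cfg.learn_threshold:
        if coding_refs is None or noncoding_refs is None:
            raise PipelineError("coverage_threshold",
                                ValueError("learning requested without "
                                           "reference sets"))
        learned = run_stage("coverage_threshold", learn_coverage_threshold,
                            coding_refs, noncoding_refs, coverage,
                            cfg.integrity_cut, cfg.min_depth,
                            cfg.coverage_threshold)
        threshold = learned.final
    result.coverage_threshold = threshold

    def best_over_samples(fn, t, samples):
        return max((fn(t, coverage[s]) for s in samples if s in coverage),
                   default=0.0)

    kept = [(t, s) for t, s in current
            if best_over_samples(max_coverage, t, s) >= threshold]
    report.add("coverage", len(current), len(kept),
               n_loci([t for t, _ in kept]))
    current = kept

    # -- integrity ---------------------------------------------------------
    kept = [(t, s) for t, s in current
            if best_over_samples(
                lambda tr, cov: transcript_integrity(tr, cov, cfg.min_depth),
                t, s) >= cfg.integrity_cut]
    report.add("integrity", len(current), len(kept),
               n_loci([t for t, _ in kept]))
    current = kept

    # -- strand inference --------------------------------------------------
    # multi-exon transcripts with unresolvable junctions are dropped;
    # single-exon transcripts pass through (removed by the next stage)
    stranded: List[Tuple[TranscriptModel, Set[str]]] = []
    for t, s in current:
        strand = run_stage("strand", infer_strand, t, genome)
        if t.n_exons >= 2 and strand == STRAND_UNKNOWN:
            continue
        stranded.append((t.with_strand(strand), s))
    report.add("strand", len(current), len(stranded),
               n_loci([t for t, _ in stranded]))
    current = stranded

    # -- basic filters -----------------------------------------------------
    kept_t = run_stage("basic_filters", basic_filters,
                       [t for t, _ in current], cfg.min_length,
                       cfg.require_multiexon)
    kept_ids = {t.transcript_id for t in kept_t}
    prev_n = len(current)
    current = [(t, s) for t, s in current if t.transcript_id in kept_ids]
    report.add("length_exon", prev_n, len(current),
               n_loci([t for t, _ in current]))

    # -- known annotation removal -----------------------------------------
    retained_t, codes, _counts = run_stage(
        "remove_known", remove_known, [t for t, _ in current],
        reference_sets, cfg.removed_codes)
    result.class_codes = codes
    retained_ids = {t.transcript_id for t in retained_t}
    prev_n = len(current)
    current = [(t, s) for t, s in current
               if t.transcript_id in retained_ids]
    report.add("remove_known", prev_n, len(current),
               n_loci([t for t, _ in current]))

    # -- lncRNA database split --------------------------------------------
    matched, novel = run_stage("lnc_db", known_lncRNA_annotate,
                               [t for t, _ in current], lnc_db,
                               cfg.db_match_codes)
    result.db_matched = matched
    novel_ids = {t.transcript_id for t in novel}
    prev_n = len(current)
    current = [(t, s) for t, s in current if t.transcript_id in novel_ids]
    report.add("lnc_db_novel", prev_n, len(current),
               n_loci([t for t, _ in current]))

    # -- coding potential + homology --------------------------------------
    noncoding: List[TranscriptModel] = []
    for t, _s in current:
        seq = run_stage("coding", spliced_sequence, t, genome)
        feats = run_stage("coding", extract_orf_features, seq, cfg.min_orf,
                          t.strand == STRAND_UNKNOWN)
        score = coding_score(feats, t.length)
        result.coding_scores[t.transcript_id] = score
        if is_noncoding(score, cfg.coding_cutoff):
            noncoding.append(t)
    _coding_ids, nc_ids = run_stage(
        "homology", homology_filter,
        [t.transcript_id for t in noncoding], homology_oracle,
        cfg.e_value_cutoff)
    nc_set = set(nc_ids)
    catalog = [t for t in noncoding if t.transcript_id in nc_set]
    report.add("noncoding", len(current), len(catalog), n_loci(catalog))

    result.catalog = sort_transcripts(catalog)
    return result


def sort_with_samples(pairs: List[Tuple[TranscriptModel, Set[str]]]
                      ) -> List[Tuple[TranscriptModel, Set[str]]]:
    return sorted(pairs, key=lambda p: (p[0].chrom, p[0].start, p[0].end,
                                        p[0].transcript_id))
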