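"""Neighbouring-gene analysis: pair construction, expression correlation
against a permutation null, orientation/bidirectional-promoter
classification and TSS-distance statistics.

Two pairing modes mirror two distinct analyses: *genebody* mode pairs genes
whose span-to-span distance is < 10 kb ignoring direction; *tss* mode pairs
genes whose TSS-to-TSS distance is < 10 kb. Expression correlation of a
pair is the Pearson correlation of ``log2(FPKM + 0.05)`` profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MAX_GAP = 10_000
PSEUDOCOUNT = 0.05


@dataclass(frozen=True)
class Feature:
    """Minimal gene-level record for pairing (half-open genome coords)."""
    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str            # "+", "-", "."
    kind: str              # "lncRNA" | "coding"

    @property
    def tss(self) -> int:
        return self.end if self.strand == "-" else self.start


@dataclass
class GenePair:
    id_a: str              # in lnc:coding pairs, a = lncRNA
    id_b: str              # the coding reference gene
    pair_class: str        # "lnc:coding" | "coding:coding"
    genebody_gap: int
    tss_distance: Optional[int] = None  # signed, coding-gene convention
    orientation: Optional[str] = None   # divergent | convergent | tandem
    pearson_r: Optional[float] = None


def features_from_transcripts(transcripts, kind_of: Mapping[str, str]
                              ) -> List[Feature]:
    """Feature records from TranscriptModels, labelled by ``kind_of[id]``."""
    return [Feature(t.transcript_id, t.chrom, t.start, t.end, t.strand,
                    kind_of.get(t.transcript_id, "coding"))
            for t in transcripts]


def _span_gap(a: Feature, b: Feature) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def find_neighbors(features: Sequence[Feature],
                   max_gap: int = DEFAULT_MAX_GAP,
                   mode: str = "genebody") -> List[GenePair]:
    """All unordered feature pairs closer than ``max_gap`` (strict ``<``).

    genebody mode: minimal span-to-span distance, overlap counting as 0,
    direction ignored. tss mode: |TSS − TSS| distance. Pairs mixing kinds
    are classed ``lnc:coding`` (lncRNA listed first); coding:coding pairs
    keep input order. lnc:lnc pairs are not emitted.
    """
    if mode not in ("genebody", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: Dict[str, List[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    pairs: List[GenePair] = []
    for chrom in sorted(by_chrom):
        fs = sorted(by_chrom[chrom],
                    key=lambda f: (f.start, f.end, f.feature_id))
        for i, a in enumerate(fs):
            for b in fs[i + 1:]:
                # sorted by start: once b.start is max_gap past a.end, both
                # the span gap and any TSS distance are >= max_gap
                if b.start - a.end >= max_gap:
                    break
                if mode == "genebody":
                    dist = _span_gap(a, b)
                else:
                    dist = abs(a.tss - b.tss)
                if dist >= max_gap:
                    continue
                kinds = {a.kind, b.kind}
                if kinds == {"lncRNA"}:
                    continue
                if kinds == {"lncRNA", "coding"}:
                    lnc, cod = (a, b) if a.kind == "lncRNA" else (b, a)
                    pairs.append(GenePair(lnc.feature_id, cod.feature_id,
                                          "lnc:coding", _span_gap(a, b)))
                else:
                    pairs.append(GenePair(a.feature_id, b.feature_id,
                                          "coding:coding", _span_gap(a, b)))
    return pairs


# --- expression correlation ----------------------------------------------

def _log_expr(expr: pd.DataFrame, pseudo: float = PSEUDOCOUNT) -> pd.DataFrame:
    return np.log2(expr + pseudo)


def pair_correlation(pair: GenePair, expr: pd.DataFrame,
                     pseudo: float = PSEUDOCOUNT) -> Optional[float]:
    """Pearson r of log2(FPKM+pseudo) profiles; None if either is constant."""
    for fid in (pair.id_a, pair.id_b):
        if fid not in expr.index:
            raise KeyError(f"feature {fid!r} not in expression matrix")
    x = np.log2(expr.loc[pair.id_a].to_numpy(dtype=float) + pseudo)
    y = np.log2(expr.loc[pair.id_b].to_numpy(dtype=float) + pseudo)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    pair.pearson_r = r
    return r


def pair_correlations(pairs: Sequence[GenePair], expr: pd.DataFrame,
                      pseudo: float = PSEUDOCOUNT) -> np.ndarray:
    """Vectorised pair correlations; undefined (constant-profile) pairs are
    dropped from the returned distribution."""
    logx = _log_expr(expr, pseudo).to_numpy(dtype=float)
    index = {fid: i for i, fid in enumerate(expr.index)}
    sd = logx.std(axis=1)
    centered = logx - logx.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / np.where(sd > 0, sd, np.nan)[:, None]
    out = []
    n = logx.shape[1]
    for p in pairs:
        i, j = index[p.id_a], index[p.id_b]
        r = float(np.dot(z[i], z[j]) / n)
        if np.isfinite(r):
            p.pearson_r = r
            out.append(r)
    return np.array(out)


def random_pair_null(coding_ids: Sequence[str], expr: pd.DataFrame,
                     n_pairs: int, n_permutations: int = 100,
                     seed: int = 0, pseudo: float = PSEUDOCOUNT,
                     ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Null correlation distribution from random coding-gene pairs.

    Each permutation draws ``n_pairs`` distinct unordered coding pairs
    uniformly without replacement and computes their correlations. Returns
    (per-permutation arrays, pooled array).
    """
    ids = [i for i in coding_ids if i in expr.index]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 coding features")
    total = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    per_perm = []
    for _ in range(n_permutations):
        codes = rng.choice(total, size=min(n_pairs, total), replace=False)
        pairs = []
        for code in np.sort(codes):
            i = int((1 + np.sqrt(1 + 8 * code)) // 2)  # row of triangle
            j = int(code - i * (i - 1) // 2)
            pairs.append(GenePair(ids[i], ids[j], "coding:coding", 0))
        per_perm.append(pair_correlations(pairs, expr, pseudo))
    pooled = np.concatenate(per_perm) if per_perm else np.empty(0)
    return per_perm, pooled


def compare_distributions(dist_a: np.ndarray, dist_b: np.ndarray
                          ) -> Tuple[float, float, float, float]:
    """Two-sample KS test; returns (statistic, p, mean_a, mean_b)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty distribution")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue), float(a.mean()), float(b.mean())


# --- orientation / TSS geometry ------------------------------------------

def signed_tss_distance(coding: Feature, partner: Feature) -> int:
    """Partner TSS position relative to the coding gene's TSS, positive
    downstream of the coding gene's transcription direction."""
    d = partner.tss - coding.tss
    return -d if coding.strand == "-" else d


def orientation_class(coding: Feature, partner: Feature
                      ) -> Tuple[Optional[str], Optional[int]]:
    """(orientation, signed TSS distance) of a pair.

    Same strand → tandem. Opposite strands: partner TSS at or upstream of
    the coding TSS (distance ≤ 0) → divergent (bidirectional-promoter
    candidate); downstream → convergent. Unknown strand on either gene →
    (None, None), classification skipped.
    """
    if coding.strand not in "+-" or partner.strand not in "+-":
        return None, None
    d = signed_tss_distance(coding, partner)
    if coding.strand == partner.strand:
        return "tandem", d
    return ("divergent" if d <= 0 else "convergent"), d


def annotate_pairs(pairs: Sequence[GenePair],
                   features: Mapping[str, Feature]) -> None:
    """Fill orientation and signed TSS distance in-place.

    In lnc:coding pairs the coding gene is the reference; in coding:coding
    pairs ``id_b`` is used as the reference (callers wanting the random
    convention shuffle a/b beforehand)."""
    for p in pairs:
        ref = features[p.id_b]
        partner = features[p.id_a]
        p.orientation, p.tss_distance = orientation_class(ref, partner)


def tss_window_stats(lnc_features: Sequence[Feature],
                     coding_features: Sequence[Feature],
                     windows: Sequence[int] = (2000, 5000, 10_000),
                     bin_width: int = 100,
                     max_distance: int = 10_000,
                     ) -> Tuple[Dict[int, float], pd.DataFrame]:
    """Nearest coding-TSS distance statistics for lncRNA 5' ends.

    For each lncRNA, the signed distance (coding-gene convention) to the
    nearest coding TSS is computed. Returns ({window: fraction of lncRNAs
    with |distance| < window}, signed-distance histogram with ``bin_width``
    bins over ±``max_distance``).
    """
    coding_by_chrom: Dict[str, List[Feature]] = {}
    for f in coding_features:
        coding_by_chrom.setdefault(f.chrom, []).append(f)
    for fs in coding_by_chrom.values():
        fs.sort(key=lambda f: f.tss)

    distances = []
    for lnc in lnc_features:
        fs = coding_by_chrom.get(lnc.chrom)
        if not fs:
            continue
        best = min(fs, key=lambda f: (abs(f.tss - lnc.tss), f.feature_id))
        distances.append(signed_tss_distance(best, lnc))
    d = np.array(distances, dtype=float)

    n_lnc = len(lnc_features)
    fractions = {w: float((np.abs(d) < w).sum()) / n_lnc if n_lnc else 0.0
                 for w in windows}
    edges = np.arange(-max_distance, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(d[np.abs(d) <= max_distance], bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts})
    return fractions, hist
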