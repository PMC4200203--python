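"""Expression-profile summaries: temporal specificity (Jensen-Shannon),
between-sample correlation structure, maximal expression, conservation
averaging.

The temporal specificity of a transcript in condition *c* is
``1 − JSdist(p, e_c)`` where ``p`` is the transcript's normalised
``log10(FPKM+1)`` profile over conditions, ``e_c`` the unit vector of
condition *c*, and ``JSdist`` the square root of the Jensen-Shannon
divergence in base-2 logarithms (so the distance lives in [0,1] and a
transcript expressed exclusively in one condition scores exactly 1 there).
A transcript's overall specificity is its maximum score over conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import ConservationTrack, transcript_conservation  # re-export
from .transcripts import TranscriptModel

__all__ = [
    "SpecificityResult", "specificity_scores", "js_distance",
    "sample_correlation_compare", "max_expression_distribution",
    "transcript_conservation",
]


@dataclass
class SpecificityResult:
    scores: pd.DataFrame      # features × conditions, in [0,1]
    max_score: pd.Series      # per feature
    argmax_condition: pd.Series

    def __post_init__(self):
        assert ((self.scores.values >= -1e-12)
                & (self.scores.values <= 1 + 1e-12)).all()


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon distance (base-2) between two probability vectors."""
    return float(_jsd_rows(np.atleast_2d(p), np.asarray(q, dtype=float))[0])


def _jsd_rows(P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """sqrt(JSD_base2(p_i, q)) for each row p_i of P (rows sum to 1)."""
    P = np.asarray(P, dtype=float)
    M = (P + q) / 2.0
    logP = np.zeros_like(P)
    np.log2(P, out=logP, where=P > 0)
    logM = np.zeros_like(M)
    np.log2(M, out=logM, where=M > 0)
    logq = np.zeros_like(q)
    np.log2(q, out=logq, where=q > 0)
    t1 = (P * (logP - logM)).sum(axis=1)          # KL(p || m), bits
    t2 = (q * (logq - logM)).sum(axis=1)          # KL(q || m), bits
    jsd = 0.5 * t1 + 0.5 * t2
    return np.sqrt(np.clip(jsd, 0.0, 1.0))


def specificity_scores(expr: pd.DataFrame,
                       stages: Optional[pd.Series] = None
                       ) -> SpecificityResult:
    """Per-condition JS specificity scores for every feature.

    ``expr`` is a features × samples FPKM table. Conditions are individual
    samples by default; passing ``stages`` (sample → stage label) averages
    FPKM within stage first, making stages the conditions. A feature with an
    all-zero profile scores 0 everywhere by convention (maximally
    non-specific).
    """
    if stages is not None:
        expr = expr.T.groupby(stages.reindex(expr.columns)).mean().T
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    v = np.log10(expr.to_numpy(dtype=float) + 1.0)
    total = v.sum(axis=1, keepdims=True)
    nonzero = total[:, 0] > 0
    P = np.zeros_like(v)
    np.divide(v, total, out=P, where=total > 0)

    n_cond = expr.shape[1]
    scores = np.zeros((expr.shape[0], n_cond))
    for c in range(n_cond):
        e_c = np.zeros(n_cond)
        e_c[c] = 1.0
        scores[nonzero, c] = 1.0 - _jsd_rows(P[nonzero], e_c)
    score_df = pd.DataFrame(scores, index=expr.index, columns=expr.columns)
    return SpecificityResult(score_df, score_df.max(axis=1),
                             score_df.idxmax(axis=1))


def sample_correlation_compare(expr_lnc: pd.DataFrame,
                               expr_mrna: pd.DataFrame
                               ) -> Tuple[pd.DataFrame, pd.DataFrame,
                                          float, float]:
    """Spearman sample-sample correlation matrices per feature class and a
    two-sample t-test comparing the upper-triangle coefficient sets.

    Lower lncRNA-derived coefficients indicate more variable lncRNA
    profiles across samples than mRNA profiles.
    """
    if list(expr_lnc.columns) != list(expr_mrna.columns):
        raise ValueError("both matrices must share the same samples")
    if expr_lnc.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    cor_lnc = expr_lnc.corr(method="spearman")
    cor_mrna = expr_mrna.corr(method="spearman")
    iu = np.triu_indices(expr_lnc.shape[1], k=1)
    t, p = stats.ttest_ind(cor_lnc.to_numpy()[iu], cor_mrna.to_numpy()[iu])
    return cor_lnc, cor_mrna, float(t), float(p)


def max_expression_distribution(expr: pd.DataFrame,
                                groups: Dict[str, Sequence[str]],
                                quantiles: Sequence[float] = (0.25, 0.5, 0.75),
                                ) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-feature max FPKM over samples and per-group quantile summaries.

    ``groups`` maps a group label (e.g. "lncRNA", "mRNA") to feature ids.
    """
    max_fpkm = expr.max(axis=1)
    rows = {}
    for label, ids in groups.items():
        vals = max_fpkm.reindex([i for i in ids if i in max_fpkm.index])
        rows[label] = {f"q{q}": float(vals.quantile(q)) for q in quantiles}
    return max_fpkm, pd.DataFrame(rows).T
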