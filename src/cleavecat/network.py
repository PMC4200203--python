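"""Signed weighted co-expression network, from scratch.

The construction follows the classic weighted-correlation-network recipe:
a signed adjacency ``a_ij = ((1 + r_ij)/2)^β`` with β = 6 (the soft
threshold at which the network exhibits approximate scale-free topology),
the topological overlap transform to suppress spurious links, average
linkage clustering of ``1 − TOM``, a simplified dynamic branch cut, module
eigengenes (first principal components), merging of modules whose
eigengenes correlate above 0.75, module membership (kME) and module–trait
correlation. A local hypergeometric enrichment with Benjamini–Hochberg
adjustment replaces web-service annotation lookups.

Note on "signed correlation raised to a power": raising ``r`` itself to an
even power destroys the sign, so the standard signed-network map
``((1+r)/2)^β`` is used; the naive ``r^β`` is available behind
``signed=False`` for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cut_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_POWER = 6
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_MERGE_CUT = 0.75
VARIANCE_FLOOR = 1e-12


@dataclass
class Network:
    gene_ids: List[str]
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: Optional[np.ndarray] = None

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum of adjacency to all other nodes."""
        return self.adjacency.sum(axis=1) - np.diag(self.adjacency)


@dataclass
class ModuleAssignment:
    labels: pd.Series                 # gene → module label (0 = unassigned)
    eigengenes: pd.DataFrame          # module × sample, unit-normalised
    kme: Optional[pd.DataFrame] = None
    kme_p: Optional[pd.DataFrame] = None
    trait_r: Optional[pd.DataFrame] = None
    trait_p: Optional[pd.DataFrame] = None


def signed_adjacency(expr: pd.DataFrame, power: int = DEFAULT_POWER,
                     signed: bool = True) -> Network:
    """Adjacency from gene expression profiles (genes × samples).

    Zero-variance genes are removed (logged) before correlation.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expr.to_numpy(dtype=float)
    var = X.var(axis=1)
    keep = var > VARIANCE_FLOOR
    if not keep.all():
        log.info("removing %d zero-variance genes", (~keep).sum())
        expr = expr.loc[keep]
        X = X[keep]
    if X.shape[0] == 0:
        raise ValueError("no genes with variance left")
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** power if signed else r ** power
    np.fill_diagonal(a, 1.0)
    return Network(list(expr.index), r, a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Bins connectivity into ``n_bins`` equal-width bins and regresses
    log10(frequency) on log10(mean connectivity) over non-empty bins;
    returns −sign(slope)·R² so a decaying power law scores close to +1.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        n = sel.sum()
        if n == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0 or n <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(n / k.size))
    if len(xs) < 2:
        raise ValueError("fewer than two usable connectivity bins")
    slope, _, r_value, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r_value ** 2)


def tom_similarity(network: Network) -> np.ndarray:
    """Topological overlap matrix of a valid adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij) with
    l_ij = Σ_{u≠i,j} a_iu·a_uj; unit diagonal.
    """
    a0 = network.adjacency.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l + a0) / (kmin + 1.0 - a0)
    np.fill_diagonal(tom, 1.0)
    network.tom = tom
    return tom


# --- clustering -----------------------------------------------------------

def cluster_and_cut(tom: np.ndarray, gene_ids: Sequence[str],
                    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                    deep_split: bool = True,
                    cut_quantile: float = 0.99,
                    gap_threshold: float = 0.03,
                    core_scatter: float = 0.55,
                    max_dissim: float = 0.9,
                    ) -> Tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering of 1−TOM with a simplified dynamic cut.

    Branches of the dendrogram are decomposed top-down: an internal merge
    is split when its height exceeds the ``cut_quantile`` of all merge
    heights (the static cut), or — with ``deep_split`` — when the height
    gap between the merge and its higher child branch exceeds
    ``gap_threshold`` (a branch joined to the rest well above its own
    interior is its own module). A resulting branch becomes a module only
    if it has at least ``min_module_size`` genes and is cohesive: its
    median internal merge height must stay below
    ``q05 + core_scatter · (cut height − q05)``, which separates tight
    co-expression branches from loosely agglomerated background. Everything
    else is label 0 (unassigned). Labels are renumbered 1..m by decreasing
    size. Returns (scipy linkage matrix, gene → label Series).

    Over-split tight branches are not a concern here: the downstream
    eigengene merge step reunites modules whose profiles correlate.
    """
    n = len(gene_ids)
    if n < min_module_size or n < 2:
        log.warning("fewer genes (%d) than min_module_size", n)
        link = average(squareform(1.0 - tom, checks=False)) if n > 1 else \
            np.empty((0, 4))
        return link, pd.Series(0, index=list(gene_ids))
    dist = squareform(1.0 - tom, checks=False)
    link = average(dist)
    heights = link[:, 2]
    cut_h = float(np.quantile(heights, cut_quantile))
    q05 = float(np.quantile(heights, 0.05))
    # relative cap separates tight branches from the loose background of
    # the same dendrogram; the absolute cap (``max_dissim``) rejects
    # "modules" whose members barely co-vary at all, which matters when the
    # whole dendrogram is loose (no planted structure)
    h_max = float(heights.max())
    max_scatter = min(q05 + core_scatter * (h_max - q05), max_dissim)

    flat = cut_tree(link, height=cut_h * (1 + 1e-9) + 1e-12).ravel()
    branches: Dict[int, List[int]] = {}
    for i, c in enumerate(flat):
        branches.setdefault(int(c), []).append(i)

    clusters: List[List[int]] = []
    for c in sorted(branches):
        idx = np.array(branches[c], dtype=int)
        if deep_split and len(idx) >= min_module_size:
            clusters.extend(_gap_split(idx, tom, min_module_size,
                                       gap_threshold))
        else:
            clusters.append(list(idx))

    labels = np.zeros(n, dtype=int)
    kept: List[List[int]] = []
    for idx in clusters:
        if len(idx) < min_module_size:
            continue
        sub_h = average(squareform(
            1.0 - tom[np.ix_(idx, idx)], checks=False))[:, 2]
        if float(np.median(sub_h)) <= max_scatter:
            kept.append(list(idx))
    kept.sort(key=lambda c: (-len(c), min(c)))
    for m, idx in enumerate(kept, start=1):
        labels[np.asarray(idx, dtype=int)] = m
    return link, pd.Series(labels, index=list(gene_ids))


def _gap_split(idx: np.ndarray, tom: np.ndarray, min_size: int,
               gap_threshold: float) -> List[List[int]]:
    """Recursively re-cut a branch at the largest jump of its sorted merge
    heights.

    A branch whose agglomeration history jumps by more than
    ``gap_threshold`` consists of a tight core plus loosely attached
    material (or several cores): cutting at the jump midpoint separates
    them. Branches without such a jump are homogeneous and returned whole.
    """
    if len(idx) < 2:
        return [list(idx)]
    link = average(squareform(1.0 - tom[np.ix_(idx, idx)], checks=False))
    h = np.sort(link[:, 2])
    gaps = np.diff(h)
    if gaps.size == 0 or gaps.max() <= gap_threshold:
        return [list(idx)]
    pos = int(np.argmax(gaps))
    mid = (h[pos] + h[pos + 1]) / 2.0
    parts = cut_tree(link, height=mid).ravel()
    uniq, counts = np.unique(parts, return_counts=True)
    # a split that shatters the branch into nothing of module size has cut
    # through a genuine cluster's sparse top merges — keep the branch whole
    if uniq.size <= 1 or counts.max() < min_size:
        return [list(idx)]
    out: List[List[int]] = []
    for u in uniq:
        part = idx[parts == u]
        if len(part) >= min_size:
            out.extend(_gap_split(part, tom, min_size, gap_threshold))
        else:
            out.append(list(part))
    return out


def refine_by_kme(expr: pd.DataFrame, labels: pd.Series,
                  min_kme: float = 0.6, min_module_size: int =
                  DEFAULT_MIN_MODULE_SIZE, n_iter: int = 2) -> pd.Series:
    """Clean module assignments by module membership.

    Iteratively recomputes eigengenes and reassigns every gene to the
    module whose eigengene it correlates with most, provided that
    correlation reaches ``min_kme``; everything else becomes label 0.
    Loosely attached background picked up by the dendrogram cut fails the
    membership test and is released. Modules falling below
    ``min_module_size`` are dissolved.
    """
    labels = labels.copy()
    for _ in range(n_iter):
        if (labels > 0).sum() == 0:
            break
        mes = module_eigengene(expr, labels)
        r, _p = kme(expr, mes)
        best = r.idxmax(axis=1)
        best_r = r.max(axis=1)
        new = pd.Series(0, index=labels.index, dtype=int)
        ok = best_r >= min_kme
        new[ok] = best[ok].str.slice(2).astype(int)
        for m in new[new > 0].unique():
            if (new == m).sum() < min_module_size:
                new[new == m] = 0
        if new.equals(labels):
            break
        labels = new
    return labels


def detect_modules(expr: pd.DataFrame,
                   power: int = DEFAULT_POWER,
                   min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                   merge_cut: float = DEFAULT_MERGE_CUT,
                   min_kme: float = 0.6,
                   ) -> Tuple[Network, ModuleAssignment]:
    """The full module-detection recipe on a (log-scale) expression matrix.

    signed adjacency → TOM → average-linkage + simplified dynamic cut →
    kME refinement → eigengene merge → kME table. Returns the network and
    a complete ModuleAssignment (without trait correlations, which need
    sample metadata — see :func:`module_trait_correlation`).
    """
    net = signed_adjacency(expr, power)
    tom = tom_similarity(net)
    _link, raw = cluster_and_cut(tom, net.gene_ids, min_module_size)
    kept = expr.loc[net.gene_ids]
    refined = refine_by_kme(kept, raw, min_kme, min_module_size)
    if (refined > 0).sum() == 0:
        return net, ModuleAssignment(refined, pd.DataFrame())
    merged, mes = merge_modules(kept, refined, merge_cut)
    r, p = kme(kept, mes)
    return net, ModuleAssignment(merged, mes, r, p)


# --- eigengenes -----------------------------------------------------------

def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardised expression.

    Rows are modules ("ME<label>"), columns samples; each eigengene is
    unit-normalised and sign-oriented so its mean correlation with the
    module's member genes is non-negative. Label 0 (unassigned) is skipped.
    """
    labels = labels.reindex(expr.index)
    mes = {}
    for m in sorted(labels.dropna().unique()):
        if m == 0:
            continue
        members = expr.loc[labels == m]
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        X = members.to_numpy(dtype=float)
        sd = X.std(axis=1)
        if (sd <= VARIANCE_FLOOR).any():
            raise ValueError(f"module {m} contains constant genes")
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        e = vt[0]
        e /= np.linalg.norm(e)
        cors = (Z / np.linalg.norm(Z, axis=1, keepdims=True)) @ e
        if cors.mean() < 0:
            e = -e
        mes[f"ME{int(m)}"] = e
    return pd.DataFrame(mes, index=expr.columns).T


def merge_modules(expr: pd.DataFrame, labels: pd.Series,
                  cut: float = DEFAULT_MERGE_CUT
                  ) -> Tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge the most-correlated eigengene pair while r > cut.

    Eigengenes are recomputed after every merge; ties break toward the
    smaller label pair; merged modules keep the smaller label. Labels are
    renumbered consecutively at the end. Idempotent.
    """
    labels = labels.copy()
    while True:
        mes = module_eigengene(expr, labels)
        mods = [int(name[2:]) for name in mes.index]
        if len(mods) < 2:
            break
        E = mes.to_numpy(dtype=float)
        r = np.corrcoef(E)
        best_pair, best_r = None, cut
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if r[i, j] > best_r:
                    best_pair, best_r = (mods[i], mods[j]), r[i, j]
        if best_pair is None:
            break
        lo, hi = min(best_pair), max(best_pair)
        labels[labels == hi] = lo
    # renumber 1..m by decreasing size, deterministic
    sizes = labels[labels > 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    labels = labels.map(remap)
    return labels, module_eigengene(expr, labels)


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame
        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Module membership: Pearson r of each gene with each eigengene,
    with p-values from the t distribution on n−2 df."""
    X = expr.to_numpy(dtype=float)
    n = X.shape[1]
    Z = _standardize_rows(X)
    E = _standardize_rows(eigengenes.to_numpy(dtype=float))
    r = np.clip(Z @ E.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    cols = list(eigengenes.index)
    return (pd.DataFrame(r, index=expr.index, columns=cols),
            pd.DataFrame(p, index=expr.index, columns=cols))


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             r_flag: float = 0.7, p_flag: float = 1e-4,
                             ) -> Tuple[pd.DataFrame, pd.DataFrame,
                                        pd.DataFrame]:
    """Pearson correlation of eigengenes with numeric sample traits.

    Returns (r table, p table, boolean flag table with the stage-specific
    rule r > ``r_flag`` and p < ``p_flag``). Constant traits yield NaN.
    """
    n = eigengenes.shape[1]
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns,
                     dtype=float)
    p = r.copy()
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        for me in eigengenes.index:
            res = stats.pearsonr(eigengenes.loc[me].to_numpy(dtype=float), y)
            r.loc[me, trait] = res.statistic
            p.loc[me, trait] = res.pvalue
    flags = (r > r_flag) & (p < p_flag)
    return r, p, flags.fillna(False)


def hub_edges(network: Network, labels: pd.Series, module: int,
              top_k: int = 100, use_tom: bool = True) -> pd.DataFrame:
    """Top-``top_k`` intra-module edges by TOM weight (adjacency fallback).

    Columns: gene_a, gene_b, weight — sorted by decreasing weight, ties by
    gene ids."""
    ids = [g for g in network.gene_ids if labels.get(g) == module]
    pos = {g: i for i, g in enumerate(network.gene_ids)}
    w = network.tom if (use_tom and network.tom is not None) \
        else network.adjacency
    rows = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            rows.append((ga, gb, float(w[pos[ga], pos[gb]])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows[:top_k], columns=["gene_a", "gene_b", "weight"])


def enrichment(module_genes: Sequence[str],
               gene_sets: Mapping[str, Sequence[str]],
               universe: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a module.

    Upper-tail p (probability of an overlap at least as large) with
    Benjamini–Hochberg adjustment across sets. Genes outside the universe
    are ignored.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    mod = set(module_genes) & uni
    rows = []
    for name in sorted(gene_sets):
        s = set(gene_sets[name]) & uni
        k = len(mod & s)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(mod)))
        rows.append((name, len(s), k, p))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    return df


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    sd = np.where(sd > 0, sd, np.nan)
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
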