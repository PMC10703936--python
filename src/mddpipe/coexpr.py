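"""Co-expression module detection and per-class GSEA enrichment.

A transparent WGCNA-style procedure: variance-based gene filtering against
a fitted scaled chi-square null, soft-threshold selection by scale-free
topology fit, topological-overlap clustering with a fixed-height tree cut,
and per-class module activity scored by a weighted Kolmogorov-Smirnov
enrichment statistic normalized against size-matched random gene sets.
With two balanced classes the class scores are antisymmetric, so a module
enriched in controls scores positive there and negative in cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.spatial.distance import squareform

from mddpipe.dge import bh_adjust, estimate_size_factors

__all__ = [
    "ModuleSet",
    "normalized_log_expression",
    "filter_genes_by_variance",
    "select_soft_threshold",
    "detect_modules",
    "rank_genes_per_class",
    "gsea_enrichment_score",
    "module_nes",
]


@dataclass
class ModuleSet:
    """Disjoint co-expression modules over the filtered gene universe."""

    modules: list[set[str]]
    unassigned: set[str]
    beta: int
    filter_pvalue: float | None = None

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def universe(self) -> set[str]:
        out = set(self.unassigned)
        for m in self.modules:
            out |= m
        return out


def normalized_log_expression(
    counts: pd.DataFrame, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """log2(normalized counts + 1), using median-of-ratios size factors."""
    if size_factors is None:
        try:
            size_factors = estimate_size_factors(counts)
        except ValueError:  # no all-positive reference gene
            size_factors = estimate_size_factors(counts, pseudocount=0.5)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / s[None, :] + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def _fit_scaled_chi2(u: np.ndarray) -> tuple[float, float]:
    """Fit (scale, df) of a scaled chi-square to u by quantile matching.

    Matches the lower quartile and the median, so even a sizeable minority
    of genuinely high-variance genes does not distort the null.
    Deterministic.
    """
    q25, q50 = np.quantile(u, [0.25, 0.5])
    if q25 <= 0:
        return 1.0, 1.0
    r_obs = q50 / q25

    def gap(df):
        return stats.chi2.ppf(0.5, df) / stats.chi2.ppf(0.25, df) - r_obs

    lo, hi = 0.2, 5000.0
    if gap(lo) < 0:  # even df=0.2 has a smaller ratio: extremely heavy tail
        df = lo
    elif gap(hi) > 0:  # ratio smaller than any chi-square: near-degenerate
        df = hi
    else:
        df = brentq(gap, lo, hi, xtol=1e-6)
    scale = q25 / stats.chi2.ppf(0.25, df)
    return float(scale), float(df)


def filter_genes_by_variance(
    expr: pd.DataFrame, p_threshold: float = 0.1
) -> pd.Index:
    """Keep genes with excess variance relative to a fitted parametric null.

    The statistic is the variance-to-mean ratio of each gene's expression;
    its null is modelled as a scaled chi-square with empirically fitted
    scale and degrees of freedom, and genes with null p < ``p_threshold``
    are retained.  ``p_threshold >= 1`` keeps every gene.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = expr.to_numpy(dtype=float)
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(mean > 0, var / mean, 0.0)
    if p_threshold >= 1.0:
        return expr.index
    scale, df = _fit_scaled_chi2(u[u > 0]) if np.any(u > 0) else (1.0, 1.0)
    p = stats.chi2.sf(u / scale, df)
    keep = p < p_threshold
    if keep.sum() < 10:
        warnings.warn(
            f"variance filter retained only {int(keep.sum())} genes; proceeding"
        )
    return expr.index[keep]


def _abs_correlation(expr: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    mat = expr.to_numpy(dtype=float)
    const = mat.std(axis=1) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) excluded from correlation")
    if method == "pearson":
        cor = np.corrcoef(mat)
    elif method == "spearman":
        ranks = stats.rankdata(mat, axis=1)
        cor = np.corrcoef(ranks)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.abs(cor), const


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k, zeroed when the slope is positive."""
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2) if slope < 0 else 0.0


def select_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas: range | list[int] = range(1, 21),
    rsq_target: float = 0.8,
    method: str = "pearson",
) -> int:
    """Smallest power beta giving scale-free topology fit R^2 >= target.

    Connectivity is k_i = sum_j |cor_ij|^beta (j != i).  If no candidate
    reaches the target, the beta with the best fit is returned with a
    warning.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    betas = list(candidate_betas)
    if len(betas) == 1:
        return betas[0]
    acor, const = _abs_correlation(expr, method)
    acor = acor[~const][:, ~const]
    fits = []
    for beta in betas:
        adj = acor**beta
        k = adj.sum(axis=1) - 1.0  # exclude self
        fits.append(scale_free_fit_index(k))
    for beta, fit in zip(betas, fits):
        if fit >= rsq_target:
            return beta
    best = betas[int(np.argmax(fits))]
    warnings.warn(
        f"no candidate beta reached scale-free fit {rsq_target}; "
        f"using beta={best} (R^2={max(fits):.2f})"
    )
    return best


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM similarity of an adjacency matrix (diagonal treated as absent)."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _gap_cut_height(merge_heights: np.ndarray, min_gap_decades: float = 1.0,
                    fallback: float = 0.98) -> float:
    """Cut height from the largest gap of the merge heights in log-TOM space.

    Module merges happen at high topological overlap (1 - height), noise
    merges at overlap orders of magnitude lower; the boundary between the
    two bands is scale-free in log10(1 - height) whatever the soft power.
    If no gap spans ``min_gap_decades`` the data has no band structure and
    the fixed ``fallback`` cut applies.
    """
    tom = np.clip(1.0 - np.asarray(merge_heights, dtype=float), 1e-12, None)
    levels = np.sort(np.log10(tom))
    if levels.size < 2:
        return fallback
    gaps = np.diff(levels)
    best = int(np.argmax(gaps))
    if gaps[best] < min_gap_decades:
        return fallback
    mid = (levels[best] + levels[best + 1]) / 2.0
    return float(1.0 - 10.0**mid)


def detect_modules(
    expr: pd.DataFrame,
    beta: int,
    min_module_size: int = 30,
    cut_height: float | None = None,
    method: str = "pearson",
    filter_pvalue: float | None = None,
    kme_min: float | None = 0.5,
) -> ModuleSet:
    """Cluster genes on topological-overlap dissimilarity.

    Adjacency |cor|^beta -> TOM -> 1 - TOM -> average-linkage hierarchical
    clustering -> fixed-height cut; clusters smaller than
    ``min_module_size`` land in ``unassigned``.  With ``cut_height=None``
    the height is placed in the largest gap of the dendrogram's merge
    heights on the log-overlap scale (see :func:`_gap_cut_height`), which
    separates the module band from the noise band at any soft power;
    uncorrelated genes merge at overlap near zero and stay unassigned.

    Members whose expression correlates with the module eigengene (first
    principal component) below ``kme_min`` in absolute value are moved to
    ``unassigned`` — the usual eigengene-membership cleanup.
    """
    genes = list(expr.index)
    if len(genes) < min_module_size:
        return ModuleSet([], set(genes), beta, filter_pvalue)
    acor, _ = _abs_correlation(expr, method)
    adj = acor**beta
    dissim = 1.0 - topological_overlap(adj)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        cut_height = _gap_cut_height(Z[:, 2])
    labels = fcluster(Z, t=cut_height, criterion="distance")
    modules: list[set[str]] = []
    unassigned: set[str] = set()
    for lab in np.unique(labels):
        members = {genes[i] for i in np.flatnonzero(labels == lab)}
        if len(members) < min_module_size:
            unassigned |= members
            continue
        if kme_min is not None:
            kept_members = _kme_filter(expr, members, kme_min)
            unassigned |= members - kept_members
            members = kept_members
        if len(members) >= min_module_size:
            modules.append(members)
        else:
            unassigned |= members
    modules.sort(key=lambda m: (-len(m), sorted(m)[0]))
    return ModuleSet(modules, unassigned, beta, filter_pvalue)


def _kme_filter(expr: pd.DataFrame, members: set[str], kme_min: float) -> set[str]:
    """Drop members weakly correlated with the module eigengene."""
    sub = expr.loc[sorted(members)].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    # first right singular vector = eigengene across samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    eig_sd = eig.std()
    kme = z @ (eig - eig.mean()) / (z.shape[1] * eig_sd + 1e-12)
    return {g for g, k in zip(sorted(members), kme) if abs(k) >= kme_min}


def rank_genes_per_class(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-class gene scores: mean z-score of each gene over class samples.

    Genes are z-scored across all samples first; zero-variance genes score
    zero.  Ranking a class's column descending gives its GSEA input.
    """
    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    mat = expr.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.divide(mat - mean, sd, out=np.zeros_like(mat), where=sd > 0)
    scores = {
        cls: z[:, (labels == cls).to_numpy()].mean(axis=1) for cls in classes
    }
    return pd.DataFrame(scores, index=expr.index)


def _running_es(ordered_scores: np.ndarray, hits: np.ndarray, weight_p: float) -> float:
    """ES for one hit indicator over scores already sorted descending."""
    N = ordered_scores.size
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if nh == N:
        return 1.0  # degenerate: no misses; by convention ES = +1
    w = np.abs(ordered_scores) ** weight_p
    hw = np.where(hits, w, 0.0)
    total = hw.sum()
    if total == 0:
        hw = hits.astype(float)
        total = float(nh)
    steps = hw / total - (~hits) / (N - nh)
    running = np.cumsum(steps)
    # extremum by |.|; ties (within 1e-12) resolve to the earliest position
    m = np.abs(running)
    idx = int(np.flatnonzero(m >= m.max() - 1e-12)[0])
    return float(np.clip(running[idx], -1.0, 1.0))


def gsea_enrichment_score(
    scores: pd.Series, gene_set: set[str], weight_p: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score of a gene set.

    Genes are ranked by descending score; hits advance the running sum by
    |score|^p / sum_hits |score|^p, misses retreat by 1/(N - N_hits); ES is
    the extremum by absolute value, in [-1, 1].
    """
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    hits = ordered.index.isin(gene_set)
    return _running_es(ordered.to_numpy(dtype=float), hits, weight_p)


def _null_es(
    ordered_scores: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_p: float,
) -> np.ndarray:
    """ES distribution of size-matched random gene sets on a fixed ranking."""
    N = ordered_scores.size
    w = np.abs(ordered_scores) ** weight_p
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(N, size=set_size, replace=False)
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        hw = np.where(hits, w, 0.0)
        total = hw.sum()
        if total == 0:
            hw = hits.astype(float)
            total = float(set_size)
        steps = hw / total - (~hits) / (N - set_size)
        running = np.cumsum(steps)
        out[i] = running[np.argmax(np.abs(running))]
    return out


def module_nes(
    expr: pd.DataFrame,
    labels: pd.Series,
    modules: ModuleSet,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Normalized enrichment score of each module in each class.

    For every (module, class): ES of the module on the class's ranked
    scores; a null from ``n_perm`` size-matched random gene sets;
    NES = ES / mean |null ES of the same sign|; two-sided p from the
    signed null tail; BH across modules within each class.

    Returns a table with columns module, class, ES, NES, p, padj (module
    ids are 1-based, ordered by size).
    """
    if not modules.modules:
        raise ValueError("no modules to score")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values will be unstable")
    rng = np.random.default_rng(seed)
    class_scores = rank_genes_per_class(expr, labels)
    rows = []
    for cls in class_scores.columns:
        ordered = class_scores[cls].sort_values(ascending=False, kind="mergesort")
        ovals = ordered.to_numpy(dtype=float)
        null_cache: dict[int, np.ndarray] = {}
        es_list, p_list = [], []
        for mod in modules.modules:
            hits = ordered.index.isin(mod)
            es = _running_es(ovals, hits, weight_p)
            size = int(hits.sum())
            if size not in null_cache:
                null_cache[size] = _null_es(ovals, size, n_perm, rng, weight_p)
            null = null_cache[size]
            same = null * np.sign(es) > 0
            denom = np.abs(null[same]).mean() if same.any() else np.abs(null).mean()
            nes = es / denom if denom > 0 else 0.0
            p = (1.0 + np.sum(same & (np.abs(null) >= abs(es)))) / (1.0 + same.sum())
            es_list.append((es, nes))
            p_list.append(p)
        padj = bh_adjust(np.asarray(p_list))
        for i, ((es, nes), p, pa) in enumerate(zip(es_list, p_list, padj)):
            rows.append(
                {"module": i + 1, "class": cls, "ES": es, "NES": nes, "p": p,
                 "padj": pa}
            )
    return pd.DataFrame(rows)
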