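"""Covariate-adjusted negative-binomial differential expression.

Independent re-implementation of the standard bulk RNA-seq workflow:
median-of-ratios size factors, gene-wise method-of-moments dispersion
(Var = mu + alpha * mu^2), NB GLM with log link fitted by IRLS against a
design matrix of nuisance covariates plus condition, Wald test on the
condition coefficient, and Benjamini-Hochberg adjustment.  Because every
gene shares the design matrix, the IRLS runs batched over all genes at
once.  Numerical parity with DESeq2 is not claimed: dispersion shrinkage
and independent filtering are deliberately simpler, transparent variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec",
    "DGEResult",
    "estimate_size_factors",
    "build_design_matrix",
    "estimate_dispersions",
    "fit_nb_glm",
    "fit_nb_glm_batch",
    "wald_test",
    "bh_adjust",
    "run_region_dge",
    "cross_region_spearman",
    "intersect_de_sets",
]

MAX_ETA = 30.0  # clamp on the natural-log linear predictor


@dataclass(frozen=True)
class DesignSpec:
    """Which metadata columns enter the model, and how condition is coded.

    Numeric covariates are centered; categorical covariates are
    treatment-coded with the lexicographically first level as reference.
    The condition coefficient is case vs ``reference_level``, so
    downregulation in cases reports a negative log2 fold change.
    """

    covariates: tuple[str, ...] = ("dataset", "sex", "age", "pmi")
    condition_column: str = "condition"
    reference_level: str = "CTRL"

    def validate(self, metadata: pd.DataFrame) -> None:
        if self.condition_column in self.covariates:
            raise ValueError("condition column cannot also be a covariate")
        missing = [
            c
            for c in (*self.covariates, self.condition_column)
            if c not in metadata.columns
        ]
        if missing:
            raise ValueError(f"metadata is missing design columns: {missing}")


@dataclass
class DGEResult:
    """Per-gene DE table plus the fitted normalization and dispersions.

    ``table`` columns: baseMean, log2fc, se, wald_z, p, padj (log2fc is the
    condition coefficient on the log2 scale).
    """

    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    condition_coef: str
    n_nonconverged: int = 0
    prefiltered_genes: list[str] = field(default_factory=list)

    def de_genes(self, threshold: float = 0.05) -> set[str]:
        padj = self.table["padj"]
        return set(self.table.index[(padj < threshold).fillna(False)])


def estimate_size_factors(
    counts: pd.DataFrame, pseudocount: float | None = None
) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Reference genes are those with strictly positive counts in every
    sample; each sample's factor is the median ratio of its counts to the
    gene-wise geometric mean, rescaled so the factors have geometric mean
    one.  If no gene is all-positive, pass ``pseudocount`` to fall back to
    counts + pseudocount.
    """
    mat = counts.to_numpy(dtype=float)
    if pseudocount is not None:
        mat = mat + pseudocount
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "re-run with a pseudocount (e.g. pseudocount=0.5)"
        )
    ref = mat[positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def build_design_matrix(
    metadata: pd.DataFrame, design: DesignSpec
) -> tuple[pd.DataFrame, str]:
    """Treatment-coded design matrix with intercept; returns (X, condition term).

    Raises on rank deficiency, naming the offending columns.
    """
    design.validate(metadata)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
    for cov in design.covariates:
        values = metadata[cov]
        if np.issubdtype(values.dtype, np.number):
            cols[cov] = values.to_numpy(dtype=float) - float(values.mean())
        else:
            levels = sorted(values.astype(str).unique())
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (values.astype(str) == level).to_numpy(float)
    cond = metadata[design.condition_column].astype(str)
    levels = sorted(cond.unique())
    if design.reference_level not in levels:
        raise ValueError(
            f"reference level {design.reference_level!r} absent from "
            f"{design.condition_column!r} (levels: {levels})"
        )
    non_ref = [lv for lv in levels if lv != design.reference_level]
    if len(non_ref) != 1:
        raise ValueError(
            f"{design.condition_column!r} must have exactly two levels, got {levels}"
        )
    coef_name = f"{design.condition_column}[{non_ref[0]}]"
    cols[coef_name] = (cond == non_ref[0]).to_numpy(float)
    X = pd.DataFrame(cols, index=metadata.index)
    # drop constant non-intercept columns (e.g. a single-level factor subset)
    keep = [c for c in X.columns if c == "Intercept" or X[c].nunique() > 1]
    dropped_const = set(X.columns) - set(keep)
    if coef_name in dropped_const:
        raise ValueError("condition has a single level in this sample subset")
    X = X[keep]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a culprit set via pivoted QR
        _, _, piv = _qr_pivot(X.to_numpy())
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, coef_name


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, pivoting=True, mode="economic")
    return q, r, piv


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design_matrix: pd.DataFrame,
    alpha_min: float = 1e-8,
    shrink: bool = False,
) -> pd.Series:
    """Gene-wise method-of-moments NB dispersions on normalized counts.

    With y = K/s, fitted means from an OLS projection onto the design,
    residual variance s2 (dof-corrected) and mean ybar:

        alpha_hat = max(alpha_min, (s2 - xi * ybar) / ybar^2)

    where xi = mean(1/s) corrects for the Poisson variance of normalized
    counts.  ``shrink=True`` shrinks log-dispersions halfway toward a
    1/mean trend fitted across genes.
    """
    X = design_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float) / s[None, :]
    # OLS hat projection (shared across genes)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ coef).T
    resid = y - fitted
    s2 = np.sum(resid**2, axis=1) / (n - p)
    ybar = y.mean(axis=1)
    xi = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - xi * ybar) / ybar**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, alpha_min)
    if shrink:
        ok = ybar > 0
        t = 1.0 / np.maximum(ybar, 1e-8)
        A = np.column_stack([np.ones(ok.sum()), t[ok]])
        coefs, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
        trend = np.maximum(coefs[0] + coefs[1] * t, alpha_min)
        alpha = np.exp(0.5 * (np.log(alpha) + np.log(trend)))
        alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def fit_nb_glm_batch(
    counts: np.ndarray,
    size_factors: np.ndarray,
    X: np.ndarray,
    alphas: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS for NB GLMs with log link and log-size-factor offsets, batched.

    All genes share the design matrix ``X`` (n x p); ``counts`` is G x n,
    ``alphas`` length G.  Returns (beta [G x p, natural-log scale],
    cov [G x p x p] = (X' W X)^-1, converged [G]).  Convergence:
    max |delta beta| < tol, else flagged after ``max_iter`` iterations.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    G, n = counts.shape
    p = X.shape[1]
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (G,)).copy()
    offset = np.log(size_factors)[None, :]

    beta = np.zeros((G, p))
    norm_mean = np.maximum((counts / size_factors[None, :]).mean(axis=1), 1e-8)
    # column 0 is the intercept by construction
    beta[:, 0] = np.log(norm_mean)

    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    eye = np.eye(p) * 1e-10
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        b = beta[idx]
        eta = np.clip(offset + b @ X.T, -MAX_ETA, MAX_ETA)
        mu = np.exp(eta)
        w = mu / (1.0 + alphas[idx, None] * mu)
        z = (eta - offset) + (counts[idx] - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWz = np.einsum("ni,gn->gi", X, w * z)
        try:
            new_b = np.linalg.solve(XtWX + eye, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_b = np.stack(
                [np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(len(idx))]
            )
        delta = np.max(np.abs(new_b - b), axis=1)
        beta[idx] = new_b
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    # covariance at the final fit
    eta = np.clip(offset + beta @ X.T, -MAX_ETA, MAX_ETA)
    mu = np.exp(eta)
    w = mu / (1.0 + alphas[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
    cov = np.linalg.inv(XtWX + eye)
    return beta, cov, converged


def fit_nb_glm(
    counts_g: np.ndarray,
    size_factors: np.ndarray,
    design_matrix: np.ndarray,
    alpha_g: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Single-gene convenience wrapper around :func:`fit_nb_glm_batch`."""
    beta, cov, conv = fit_nb_glm_batch(
        np.asarray(counts_g, dtype=float)[None, :],
        np.asarray(size_factors, dtype=float),
        np.asarray(design_matrix, dtype=float),
        np.asarray([alpha_g], dtype=float),
        tol=tol,
        max_iter=max_iter,
    )
    return beta[0], cov[0], bool(conv[0])


def wald_test(
    beta: np.ndarray, cov: np.ndarray, coef_index: int
) -> tuple[float, float]:
    """Two-sided Wald z-test for one coefficient: z = beta/SE, p = 2*Phi(-|z|)."""
    se = np.sqrt(cov[..., coef_index, coef_index])
    b = beta[..., coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, b / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from m and propagated.  padj_(i) = min_{j>=i}
    p_(j) * m / j, capped at 1; ties handled by position.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    pv = arr[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    padj = np.empty(m)
    padj[order] = adj
    out[ok] = padj
    return out


def run_region_dge(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec | None = None,
    region: str = "pooled",
    region_column: str = "region",
    min_mean: float = 1.0,
    alpha_min: float = 1e-8,
    shrink_dispersion: bool = True,
    pseudocount: float | None = None,
    dispersions: pd.Series | None = None,
) -> DGEResult:
    """Full DE analysis for one brain region, or pooled across regions.

    Orchestrates size factors -> dispersions -> batched NB GLM -> Wald ->
    BH.  When ``region="pooled"`` the region column joins the design as a
    covariate; otherwise samples are subset to the region and the region
    column is excluded.  Dispersions are shrunk toward the fitted
    mean-dispersion trend by default; the raw gene-wise estimates are
    noisy enough to inflate far-tail significance on null data.
    Genes with all-zero counts are dropped; genes
    whose normalized mean falls below ``min_mean`` are prefiltered before
    BH.  No fold-change cut-off is applied.  Pass ``dispersions`` to reuse
    externally estimated gene dispersions instead of re-estimating.
    """
    if design is None:
        design = DesignSpec()
    if region == "pooled":
        meta = metadata
        covs = design.covariates
        if region_column in metadata.columns and region_column not in covs:
            covs = (*covs, region_column)
        spec = DesignSpec(covs, design.condition_column, design.reference_level)
    else:
        mask = metadata[region_column] == region
        if not mask.any():
            raise ValueError(f"no samples for region {region!r}")
        meta = metadata.loc[mask]
        covs = tuple(c for c in design.covariates if c != region_column)
        spec = DesignSpec(covs, design.condition_column, design.reference_level)
    conditions = meta[design.condition_column].unique()
    if len(conditions) < 2:
        raise ValueError(
            f"region {region!r} has a single condition ({conditions[0]!r}); "
            "differential expression is not testable"
        )
    sub = counts.loc[:, meta.index]
    nonzero = sub.sum(axis=1) > 0
    sub = sub.loc[nonzero]

    s = estimate_size_factors(sub, pseudocount=pseudocount)
    X_df, coef_name = build_design_matrix(meta, spec)
    X = X_df.to_numpy(dtype=float)
    coef_index = list(X_df.columns).index(coef_name)

    norm = sub.to_numpy(dtype=float) / s.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)
    keep = base_mean >= min_mean
    prefiltered = list(sub.index[~keep])
    tested = sub.loc[keep]

    if dispersions is None:
        disp = estimate_dispersions(tested, s, X_df, alpha_min=alpha_min,
                                    shrink=shrink_dispersion)
    else:
        disp = dispersions.loc[tested.index]
    beta, cov, conv = fit_nb_glm_batch(
        tested.to_numpy(dtype=float), s.to_numpy(), X, disp.to_numpy()
    )
    z, p = wald_test(beta, cov, coef_index)
    n_nonconv = int((~conv).sum())
    p = np.where(conv, p, np.nan)  # non-converged genes excluded from BH
    z = np.where(conv, z, np.nan)
    padj = bh_adjust(p)

    ln2 = np.log(2.0)
    table = pd.DataFrame(
        {
            "baseMean": base_mean[keep],
            "log2fc": beta[:, coef_index] / ln2,
            "se": np.sqrt(cov[:, coef_index, coef_index]) / ln2,
            "wald_z": z,
            "p": p,
            "padj": padj,
        },
        index=tested.index,
    )
    return DGEResult(
        table=table,
        size_factors=s,
        dispersions=disp,
        condition_coef=coef_name,
        n_nonconverged=n_nonconv,
        prefiltered_genes=prefiltered,
    )


def cross_region_spearman(results: Mapping[str, DGEResult]) -> pd.DataFrame:
    """Pairwise Spearman correlation of log2FC over shared finite genes."""
    regions = list(results)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    mat = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
    for ra, rb in combinations(regions, 2):
        fa = results[ra].table["log2fc"]
        fb = results[rb].table["log2fc"]
        common = fa.index.intersection(fb.index)
        va, vb = fa.loc[common], fb.loc[common]
        finite = np.isfinite(va) & np.isfinite(vb)
        if finite.sum() < 3:
            warnings.warn(f"regions {ra}/{rb}: fewer than 3 shared genes; rho=NaN")
            rho = np.nan
        else:
            rho = stats.spearmanr(va[finite], vb[finite]).statistic
        mat.loc[ra, rb] = mat.loc[rb, ra] = rho
    return mat


@dataclass
class VennResult:
    """Per-region DE sets, all intersection cardinalities, and the common core."""

    de_sets: dict[str, set[str]]
    intersection_counts: dict[tuple[str, ...], int]
    common_genes: set[str]
    common_signs: dict[str, dict[str, int]]  # gene -> region -> sign(log2fc)


def intersect_de_sets(
    results: Mapping[str, DGEResult], threshold: float = 0.05
) -> VennResult:
    """DE sets at padj < threshold and their full intersection structure."""
    de_sets = {r: res.de_genes(threshold) for r, res in results.items()}
    regions = list(results)
    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(regions) + 1):
        for combo in combinations(regions, k):
            inter = set.intersection(*(de_sets[r] for r in combo))
            counts[combo] = len(inter)
    common = set.intersection(*de_sets.values()) if de_sets else set()
    signs = {
        g: {
            r: int(np.sign(results[r].table.loc[g, "log2fc"]))
            for r in regions
            if g in results[r].table.index
        }
        for g in common
    }
    return VennResult(de_sets, counts, common, signs)
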