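"""Sparse multiple kernel learning over pathway-restricted kernels.

Each gene set maps to a Gaussian kernel computed on the expression of its
member genes; a soft-margin SVM is trained on the simplex-weighted kernel
combination, and kernel weights are updated multiplicatively toward
kernels the decision function actually uses.  The l1 (simplex) constraint
drives most weights to zero, so the surviving pathways are the informative
ones.  The replication protocol mirrors the study design: stratified 80/20
train/test splits, 4-fold inner cross-validation for the SVM cost C,
test-set AUC per replication, and per-pathway selection frequencies at a
kernel-weight threshold of 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from mddpipe.io import GeneSetCollection

__all__ = [
    "SplitData",
    "KernelBundle",
    "MKLModel",
    "MKLReport",
    "preprocess_split",
    "pathway_kernel",
    "build_kernel_bundle",
    "solve_svm_dual",
    "optimize_kernel_weights",
    "inner_cv_select_C",
    "auc",
    "replicate_experiment",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class SplitData:
    """A stratified split with train-fitted normalization applied to both sides.

    ``X_*`` are samples x genes; features are log2(x+1) then z-scored with
    the train mean and standard deviation only, so the test side never
    leaks into the normalizer.
    """

    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: pd.Series
    y_test: pd.Series
    train_mean: pd.Series
    train_sd: pd.Series
    n_zero_variance: int = 0


def preprocess_split(
    expr: pd.DataFrame,
    labels: pd.Series,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> SplitData:
    """Stratified train/test split with log2 + train-only z-normalization.

    ``expr`` is genes x samples of normalized counts.  Class proportions
    are preserved exactly (up to rounding) in both partitions.  Genes with
    zero variance in the train partition get unit standard deviation.
    """
    labels = labels.loc[expr.columns]
    counts = labels.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("both classes need at least 2 samples")
    samples = np.asarray(expr.columns)
    tr, te = train_test_split(
        samples,
        test_size=1.0 - train_frac,
        stratify=labels.to_numpy(),
        random_state=None if seed is None else int(seed) % (2**32),
    )
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    logdf = pd.DataFrame(logx, index=expr.index, columns=expr.columns)
    Xtr = logdf[tr].T
    Xte = logdf[te].T
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    n_zero = int((sd == 0).sum())
    sd = sd.where(sd > 0, 1.0)
    return SplitData(
        X_train=(Xtr - mean) / sd,
        X_test=(Xte - mean) / sd,
        y_train=labels.loc[tr],
        y_test=labels.loc[te],
        train_mean=mean,
        train_sd=sd,
        n_zero_variance=n_zero,
    )


def pathway_kernel(
    train_expr: pd.DataFrame,
    test_expr: pd.DataFrame | None,
    gene_set: list[str] | set[str],
    min_genes: int = 3,
    sigma_sq: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None, float, list[str]]:
    """Gaussian kernel on the expression of a pathway's genes.

    K(x, y) = exp(-||x - y||^2 / (2 sigma^2)); by default sigma^2 is the
    mean squared pairwise distance between train samples (computed once on
    train, reused for the cross kernel).  Raises if fewer than
    ``min_genes`` of the set are present in the expression matrix.
    """
    genes = [g for g in gene_set if g in train_expr.columns]
    if len(genes) < min_genes:
        raise ValueError(
            f"pathway has {len(genes)} expressed genes (< min_genes={min_genes})"
        )
    A = train_expr[genes].to_numpy(dtype=float)
    d2 = cdist(A, A, metric="sqeuclidean")
    if sigma_sq is None:
        n = A.shape[0]
        off = d2[~np.eye(n, dtype=bool)]
        sigma_sq = float(off.mean()) if off.size and off.mean() > 0 else 1.0
    K_train = np.exp(-d2 / (2.0 * sigma_sq))
    K_cross = None
    if test_expr is not None:
        B = test_expr[genes].to_numpy(dtype=float)
        K_cross = np.exp(-cdist(B, A, metric="sqeuclidean") / (2.0 * sigma_sq))
    return K_train, K_cross, sigma_sq, genes


@dataclass
class KernelBundle:
    """Per-pathway train and cross kernels sharing one sample partition."""

    pathways: list[str]
    train_kernels: dict[str, np.ndarray]
    cross_kernels: dict[str, np.ndarray]
    sigma_sq: dict[str, float]
    genes_used: dict[str, list[str]]
    skipped: list[str] = field(default_factory=list)


def build_kernel_bundle(
    train_expr: pd.DataFrame,
    test_expr: pd.DataFrame | None,
    collection: GeneSetCollection,
    min_genes: int = 3,
) -> KernelBundle:
    """One Gaussian kernel per pathway; under-covered pathways are skipped."""
    bundle = KernelBundle([], {}, {}, {}, {})
    for name in collection.names():
        try:
            K, Kx, s2, genes = pathway_kernel(
                train_expr, test_expr, collection[name], min_genes=min_genes
            )
        except ValueError:
            bundle.skipped.append(name)
            continue
        bundle.pathways.append(name)
        bundle.train_kernels[name] = K
        if Kx is not None:
            bundle.cross_kernels[name] = Kx
        bundle.sigma_sq[name] = s2
        bundle.genes_used[name] = genes
    if not bundle.pathways:
        raise ValueError("no pathway has enough expressed genes")
    return bundle


def solve_svm_dual(
    K: np.ndarray, y: np.ndarray, C: float
) -> tuple[np.ndarray, float, float]:
    """Soft-margin SVM dual with a precomputed kernel.

    Returns (signed dual coefficients a_i = y_i alpha_i over all samples,
    bias, dual objective sum alpha - 1/2 a' K a).
    """
    y = np.asarray(y, dtype=float)
    svc = SVC(kernel="precomputed", C=C, tol=1e-6)
    try:
        svc.fit(K, y)
    except np.linalg.LinAlgError:
        svc.fit(K + 1e-8 * np.eye(K.shape[0]), y)
    a = np.zeros(K.shape[0])
    a[svc.support_] = svc.dual_coef_[0]
    b = float(svc.intercept_[0])
    obj = float(np.sum(np.abs(a)) - 0.5 * a @ K @ a)
    return a, b, obj


@dataclass
class MKLModel:
    """Fitted MKL classifier: simplex kernel weights plus SVM duals."""

    eta: pd.Series
    dual_coef: np.ndarray
    bias: float
    C: float
    selection_threshold: float = 0.01
    objective: float = np.nan
    objective_history: list[float] = field(default_factory=list)
    eta_history: list[np.ndarray] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def selected_pathways(self) -> list[str]:
        return list(self.eta.index[self.eta > self.selection_threshold])

    def decision_function(self, cross_kernels: dict[str, np.ndarray]) -> np.ndarray:
        Kx = None
        for name, w in self.eta.items():
            if w <= 0:
                continue
            term = w * cross_kernels[name]
            Kx = term if Kx is None else Kx + term
        if Kx is None:
            return np.full(
                next(iter(cross_kernels.values())).shape[0], self.bias
            )
        return Kx @ self.dual_coef + self.bias


def _combine(kernels: dict[str, np.ndarray], eta: pd.Series) -> np.ndarray:
    names = list(eta.index)
    K = np.zeros_like(kernels[names[0]])
    for name, w in eta.items():
        if w > 0:
            K += w * kernels[name]
    return K


def optimize_kernel_weights(
    kernels: dict[str, np.ndarray],
    y: np.ndarray,
    C: float,
    tol: float = 1e-4,
    max_iter: int = 50,
    selection_threshold: float = 0.01,
    eta_init: pd.Series | None = None,
) -> MKLModel:
    """Alternating MKL optimization on the simplex.

    Repeats: (a) solve the SVM dual on K_eta = sum eta_m K_m; (b) update
    eta_m <- eta_m * sqrt(a' K_m a) and renormalize to the simplex.  A
    geometric damping line-search rejects weight steps that increase the
    min-max objective, so the objective is non-increasing across
    alternations.  Entries below 1e-6 are clamped to zero (and stay zero,
    the update being multiplicative).  Stops when max |delta eta| < tol.
    """
    names = list(kernels)
    if not names:
        raise ValueError("need at least one kernel")
    y = np.asarray(y, dtype=float)
    if eta_init is None:
        eta = pd.Series(np.full(len(names), 1.0 / len(names)), index=names)
    else:
        eta = eta_init.reindex(names).astype(float)
        eta = eta / eta.sum()
    if len(names) == 1:
        a, b, obj = solve_svm_dual(kernels[names[0]], y, C)
        return MKLModel(pd.Series([1.0], index=names), a, b, C,
                        selection_threshold, obj, [obj],
                        [np.array([1.0])], 1, True)

    a, b, obj = solve_svm_dual(_combine(kernels, eta), y, C)
    history = [obj]
    eta_history = [eta.to_numpy().copy()]
    best = (obj, eta.copy(), a, b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = np.array([max(a @ kernels[m] @ a, 0.0) for m in names])
        raw = eta.to_numpy() * np.sqrt(f)
        if raw.sum() <= 0:
            break
        target = raw / raw.sum()
        accepted = False
        step = 1.0
        for _ in range(4):
            cand = (1.0 - step) * eta.to_numpy() + step * target
            cand[cand < 1e-6] = 0.0
            cand = cand / cand.sum()
            cand_s = pd.Series(cand, index=names)
            a_c, b_c, obj_c = solve_svm_dual(_combine(kernels, cand_s), y, C)
            if obj_c <= obj + 1e-12:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            warnings.warn("MKL weight update stalled; returning best iterate")
            break
        delta = float(np.max(np.abs(cand_s.to_numpy() - eta.to_numpy())))
        eta, a, b, obj = cand_s, a_c, b_c, obj_c
        history.append(obj)
        eta_history.append(eta.to_numpy().copy())
        if obj <= best[0]:
            best = (obj, eta.copy(), a, b)
        if delta < tol:
            converged = True
            break
    obj, eta, a, b = best
    if not converged and it == max_iter:
        warnings.warn("MKL did not converge within max_iter; best iterate returned")
    return MKLModel(eta, a, b, C, selection_threshold, obj, history,
                    eta_history, it, converged)


def auc(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 0.5).

    ``labels`` must contain exactly two values; the larger one (after
    sorting) is the positive class for +1/-1 or boolean labels; for string
    labels pass +1/-1 converted beforehand.
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("AUC needs exactly two classes in the labels")
    pos = y == classes[-1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def inner_cv_select_C(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    collection: GeneSetCollection,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    k: int = 4,
    seed: int | None = None,
    min_genes: int = 3,
    tol: float = 1e-3,
    max_iter: int = 20,
) -> float:
    """Pick C by stratified k-fold CV on the training partition.

    Maximizes the mean validation-fold AUC; ties break toward the
    smallest C.  If a fold ends up single-class the split is redrawn with
    a new seed (with a warning).
    """
    C_grid = tuple(C_grid)
    if not C_grid:
        raise ValueError("empty C grid")
    if len(C_grid) == 1:
        return C_grid[0]
    y = np.asarray(y_train, dtype=float)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        warnings.warn(
            f"smallest class ({int(counts.min())}) < {k} folds; using "
            f"{int(counts.min())} folds"
        )
        k = int(counts.min())
    base_seed = 0 if seed is None else int(seed)
    folds = None
    for attempt in range(5):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=(base_seed + attempt) % (2**32)
        )
        candidate = list(skf.split(np.zeros(len(y)), y))
        if all(
            np.unique(y[tr]).size == 2 and np.unique(y[va]).size == 2
            for tr, va in candidate
        ):
            folds = candidate
            if attempt:
                warnings.warn("refolded inner CV with a new seed (degenerate fold)")
            break
    if folds is None:
        raise ValueError("could not build stratified inner folds with both classes")
    mean_auc = []
    for C in C_grid:
        fold_aucs = []
        for tr, va in folds:
            Xtr, Xva = X_train.iloc[tr], X_train.iloc[va]
            bundle = build_kernel_bundle(Xtr, Xva, collection, min_genes=min_genes)
            model = optimize_kernel_weights(
                bundle.train_kernels, y[tr], C, tol=tol, max_iter=max_iter
            )
            scores = model.decision_function(bundle.cross_kernels)
            fold_aucs.append(auc(scores, y[va]))
        mean_auc.append(float(np.mean(fold_aucs)))
    best = max(mean_auc)
    for C, m in zip(C_grid, mean_auc):  # smallest C among ties
        if m >= best - 1e-12:
            return C
    return C_grid[int(np.argmax(mean_auc))]


@dataclass
class MKLReport:
    """Aggregate of the replicated MKL protocol."""

    replications: list[dict]
    selection_counts: pd.Series
    n_replications: int
    selection_threshold: float
    n_failures: int = 0

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r["auc"] for r in self.replications])

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.replications) > 1 else 0.0

    def informative_pathways(self) -> list[str]:
        """Pathways selected in at least half of the replications."""
        cut = self.n_replications / 2.0
        return list(self.selection_counts.index[self.selection_counts >= cut])

    def selection_table(self) -> pd.DataFrame:
        mean_w = {}
        for name in self.selection_counts.index:
            ws = [float(r["eta"].get(name, 0.0)) for r in self.replications]
            mean_w[name] = float(np.mean(ws)) if ws else 0.0
        out = pd.DataFrame(
            {
                "pathway": self.selection_counts.index,
                "selection_count": self.selection_counts.to_numpy(),
                "selection_frequency": self.selection_counts.to_numpy()
                / self.n_replications,
                "mean_weight": [mean_w[n] for n in self.selection_counts.index],
            }
        )
        return out.sort_values(
            ["selection_count", "mean_weight"], ascending=False, kind="mergesort"
        ).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "n_replications": self.n_replications,
            "n_failures": self.n_failures,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "selection_threshold": self.selection_threshold,
            "selection_counts": self.selection_counts.to_dict(),
            "replications": [
                {
                    "auc": r["auc"],
                    "C": r["C"],
                    "seed": r["seed"],
                    "eta": {k: float(v) for k, v in r["eta"].items() if v > 0},
                }
                for r in self.replications
            ],
        }


def replicate_experiment(
    expr: pd.DataFrame,
    labels: pd.Series,
    collection: GeneSetCollection,
    n_replications: int = 100,
    seed: int = 0,
    train_frac: float = 0.8,
    inner_folds: int = 4,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    selection_threshold: float = 0.01,
    min_genes: int = 3,
    positive_label: str = "CASE",
    tol: float = 1e-4,
    max_iter: int = 50,
) -> MKLReport:
    """Full replicated MKL protocol on a normalized-count expression matrix.

    Per replication (child seed = root seed + replication index):
    stratified split -> inner CV for C -> MKL fit on the full training
    partition -> decision values and AUC on the held-out test partition.
    A pathway counts as selected when its kernel weight exceeds
    ``selection_threshold``; 'informative' means selected in at least half
    of the replications.  Failed replications are recorded and excluded.
    """
    labels = labels.loc[expr.columns]
    replications: list[dict] = []
    counts = pd.Series(0, index=collection.names(), dtype=int)
    failures = 0
    for rep in range(n_replications):
        child = (int(seed) + rep) % (2**31)
        try:
            split = preprocess_split(expr, labels, train_frac, seed=child)
            ytr = np.where(split.y_train == positive_label, 1.0, -1.0)
            yte = np.where(split.y_test == positive_label, 1.0, -1.0)
            C = inner_cv_select_C(
                split.X_train, ytr, collection, C_grid,
                k=inner_folds, seed=child, min_genes=min_genes,
            )
            bundle = build_kernel_bundle(
                split.X_train, split.X_test, collection, min_genes=min_genes
            )
            model = optimize_kernel_weights(
                bundle.train_kernels, ytr, C, tol=tol, max_iter=max_iter,
                selection_threshold=selection_threshold,
            )
            scores = model.decision_function(bundle.cross_kernels)
            rep_auc = auc(scores, yte)
        except Exception as exc:  # noqa: BLE001 — protocol isolates failures
            warnings.warn(f"replication {rep} failed: {exc}")
            failures += 1
            continue
        for name in model.selected_pathways:
            counts[name] += 1
        replications.append(
            {"auc": rep_auc, "C": C, "eta": model.eta.to_dict(), "seed": child}
        )
    return MKLReport(
        replications=replications,
        selection_counts=counts,
        n_replications=n_replications,
        selection_threshold=selection_threshold,
        n_failures=failures,
    )
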