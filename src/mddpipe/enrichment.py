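"""Overrepresentation analysis of a gene list against a gene-set collection.

One-sided Fisher exact enrichment p (hypergeometric tail), BH adjustment
across the collection, an odds ratio with Haldane correction, and an
Enrichr-style combined score  c = -ln(p) * z  where z measures how far the
pathway's rank under the real query deviates from its rank under random
queries of the same size.  Also emits the gene-gene co-occurrence edge
list over the top pathways, and the count of query genes covered by no
pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from mddpipe.dge import bh_adjust
from mddpipe.io import GeneSetCollection

__all__ = ["ORAResult", "fisher_ora", "odds_ratio", "combined_score", "run_ora"]

_TINY = np.finfo(float).tiny


@dataclass
class ORAResult:
    """Ranked pathway table plus the co-occurrence network and coverage."""

    table: pd.DataFrame  # pathway, overlap (k/K), p, padj, odds ratio, score, genes
    edges: pd.DataFrame  # gene_a, gene_b, weight
    uncovered_genes: set[str]
    background_size: int


def fisher_ora(
    query: set[str], pathway: set[str], background: set[str]
) -> tuple[float, tuple[int, int, int, int]]:
    """One-sided (enrichment) Fisher exact test for query-pathway overlap.

    2x2 table: a = |query & pathway|, b = |query| - a, c = K - a,
    d = |background| - |query| - K + a, with K = |pathway & background|.
    p is the upper hypergeometric tail P(X >= a).
    """
    if not background:
        raise ValueError("empty background universe")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N = len(background)
    K = len(pathway & background)
    n = len(query)
    a = len(query & pathway & background)
    b, c, d = n - a, K - a, N - n - K + a
    p = float(stats.hypergeom.sf(a - 1, N, K, n))
    return min(p, 1.0), (a, b, c, d)


def odds_ratio(table: tuple[int, int, int, int]) -> float:
    """(a*d)/(b*c), with Haldane 0.5 added to every cell when any is zero."""
    a, b, c, d = table
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell in 2x2 table; Haldane 0.5 correction applied")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def combined_score(p: float, z: float) -> float:
    """Enrichr-style combined score c = -ln(p) * z."""
    if p <= 0:
        warnings.warn("p = 0 clamped to the smallest positive float")
        p = _TINY
    return -np.log(p) * z


def _membership_matrix(
    collection: GeneSetCollection, background: list[str]
) -> np.ndarray:
    index = {g: i for i, g in enumerate(background)}
    M = np.zeros((len(collection), len(background)), dtype=bool)
    for row, name in enumerate(collection.names()):
        for g in collection[name]:
            if g in index:
                M[row, index[g]] = True
    return M


def _tail_p(a: np.ndarray, N: int, K: np.ndarray, n: int) -> np.ndarray:
    return np.minimum(stats.hypergeom.sf(a - 1, N, K, n), 1.0)


def run_ora(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    top_k: int = 10,
    n_resample: int = 1000,
    seed: int | None = None,
    score_mode: str = "resample",
) -> ORAResult:
    """Score every pathway against the query and rank by combined score.

    ``score_mode="resample"``: the deviation z of each pathway is the
    z-score of its rank (by Fisher p within the collection) under the real
    query against the rank distribution over ``n_resample`` random queries
    of equal size, clipped at zero.  ``score_mode="logor"`` uses
    max(0, ln OR) instead (cheaper, not the Enrichr construction).

    The edge list pairs overlap genes co-occurring in the ``top_k``
    pathways, weighted by the number of shared top pathways.
    """
    query = set(query) & set(background)
    if not query:
        raise ValueError("query does not intersect the background")
    bg_list = sorted(background)
    N, n = len(bg_list), len(query)
    names = collection.names()
    if not names:
        raise ValueError("empty gene-set collection")
    M = _membership_matrix(collection, bg_list).astype(np.int64)
    qvec = np.zeros(N, dtype=np.int64)
    qidx = {g: i for i, g in enumerate(bg_list)}
    for g in query:
        qvec[qidx[g]] = 1
    K = M.sum(axis=1)
    a = M @ qvec
    p = _tail_p(a, N, K, n)
    padj = bh_adjust(p)

    ors = np.empty(len(names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(names)):
            table = (int(a[i]), n - int(a[i]), int(K[i] - a[i]),
                     N - n - int(K[i]) + int(a[i]))
            ors[i] = odds_ratio(table)

    if score_mode == "resample":
        rng = np.random.default_rng(seed)
        ranks_null = np.empty((n_resample, len(names)))
        for r in range(n_resample):
            rq = np.zeros(N, dtype=np.int64)
            rq[rng.choice(N, size=n, replace=False)] = 1
            pr = _tail_p(M @ rq, N, K, n)
            ranks_null[r] = stats.rankdata(pr, method="average")
        actual_rank = stats.rankdata(p, method="average")
        mu = ranks_null.mean(axis=0)
        sd = ranks_null.std(axis=0, ddof=1)
        z = np.divide(mu - actual_rank, sd, out=np.zeros(len(names)), where=sd > 0)
        z = np.maximum(z, 0.0)
    elif score_mode == "logor":
        z = np.maximum(np.log(ors), 0.0)
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = np.array([combined_score(pi, zi) for pi, zi in zip(p, z)])

    overlap_genes = [
        sorted(query & set(collection[name]) & background) for name in names
    ]
    table = pd.DataFrame(
        {
            "pathway": names,
            "overlap": [f"{ai}/{Ki}" for ai, Ki in zip(a, K)],
            "overlap_count": a,
            "set_size": K,
            "p": p,
            "padj": padj,
            "odds_ratio": ors,
            "combined_score": scores,
            "genes": [";".join(g) for g in overlap_genes],
        }
    ).sort_values("combined_score", ascending=False, kind="mergesort")
    top = table.head(top_k)

    weights: dict[tuple[str, str], int] = {}
    for name in top["pathway"]:
        members = sorted(query & set(collection[name]))
        for ga, gb in combinations(members, 2):
            weights[(ga, gb)] = weights.get((ga, gb), 0) + 1
    edges = pd.DataFrame(
        [(ga, gb, w) for (ga, gb), w in sorted(weights.items())],
        columns=["gene_a", "gene_b", "weight"],
    )
    covered: set[str] = set()
    for name in names:
        covered |= set(collection[name])
    uncovered = query - covered
    return ORAResult(
        table=top.reset_index(drop=True),
        edges=edges,
        uncovered_genes=uncovered,
        background_size=N,
    )
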