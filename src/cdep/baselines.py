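"""Comparator meta-analysis methods: signature counting and pooled rank
products.

*Meta-Profile* thresholds each study's FDR column at a fixed cutoff ``l`` to
form per-study "differential expression signatures" and scores each gene by
the number of signatures it appears in.  Its null distribution shuffles
every study's FDR column over genes, exactly as the CDEP meta-permutation
does, and the gene-level FDR applies the same ratio-of-counts estimator to
the count statistic (larger = more significant).

*Meta-RankProd* pools all pairwise case-control comparisons from all
studies into one rank product per gene (geometric mean over the combined
``sum_i H_i`` comparisons), assigning genes absent from a study that
study's median rank.  Its null permutes expression values within each
single array, and significance follows the standard rank-product recipe
(pooled permutation p-value, then p * G / rank).  Because every comparison
enters with equal weight, studies with many samples dominate the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import FdrPanel
from .datasets import ExpressionDataset, GeneUniverse
from .rankprod import RankProdResult, _rank_rows, pairwise_fold_changes

__all__ = ["BaselineResult", "meta_profile", "meta_rankprod"]


@dataclass
class BaselineResult:
    method: str  # "meta_profile" | "meta_rankprod"
    direction: str
    genes: list[str]
    score: np.ndarray
    fdr_g: np.ndarray
    B: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "score": self.score, "fdr_g": self.fdr_g}
        )

    def called_genes(self, threshold: float) -> list[str]:
        return [g for g, f in zip(self.genes, self.fdr_g) if f <= threshold]


def meta_profile(
    panel: FdrPanel,
    l: float,
    B: int,
    seed: int | np.random.SeedSequence | None,
    direction: str,
) -> BaselineResult:
    """Signature-count meta-analysis on an FDR panel.

    ``score_g = sum_i I(F_gi < l)``; FDR_g compares the observed counts with
    ``B`` within-study column shuffles using inclusive-tie counting:

        FDR_g = [(1/B) sum_b #{g': score_b,g' >= score_g}] / #{g': score_g' >= score_g}
    """
    if not 0.0 < l < 1.0:
        raise ValueError("signature threshold l must lie in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    F = panel.matrix(direction)
    G, D = F.shape
    hits = F < l
    score = hits.sum(axis=1)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(D)]
    # shuffling a 0/1 column and summing: accumulate null counts per gene
    null_scores = np.zeros((B, G), dtype=np.int64)
    for i in range(D):
        rng = streams[i]
        col = hits[:, i]
        for b in range(B):
            null_scores[b] += col[rng.permutation(G)]

    # counts take values 0..D: tail sums via bincount
    obs_hist = np.bincount(score, minlength=D + 1)
    null_hist = np.bincount(null_scores.ravel(), minlength=D + 1)
    obs_tail = np.cumsum(obs_hist[::-1])[::-1]  # #{score >= v}
    null_tail = np.cumsum(null_hist[::-1])[::-1]
    fdr = np.minimum((null_tail[score] / B) / obs_tail[score], 1.0)
    return BaselineResult(
        method="meta_profile", direction=direction, genes=list(panel.genes),
        score=score, fdr_g=fdr, B=B,
    )


def _permuted_within_arrays(ds: ExpressionDataset, rng: np.random.Generator) -> np.ndarray:
    """Shuffle each array's (column's) expression values over genes."""
    return rng.permuted(ds.values, axis=0)


def _logrank_sums(values: np.ndarray, ds: ExpressionDataset):
    """Sums over all comparisons of log up-ranks and log down-ranks, per gene."""
    cases = ds.case_indices()
    controls = ds.control_indices()
    fc = (values[:, cases][:, :, None] - values[:, controls][:, None, :]).reshape(
        ds.n_genes, len(cases) * len(controls)
    )
    r = _rank_rows(fc.T)  # ascending: rank 1 = strongest down
    G = ds.n_genes
    sum_down = np.log(r, dtype=np.float64).sum(axis=0)
    sum_up = np.log(G + 1.0 - r).sum(axis=0)
    return sum_up, sum_down


def meta_rankprod(
    results: list[RankProdResult],
    universe: GeneUniverse,
    datasets: list[ExpressionDataset],
    B: int,
    seed: int | np.random.SeedSequence | None,
    direction: str = "both",
):
    """Pooled rank product across all comparisons of all studies.

    Uses the per-study geometric-mean ranks of ``results`` for the observed
    statistic (``prod_i gamma_gi^H_i`` over ``sum_i H_i`` comparisons;
    absent genes contribute the study's median gamma per comparison) and
    within-array value permutations of ``datasets`` for the null.  With
    ``direction="both"`` a (up, down) tuple is returned from one shared
    permutation pass.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(results) != len(datasets):
        raise ValueError("results and datasets must align")
    G = len(universe)
    H_total = sum(r.H for r in results)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    def observed(direction: str) -> np.ndarray:
        logsum = np.zeros(G)
        for res in results:
            gamma = res.gmean_rank_up if direction == "up" else res.gmean_rank_down
            med = np.median(gamma)
            contrib = np.full(G, res.H * np.log(med))
            contrib[universe.positions(res.genes)] = res.H * np.log(gamma)
            logsum += contrib
        return np.exp(logsum / H_total)

    obs = {d: observed(d) for d in ("up", "down")}

    null_up = np.empty((B, G))
    null_down = np.empty((B, G))
    streams = [np.random.default_rng(s) for s in ss.spawn(len(datasets))]
    med_log_up = [np.log(np.median(r.gmean_rank_up)) for r in results]
    med_log_down = [np.log(np.median(r.gmean_rank_down)) for r in results]
    positions = [universe.positions(ds.genes) for ds in datasets]
    for b in range(B):
        lsum_up = np.zeros(G)
        lsum_down = np.zeros(G)
        for j, ds in enumerate(datasets):
            su, sd = _logrank_sums(_permuted_within_arrays(ds, streams[j]), ds)
            lsum_up += results[j].H * med_log_up[j]
            lsum_down += results[j].H * med_log_down[j]
            np.add.at(lsum_up, positions[j], su - results[j].H * med_log_up[j])
            np.add.at(lsum_down, positions[j], sd - results[j].H * med_log_down[j])
        null_up[b] = np.exp(lsum_up / H_total)
        null_down[b] = np.exp(lsum_down / H_total)

    def finish(direction: str, null: np.ndarray) -> BaselineResult:
        score = obs[direction]
        pooled = np.sort(null, axis=None)
        p = (1.0 + np.searchsorted(pooled, score, side="right")) / (1.0 + pooled.size)
        rank = scipy.stats.rankdata(score, method="average")
        fdr = np.minimum(p * G / rank, 1.0)
        return BaselineResult(
            method="meta_rankprod", direction=direction, genes=list(universe.genes),
            score=score, fdr_g=fdr, B=B,
        )

    res_up = finish("up", null_up)
    res_down = finish("down", null_down)
    if direction == "up":
        return res_up
    if direction == "down":
        return res_down
    if direction == "both":
        return res_up, res_down
    raise ValueError(f"direction must be 'up', 'down' or 'both', got {direction!r}")
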