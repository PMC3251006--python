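"""Per-dataset rank-product statistics with permutation p-values and FDRs.

For a study with ``m`` cases and ``n`` controls every one of the
``H = m*n`` case-control pairs yields a log fold change per gene.  Genes are
ranked within each pairwise comparison (rank 1 = most extreme in the tested
direction) and the rank product is the geometric mean rank across the H
comparisons:

    gamma_g = (prod_h rank_gh) ** (1/H)

Small rank products flag genes consistently extreme across comparisons.
Significance comes from permuting the sample labels: the p-value of a gene
is the fraction of permutation rank products (pooled over all genes) at or
below its observed value, and the FDR is the p-value divided by the gene's
rank-product rank, times the number of genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import ExpressionDataset

__all__ = [
    "RankProdResult",
    "pairwise_fold_changes",
    "rank_product",
    "rankprod_significance",
]

# Below this element count, exact average-tie ranking is used.  Larger
# matrices (continuous expression data, where exact ties are incidental) go
# through a float32 stable-argsort path with ordinal ranks, ties broken
# deterministically by gene order.
_EXACT_RANK_MAX_SIZE = 250_000


@dataclass
class RankProdResult:
    """Rank-product output for one dataset, both directions."""

    dataset_id: str
    genes: list[str]
    gmean_rank_up: np.ndarray
    gmean_rank_down: np.ndarray
    pval_up: np.ndarray
    pval_down: np.ndarray
    fdr_up: np.ndarray
    fdr_down: np.ndarray
    H: int
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "gmean_rank_up": self.gmean_rank_up,
                "gmean_rank_down": self.gmean_rank_down,
                "pval_up": self.pval_up,
                "pval_down": self.pval_down,
                "fdr_up": self.fdr_up,
                "fdr_down": self.fdr_down,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Ascending ranks along axis 1 (rank 1 = smallest value).

    Exact average ranks for small inputs; for large inputs a float32
    stable-argsort with ordinal ranks (gene-order tie-break).
    """
    if a.size <= _EXACT_RANK_MAX_SIZE:
        return scipy.stats.rankdata(a, axis=1, method="average")
    a32 = np.ascontiguousarray(a, dtype=np.float32)
    order = np.argsort(a32, axis=1, kind="stable")
    ranks = np.empty(a.shape, dtype=np.float32)
    np.put_along_axis(ranks, order, np.arange(1, a.shape[1] + 1, dtype=np.float32)[None, :], axis=1)
    return ranks


def pairwise_fold_changes(ds: ExpressionDataset) -> np.ndarray:
    """All case-minus-control log fold changes, one column per comparison.

    Columns are enumerated case-major: for cases ``c1..cm`` and controls
    ``t1..tn`` the order is (c1,t1), (c1,t2), ..., (c2,t1), ...
    """
    cases = ds.case_indices()
    controls = ds.control_indices()
    fc = ds.values[:, cases][:, :, None] - ds.values[:, controls][:, None, :]
    return fc.reshape(ds.n_genes, len(cases) * len(controls))


def rank_product(fc: np.ndarray, direction: str) -> np.ndarray:
    """Geometric-mean rank across comparisons for one direction.

    For ``direction="up"`` rank 1 goes to the largest fold change in each
    comparison; for ``"down"`` to the smallest.  Ties get average ranks.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if fc.shape[0] < 2:
        raise ValueError("rank product needs at least 2 genes")
    # exact path irrespective of size: this public helper is not the hot loop
    r = scipy.stats.rankdata(fc, axis=0, method="average")
    if direction == "up":
        r = fc.shape[0] + 1 - r
    return np.exp(np.mean(np.log(r), axis=1))


def _gamma_from_rank_rows(rank_rows: np.ndarray, G: int) -> tuple[np.ndarray, np.ndarray]:
    """(gamma_up, gamma_down) per gene from ascending fold-change ranks.

    ``rank_rows`` is (H, G): ascending ranks of the fold change, so rank 1 =
    strongest down-regulation.  Up-ranks are the complementary G+1-r, which
    also holds under average ties.
    """
    logr = np.log(rank_rows, dtype=np.float64)
    gamma_down = np.exp(logr.mean(axis=0))
    gamma_up = np.exp(np.log(G + 1.0 - rank_rows).mean(axis=0))
    return gamma_up, gamma_down


def _label_permutations(m: int, n: int, n_perm: int, rng: np.random.Generator):
    """Yield case-index tuples for each permutation of the labels.

    When the number of distinct case/control assignments C(m+n, m) does not
    exceed ``n_perm``, all of them are enumerated; otherwise ``n_perm``
    uniform random label shuffles are drawn (repeats allowed, the original
    labeling not excluded).
    """
    total = m + n
    n_distinct = math.comb(total, m)
    if n_distinct <= n_perm:
        yield from itertools.combinations(range(total), m)
    else:
        for _ in range(n_perm):
            perm = rng.permutation(total)
            yield tuple(perm[:m])


def rankprod_significance(
    ds: ExpressionDataset,
    n_perm: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    cap_fdr: bool = False,
) -> RankProdResult:
    """Rank products with label-permutation p-values and rank-based FDRs.

    p-values pool the permutation rank products over all genes, with
    add-one smoothing so p is never 0:

        p_g = (1 + #{(b, g'): gamma_perm <= gamma_g}) / (1 + n_perm * G)

    and FDR_g = p_g * G / rank(gamma_g).  FDRs are reported uncapped by
    default (they may exceed 1); ``cap_fdr=True`` clips at 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    G = ds.n_genes
    m, n = ds.m, ds.n
    X = ds.values
    XT = np.ascontiguousarray(X.T)  # (samples, G)

    fc_rows = pairwise_fold_changes(ds).T  # (H, G)
    H = fc_rows.shape[0]
    gamma_up, gamma_down = _gamma_from_rank_rows(_rank_rows(fc_rows), G)

    case_sets = list(_label_permutations(m, n, n_perm, rng))
    n_used = len(case_sets)
    null_up = np.empty((n_used, G))
    null_down = np.empty((n_used, G))
    # chunk permutations so each ranking call sees a row block of bounded size
    rows_per_chunk = max(1, int(2e7 // (G * H)) if G * H else 1)
    all_idx = np.arange(m + n)
    for start in range(0, n_used, rows_per_chunk):
        chunk = case_sets[start : start + rows_per_chunk]
        blocks = []
        for cs in chunk:
            cs = np.asarray(cs, dtype=np.intp)
            ts = np.setdiff1d(all_idx, cs, assume_unique=True)
            diff = XT[cs][:, None, :] - XT[ts][None, :, :]
            blocks.append(diff.reshape(m * n, G))
        ranks = _rank_rows(np.concatenate(blocks, axis=0))
        for k in range(len(chunk)):
            gu, gd = _gamma_from_rank_rows(ranks[k * H : (k + 1) * H], G)
            null_up[start + k] = gu
            null_down[start + k] = gd

    def _p_and_fdr(gamma: np.ndarray, null: np.ndarray):
        pooled = np.sort(null, axis=None)
        count = np.searchsorted(pooled, gamma, side="right")
        p = (1.0 + count) / (1.0 + pooled.size)
        rank = scipy.stats.rankdata(gamma, method="average")
        fdr = p * G / rank
        if cap_fdr:
            fdr = np.minimum(fdr, 1.0)
        return p, fdr

    pval_up, fdr_up = _p_and_fdr(gamma_up, null_up)
    pval_down, fdr_down = _p_and_fdr(gamma_down, null_down)

    return RankProdResult(
        dataset_id=ds.dataset_id,
        genes=list(ds.genes),
        gmean_rank_up=gamma_up,
        gmean_rank_down=gamma_down,
        pval_up=pval_up,
        pval_down=pval_down,
        fdr_up=fdr_up,
        fdr_down=fdr_down,
        H=H,
        n_perm=n_used,
    )
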