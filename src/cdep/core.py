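"""CDEP aggregation: Bernoulli likelihood of significance patterns over an
FDR-threshold grid, expected minus-log-likelihood, and permutation meta-FDR.

Given per-dataset rank-product FDRs ``F_gi`` (per direction), a gene's
significance pattern at a threshold ``l`` is the indicator vector
``delta_gil = I(F_gi < l)`` over datasets.  If ``r_il`` is the probability
that a *non*-regulated gene is falsely declared significant in dataset ``i``
at threshold ``l``, then under the null hypothesis that gene ``g`` is
nowhere truly regulated its pattern has Bernoulli likelihood

    L(g, l) = prod_i r_il^delta * (1 - r_il)^(1 - delta)

and Q(g, l) = -ln L(g, l) measures how surprising the pattern is under pure
false positives.  The per-dataset rate is r_il = l * d_il / M_i where d_il
counts genes passing the threshold and M_i is the Beta-mixture estimate of
the non-regulated gene count.  Rather than fixing one threshold, Q is
averaged over l with the linearly decreasing density p(l) = -2l + 2
(small thresholds emphasised), giving the evidence score

    EL_g = integral_0^1 Q(g, l) p(l) dl

approximated on a 100-bin midpoint (rectangular) grid.  Significance of EL
is assessed by shuffling each dataset's FDR column over genes and applying a
ratio-of-counts FDR estimate to the observed versus null EL values.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneUniverse, build_universe
from .mixture import MixtureFit, PriorSpec, SamplerConfig, fit_beta_mixture
from .rankprod import RankProdResult, rankprod_significance

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdGrid",
    "FdrPanel",
    "CdepConfig",
    "CdepResult",
    "assemble_fdr_panel",
    "count_significant",
    "false_positive_rate",
    "minus_log_likelihood",
    "expected_likelihood",
    "permutation_fdr",
    "run_cdep",
]

RATE_MIN = 1e-8  # keeps the Bernoulli log likelihood finite


@dataclass(frozen=True)
class ThresholdGrid:
    """Midpoint discretisation of the FDR-threshold density p(l) = -2l + 2."""

    l_values: np.ndarray
    weights: np.ndarray
    bin_width: float

    @classmethod
    def make(cls, bins: int = 100) -> "ThresholdGrid":
        if bins < 1:
            raise ValueError("bins must be >= 1")
        l = (np.arange(bins) + 0.5) / bins
        return cls(l_values=l, weights=-2.0 * l + 2.0, bin_width=1.0 / bins)


@dataclass
class FdrPanel:
    """Gene x dataset FDR matrices on the universe, with imputation flags.

    Genes absent from a dataset's platform receive that dataset's median
    observed FDR (per direction) and are flagged in ``imputed``.
    """

    genes: list[str]
    dataset_ids: list[str]
    fdr_up: np.ndarray  # (G, D)
    fdr_down: np.ndarray
    imputed: np.ndarray  # (G, D) bool

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)

    def matrix(self, direction: str) -> np.ndarray:
        if direction == "up":
            return self.fdr_up
        if direction == "down":
            return self.fdr_down
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


@dataclass(frozen=True)
class CdepConfig:
    n_perm_rankprod: int = 100
    n_meta_perm: int = 100
    bins: int = 100
    fdr_call: float = 0.05
    cap_rankprod_fdr: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int | None = None


@dataclass
class CdepResult:
    genes: list[str]
    EL_up: np.ndarray
    EL_down: np.ndarray
    fdr_g_up: np.ndarray
    fdr_g_down: np.ndarray
    call: np.ndarray  # 'up' | 'down' | 'none'
    B: int
    panel: FdrPanel | None = field(default=None, repr=False)
    mixtures_up: list[MixtureFit] | None = field(default=None, repr=False)
    mixtures_down: list[MixtureFit] | None = field(default=None, repr=False)
    rankprod: list[RankProdResult] | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "EL_up": self.EL_up,
                "EL_down": self.EL_down,
                "FDR_g_up": self.fdr_g_up,
                "FDR_g_down": self.fdr_g_down,
                "call": self.call,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def called_genes(self) -> list[str]:
        return [g for g, c in zip(self.genes, self.call) if c != "none"]


def assemble_fdr_panel(
    results: list[RankProdResult], universe: GeneUniverse
) -> FdrPanel:
    """Place each dataset's FDR columns on the universe, median-imputing
    genes absent from that dataset's platform."""
    if len(results) < 2:
        raise ValueError("meta-analysis requires at least 2 datasets")
    G, D = len(universe), len(results)
    fdr_up = np.empty((G, D))
    fdr_down = np.empty((G, D))
    imputed = np.ones((G, D), dtype=bool)
    for j, res in enumerate(results):
        pos = universe.positions(res.genes)
        fdr_up[:, j] = np.median(res.fdr_up)
        fdr_down[:, j] = np.median(res.fdr_down)
        fdr_up[pos, j] = res.fdr_up
        fdr_down[pos, j] = res.fdr_down
        imputed[pos, j] = False
    return FdrPanel(
        genes=list(universe.genes),
        dataset_ids=[r.dataset_id for r in results],
        fdr_up=fdr_up,
        fdr_down=fdr_down,
        imputed=imputed,
    )


def count_significant(panel: FdrPanel, l: float, dataset: int, direction: str) -> int:
    """d_il: number of genes with F_gi strictly below the threshold l."""
    if not 0.0 < l < 1.0:
        raise ValueError("threshold l must lie in (0, 1)")
    return int(np.count_nonzero(panel.matrix(direction)[:, dataset] < l))


def false_positive_rate(d_il: int, l: float, m_not: int) -> float:
    """r̂_il = l * d_il / M_i, clamped into [RATE_MIN, 1 - RATE_MIN]."""
    if m_not < 1:
        raise ValueError("m_not must be >= 1")
    return float(np.clip(l * d_il / m_not, RATE_MIN, 1.0 - RATE_MIN))


def minus_log_likelihood(delta_row: np.ndarray, rates: np.ndarray) -> float:
    """Q = -sum_i [delta ln r_i + (1 - delta) ln(1 - r_i)] >= 0."""
    delta = np.asarray(delta_row, dtype=float)
    r = np.asarray(rates, dtype=float)
    return float(-(delta * np.log(r) + (1.0 - delta) * np.log1p(-r)).sum())


def _bin_rates(
    panel: FdrPanel, mixtures: list[MixtureFit], grid: ThresholdGrid, direction: str
) -> np.ndarray:
    """False-positive rates r̂_il for every (dataset, bin), shape (D, bins)."""
    F = panel.matrix(direction)
    rates = np.empty((panel.n_datasets, grid.l_values.size))
    for i in range(panel.n_datasets):
        col = np.sort(F[:, i])
        d_il = np.searchsorted(col, grid.l_values, side="left")  # strict F < l
        rates[i] = np.clip(
            grid.l_values * d_il / mixtures[i].m_not_de, RATE_MIN, 1.0 - RATE_MIN
        )
    return rates


def _gene_contributions(
    F: np.ndarray, grid: ThresholdGrid, rates: np.ndarray
) -> np.ndarray:
    """Per-(gene, dataset) share of EL, shape (G, D).

    For dataset i the integrand splits into a constant part (delta = 0 at
    every bin) plus, for the bins with l > F_gi, the delta = 1 correction.
    Both are precomputed per bin, so each gene costs one bin lookup.
    """
    w = grid.weights * grid.bin_width
    C = np.empty(F.shape)
    for i in range(F.shape[1]):
        r = rates[i]
        base = -(w * np.log1p(-r)).sum()
        corr = w * (np.log1p(-r) - np.log(r))  # added where delta = 1
        suffix = np.concatenate([np.cumsum(corr[::-1])[::-1], [0.0]])
        idx = np.searchsorted(grid.l_values, F[:, i], side="right")
        C[:, i] = base + suffix[idx]
    return C


def expected_likelihood(
    panel: FdrPanel,
    mixtures: list[MixtureFit],
    grid: ThresholdGrid,
    direction: str,
) -> np.ndarray:
    """EL_g: expected minus-log-likelihood over the threshold density."""
    _check_mixtures(panel, mixtures, direction)
    F = panel.matrix(direction)
    rates = _bin_rates(panel, mixtures, grid, direction)
    return _gene_contributions(F, grid, rates).sum(axis=1)


def _check_mixtures(panel: FdrPanel, mixtures: list[MixtureFit], direction: str):
    if len(mixtures) != panel.n_datasets:
        raise ValueError("one MixtureFit per dataset required")
    for fit in mixtures:
        if fit.direction != direction:
            raise ValueError(
                f"mixture fit for {fit.dataset_id!r} is direction {fit.direction!r}, "
                f"expected {direction!r}"
            )


def permutation_fdr(
    panel: FdrPanel,
    mixtures: list[MixtureFit],
    grid: ThresholdGrid,
    B: int,
    seed: int | np.random.SeedSequence | None,
    direction: str,
    el_obs: np.ndarray | None = None,
    return_null: bool = False,
):
    """Meta-level FDR_g by within-dataset shuffling of the FDR columns.

    Each permutation independently shuffles every dataset's FDR column over
    genes and recomputes EL; the per-bin rates are unchanged because the
    counts d_il are permutation invariant.  Then

        FDR_g = [(1/B) sum_b #{g': EL_g <= EL_b,g'}] / #{g': EL_g <= EL_g'}

    with inclusive ties (the denominator counts g itself, so it is >= 1).
    Values are reported capped at 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_mixtures(panel, mixtures, direction)
    F = panel.matrix(direction)
    G, D = F.shape
    rates = _bin_rates(panel, mixtures, grid, direction)
    C = _gene_contributions(F, grid, rates)
    if el_obs is None:
        el_obs = C.sum(axis=1)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(D)]
    null_el = np.zeros((B, G))
    for i in range(D):
        rng = streams[i]
        for b in range(B):
            null_el[b] += C[rng.permutation(G), i]

    pooled = np.sort(null_el, axis=None)
    num = (pooled.size - np.searchsorted(pooled, el_obs, side="left")) / B
    obs_sorted = np.sort(el_obs)
    den = G - np.searchsorted(obs_sorted, el_obs, side="left")
    fdr = np.minimum(num / den, 1.0)
    if return_null:
        return fdr, null_el
    return fdr


def run_cdep(
    datasets: list[ExpressionDataset], config: CdepConfig | None = None
) -> CdepResult:
    """Full pipeline: per-dataset rank products -> FDR panel -> Beta-mixture
    non-regulated counts -> expected likelihood -> permutation meta-FDR.

    A gene is called up (down) when its meta-FDR in that direction is at or
    below ``config.fdr_call``; if both directions pass, the smaller FDR
    wins, with the larger EL breaking exact ties.
    """
    config = config or CdepConfig()
    if len(datasets) < 2:
        raise ValueError("meta-analysis requires at least 2 datasets")
    ss = np.random.SeedSequence(config.seed)
    seed_rp, seed_mix, seed_perm_up, seed_perm_down = ss.spawn(4)

    t0 = time.perf_counter()
    universe = build_universe(datasets)
    logger.info("universe: %d genes across %d datasets", len(universe), len(datasets))

    results = []
    for ds, s in zip(datasets, seed_rp.spawn(len(datasets))):
        t = time.perf_counter()
        results.append(
            rankprod_significance(
                ds, n_perm=config.n_perm_rankprod, seed=s, cap_fdr=config.cap_rankprod_fdr
            )
        )
        logger.info("rank product %s: %.2fs", ds.dataset_id, time.perf_counter() - t)

    panel = assemble_fdr_panel(results, universe)

    mixtures_up, mixtures_down = [], []
    mix_seeds = seed_mix.spawn(2 * len(datasets))
    for j, res in enumerate(results):
        t = time.perf_counter()
        mixtures_up.append(
            fit_beta_mixture(
                res.pval_up, config.priors, config.sampler,
                seed=mix_seeds[2 * j], dataset_id=res.dataset_id, direction="up",
            )
        )
        mixtures_down.append(
            fit_beta_mixture(
                res.pval_down, config.priors, config.sampler,
                seed=mix_seeds[2 * j + 1], dataset_id=res.dataset_id, direction="down",
            )
        )
        logger.info("beta mixture %s: %.2fs", res.dataset_id, time.perf_counter() - t)

    grid = ThresholdGrid.make(config.bins)
    el_up = expected_likelihood(panel, mixtures_up, grid, "up")
    el_down = expected_likelihood(panel, mixtures_down, grid, "down")
    fdr_up = permutation_fdr(
        panel, mixtures_up, grid, config.n_meta_perm, seed_perm_up, "up", el_obs=el_up
    )
    fdr_down = permutation_fdr(
        panel, mixtures_down, grid, config.n_meta_perm, seed_perm_down, "down", el_obs=el_down
    )

    call = np.full(len(universe), "none", dtype=object)
    up_ok = fdr_up <= config.fdr_call
    down_ok = fdr_down <= config.fdr_call
    call[up_ok & ~down_ok] = "up"
    call[down_ok & ~up_ok] = "down"
    both = up_ok & down_ok
    if both.any():
        prefer_up = (fdr_up[both] < fdr_down[both]) | (
            (fdr_up[both] == fdr_down[both]) & (el_up[both] >= el_down[both])
        )
        call[both] = np.where(prefer_up, "up", "down")
    logger.info("run_cdep total: %.2fs", time.perf_counter() - t0)

    return CdepResult(
        genes=list(universe.genes),
        EL_up=el_up,
        EL_down=el_down,
        fdr_g_up=fdr_up,
        fdr_g_down=fdr_down,
        call=np.asarray(call),
        B=config.n_meta_perm,
        panel=panel,
        mixtures_up=mixtures_up,
        mixtures_down=mixtures_down,
        rankprod=results,
    )
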