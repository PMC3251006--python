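"""Power / Type-I-error scoring of meta-analysis calls against planted truth.

*Statistical power* is the percentage of planted consistently-DE genes
(category ``G_M``) that a method calls at the chosen meta-level FDR;
*Type I error* is the fraction of all other genes falsely called.  The
simulation grid repeats scenarios (p, q, delta, call FDR) over replicates
and compares CDEP with the two baseline methods on the same simulated
panels.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import meta_profile, meta_rankprod
from .core import CdepConfig, run_cdep
from .simulate import SimulationConfig, TruthTable, simulate_panel

logger = logging.getLogger(__name__)

__all__ = ["EvaluationResult", "Scenario", "score_calls", "comparison_grid", "summarize_grid"]

METHODS = ("cdep", "meta_profile", "meta_rankprod")


@dataclass
class EvaluationResult:
    method: str
    fdr_threshold: float
    power: float  # percent of G_M genes detected
    type1: float  # fraction of non-G_M genes called
    n_true_gm: int
    n_called: int
    n_false: int
    replicate: int = 0

    def as_dict(self) -> dict:
        return dict(
            method=self.method,
            fdr_threshold=self.fdr_threshold,
            power=self.power,
            type1=self.type1,
            n_true_gm=self.n_true_gm,
            n_called=self.n_called,
            n_false=self.n_false,
            replicate=self.replicate,
        )


@dataclass(frozen=True)
class Scenario:
    p: float
    q: float
    delta: float
    fdr: float


def score_calls(
    calls,
    truth: TruthTable,
    threshold: float,
    method: str = "",
    replicate: int = 0,
    strict_direction: bool = False,
) -> EvaluationResult:
    """Score a call set against the planted truth.

    ``calls`` is an iterable of gene names, or a mapping gene -> "up"/"down"
    when ``strict_direction`` is set, in which case a consistent gene only
    counts as detected if the called direction matches its planted sign.
    """
    gm = set(truth.consistent_genes())
    if not gm:
        raise ValueError("no consistently DE genes planted; power is undefined")
    called = set(calls)
    if strict_direction:
        if not hasattr(calls, "items"):
            raise ValueError("strict_direction scoring needs a gene -> direction mapping")
        sign = {g: s for g, s in zip(truth.genes, truth.consistent_direction)}
        tp = sum(
            1
            for g, d in calls.items()
            if g in gm and sign[g] == (1 if d == "up" else -1)
        )
    else:
        tp = len(called & gm)
    n_called = len(called)
    fp = len(called - gm)
    n_non_gm = len(truth.genes) - len(gm)
    return EvaluationResult(
        method=method,
        fdr_threshold=threshold,
        power=100.0 * tp / len(gm),
        type1=fp / n_non_gm if n_non_gm else 0.0,
        n_true_gm=len(gm),
        n_called=n_called,
        n_false=fp,
        replicate=replicate,
    )


def _run_methods_on_panel(
    datasets, truth, scenario: Scenario, methods, cdep_config: CdepConfig, replicate: int
) -> list[EvaluationResult]:
    rows = []
    res = run_cdep(datasets, cdep_config)
    if "cdep" in methods:
        rows.append(
            score_calls(res.called_genes(), truth, scenario.fdr, "cdep", replicate)
        )
    B = cdep_config.n_meta_perm
    ss = np.random.SeedSequence((cdep_config.seed or 0) + 1_000_003)
    s_prof, s_mrp = ss.spawn(2)
    if "meta_profile" in methods:
        up = meta_profile(res.panel, scenario.fdr, B, s_prof.spawn(1)[0], "up")
        down = meta_profile(res.panel, scenario.fdr, B, s_prof.spawn(1)[0], "down")
        called = set(up.called_genes(scenario.fdr)) | set(down.called_genes(scenario.fdr))
        rows.append(score_calls(called, truth, scenario.fdr, "meta_profile", replicate))
    if "meta_rankprod" in methods:
        up, down = meta_rankprod(
            res.rankprod, _universe_of(res), datasets, B, s_mrp, direction="both"
        )
        called = set(up.called_genes(scenario.fdr)) | set(down.called_genes(scenario.fdr))
        rows.append(score_calls(called, truth, scenario.fdr, "meta_rankprod", replicate))
    return rows


def _universe_of(res):
    from .datasets import GeneUniverse

    panel = res.panel
    membership = ~panel.imputed
    return GeneUniverse(
        genes=list(panel.genes), dataset_ids=list(panel.dataset_ids), membership=membership
    )


def comparison_grid(
    scenarios: list[Scenario],
    replicates: int = 10,
    seed: int | None = None,
    methods=METHODS,
    base_config: SimulationConfig | None = None,
    cdep_config: CdepConfig | None = None,
) -> pd.DataFrame:
    """Simulate, run each method and score, per scenario x replicate.

    All methods in a replicate see the same simulated panel.  Returns the
    per-replicate grid; aggregate with :func:`summarize_grid`.
    """
    from dataclasses import replace

    base_config = base_config or SimulationConfig()
    cdep_config = cdep_config or CdepConfig()
    master = np.random.SeedSequence(seed)
    rows = []
    for s_idx, sc in enumerate(scenarios):
        sim_cfg = replace(base_config, p=sc.p, q=sc.q, delta=sc.delta)
        sc_seed = master.spawn(1)[0]
        rep_seeds = sc_seed.spawn(replicates)
        for rep in range(replicates):
            t0 = time.perf_counter()
            datasets, truth = simulate_panel(sim_cfg, seed=rep_seeds[rep])
            run_cfg = replace(
                cdep_config,
                fdr_call=sc.fdr,
                seed=int(rep_seeds[rep].generate_state(1)[0] % 2**31),
            )
            for r in _run_methods_on_panel(datasets, truth, sc, methods, run_cfg, rep):
                rows.append(
                    dict(p=sc.p, q=sc.q, delta=sc.delta, fdr=sc.fdr, **r.as_dict())
                )
            logger.info(
                "scenario %d replicate %d: %.1fs", s_idx, rep, time.perf_counter() - t0
            )
    return pd.DataFrame(rows)


def summarize_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Mean power/Type-I (with sd) across replicates per scenario x method."""
    return (
        grid.groupby(["p", "q", "delta", "fdr", "method"])
        .agg(
            power_mean=("power", "mean"),
            power_sd=("power", "std"),
            type1_mean=("type1", "mean"),
            type1_sd=("type1", "std"),
            replicates=("replicate", "count"),
        )
        .reset_index()
    )
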