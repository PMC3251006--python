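"""Multi-study expression panel simulator with planted differential expression.

Each simulated study follows a mixed-effects model for the log expression of
gene ``g`` in sample ``k`` of study ``i``:

    y_gijk = mu + L_i + G_gi + effect_gi * I(case) + eps_gijk

with a laboratory effect ``L_i ~ N(0, lab_sd^2)`` shared by all genes of a
study, a per-(gene, study) baseline ``G_gi ~ N(0, gene_sd^2)``, and
measurement noise ``eps ~ N(0, noise_sd^2)``.  Differential expression is
planted through two mutually exclusive gene categories:

* *consistent* genes (fraction ``q``) carry a case effect in every study in
  which they are measured, with one panel-wide random sign;
* *study-specific* genes (marginal fraction ``p`` per study) are selected
  independently within each study and carry a case effect, with an
  independent random sign, only in the study (or studies) that selected
  them, so their pattern is not consistent across the panel.

Effect sizes are drawn per case sample as ``N(delta, psi)`` (``psi`` is a
variance) and multiplied by the assigned sign.  Remaining genes are null.
Studies may measure different gene subsets: smaller platforms are nested
prefixes of the largest platform's gene list.

The default panel shape mirrors six published primary-versus-metastatic
cancer studies (cervical, prostate, gastric, colon, oral squamous cell and
renal cell carcinoma) with case/control splits 12/21, 25/65, 15/7, 3/3,
19/8, 10/22 and platform sizes from ~5.5k to ~20k genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_panel",
    "default_cancer_panel_config",
]

# (study id, cases m, controls n, platform gene count)
_CANCER_PANEL_SHAPES = [
    ("cervical", 12, 21, 20271),
    ("prostate", 25, 65, 9000),
    ("gastric", 15, 7, 5526),
    ("colon", 3, 3, 13069),
    ("oscc", 19, 8, 13069),
    ("rcc", 10, 22, 13069),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-level simulation settings.

    ``p`` is the fraction of study-specific DE genes, ``q`` the fraction of
    consistently DE genes (mutually exclusive per gene, so p + q <= 1).
    ``delta`` is the mean |effect| on the log scale and ``psi`` its variance;
    the sign is randomised as described in the module docstring.
    """

    dataset_ids: tuple = ("ds1", "ds2")
    n_genes: tuple = (1000, 1000)
    m: tuple = (5, 5)
    n: tuple = (5, 5)
    p: float = 0.05
    q: float = 0.05
    delta: float = 1.0
    psi: float = 0.25
    mu: float = 8.0
    lab_sd: float = 0.5
    gene_sd: tuple | float = 1.0
    noise_sd: tuple | float = 0.5
    seed: int | None = None

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)

    def _per_dataset(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_datasets,))
        return np.array(arr)

    def validate(self) -> None:
        D = self.n_datasets
        for name in ("n_genes", "m", "n"):
            if len(getattr(self, name)) != D:
                raise ValueError(f"{name} must have one entry per dataset")
        if self.p < 0 or self.q < 0 or self.p + self.q > 1:
            raise ValueError("need p >= 0, q >= 0 and p + q <= 1")
        if self.delta == 0:
            raise ValueError("delta must be nonzero for differentially expressed genes")
        if self.psi <= 0 or self.lab_sd <= 0:
            raise ValueError("variance parameters must be positive")
        if (self._per_dataset(self.gene_sd) <= 0).any() or (
            self._per_dataset(self.noise_sd) <= 0
        ).any():
            raise ValueError("sd parameters must be positive")
        if min(self.m) < 1 or min(self.n) < 1:
            raise ValueError("each study needs at least one case and one control")
        if min(self.n_genes) < 2:
            raise ValueError("each study needs at least 2 genes")


@dataclass
class TruthTable:
    """Planted gene classes for a simulated panel.

    ``category`` per universe gene: ``"G_M"`` (consistent), ``"G_C"``
    (study-specific) or ``"G_N"`` (null).  ``direction`` holds the realised
    sign per (gene, study): +1 up, -1 down, 0 null or not measured.
    """

    genes: list[str]
    dataset_ids: list[str]
    category: np.ndarray  # (G,) of {"G_M","G_C","G_N"}
    direction: np.ndarray  # (G, D) int8 in {-1, 0, +1}
    consistent_direction: np.ndarray  # (G,) int8; 0 unless category == G_M
    present: np.ndarray = field(default=None)  # (G, D) bool

    def consistent_genes(self) -> list[str]:
        return [g for g, c in zip(self.genes, self.category) if c == "G_M"]

    def genes_in_category(self, category: str) -> list[str]:
        return [g for g, c in zip(self.genes, self.category) if c == category]

    def write_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"gene": self.genes, "category": self.category})
        df["consistent_direction"] = self.consistent_direction
        for j, ds in enumerate(self.dataset_ids):
            df[f"direction_{ds}"] = self.direction[:, j]
        df.to_csv(path, sep="\t", index=False)


def default_cancer_panel_config(
    n_genes: int | None = None, **overrides
) -> SimulationConfig:
    """Config mirroring the six-study metastatic-cancer panel shape.

    ``n_genes`` rescales every platform proportionally so the largest study
    has that many genes (platform nesting preserved); ``None`` keeps the
    original platform sizes.  Keyword overrides are forwarded to
    :class:`SimulationConfig`.
    """
    ids, ms, ns, gs = zip(*_CANCER_PANEL_SHAPES)
    if n_genes is not None:
        scale = n_genes / max(gs)
        gs = tuple(max(2, round(g * scale)) for g in gs)
    cfg = SimulationConfig(dataset_ids=ids, n_genes=gs, m=ms, n=ns)
    return replace(cfg, **overrides) if overrides else cfg


def simulate_panel(
    cfg: SimulationConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[list[ExpressionDataset], TruthTable]:
    """Draw one panel of studies plus the planted truth.

    Reproducible: the same config and seed give a bit-identical panel.  The
    ``seed`` argument overrides ``cfg.seed`` when given.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    G = max(cfg.n_genes)
    D = cfg.n_datasets
    width = len(str(G))
    genes = [f"g{i:0{width}d}" for i in range(G)]
    gene_sd = cfg._per_dataset(cfg.gene_sd)
    noise_sd = cfg._per_dataset(cfg.noise_sd)

    # mutually exclusive categories: consistent genes (beta) drawn once
    # panel-wide at rate q; study-specific genes (alpha) drawn per study at
    # rate p/(1-q) among the remainder so the per-study marginal matches p
    beta = rng.random(G) < cfg.q
    consistent_sign = np.where(beta, np.where(rng.random(G) < 0.5, 1, -1), 0).astype(np.int8)
    p_cond = cfg.p / (1.0 - cfg.q) if cfg.q < 1.0 else 0.0

    alpha = np.zeros((G, D), dtype=bool)
    direction = np.zeros((G, D), dtype=np.int8)
    present = np.zeros((G, D), dtype=bool)
    datasets = []
    for j in range(D):
        Gj = cfg.n_genes[j]
        present[:Gj, j] = True
        m, n = cfg.m[j], cfg.n[j]
        L = rng.normal(0.0, cfg.lab_sd)
        gene_effect = rng.normal(0.0, gene_sd[j], size=Gj)
        values = cfg.mu + L + gene_effect[:, None] + rng.normal(
            0.0, noise_sd[j], size=(Gj, m + n)
        )

        a = ~beta[:Gj] & (rng.random(Gj) < p_cond)
        alpha[:Gj, j] = a
        sign_j = np.zeros(Gj, dtype=np.int8)
        sign_j[a] = np.where(rng.random(a.sum()) < 0.5, 1, -1)
        b = beta[:Gj]
        sign_j[b] = consistent_sign[:Gj][b]
        de = a | b
        effect = rng.normal(cfg.delta, np.sqrt(cfg.psi), size=(de.sum(), m))
        values[np.flatnonzero(de)[:, None], np.arange(m)[None, :]] += (
            sign_j[de][:, None] * effect
        )
        direction[:Gj, j] = sign_j

        samples = [f"{cfg.dataset_ids[j]}_c{k}" for k in range(m)] + [
            f"{cfg.dataset_ids[j]}_t{k}" for k in range(n)
        ]
        condition = np.r_[np.ones(m, dtype=int), np.zeros(n, dtype=int)]
        datasets.append(
            ExpressionDataset(
                dataset_id=cfg.dataset_ids[j],
                genes=genes[:Gj],
                samples=samples,
                values=values,
                condition=condition,
            )
        )

    category = np.where(beta, "G_M", np.where(alpha.any(axis=1), "G_C", "G_N"))
    truth = TruthTable(
        genes=genes,
        dataset_ids=list(cfg.dataset_ids),
        category=category,
        direction=direction,
        consistent_direction=consistent_sign,
        present=present,
    )
    return datasets, truth
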