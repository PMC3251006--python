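import numpy as np
import pytest

from cdep import ExpressionDataset, MixtureFit, RankProdResult


def make_dataset(values, condition, dataset_id="ds", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=list(genes),
        samples=list(samples),
        values=values,
        condition=np.asarray(condition, dtype=int),
    )


def make_rp_result(dataset_id, genes, fdr_up, fdr_down=None, gamma_up=None, gamma_down=None, H=1):
    G = len(genes)
    fdr_up = np.asarray(fdr_up, dtype=float)
    fdr_down = np.asarray(fdr_down, dtype=float) if fdr_down is not None else fdr_up.copy()
    gamma_up = np.asarray(gamma_up, dtype=float) if gamma_up is not None else np.arange(1, G + 1, dtype=float)
    gamma_down = (
        np.asarray(gamma_down, dtype=float) if gamma_down is not None else G + 1.0 - gamma_up
    )
    return RankProdResult(
        dataset_id=dataset_id,
        genes=list(genes),
        gmean_rank_up=gamma_up,
        gmean_rank_down=gamma_down,
        pval_up=np.clip(fdr_up, 1e-6, 1.0),
        pval_down=np.clip(fdr_down, 1e-6, 1.0),
        fdr_up=fdr_up,
        fdr_down=fdr_down,
        H=H,
        n_perm=10,
    )


def make_fit(m_not, direction="up", dataset_id="ds", n_genes=None, theta=None):
    n_genes = n_genes if n_genes is not None else m_not
    theta = np.asarray(theta, dtype=float) if theta is not None else np.array([0.05, 0.9, 0.05])
    return MixtureFit(
        dataset_id=dataset_id,
        direction=direction,
        theta=theta,
        beta_params=np.array([[1.0, 20.0], [2.0, 2.0], [20.0, 1.0]]),
        m_not_de=int(m_not),
        n_genes=int(n_genes),
        converged=True,
        rhat=1.0,
        n_draws=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
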