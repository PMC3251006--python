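"""Expression-matrix I/O, probeset collapsing and the cross-study gene universe.

A meta-analysis combines several independent two-condition studies.  Each
study is held as an :class:`ExpressionDataset`: a genes x samples matrix of
log-scale expression values plus a binary condition label per sample
(1 = case, e.g. metastatic; 0 = control, e.g. primary tumour).  Studies run
on different platforms measure different gene sets, so downstream code works
on the ordered union of genes, the :class:`GeneUniverse`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneUniverse",
    "read_expression_matrix",
    "collapse_probesets",
    "build_universe",
]


@dataclass
class ExpressionDataset:
    """One study's log-expression matrix with two-condition sample labels.

    Parameters
    ----------
    dataset_id
        Short identifier for the study.
    genes
        Ordered gene (or probeset) identifiers; unique within the dataset.
    samples
        Ordered sample identifiers matching the matrix columns.
    values
        ``(len(genes), len(samples))`` array of log-scale expression.
    condition
        Per-sample binary label, 1 for case and 0 for control.
    """

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition = np.asarray(self.condition, dtype=int)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = pd.Index(self.genes)
            dup = dup[dup.duplicated()].unique()[:5].tolist()
            raise ValueError(f"{self.dataset_id}: duplicate gene identifiers {dup}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"{self.dataset_id}: duplicate sample identifiers")
        if not np.isin(self.condition, (0, 1)).all():
            raise ValueError(f"{self.dataset_id}: condition labels must be 0/1")
        if self.condition.shape != (len(self.samples),):
            raise ValueError(f"{self.dataset_id}: one condition label per sample required")
        if self.m < 1 or self.n < 1:
            raise ValueError(f"{self.dataset_id}: need at least one case and one control")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.dataset_id}: matrix contains missing/non-finite values")

    @property
    def m(self) -> int:
        """Number of case samples."""
        return int(self.condition.sum())

    @property
    def n(self) -> int:
        """Number of control samples."""
        return int(len(self.condition) - self.condition.sum())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.condition == 1)

    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.condition == 0)


@dataclass
class GeneUniverse:
    """Ordered union of gene identifiers across datasets with presence flags."""

    genes: list[str]
    dataset_ids: list[str]
    membership: np.ndarray  # (n_genes, n_datasets) boolean
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.genes), len(self.dataset_ids)):
            raise ValueError("membership shape mismatch")
        if not self.membership.any(axis=1).all():
            raise ValueError("every universe gene must appear in at least one dataset")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, genes: list[str]) -> np.ndarray:
        """Universe row index for each of ``genes``."""
        return np.array([self._index[g] for g in genes], dtype=np.intp)


def _read_matrix_file(path) -> pd.DataFrame:
    """Read a tab-delimited expression matrix; GCT 1.2 headers are skipped."""
    with open(path) as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.2") else 0
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    if skip:  # GCT carries a Description column after the id
        if df.columns[0].lower() in ("description", "desc"):
            df = df.drop(columns=df.columns[0])
    return df


def read_expression_matrix(
    path,
    label_path,
    dataset_id: str | None = None,
    log2_transform: bool = False,
) -> ExpressionDataset:
    """Load a tab-delimited expression matrix and its sample-label file.

    The matrix has gene/probeset identifiers in the first column and one
    column per sample; the label file is a two-column TSV mapping sample id
    to a 0/1 condition.  Values are assumed to be on a log scale already
    (e.g. RMA output); set ``log2_transform`` for raw-intensity input.
    """
    df = _read_matrix_file(path)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in header")
    labels = pd.read_csv(
        label_path, sep="\t", header=None, names=["sample", "condition"], dtype={"sample": str}
    )
    labels = labels.set_index("sample")["condition"]
    missing = [s for s in df.columns if s not in labels.index]
    if missing:
        raise ValueError(f"{label_path}: no condition label for sample(s) {missing[:5]}")
    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    values = bad.values.astype(float)
    if log2_transform:
        values = np.log2(values + 1.0)
    ds_id = dataset_id if dataset_id is not None else str(path)
    return ExpressionDataset(
        dataset_id=ds_id,
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=values,
        condition=labels.loc[df.columns].astype(int).values,
    )


def read_probeset_mapping(path) -> pd.DataFrame:
    """Two-column TSV ``probeset<TAB>gene`` -> DataFrame."""
    return pd.read_csv(path, sep="\t", header=None, names=["probeset", "gene"], dtype=str)


def collapse_probesets(ds: ExpressionDataset, mapping: pd.DataFrame) -> ExpressionDataset:
    """Collapse probeset rows to gene rows by the per-sample median.

    Probesets mapping to the same gene are summarised, per sample, by the
    median of their expression values.  Probesets absent from the mapping, or
    mapping to more than one gene, are dropped (with a log message).
    """
    mapping = mapping.drop_duplicates()
    multi = mapping.groupby("probeset")["gene"].nunique()
    ambiguous = set(multi[multi > 1].index)
    if ambiguous:
        logger.info("dropping %d probesets mapping to multiple genes", len(ambiguous))
    probe_to_gene = {
        p: g
        for p, g in zip(mapping["probeset"], mapping["gene"])
        if p not in ambiguous
    }
    keep = [i for i, p in enumerate(ds.genes) if p in probe_to_gene]
    if not keep:
        raise ValueError(f"{ds.dataset_id}: no probesets overlap the mapping")
    dropped = ds.n_genes - len(keep)
    if dropped:
        logger.info("%s: dropping %d unmapped probesets", ds.dataset_id, dropped)
    sub = pd.DataFrame(ds.values[keep], index=[probe_to_gene[ds.genes[i]] for i in keep])
    collapsed = sub.groupby(level=0, sort=True).median()
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        genes=[str(g) for g in collapsed.index],
        samples=ds.samples,
        values=collapsed.values,
        condition=ds.condition,
    )


def build_universe(datasets: list[ExpressionDataset]) -> GeneUniverse:
    """Ordered (lexicographic) union of gene sets with presence flags."""
    if len(datasets) < 2:
        raise ValueError("meta-analysis requires at least 2 datasets")
    genes = sorted(set().union(*(ds.genes for ds in datasets)))
    index = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((len(genes), len(datasets)), dtype=bool)
    for j, ds in enumerate(datasets):
        membership[[index[g] for g in ds.genes], j] = True
    return GeneUniverse(
        genes=genes,
        dataset_ids=[ds.dataset_id for ds in datasets],
        membership=membership,
    )
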