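"""Expression-matrix container, delimited-text I/O, z-scoring and synthetic data.

The canonical in-memory orientation is samples x genes: rows are biological
samples, columns are gene probes.  Microarray studies routinely publish the
transpose (genes as rows), so the loader accepts either orientation.

Z-scoring standardizes each gene column to mean 0 and unit spread using the
population standard deviation (divide by n, no Bessel correction).  Flat
probes -- genes with zero variance across samples -- are mapped to all-zero
columns rather than raising, since real microarray matrices commonly contain
them and the downstream feature-selection stage can discard them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError, ParseError

__all__ = [
    "ExpressionDataset",
    "SyntheticSpec",
    "zscore_normalize",
    "load_dataset",
    "save_dataset",
    "generate_synthetic",
]


@dataclass
class ExpressionDataset:
    """A samples x genes real-valued expression matrix with binary labels.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Expression values; any real scale, no missing entries.
    labels : ndarray of int, shape (n_samples,)
        Per-sample class in {0, 1}; each class must have at least one sample.
    gene_ids, sample_ids : sequences of str
        Identifiers matching the matrix dimensions.
    metadata : dict
        Free-form provenance (label mapping, informative-gene indices, ...).
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidInputError("expression matrix must be 2-D and non-empty")
        if not np.isfinite(self.values).all():
            raise InvalidInputError("expression matrix contains NaN/inf values")
        n, g = self.values.shape
        if len(self.labels) != n:
            raise InvalidInputError(f"{len(self.labels)} labels for {n} samples")
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise InvalidInputError("identifier lengths do not match matrix shape")
        present = set(np.unique(self.labels).tolist())
        if not present <= {0, 1}:
            raise InvalidInputError(f"labels must lie in {{0,1}}, got {sorted(present)}")
        if present != {0, 1}:
            raise InvalidInputError("each class needs at least one sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def select_genes(self, mask: np.ndarray) -> "ExpressionDataset":
        """Return a copy restricted to the gene columns where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_genes,):
            raise InvalidInputError("gene mask length must equal n_genes")
        return ExpressionDataset(
            values=self.values[:, mask].copy(),
            labels=self.labels.copy(),
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
            sample_ids=list(self.sample_ids),
            metadata=dict(self.metadata),
        )

    def select_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        """Return a copy restricted to the given sample indices (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a seeded synthetic microarray-shaped dataset.

    ``shift`` is the mean difference of the informative genes between the two
    classes, in units of the background standard deviation.
    """

    n_samples: int = 60
    n_genes: int = 200
    n_informative: int = 10
    shift: float = 2.0
    class1_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise InvalidConfigError("n_informative cannot exceed n_genes")
        if not 0.0 < self.class1_fraction < 1.0:
            raise InvalidConfigError("class1_fraction must lie strictly in (0,1)")
        if self.n_samples < 2 or self.n_genes < 1:
            raise InvalidConfigError("need at least 2 samples and 1 gene")


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene to zero mean and unit population SD.

    Genes with zero variance map to all-zero columns.  Idempotent up to
    floating error: z-scoring an already z-scored matrix changes nothing.
    """
    if ds.n_samples < 2:
        raise InvalidInputError("z-scoring needs at least 2 samples per gene")
    mu = ds.values.mean(axis=0)
    sigma = ds.values.std(axis=0)  # population SD: ddof=0
    safe = np.where(sigma > 0.0, sigma, 1.0)
    z = (ds.values - mu) / safe
    z[:, sigma == 0.0] = 0.0
    return dataclasses.replace(ds, values=z, metadata={**ds.metadata, "normalized": True})


def _coerce_labels(raw: pd.Series) -> tuple[np.ndarray, dict]:
    uniques = sorted(pd.unique(raw), key=str)
    if len(uniques) > 2:
        raise InvalidInputError(
            f"only binary labels are supported; found {len(uniques)} values: {uniques}"
        )
    if len(uniques) < 2:
        raise InvalidInputError("label column contains a single class")
    # Map numerically when the values already look like 0/1, else sort order.
    if set(map(str, uniques)) <= {"0", "1", "0.0", "1.0"}:
        mapping = {u: int(float(u)) for u in uniques}
    else:
        mapping = {u: i for i, u in enumerate(uniques)}
    return raw.map(mapping).to_numpy(dtype=int), {str(k): v for k, v in mapping.items()}


def load_dataset(
    path,
    orientation: str = "samples-rows",
    label_column: str = "label",
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load an expression matrix from delimited text (gzip transparent).

    ``orientation`` is ``"samples-rows"`` (one row per sample, a label column)
    or ``"genes-rows"`` (one row per gene, first column gene ids, plus one row
    named ``label_column`` holding per-sample labels).
    """
    if orientation not in ("samples-rows", "genes-rows"):
        raise InvalidConfigError(f"unknown orientation {orientation!r}")
    sep = delimiter if delimiter is not None else (
        "\t" if str(path).rstrip(".gz").endswith((".tsv", ".tab")) else ","
    )
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if orientation == "genes-rows":
        frame = frame.T
    if label_column not in frame.columns:
        raise ParseError(f"label column {label_column!r} not found in {path}")
    labels_raw = frame[label_column]
    expr = frame.drop(columns=[label_column])
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    missing = numeric.isna().to_numpy()
    if missing.any():
        r, c = map(int, np.argwhere(missing)[0])
        raise ParseError(
            f"non-numeric or missing expression value at sample "
            f"{numeric.index[r]!r}, gene {numeric.columns[c]!r}"
        )
    labels, mapping = _coerce_labels(labels_raw)
    return ExpressionDataset(
        values=numeric.to_numpy(dtype=float),
        labels=labels,
        gene_ids=[str(c) for c in numeric.columns],
        sample_ids=[str(i) for i in numeric.index],
        metadata={"label_mapping": mapping, "source": str(path)},
    )


def save_dataset(ds: ExpressionDataset, path, label_column: str = "label") -> None:
    """Write a dataset as samples-rows delimited text (extension picks the sep)."""
    sep = "\t" if str(path).rstrip(".gz").endswith((".tsv", ".tab")) else ","
    frame = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    frame[label_column] = ds.labels
    frame.to_csv(path, sep=sep)


def generate_synthetic(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw a seeded microarray-shaped dataset from the spec.

    Background genes are standard normal in both classes; the first
    ``n_informative`` genes get a ``shift``-SD mean increase in class 1.
    Class labels are assigned by ``class1_fraction`` and shuffled so class
    membership is not confounded with sample order.  The informative gene
    indices are recorded in ``metadata["informative_genes"]`` so recovery
    experiments can score a selector against the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.class1_fraction * spec.n_samples))
    n1 = min(max(n1, 1), spec.n_samples - 1)
    labels = np.array([0] * (spec.n_samples - n1) + [1] * n1)
    labels = labels[rng.permutation(spec.n_samples)]
    values = rng.standard_normal((spec.n_samples, spec.n_genes))
    values[labels == 1, : spec.n_informative] += spec.shift
    digits = max(len(str(spec.n_genes)), 3)
    return ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=[f"g{j:0{digits}d}" for j in range(spec.n_genes)],
        sample_ids=[f"s{i:03d}" for i in range(spec.n_samples)],
        metadata={
            "informative_genes": list(range(spec.n_informative)),
            "spec": dataclasses.asdict(spec),
        },
    )
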