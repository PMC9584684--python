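"""Synthetic gene-expression datasets with planted class structure.

High-dimensional expression benchmarks (tens-to-hundreds of samples,
thousands of genes, 2-26 classes) are emulated by a Gaussian class-shift
model: background genes are pure noise, and each planted informative gene
carries a mean offset of ``effect_size`` in exactly one class (classes
assigned round-robin), so between-class mean differences on informative
genes equal the effect size by construction.  The ground-truth informative
mask travels with the dataset, which makes wrapper-selection recall
measurable — something no real microarray dataset offers.

Values are on a log-intensity-like scale (noise sd ~1).  Optional
block-correlated noise makes harder instances; real-data features such as
heavy-tailed intensities, batch effects and gene-gene pathway correlation
are deliberately not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "generate_expression_dataset", "write_dataset", "read_dataset"]

LABEL_COLUMN = "label"


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with class labels.

    ``informative_mask`` is the ground-truth planted-gene indicator
    (synthetic data only).
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: List[str]
    informative_mask: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x features)")
        n, p = self.matrix.shape
        if n == 0 or p == 0:
            raise ValueError("dataset must have at least one sample and one feature")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains missing or non-finite values")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per sample")
        if len(self.feature_names) != p:
            raise ValueError("feature_names must have one entry per feature")
        _, counts = np.unique(self.labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 samples")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape != (p,):
                raise ValueError("informative_mask length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).shape[0])


def generate_expression_dataset(
    n_samples: int = 62,
    n_features: int = 2000,
    n_classes: int = 2,
    n_informative: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    block_corr: float = 0.0,
    block_size: int = 20,
) -> ExpressionDataset:
    """Draw a seeded dataset from the Gaussian class-shift model.

    Background entries are ``N(0, noise_sd^2)``.  ``n_informative`` genes
    (positions drawn without replacement) are each assigned one class
    round-robin; samples of that class receive a ``+effect_size`` mean shift
    on that gene.  Labels are balanced up to remainder.  With
    ``block_corr`` > 0 background genes share block-level latent factors
    (equicorrelation ``block_corr`` within blocks of ``block_size``).
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if n_classes < 2 or n_classes > n_samples // 2:
        raise ValueError("need 2 <= n_classes <= n_samples/2")
    if not 0.0 <= block_corr < 1.0:
        raise ValueError("block_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    labels = np.arange(n_samples) % n_classes
    X = rng.normal(0.0, noise_sd, size=(n_samples, n_features))
    if block_corr > 0.0:
        n_blocks = int(np.ceil(n_features / block_size))
        factors = rng.normal(0.0, noise_sd, size=(n_samples, n_blocks))
        block_of = np.arange(n_features) // block_size
        X = np.sqrt(1.0 - block_corr) * X + np.sqrt(block_corr) * factors[:, block_of]

    informative = rng.choice(n_features, size=n_informative, replace=False)
    mask = np.zeros(n_features, dtype=bool)
    mask[informative] = True
    for j, gene in enumerate(np.sort(informative)):
        X[labels == (j % n_classes), gene] += effect_size

    names = [f"gene_{i:05d}" for i in range(n_features)]
    return ExpressionDataset(
        matrix=X, labels=labels, feature_names=names,
        informative_mask=mask, seed=seed,
    )


def _mask_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".informative.txt")


def write_dataset(data: ExpressionDataset, path: Union[str, Path]) -> None:
    """Write samples x genes CSV (label last column); the informative mask,
    when present, goes to a ``<path>.informative.txt`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(data.matrix, columns=data.feature_names)
    df[LABEL_COLUMN] = data.labels
    df.to_csv(path, index=False)
    if data.informative_mask is not None:
        genes = [n for n, m in zip(data.feature_names, data.informative_mask) if m]
        _mask_path(path).write_text("\n".join(genes) + "\n")


def read_dataset(path: Union[str, Path]) -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset` (or any CSV with a
    header row of gene identifiers and a trailing ``label`` column)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, not a dataset") from exc
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required '{LABEL_COLUMN}' column")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no sample rows")
    labels = df[LABEL_COLUMN].to_numpy()
    feats = df.drop(columns=[LABEL_COLUMN])
    non_numeric = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric expression columns {non_numeric[:5]}")
    mask = None
    mp = _mask_path(path)
    if mp.exists():
        genes = {g for g in mp.read_text().split() if g}
        unknown = genes - set(feats.columns)
        if unknown:
            warnings.warn(f"{mp}: {len(unknown)} mask genes absent from the matrix")
        mask = np.array([c in genes for c in feats.columns], dtype=bool)
    return ExpressionDataset(
        matrix=feats.to_numpy(dtype=float), labels=labels,
        feature_names=list(feats.columns), informative_mask=mask,
    )
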