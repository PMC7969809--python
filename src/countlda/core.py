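"""Shared data model for count-based discriminant analysis.

The package classifies samples of non-negative integer expression counts
(bulk or single-cell RNA-seq) with four generative models that share the
mean decomposition

    mu_{k i g} = d_{kg} * s_i * lambda_g,

where ``s_i`` is a per-sample size factor (sequencing-depth scale),
``lambda_g`` a per-gene abundance, and ``d_{kg}`` a multiplicative class
effect equal to 1 for genes that are not differentially expressed.  The
four classifiers differ only in the per-gene count distribution:

* PLDA    -- Poisson(mu)
* NBLDA   -- negative binomial, variance mu + phi * mu^2
* ZIPLDA  -- point mass at zero (probability p) mixed with Poisson
* ZINBLDA -- point mass at zero mixed with negative binomial

This module houses the containers those classifiers exchange and the
numerical constants shared across the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .estimation import LogisticZeroModel

logger = logging.getLogger("countlda")

#: Methods in increasing model complexity; also the tie-break order used
#: whenever two classifiers score identically.
METHODS = ("PLDA", "NBLDA", "ZIPLDA", "ZINBLDA")

#: Gamma(beta, beta) prior on the class effect d_kg; keeps d_kg finite and
#: positive even when a class has zero total count for a gene.
GAMMA_PRIOR_BETA = 1.0

#: Search bounds for the per-gene dispersion MLE.  An optimum at the lower
#: bound is reported as exactly 0 (the Poisson limit).
PHI_LOWER = 1e-8
PHI_UPPER = 1e3

#: Mixture weights (1 - p) are floored at this value before taking logs.
PROB_FLOOR = 1e-12


class DataError(ValueError):
    """Raised for structurally invalid count matrices or labels."""


def _as_count_array(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise DataError(f"count matrix must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise DataError("count matrix is empty")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.all(np.isfinite(arr)) or np.any(np.abs(arr - rounded) > 1e-9):
            raise DataError("non-integer count encountered")
        arr = rounded.astype(np.int64)
    if np.any(arr < 0):
        raise DataError("negative count encountered")
    return np.ascontiguousarray(arr, dtype=np.int64)


@dataclass
class CountMatrix:
    """Genes x samples table of read counts.

    Parameters
    ----------
    counts
        Integer array of shape ``(G, n)``; genes in rows.  Float input is
        accepted when every entry is integral.
    gene_ids, sample_ids
        Optional identifiers; generated as ``g1..gG`` / ``s1..sn`` when
        omitted.  Duplicates are rejected.
    """

    counts: np.ndarray
    gene_ids: list = None
    sample_ids: list = None

    def __post_init__(self):
        self.counts = _as_count_array(self.counts)
        G, n = self.counts.shape
        if self.gene_ids is None:
            self.gene_ids = [f"g{i + 1}" for i in range(G)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != G:
            raise DataError(f"{len(self.gene_ids)} gene ids for {G} genes")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if len(set(self.gene_ids)) != G:
            raise DataError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample identifiers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def all_zero_genes(self) -> np.ndarray:
        """Boolean mask of genes with zero total count across all samples."""
        return self.counts.sum(axis=1) == 0

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[idx],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
        )

    def subset_samples(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
        )


@dataclass
class ClassLabels:
    """1-based class assignment for the training samples."""

    labels: np.ndarray
    K: int = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise DataError("labels must be a non-empty 1-D vector")
        if self.K is None:
            self.K = int(self.labels.max())
        if np.any(self.labels < 1) or np.any(self.labels > self.K):
            raise DataError(f"labels must lie in 1..{self.K}")
        sizes = np.bincount(self.labels, minlength=self.K + 1)[1:]
        for k, nk in enumerate(sizes, start=1):
            if nk == 0:
                raise DataError(f"empty class {k}")
        self.class_sizes = sizes

    @property
    def n(self) -> int:
        return self.labels.size

    @classmethod
    def from_raw(cls, raw: Sequence) -> "ClassLabels":
        """Map arbitrary label values to 1..K in first-appearance order."""
        mapping: dict = {}
        out = []
        for value in raw:
            if value not in mapping:
                mapping[value] = len(mapping) + 1
            out.append(mapping[value])
        lab = cls(np.asarray(out), K=len(mapping))
        lab.mapping = mapping
        return lab


@dataclass
class FittedModel:
    """Parameter bundle produced by :func:`countlda.classifiers.fit`.

    ``phi`` is present only for the NB-family methods, ``logistic`` only
    for the zero-inflated ones.  ``train_grand_total`` is kept so test
    size factors can be formed as test-column-total / training grand
    total; ``ref_depth`` is the library size of the first training sample
    of class 1, the reference depth of the zero-probability logistic
    model.
    """

    method: str
    d: np.ndarray                      # (K, G), all entries > 0
    size_factors: np.ndarray           # (n,), sums to 1
    lam: np.ndarray                    # (G,), >= 0
    priors: np.ndarray                 # (K,), sums to 1
    train_grand_total: float
    ref_depth: float
    phi: Optional[np.ndarray] = None   # (G,), >= 0
    logistic: Optional["LogisticZeroModel"] = None
    gene_ids: Optional[list] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.d = np.asarray(self.d, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if np.any(self.d <= 0):
            raise ValueError("class effects d_kg must be positive")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)
            if np.any(self.phi < 0):
                raise ValueError("dispersions must be non-negative")

    @property
    def K(self) -> int:
        return self.d.shape[0]

    @property
    def G(self) -> int:
        return self.d.shape[1]


def validate_matrix(counts: CountMatrix, labels: ClassLabels):
    """Check that a count matrix and label vector describe one dataset.

    All-zero genes are retained (the Gamma prior keeps their class
    effects finite downstream) but logged, so callers can drop them
    deliberately if they wish.
    """
    if not isinstance(counts, CountMatrix):
        counts = CountMatrix(counts)
    if not isinstance(labels, ClassLabels):
        labels = ClassLabels(labels)
    if labels.n != counts.n_samples:
        raise DataError(
            f"{labels.n} labels for {counts.n_samples} samples"
        )
    n_zero = int(counts.all_zero_genes().sum())
    if n_zero:
        logger.warning("%d gene(s) have zero counts in every sample", n_zero)
    return counts, labels
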