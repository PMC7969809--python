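"""Univariate gene screening by the between/within sum-of-squares ratio.

For gene g with class means xbar_kg and overall mean xbar_g,

    ratio_g = sum_k n_k (xbar_kg - xbar_g)^2
              / sum_k sum_{i in k} (x_ig - xbar_kg)^2 ,

genes are ranked from greatest to least ratio and the top p are kept for
classification.  Screening runs on training data only; the test set
inherits the selected index list.  Raw counts are used by default (the
classical expression screen); pass ``normalize=True`` to rank
depth-normalized values instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ClassLabels, CountMatrix


@dataclass
class GeneRanking:
    ratios: np.ndarray        # (G,), non-negative, +inf for perfect separators
    order: np.ndarray         # permutation of 0..G-1, non-increasing ratio

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.order = np.asarray(self.order, dtype=np.int64)


def bss_wss_rank(counts, labels, normalize: bool = False) -> GeneRanking:
    """Rank genes by BSS/WSS; ties and 0/0 resolve deterministically.

    Zero within-group scatter with non-zero between-group scatter yields
    a +inf sentinel (a perfect separator, ranked first); a gene constant
    everywhere scores 0.  Equal ratios keep original gene order.
    """
    X = (counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)).astype(float)
    if not isinstance(labels, ClassLabels):
        labels = ClassLabels(labels)
    if normalize:
        col = X.sum(axis=0)
        X = X / (col / col.mean())[None, :]
    overall = X.mean(axis=1)
    bss = np.zeros(X.shape[0])
    wss = np.zeros(X.shape[0])
    for k in range(1, labels.K + 1):
        mask = labels.labels == k
        nk = int(mask.sum())
        cm = X[:, mask].mean(axis=1)
        bss += nk * np.square(cm - overall)
        wss += np.square(X[:, mask] - cm[:, None]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = bss / wss
    ratios = np.where(wss > 0, ratios, np.where(bss > 0, np.inf, 0.0))
    order = np.argsort(-ratios, kind="stable")
    return GeneRanking(ratios=ratios, order=order)


def select_top(ranking: GeneRanking, p: int) -> np.ndarray:
    """Indices of the p best-ranked genes (0-based, in ranking order)."""
    G = ranking.order.size
    if not 1 <= p <= G:
        raise ValueError(f"p must lie in 1..{G}, got {p}")
    return ranking.order[:p].copy()
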