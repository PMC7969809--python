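"""Meta-model recommending a classifier from dataset attributes.

A grid over sample size n, dispersion phi and excess-zero probability p0
is benchmarked by simulation: each cell records the mean test
misclassification rate of the four classifiers and is labeled with the
winner (ties resolve toward the simpler model, PLDA < NBLDA < ZIPLDA <
ZINBLDA).  A decision tree (and, for a more stable ruleset, a random
forest) is then trained on the features (n, phi, p0) with the winner as
the target, and queried for new datasets via their estimated attributes:

* n       -- the sample count,
* phi-hat -- the median of the per-gene zero-inflated NB dispersion MLEs,
* p0-hat  -- the observed zero fraction minus the model-implied
             structural NB zero mass, floored at 0.

Reference grid (coarsen for desk-scale runs): n from 8 to 100 by 8, phi
from 0.001 to 1.001 by 0.1, p0 from 0 to 0.6 by 0.05; simulated data per
cell use K = 2, 100 genes, 40% DE genes, sigma = 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import METHODS, ClassLabels, CountMatrix, validate_matrix
from . import estimation as est
from .simulator import SimConfig, mean_errors

logger = logging.getLogger("countlda")

FEATURES = ["n", "phi", "p0"]

#: Reference grid of the selector benchmark.
FULL_GRID = dict(
    n=list(range(8, 101, 8)),
    phi=[round(0.001 + 0.1 * i, 3) for i in range(11)],
    p0=[round(0.05 * i, 2) for i in range(13)],
)

#: Coarsened grid keeping the full ranges at desk-scale runtime.
COARSE_GRID = dict(
    n=[8, 32, 56, 80, 100],
    phi=[0.001, 0.201, 0.401, 0.601, 0.801, 1.001],
    p0=[0.0, 0.15, 0.3, 0.45, 0.6],
)


def pick_winner(errors: dict) -> str:
    """Method with the smallest mean error; ties go to the simpler model."""
    values = np.array([errors[m] for m in METHODS])
    return METHODS[int(np.argmin(values))]


def build_meta_table(grid: dict = None, reps: int = 100, seed: int = 0,
                     G: int = 100, de_rate: float = 0.4,
                     sigma: float = 0.2, K: int = 2) -> pd.DataFrame:
    """Benchmark every grid cell; one row per (n, phi, p0) combination.

    Columns: the three features, ``err_<method>`` per classifier, and the
    ``winner`` label.  Deterministic given ``seed``.
    """
    grid = dict(COARSE_GRID if grid is None else grid)
    for key in FEATURES:
        if not grid.get(key):
            raise ValueError(f"empty grid for {key}")
    rng = np.random.default_rng(seed)
    rows = []
    cells = [(n, phi, p0) for n in grid["n"] for phi in grid["phi"]
             for p0 in grid["p0"]]
    for n, phi, p0 in cells:
        cfg = SimConfig(K=K, n=int(n), G=G, de_rate=de_rate, sigma=sigma,
                        phi=float(phi), p0=float(p0))
        errs = mean_errors(cfg, reps, int(rng.integers(2 ** 31)))
        row = dict(n=n, phi=phi, p0=p0)
        row.update({f"err_{m.lower()}": errs[m] for m in METHODS})
        row["winner"] = pick_winner(errs)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SelectorModel:
    model_kind: str                   # "tree" | "forest"
    estimator: object
    meta_table: pd.DataFrame
    resubstitution_error: float

    def recommend_from_attributes(self, n: float, phi: float, p0: float) -> str:
        frame = pd.DataFrame([[n, phi, p0]], columns=FEATURES)
        return str(self.estimator.predict(frame)[0])


def fit_selector(meta_table: pd.DataFrame, model_kind: str = "tree",
                 max_depth: int = 6, min_samples_leaf: int = 5,
                 n_estimators: int = 500, seed: int = 0) -> SelectorModel:
    """Train the recommendation model on a benchmarked grid.

    The tree stays shallow (depth 6, >= 5 cells per leaf, Gini) so its
    rules read like the published flowchart; the forest trades
    readability for a lower resubstitution error.
    """
    if meta_table.empty:
        raise ValueError("empty meta-table")
    X = meta_table[FEATURES]
    y = meta_table["winner"].to_numpy()
    if len(np.unique(y)) < 2:
        logger.warning("meta-table has a single winner label (%s)", y[0])
    if model_kind == "tree":
        estimator = DecisionTreeClassifier(criterion="gini",
                                           max_depth=max_depth,
                                           min_samples_leaf=min_samples_leaf,
                                           random_state=seed)
    elif model_kind == "forest":
        estimator = RandomForestClassifier(n_estimators=n_estimators,
                                           max_depth=None,
                                           random_state=seed)
    else:
        raise ValueError("model_kind must be 'tree' or 'forest'")
    estimator.fit(X, y)
    resub = float(np.mean(estimator.predict(X) != y))
    return SelectorModel(model_kind=model_kind, estimator=estimator,
                         meta_table=meta_table.copy(),
                         resubstitution_error=resub)


# ---------------------------------------------------------------------------
# dataset attribute estimation
# ---------------------------------------------------------------------------

def estimate_attributes(counts, labels, phi_tol: float = 1e-4) -> dict:
    """Estimate (n, phi, p0) for a real dataset.

    phi-hat is the median per-gene ZINB dispersion MLE; p0-hat subtracts
    the mean structural NB zero mass at the fitted means from the
    observed zero fraction (floored at 0).
    """
    counts, labels = validate_matrix(counts, labels)
    s = est.estimate_size_factors(counts)
    lam = est.estimate_lambda(counts, s)
    d = est.estimate_class_difference(counts, labels, s, lam)
    phi = est.estimate_dispersion_zinb(counts, labels, s, lam, d, tol=phi_tol)
    phi_hat = float(np.median(phi))
    mu = est.fitted_means(labels, s, lam, d)
    structural = float(np.mean(est.nb_zero_mass(mu, phi_hat)))
    zero_frac = float(np.mean(counts.counts == 0))
    p0_hat = max(0.0, zero_frac - structural)
    return dict(n=counts.n_samples, phi=phi_hat, p0=p0_hat,
                zero_fraction=zero_frac, structural_zero_mass=structural)


def recommend(selector: SelectorModel, counts, labels):
    """Recommend a classifier for a dataset from its estimated attributes."""
    attrs = estimate_attributes(counts, labels)
    method = selector.recommend_from_attributes(attrs["n"], attrs["phi"],
                                                attrs["p0"])
    logger.info("estimated attributes n=%d phi=%.3f p0=%.3f -> %s",
                attrs["n"], attrs["phi"], attrs["p0"], method)
    return method, attrs
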