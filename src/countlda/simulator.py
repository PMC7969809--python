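"""Synthetic RNA-seq count generator and benchmark studies.

The generative model draws, per dataset,

* size factors       s_i        ~ Uniform[0.2, 2.2]
* gene abundances    lambda_g   ~ Exponential(mean 25)
* class effects      log d_kg   ~ Normal(0, sigma^2) independently per
                                  class for DE genes; d_kg = 1 otherwise
* counts             X_ig       ~ NB(d_{k(i)g} s_i lambda_g, phi)
                                  (exact Poisson when phi = 0)
* excess zeros: each entry independently replaced by 0 with prob. p0.

The NB parameterization has variance mu + phi mu^2.  Defaults mirror the
benchmark design: K = 2 with near-equal class sizes, G = 100 genes, 20%
DE genes, sigma = 0.2.

``run_study`` reproduces the six benchmark studies (dispersion sweep,
excess-zero sweep, sample-size sweep, gene-count sweep, DE-rate sweep at
n = 8, and the three-parameter grid), at a configurable number of
repetitions; each repetition draws fresh truth, simulates equally sized
training and test sets from it, fits all four classifiers on the
training half and records test misclassification rates.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import METHODS, ClassLabels, CountMatrix
from . import classifiers

logger = logging.getLogger("countlda")


@dataclass
class SimConfig:
    K: int = 2
    n: int = 50
    G: int = 100
    de_rate: float = 0.2
    sigma: float = 0.2
    phi: float = 0.0
    p0: float = 0.0
    lambda_mean: float = 25.0
    s_range: tuple = (0.2, 2.2)
    seed: int = 0

    def __post_init__(self):
        if self.K < 2 or self.n < self.K or self.G < 1:
            raise ValueError("need K >= 2, n >= K, G >= 1")
        if not 0.0 <= self.de_rate <= 1.0:
            raise ValueError("de_rate must lie in [0, 1]")
        if self.phi < 0 or not 0.0 <= self.p0 < 1.0 or self.sigma < 0:
            raise ValueError("invalid phi, p0 or sigma")

    @property
    def class_sizes(self) -> np.ndarray:
        base = np.full(self.K, self.n // self.K)
        base[: self.n % self.K] += 1
        return base

    @property
    def n_de(self) -> int:
        return int(round(self.de_rate * self.G))


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    labels: ClassLabels
    truth: dict = field(default_factory=dict)


def _draw_truth(config: SimConfig, rng: np.random.Generator):
    lam = rng.exponential(config.lambda_mean, size=config.G)
    d = np.ones((config.K, config.G))
    de_genes = rng.choice(config.G, size=config.n_de, replace=False)
    if config.n_de:
        d[:, de_genes] = np.exp(rng.normal(0.0, config.sigma,
                                           size=(config.K, config.n_de)))
    return lam, d, np.sort(de_genes)


def _draw_counts(config: SimConfig, lam, d, rng: np.random.Generator):
    sizes = config.class_sizes
    labels = np.repeat(np.arange(1, config.K + 1), sizes)
    s = rng.uniform(*config.s_range, size=config.n)
    mu = d[labels - 1] * s[:, None] * lam[None, :]        # (n, G)
    if config.phi == 0:
        X = rng.poisson(mu)
    else:
        r = 1.0 / config.phi
        X = rng.negative_binomial(r, 1.0 / (1.0 + mu * config.phi))
    if config.p0 > 0:
        X = np.where(rng.random(X.shape) < config.p0, 0, X)
    return X.T.astype(np.int64), labels, s                # (G, n)


def simulate(config: SimConfig) -> SimulatedDataset:
    """Draw one dataset; bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    lam, d, de_genes = _draw_truth(config, rng)
    X, labels, s = _draw_counts(config, lam, d, rng)
    return SimulatedDataset(
        counts=CountMatrix(X),
        labels=ClassLabels(labels, K=config.K),
        truth={"s": s, "lam": lam, "d": d, "de_genes": de_genes,
               "phi": config.phi, "p0": config.p0},
    )


def simulate_train_test(config: SimConfig):
    """Training and test sets of equal size sharing one truth draw."""
    rng = np.random.default_rng(config.seed)
    lam, d, de_genes = _draw_truth(config, rng)
    out = []
    for _ in range(2):
        X, labels, s = _draw_counts(config, lam, d, rng)
        out.append(SimulatedDataset(
            counts=CountMatrix(X), labels=ClassLabels(labels, K=config.K),
            truth={"s": s, "lam": lam, "d": d, "de_genes": de_genes,
                   "phi": config.phi, "p0": config.p0}))
    return out[0], out[1]


def _one_rep_errors(config: SimConfig, methods=METHODS,
                    phi_tol: float = 1e-3) -> dict:
    """Test misclassification of each classifier on one fresh draw."""
    train, test = simulate_train_test(config)
    models = classifiers.fit_all(train.counts, train.labels,
                                 methods=methods, phi_tol=phi_tol)
    true = test.labels.labels
    errs = {}
    for method, model in models.items():
        pred, _ = classifiers.predict(test.counts, model)
        errs[method] = float(np.mean(pred != true))
    return errs


@contextmanager
def _quiet_logs():
    """Silence per-dataset data-quality warnings inside benchmark loops."""
    prev = logger.level
    logger.setLevel(max(prev, logging.ERROR))
    try:
        yield
    finally:
        logger.setLevel(prev)


def mean_errors(config: SimConfig, reps: int, seed: int,
                methods=METHODS, phi_tol: float = 1e-3) -> dict:
    """Mean test error per method over ``reps`` fresh train/test draws."""
    rng = np.random.default_rng(seed)
    acc = {m: 0.0 for m in methods}
    with _quiet_logs():
        for _ in range(reps):
            cfg = replace(config, seed=int(rng.integers(2 ** 31)))
            errs = _one_rep_errors(cfg, methods=methods, phi_tol=phi_tol)
            for m in methods:
                acc[m] += errs[m]
    return {m: acc[m] / reps for m in methods}


# ---------------------------------------------------------------------------
# benchmark studies
# ---------------------------------------------------------------------------

#: Default parameter grids; each study varies one knob (study 6: three).
STUDY_GRIDS = {
    1: ("phi", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
        dict(n=50, G=100, p0=0.0, de_rate=0.2)),
    2: ("p0", [0.1, 0.15, 0.2, 0.25, 0.3],
        dict(n=50, G=100, phi=0.0, de_rate=0.2)),
    3: ("n", [8, 20, 50, 100, 200, 300],
        dict(G=100, phi=0.0, p0=0.3, de_rate=0.2)),
    4: ("G", [50, 100, 200, 300],
        dict(n=50, phi=0.0, p0=0.1, de_rate=0.2)),
    5: ("de_rate", [0.1, 0.2, 0.3, 0.4, 0.5],
        dict(n=8, G=100, phi=0.5, p0=0.0)),
}


def run_study(study_id: int, reps: int = 100, seed: int = 0,
              grid=None, **config_overrides) -> pd.DataFrame:
    """Replicate one benchmark study at a configurable repetition count.

    Returns a tidy frame with the varied parameter(s), method and mean
    misclassification rate.  Study 6 sweeps (n, phi, p0) jointly with 40%
    DE genes; studies 1-5 vary a single parameter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if study_id == 6:
        base = dict(G=100, de_rate=0.4, sigma=0.2)
        base.update(config_overrides)
        n_grid = grid["n"] if grid else [8, 50, 100]
        phi_grid = grid["phi"] if grid else [0.001, 0.201, 0.401, 0.601, 0.801, 1.001]
        p0_grid = grid["p0"] if grid else [0.001, 0.1, 0.3]
        for n in n_grid:
            for phi in phi_grid:
                for p0 in p0_grid:
                    cfg = SimConfig(n=int(n), phi=float(phi), p0=float(p0), **base)
                    errs = mean_errors(cfg, reps, int(rng.integers(2 ** 31)))
                    for m, e in errs.items():
                        rows.append(dict(n=n, phi=phi, p0=p0, method=m,
                                         mean_error=e))
        return pd.DataFrame(rows)
    if study_id not in STUDY_GRIDS:
        raise ValueError("study_id must lie in 1..6")
    param, default_grid, fixed = STUDY_GRIDS[study_id]
    fixed = dict(fixed)
    fixed.update(config_overrides)
    values = grid if grid is not None else default_grid
    for value in values:
        kwargs = dict(fixed)
        kwargs[param] = int(value) if param in ("n", "G") else float(value)
        cfg = SimConfig(**kwargs)
        errs = mean_errors(cfg, reps, int(rng.integers(2 ** 31)))
        for m, e in errs.items():
            rows.append({param: value, "method": m, "mean_error": e})
    return pd.DataFrame(rows)
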