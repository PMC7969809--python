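"""Discriminant scores and Bayes-rule classification.

Every classifier scores a test vector x* with
``d_k(x*) = log P(x* | y = k) + log pi_k`` up to an additive constant
shared by all classes (terms free of k are dropped), and assigns the
class with the highest score; exact ties go to the smallest class index.

Score expressions per method (sums over genes, mu_kg = d_kg s* lambda_g):

PLDA     sum X* log d_kg - s* sum lambda_g d_kg + log pi_k
NBLDA    sum X* [log d_kg - log(1 + mu_kg phi_g)]
         - sum phi_g^-1 log(1 + mu_kg phi_g) + log pi_k
ZIPLDA   zero genes:    log(p + (1-p) e^{-mu_kg})
         nonzero genes: -mu_kg + log(1-p) + X* log d_kg
ZINBLDA  zero genes:    log(p + (1-p) (1+mu_kg phi_g)^{-1/phi_g})
         nonzero genes: log(1-p) + X*[log d_kg - log(1+mu_kg phi_g)]
                        - phi_g^-1 log(1+mu_kg phi_g)

Genes with phi_g = 0 inside the NB-family scores use the closed-form
Poisson terms, so NBLDA(phi=0) == PLDA and ZINBLDA(phi=0) == ZIPLDA
exactly, and ZIPLDA/ZINBLDA with p == 0 collapse onto PLDA/NBLDA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    METHODS,
    PROB_FLOOR,
    ClassLabels,
    CountMatrix,
    FittedModel,
    validate_matrix,
)
from . import estimation as est

logger = logging.getLogger("countlda")


@dataclass
class DiscriminantScores:
    """Per-class log-scale discriminant values for one test sample."""

    scores: np.ndarray
    predicted: int

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        assert self.predicted == int(np.argmax(self.scores)) + 1


# ---------------------------------------------------------------------------
# score kernels (vectorized over test samples)
# ---------------------------------------------------------------------------

def _prepare(x_star, model: FittedModel, s_star):
    X = x_star.counts if isinstance(x_star, CountMatrix) else np.asarray(x_star)
    single = X.ndim == 1
    X = np.atleast_2d(X.T).T.astype(float)            # (G, m)
    if X.shape[0] != model.G:
        raise ValueError(f"test matrix has {X.shape[0]} genes, model expects {model.G}")
    if s_star is None:
        s_star = est.estimate_test_size_factor(X, model.train_grand_total,
                                               model.size_factors)
    s_star = np.atleast_1d(np.asarray(s_star, dtype=float))
    return X, s_star, single


def _mu_tensor(model, s_star):
    # (m, K, G): d_kg * s*_m * lambda_g
    return s_star[:, None, None] * model.d[None, :, :] * model.lam[None, None, :]


def _poisson_kernel(X, model, s_star):
    # tensor form (m, K, G) so the phi -> 0 NB limit is bit-identical
    mu = _mu_tensor(model, s_star)
    logd = np.broadcast_to(np.log(model.d)[None, :, :], mu.shape)
    return np.einsum("gm,mkg->mk", X, logd) - mu.sum(axis=2)


def _nb_kernel(X, model, s_star):
    mu = _mu_tensor(model, s_star)                    # (m, K, G)
    phi = model.phi[None, None, :]
    pos = phi > 0
    safe_phi = np.where(pos, phi, 1.0)
    log1p_muphi = np.where(pos, np.log1p(mu * safe_phi), 0.0)
    logd = np.log(model.d)[None, :, :]
    a = np.where(pos, logd - log1p_muphi, logd)       # coefficient of X*
    b = np.where(pos, -log1p_muphi / safe_phi, -mu)   # X*-free term
    return np.einsum("gm,mkg->mk", X, a) + b.sum(axis=2)


def _zero_probs(X, model, s_star, phi):
    """p-hat per (test sample, class, gene) from the logistic zero model."""
    mu = _mu_tensor(model, s_star)
    depth = X.sum(axis=0)                             # N* per test sample
    return est.predict_zero_prob(model.logistic, depth[:, None, None], mu, phi), mu


def _zi_kernel(X, model, s_star, phi):
    p, mu = _zero_probs(X, model, s_star, phi)        # (m, K, G)
    log_z = est._nb_zero_logmass(mu, phi)             # structural zero mass
    zero = (X == 0).T[:, None, :]                     # (m, 1, G)
    log1mp = np.log(np.maximum(1.0 - p, PROB_FLOOR))
    with np.errstate(divide="ignore"):
        zero_term = np.where(p > 0, np.log(p + np.exp(log1mp + log_z)),
                             log1mp + log_z)
    phi_b = np.broadcast_to(phi, mu.shape)
    safe_phi = np.where(phi_b > 0, phi_b, 1.0)
    log1p_muphi = np.where(phi_b > 0, np.log1p(mu * safe_phi), 0.0)
    logd = np.log(model.d)[None, :, :]
    coef = np.where(phi_b > 0, logd - log1p_muphi, logd)
    nonzero_term = log1mp + np.where(phi_b > 0, -log1p_muphi / safe_phi, -mu)
    Xm = X.T[:, None, :]                              # (m, 1, G)
    per_gene = np.where(zero, zero_term, nonzero_term + Xm * coef)
    return per_gene.sum(axis=2)


def _score_matrix(X, model: FittedModel, s_star) -> np.ndarray:
    log_prior = np.log(model.priors)[None, :]
    if model.method == "PLDA":
        return _poisson_kernel(X, model, s_star) + log_prior
    if model.method == "NBLDA":
        return _nb_kernel(X, model, s_star) + log_prior
    if model.method == "ZIPLDA":
        if model.logistic is None or model.logistic.degenerate:
            return _poisson_kernel(X, model, s_star) + log_prior
        return _zi_kernel(X, model, s_star, 0.0) + log_prior
    if model.method == "ZINBLDA":
        if model.logistic is None or model.logistic.degenerate:
            return _nb_kernel(X, model, s_star) + log_prior
        return _zi_kernel(X, model, s_star, model.phi[None, None, :]) + log_prior
    raise ValueError(model.method)


def _single(scores_row) -> DiscriminantScores:
    return DiscriminantScores(scores_row, int(np.argmax(scores_row)) + 1)


def _score_one(x_star, model, s_star, method):
    if model.method != method:
        raise ValueError(f"model was fitted as {model.method}, not {method}")
    X, s, single = _prepare(x_star, model, s_star)
    S = _score_matrix(X, model, s)
    return _single(S[0]) if single else [_single(row) for row in S]


def score_plda(x_star, model, s_star=None):
    """Poisson discriminant score(s) for one test vector."""
    return _score_one(x_star, model, s_star, "PLDA")


def score_nblda(x_star, model, s_star=None):
    """Negative-binomial discriminant score(s)."""
    return _score_one(x_star, model, s_star, "NBLDA")


def score_ziplda(x_star, model, s_star=None):
    """Zero-inflated Poisson discriminant score(s)."""
    return _score_one(x_star, model, s_star, "ZIPLDA")


def score_zinblda(x_star, model, s_star=None):
    """Zero-inflated negative-binomial discriminant score(s)."""
    return _score_one(x_star, model, s_star, "ZINBLDA")


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

def _common_estimates(counts, labels, beta):
    s = est.estimate_size_factors(counts)
    lam = est.estimate_lambda(counts, s)
    d = est.estimate_class_difference(counts, labels, s, lam, beta=beta)
    priors = labels.class_sizes / labels.n
    X = counts.counts
    grand = float(X.sum())
    ref_idx = int(np.nonzero(labels.labels == 1)[0][0])
    ref_depth = float(X[:, ref_idx].sum())
    return s, lam, d, priors, grand, ref_depth


def fit(counts, labels, method: str = "ZINBLDA", beta: float = 1.0,
        phi_tol: float = 1e-8, _shared=None) -> FittedModel:
    """Fit one of the four classifiers on training counts.

    Runs only the estimators the method needs: dispersions for the NB
    family, the logistic zero model for the zero-inflated family.  Class
    priors are the empirical frequencies n_k / n.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    counts, labels = validate_matrix(counts, labels)
    if _shared is None:
        _shared = _common_estimates(counts, labels, beta)
    s, lam, d, priors, grand, ref_depth = _shared
    phi = None
    logistic = None
    if method in ("NBLDA", "ZINBLDA"):
        if method == "NBLDA":
            phi = est.estimate_dispersion_nb(counts, labels, s, lam, d, tol=phi_tol)
        else:
            phi = est.estimate_dispersion_zinb(counts, labels, s, lam, d, tol=phi_tol)
    if method in ("ZIPLDA", "ZINBLDA"):
        logistic = est.fit_zero_logistic(counts, s, lam, d, labels)
    return FittedModel(method=method, d=d, size_factors=s, lam=lam,
                       priors=priors, train_grand_total=grand,
                       ref_depth=ref_depth, phi=phi, logistic=logistic,
                       gene_ids=list(counts.gene_ids))


def fit_all(counts, labels, methods=METHODS, beta: float = 1.0,
            phi_tol: float = 1e-8) -> dict:
    """Fit several classifiers sharing the common estimators.

    Size factors, abundances and class effects are identical across
    methods, and the zero-inflated pair shares one logistic fit; this
    avoids recomputation in the benchmark loops.
    """
    counts, labels = validate_matrix(counts, labels)
    shared = _common_estimates(counts, labels, beta)
    s, lam, d, priors, grand, ref_depth = shared
    phi_nb = phi_zinb = logistic = None
    models = {}
    for method in methods:
        method = method.upper()
        phi = None
        logi = None
        if method == "NBLDA":
            if phi_nb is None:
                phi_nb = est.estimate_dispersion_nb(counts, labels, s, lam, d, tol=phi_tol)
            phi = phi_nb
        elif method == "ZINBLDA":
            if phi_zinb is None:
                phi_zinb = est.estimate_dispersion_zinb(counts, labels, s, lam, d, tol=phi_tol)
            phi = phi_zinb
        if method in ("ZIPLDA", "ZINBLDA"):
            if logistic is None:
                logistic = est.fit_zero_logistic(counts, s, lam, d, labels)
            logi = logistic
        models[method] = FittedModel(method=method, d=d, size_factors=s,
                                     lam=lam, priors=priors,
                                     train_grand_total=grand,
                                     ref_depth=ref_depth, phi=phi,
                                     logistic=logi,
                                     gene_ids=list(counts.gene_ids))
    return models


def predict(x_star_matrix, model: FittedModel, s_star=None):
    """Classify test samples; returns (labels 1..K, score matrix m x K).

    Ties on the maximal score resolve to the smallest class index.
    """
    X, s, single = _prepare(x_star_matrix, model, s_star)
    S = _score_matrix(X, model, s)
    labels = np.argmax(S, axis=1) + 1
    return labels, S
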