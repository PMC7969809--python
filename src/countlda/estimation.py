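"""Parameter estimators for the count-model classifiers.

Estimation order (each step feeds the next):

1. size factors ``s_i`` -- total-count normalization, sample column total
   over the grand total, so the training factors sum to one;
2. gene abundances ``lambda_g = sum_i X_ig / sum_i s_i`` (equal to the
   gene row total under total-count factors);
3. class effects ``d_kg`` -- posterior mean under a Gamma(beta, beta)
   prior, ``(sum_{i in k} X_ig + beta) / (lambda_g sum_{i in k} s_i + beta)``,
   with beta = 1, which keeps d_kg positive even for all-zero genes;
4. per-gene dispersion ``phi_g`` -- maximum likelihood under the
   zero-inflated NB with the per-gene zero probability held at its
   initializer (NB dispersion is the same estimator with zero
   probabilities frozen at 0);
5. a single logistic model linking the probability a cell is zero to the
   sample's relative sequencing depth and the cell's fitted mean.

The dispersion maximizer replaces the reference implementation's PORT
routine with a vectorized bracketed golden-section search on log(phi) in
[1e-8, 1e3]; an optimum at the lower bound is reported as 0 (Poisson).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .core import (
    GAMMA_PRIOR_BETA,
    PHI_LOWER,
    PHI_UPPER,
    PROB_FLOOR,
    ClassLabels,
    CountMatrix,
    DataError,
)

logger = logging.getLogger("countlda")

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden ratio step


@dataclass
class LogisticZeroModel:
    """Logistic relation between zero probability, depth and mean.

    logit P(X_{i g} = 0) = alpha + beta1 * (N_i / N_ref) + beta2 * mu_{i g}

    where ``N_i`` is the library size of the sample and ``N_ref`` the
    library size of the first training sample of class 1.  ``degenerate``
    marks a training matrix without zeros, for which the model is the
    constant p = 0.
    """

    alpha: float
    beta1: float
    beta2: float
    ref_depth: float
    degenerate: bool = False

    def linear_predictor(self, depth, mu):
        return self.alpha + self.beta1 * (np.asarray(depth, dtype=float) / self.ref_depth) + self.beta2 * mu


# ---------------------------------------------------------------------------
# size factors and first moments
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix) -> np.ndarray:
    """Total-count size factors: column total / grand total (sum to 1)."""
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    col = X.sum(axis=0).astype(float)
    grand = col.sum()
    if grand <= 0:
        raise DataError("count matrix has zero grand total")
    if np.any(col == 0):
        raise DataError("all-zero sample(s): size factor would be 0")
    return col / grand


def estimate_test_size_factor(x_star, train_grand_total: float, size_factors=None):
    """Size factor of a test sample: its total over the training grand total.

    ``x_star`` may be a vector or a (G, m) matrix of test samples.  An
    all-zero test sample is assigned the smallest training factor (if
    provided, else the floor 1/train_grand_total) with a warning, so its
    fitted means stay positive.
    """
    if train_grand_total <= 0:
        raise DataError("training grand total must be positive")
    x = np.asarray(x_star, dtype=float)
    total = x.sum(axis=0) if x.ndim == 2 else x.sum()
    s = np.asarray(total, dtype=float) / train_grand_total
    if np.any(np.atleast_1d(s) == 0):
        fallback = (
            float(np.min(size_factors)) if size_factors is not None
            else 1.0 / train_grand_total
        )
        warnings.warn("all-zero test sample; using smallest training size factor")
        s = np.where(np.atleast_1d(s) == 0, fallback, np.atleast_1d(s))
        if x.ndim == 1:
            s = float(s[0])
    return s


def estimate_lambda(counts: CountMatrix, size_factors) -> np.ndarray:
    """Gene abundances lambda_g = row total / sum of size factors."""
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    s_sum = float(np.sum(size_factors))
    return X.sum(axis=1).astype(float) / s_sum


def estimate_class_difference(counts, labels: ClassLabels, size_factors, lam,
                              beta: float = GAMMA_PRIOR_BETA) -> np.ndarray:
    """Posterior-mean class effects d_kg under a Gamma(beta, beta) prior."""
    if beta <= 0:
        raise ValueError("prior beta must be positive")
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    lam = np.asarray(lam, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    K = labels.K
    d = np.empty((K, X.shape[0]))
    for k in range(1, K + 1):
        mask = labels.labels == k
        num = X[:, mask].sum(axis=1) + beta
        den = lam * s[mask].sum() + beta
        d[k - 1] = num / den
    return d


def fitted_means(labels: ClassLabels, size_factors, lam, d) -> np.ndarray:
    """Per-cell fitted means mu_{i g} = d_{k(i) g} * s_i * lambda_g, (n, G)."""
    s = np.asarray(size_factors, dtype=float)
    d_per_sample = np.asarray(d)[labels.labels - 1]          # (n, G)
    return d_per_sample * s[:, None] * np.asarray(lam, dtype=float)[None, :]


# ---------------------------------------------------------------------------
# dispersion maximum likelihood
# ---------------------------------------------------------------------------

def _nb_zero_logmass(mu, phi):
    """log of the NB zero mass (1 + mu*phi)^(-1/phi); Poisson limit at phi=0."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    phi_b = np.broadcast_to(phi, np.broadcast_shapes(mu.shape, phi.shape))
    safe = np.where(phi_b > 0, phi_b, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nb = -np.log1p(mu * safe) / safe
    return np.where(phi_b > 0, nb, -mu)


def nb_zero_mass(mu, phi):
    return np.exp(_nb_zero_logmass(mu, phi))


def _zinb_negll(log_phi, X, mu, p, zero_mask, lgam_x1):
    """Per-gene negative ZINB log-likelihood (full, reference form).

    X, mu : (n, G); log_phi, p : (G,).  ``lgam_x1`` caches gammaln(X+1).
    Entries with mu == 0 are necessarily zero counts and contribute a
    constant; they are handled through the zero branch.  The optimizer
    uses the reduced closure below; this full version backs the oracle
    tests and keeps every term of the likelihood explicit.
    """
    phi = np.exp(log_phi)
    r = 1.0 / phi
    log1p_muphi = np.log1p(mu * phi)                      # (n, G)
    log_z = -r * log1p_muphi
    with np.errstate(divide="ignore", invalid="ignore"):
        zero_ll = np.log(p + (1.0 - p) * np.exp(log_z))
        nonzero_ll = (
            np.log1p(-np.minimum(p, 1.0 - PROB_FLOOR))
            + gammaln(X + r) - gammaln(r) - lgam_x1
            + X * (np.log(mu * phi) - log1p_muphi)
            - r * log1p_muphi
        )
    ll = np.where(zero_mask, zero_ll, nonzero_ll)
    return -np.sum(ll, axis=0)


def _reduced_negll_factory(X, mu, p):
    """Per-gene negative log-likelihood up to phi-free constants.

    Drops every term constant in phi (log(1-p) on nonzero cells,
    gammaln(x+1), x*log(mu)) and evaluates gammaln only on nonzero
    cells, which leaves the argmax unchanged and roughly halves the cost
    of each optimizer step.
    """
    G = X.shape[1]
    zero = X == 0
    nz_i, nz_g = np.nonzero(~zero)
    x_nz = X[nz_i, nz_g]
    mu_nz = mu[nz_i, nz_g]
    z_i, z_g = np.nonzero(zero)
    mu_z = mu[z_i, z_g]
    p_z = p[z_g]
    n_nz = (~zero).sum(axis=0).astype(float)
    sum_x = np.bincount(nz_g, weights=x_nz, minlength=G)

    def negll(t):
        phi = np.exp(t)
        r = 1.0 / phi
        lp = np.log1p(mu_nz * phi[nz_g])
        term = gammaln(x_nz + r[nz_g]) - (x_nz + r[nz_g]) * lp
        acc = np.bincount(nz_g, weights=term, minlength=G)
        acc += -n_nz * gammaln(r) + sum_x * t
        if z_g.size:
            lp0 = np.log1p(mu_z * phi[z_g])
            with np.errstate(divide="ignore"):
                zterm = np.log(p_z + (1.0 - p_z) * np.exp(-lp0 * r[z_g]))
            acc += np.bincount(z_g, weights=zterm, minlength=G)
        return -acc

    return negll


def method_of_moments_phi(counts) -> np.ndarray:
    """Per-gene moment initializer phi0 = max{(s^2 - xbar)/xbar^2, 1e-3}."""
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    xbar = X.mean(axis=1)
    v = X.var(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(X.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        phi0 = (v - xbar) / np.square(xbar)
    phi0 = np.where(np.isfinite(phi0), phi0, 0.0)
    return np.maximum(phi0, 1e-3)


def estimate_dispersion_zinb(counts, labels, size_factors, lam, d,
                             zero_probs_init=None, phi_init=None,
                             tol: float = 1e-8, grid_size: int = 13) -> np.ndarray:
    """Per-gene ZINB dispersion MLE with zero probabilities held fixed.

    The likelihood is profiled on a log-spaced candidate grid over
    [1e-8, 1e3] (plus the per-gene initializer), then refined by a
    vectorized golden-section search in the bracketing interval down to
    ``tol`` on log(phi).  Genes whose optimum sits at the lower bound are
    reported as phi = 0.
    """
    X = (counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)).T.astype(float)  # (n, G)
    n, G = X.shape
    mu = fitted_means(labels, size_factors, lam, d)       # (n, G)
    zero_mask = X == 0
    if zero_probs_init is None:
        p = zero_mask.mean(axis=0)
    else:
        p = np.asarray(zero_probs_init, dtype=float)
        if p.ndim == 0:
            p = np.full(G, float(p))
    p = np.clip(p, 0.0, 1.0 - PROB_FLOOR)
    if phi_init is None:
        phi_init = method_of_moments_phi(X.T)
    phi_init = np.clip(np.asarray(phi_init, dtype=float), PHI_LOWER, PHI_UPPER)
    if phi_init.ndim == 0:
        phi_init = np.full(G, float(phi_init))

    lo, hi = np.log(PHI_LOWER), np.log(PHI_UPPER)
    grid = np.linspace(lo, hi, grid_size)
    spacing = grid[1] - grid[0]

    f = _reduced_negll_factory(X, mu, p)

    vals = np.empty((grid_size + 1, G))
    for j, t in enumerate(grid):
        vals[j] = f(np.full(G, t))
    t_init = np.log(phi_init)
    vals[-1] = f(t_init)
    cand = np.vstack([np.broadcast_to(grid[:, None], (grid_size, G)), t_init[None, :]])
    best = np.argmin(vals, axis=0)
    center = cand[best, np.arange(G)]
    a = np.maximum(center - spacing, lo)
    b = np.minimum(center + spacing, hi)

    # golden-section: one objective evaluation per iteration, vectorized
    c = b - _INVPHI * (b - a)
    e = a + _INVPHI * (b - a)
    fc, fe = f(c), f(e)
    n_iter = max(1, int(np.ceil(np.log(tol / (2.0 * spacing)) / np.log(_INVPHI))))
    for _ in range(n_iter):
        left = fc < fe
        b = np.where(left, e, b)
        a = np.where(left, a, c)
        c_new = np.where(left, b - _INVPHI * (b - a), e)
        e_new = np.where(left, c, a + _INVPHI * (b - a))
        x_eval = np.where(left, c_new, e_new)
        f_eval = f(x_eval)
        fc, fe = np.where(left, f_eval, fe), np.where(left, fc, f_eval)
        c, e = c_new, e_new
    t_hat = 0.5 * (a + b)
    phi_hat = np.exp(t_hat)
    if not np.all(np.isfinite(phi_hat)):  # pragma: no cover - defensive
        bad = ~np.isfinite(phi_hat)
        logger.warning("dispersion optimizer failed for %d gene(s); "
                       "falling back to moment initializer", int(bad.sum()))
        phi_hat[bad] = phi_init[bad]
    # lower-bound optima are the Poisson limit; the likelihood is flat to
    # float precision below ~1e-6, so anything there counts as boundary
    phi_hat[phi_hat <= 1e-6] = 0.0
    return phi_hat


def estimate_dispersion_nb(counts, labels, size_factors, lam, d,
                           tol: float = 1e-8, grid_size: int = 13) -> np.ndarray:
    """NB dispersion MLE: the zero-frozen (p == 0) case of the ZINB MLE."""
    return estimate_dispersion_zinb(counts, labels, size_factors, lam, d,
                                    zero_probs_init=0.0, tol=tol,
                                    grid_size=grid_size)


# ---------------------------------------------------------------------------
# zero-probability logistic model
# ---------------------------------------------------------------------------

def fit_zero_logistic(counts, size_factors, lam, d, labels: ClassLabels,
                      maxiter: int = 50) -> LogisticZeroModel:
    """Fit the shared logistic zero model over all gene x sample cells.

    The regression units are cells: response I(X_{ig} = 0), covariates
    the sample's relative depth N_i / N_ref and the fitted mean mu_{ig}.
    A matrix without zeros yields a degenerate model (p identically 0);
    perfect separation or a singular fit falls back to a ridge-penalized
    refit.
    """
    import statsmodels.api as sm

    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    depths = X.sum(axis=0).astype(float)                  # N_i
    ref_idx = int(np.nonzero(labels.labels == 1)[0][0])
    ref_depth = float(depths[ref_idx])
    zero = (X.T == 0)                                     # (n, G)
    if not zero.any():
        logger.info("no zeros in training matrix: degenerate zero model (p = 0)")
        return LogisticZeroModel(0.0, 0.0, 0.0, ref_depth, degenerate=True)
    mu = fitted_means(labels, size_factors, lam, d)       # (n, G)
    y = zero.ravel().astype(float)
    design = np.column_stack([
        np.ones(y.size),
        np.repeat(depths / ref_depth, X.shape[0]),
        mu.ravel(),
    ])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter)
        coefs = res.params
        if not np.all(np.isfinite(coefs)) or np.abs(coefs).max() > 1e6:
            raise np.linalg.LinAlgError("diverged")
    except Exception:
        logger.warning("logistic zero model separated/diverged; "
                       "using ridge-penalized refit")
        from sklearn.linear_model import LogisticRegression

        ridge = LogisticRegression(penalty="l2", C=1.0, fit_intercept=False)
        ridge.fit(design, y.astype(int))
        coefs = ridge.coef_[0]
    return LogisticZeroModel(float(coefs[0]), float(coefs[1]), float(coefs[2]),
                             ref_depth)


def predict_zero_prob(model: LogisticZeroModel, depth, mu, phi):
    """Excess-zero probability implied by the logistic model.

    Solves  p1/(1+p1) = p + (1-p) * z(mu, phi)  for p, where
    p1 = exp{alpha + beta1 N/N_ref + beta2 mu} and z is the NB zero mass
    ((1+mu*phi)^(-1/phi); e^{-mu} at phi = 0).  Raw values are clamped to
    [0, 1 - 1e-12]; cells whose total zero probability falls below the
    structural NB zero mass clamp to 0.
    """
    mu = np.asarray(mu, dtype=float)
    if model.degenerate:
        return np.zeros_like(mu)
    eta = np.clip(model.linear_predictor(depth, mu), -500.0, 500.0)
    p_total = expit(eta)                                  # p1 / (1 + p1)
    z = nb_zero_mass(mu, phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (p_total - z) / (1.0 - z)
    p = np.where(z >= 1.0 - PROB_FLOOR, 0.0, p)           # mu ~ 0: always zero anyway
    return np.clip(p, 0.0, 1.0 - PROB_FLOOR)
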