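import logging

import numpy as np
import pytest

from countlda.core import FittedModel
from countlda.estimation import LogisticZeroModel

logging.getLogger("countlda").setLevel(logging.ERROR)


def make_toy_model(method, rng, K=2, G=3, phi=None, logistic=None,
                   priors=None, n_train=4):
    """Random small fitted-model bundle with moderate means.

    Abundances and class effects are kept in ranges giving per-gene means
    below ~6, so zero masses stay well away from 0 and the zero-inflated
    mixture terms are numerically benign.
    """
    lam = rng.uniform(0.5, 2.5, G)
    d = rng.uniform(0.6, 1.6, (K, G))
    if priors is None:
        priors = rng.dirichlet(np.full(K, 5.0))
    s = rng.dirichlet(np.ones(n_train))
    return FittedModel(method=method, d=d, size_factors=s, lam=lam,
                       priors=priors, train_grand_total=100.0,
                       ref_depth=25.0, phi=phi, logistic=logistic)


def make_logistic(rng, ref_depth=25.0):
    return LogisticZeroModel(alpha=float(rng.uniform(-2.0, 0.0)),
                             beta1=float(rng.uniform(-0.5, 0.5)),
                             beta2=float(rng.uniform(-0.3, 0.0)),
                             ref_depth=ref_depth)


def degenerate_logistic(ref_depth=25.0):
    return LogisticZeroModel(0.0, 0.0, 0.0, ref_depth, degenerate=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_counts():
    """3 genes x 4 samples, labels [1,1,2,2]."""
    from countlda.core import ClassLabels, CountMatrix

    counts = CountMatrix(np.array([[1, 2, 5, 6],
                                   [0, 1, 0, 2],
                                   [3, 3, 3, 3]]))
    labels = ClassLabels(np.array([1, 1, 2, 2]))
    return counts, labels
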