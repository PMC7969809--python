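"""Readers, writers, model serialization, splitting and evaluation.

Count tables are dense TSV/CSV files with a header row of sample ids and
a first column of gene ids (genes in rows by default; pass
``orientation="samples"`` for transposed exports).  Fitted models travel
as JSON carrying every parameter of the bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClassLabels, CountMatrix, DataError, FittedModel
from .estimation import LogisticZeroModel

logger = logging.getLogger("countlda")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_counts(path, orientation: str = "genes") -> CountMatrix:
    """Read a count table; rejects non-integral or negative values."""
    if orientation not in ("genes", "samples"):
        raise ValueError("orientation must be 'genes' or 'samples'")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    except Exception as exc:
        raise DataError(f"cannot parse count table {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"empty count table {path}")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise DataError("non-numeric cells in count table")
    if orientation == "samples":
        df = df.T
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))


def write_counts(counts: CountMatrix, path, metadata: dict = None):
    path = Path(path)
    df = pd.DataFrame(counts.counts, index=counts.gene_ids,
                      columns=counts.sample_ids)
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
        df.to_csv(fh, sep=_sep_for(path))


def read_labels(path) -> ClassLabels:
    """Read labels: one per line, or two-column ``sample_id<sep>label``.

    Raw values map to 1..K in first-appearance order; the mapping is kept
    on the returned object (``labels.mapping``).
    """
    raw = []
    sample_ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", "\t").split("\t") if p]
            if len(parts) == 1:
                raw.append(parts[0])
            elif len(parts) == 2:
                sample_ids.append(parts[0])
                raw.append(parts[1])
            else:
                raise DataError(f"malformed label line: {line!r}")
    if not raw:
        raise DataError(f"no labels found in {path}")
    labels = ClassLabels.from_raw(raw)
    labels.sample_ids = sample_ids or None
    return labels


def write_labels(labels: ClassLabels, path):
    with open(path, "w") as fh:
        for value in labels.labels:
            fh.write(f"{int(value)}\n")


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: FittedModel) -> dict:
    out = dict(
        method=model.method,
        d=model.d.tolist(),
        size_factors=model.size_factors.tolist(),
        lam=model.lam.tolist(),
        priors=model.priors.tolist(),
        train_grand_total=model.train_grand_total,
        ref_depth=model.ref_depth,
        gene_ids=model.gene_ids,
    )
    if model.phi is not None:
        out["phi"] = model.phi.tolist()
    if model.logistic is not None:
        lg = model.logistic
        out["logistic"] = dict(alpha=lg.alpha, beta1=lg.beta1, beta2=lg.beta2,
                               ref_depth=lg.ref_depth, degenerate=lg.degenerate)
    return out


def model_from_dict(payload: dict) -> FittedModel:
    logistic = None
    if "logistic" in payload:
        logistic = LogisticZeroModel(**payload["logistic"])
    return FittedModel(
        method=payload["method"],
        d=np.asarray(payload["d"]),
        size_factors=np.asarray(payload["size_factors"]),
        lam=np.asarray(payload["lam"]),
        priors=np.asarray(payload["priors"]),
        train_grand_total=float(payload["train_grand_total"]),
        ref_depth=float(payload["ref_depth"]),
        phi=np.asarray(payload["phi"]) if "phi" in payload else None,
        logistic=logistic,
        gene_ids=payload.get("gene_ids"),
    )


def save_model(model: FittedModel, path, metadata: dict = None):
    payload = model_to_dict(model)
    if metadata:
        payload["_meta"] = metadata
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> FittedModel:
    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("_meta", None)
    return model_from_dict(payload)


# ---------------------------------------------------------------------------
# splitting and evaluation
# ---------------------------------------------------------------------------

def split_train_test(counts: CountMatrix, labels: ClassLabels,
                     train_fraction: float = None, train_n: int = None,
                     seed: int = 0):
    """Stratified random split keeping every class in both partitions.

    Exactly one of ``train_fraction`` / ``train_n`` must be given.
    Returns ``(train_counts, train_labels), (test_counts, test_labels)``.
    """
    if (train_fraction is None) == (train_n is None):
        raise ValueError("give exactly one of train_fraction or train_n")
    if np.any(labels.class_sizes < 2):
        raise DataError("every class needs >= 2 samples to stratify")
    rng = np.random.default_rng(seed)
    n = labels.n
    frac = train_fraction if train_fraction is not None else train_n / n
    train_idx = []
    test_idx = []
    for k in range(1, labels.K + 1):
        members = np.nonzero(labels.labels == k)[0]
        rng.shuffle(members)
        take = int(round(frac * members.size))
        take = min(max(take, 1), members.size - 1)   # both partitions non-empty
        train_idx.extend(members[:take])
        test_idx.extend(members[take:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))
    out = []
    for idx in (train_idx, test_idx):
        out.append((counts.subset_samples(idx),
                    ClassLabels(labels.labels[idx], K=labels.K)))
    return out[0], out[1]


def evaluate(predictions, true_labels) -> float:
    """Misclassification rate: the fraction of mismatched labels."""
    pred = np.asarray(predictions)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return float(np.mean(pred != true))
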