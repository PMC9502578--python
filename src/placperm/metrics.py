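"""Evaluation metrics: Pearson correlation, MAE, and per-chemical error reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import FittedModel, predict
from .tables import DescriptorTable

__all__ = [
    "pearson_r",
    "mae",
    "relative_absolute_error",
    "EvaluationReport",
    "evaluate",
]


def pearson_r(a, b) -> float:
    """Sample Pearson correlation; undefined (error) for constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("correlation requires at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def mae(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    return float(np.mean(np.abs(observed - predicted)))


def relative_absolute_error(observed: float, predicted: float) -> float:
    """|observed − predicted| / observed; the observed value must be positive."""
    if observed <= 0:
        raise ValueError("relative absolute error requires observed > 0")
    return abs(observed - predicted) / observed


@dataclass
class EvaluationReport:
    pearson_r: float
    mae: float
    per_chemical: dict  # id -> {observed, predicted, absolute_error, relative_absolute_error}
    target: str = "ci"
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "mae": self.mae,
            "per_chemical": self.per_chemical,
        }


def evaluate(
    model: FittedModel,
    table: DescriptorTable,
    against: str = "ci",
    auto_normalize: bool = False,
) -> EvaluationReport:
    """Predict ``table`` and score against its ``ci`` or ``ci_min`` column.

    Scoring against the minimum CI within experimental variation (ci_min)
    gives a variation-aware view of external-test error.  Per-chemical
    relative errors are reported where the observed value is positive and
    None where it is zero.
    """
    if against not in ("ci", "ci_min"):
        raise ValueError("against must be 'ci' or 'ci_min'")
    observed = getattr(table, against)
    if observed is None:
        raise ValueError(f"table has no {against} column")
    preds = predict(model, table, auto_normalize=auto_normalize)
    per = {}
    for cid, o, p in zip(table.chemical_ids, observed, preds):
        abs_err = abs(o - p)
        per[cid] = {
            "observed": float(o),
            "predicted": float(p),
            "absolute_error": float(abs_err),
            "relative_absolute_error": float(abs_err / o) if o > 0 else None,
        }
    return EvaluationReport(
        pearson_r=pearson_r(observed, preds),
        mae=mae(observed, preds),
        per_chemical=per,
        target=against,
        n=table.n_chemicals,
    )
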