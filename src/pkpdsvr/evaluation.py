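"""Prediction-error metrics and the model test protocol.

APE is the per-sample absolute percentage error, MAPE its mean, RMSE
the root-mean-square error in PD units.  Because the normalized PD
series crosses zero (e.g. TXB2 = −0.02% at 4 h for Moutan Cortex),
percentage errors blow up near zero observations; samples with
|observed| below a small floor are excluded from APE/MAPE with a
warning rather than poisoning the summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import PKPDDataset
from .svr_core import SVRModel

__all__ = [
    "EvaluationReport",
    "ape",
    "rmse",
    "mape",
    "evaluate_model",
    "MIN_ABS_OBSERVED",
]

#: Observations with |value| below this (PD % units) are not evaluable
#: on a percentage scale and are excluded from APE/MAPE.
MIN_ABS_OBSERVED = 0.05


def ape(observed: float, predicted: float) -> float:
    """Absolute percentage error |obs − pred| / |obs| × 100."""
    observed = float(observed)
    if observed == 0:
        raise ZeroDivisionError("APE undefined for observed == 0")
    return abs(observed - predicted) / abs(observed) * 100.0


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error, in the units of the observations."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise ValueError(f"length mismatch: {observed.shape} vs {predicted.shape}")
    if observed.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def _ape_vector(
    observed: np.ndarray, predicted: np.ndarray, min_abs: float
) -> tuple[np.ndarray, np.ndarray]:
    include = np.abs(observed) >= max(min_abs, np.finfo(float).tiny)
    if not include.all():
        warnings.warn(
            f"{int((~include).sum())} sample(s) with |observed| < {min_abs} "
            "excluded from percentage-error metrics",
            stacklevel=3,
        )
    apes = (
        np.abs(observed[include] - predicted[include])
        / np.abs(observed[include])
        * 100.0
    )
    return apes, include


def mape(
    observed: np.ndarray,
    predicted: np.ndarray,
    min_abs_observed: float = 0.0,
) -> float:
    """Mean APE in percent over evaluable samples (observed ≠ 0).

    Argument order matters: the first vector is the observed reference.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise ValueError(f"length mismatch: {observed.shape} vs {predicted.shape}")
    apes, include = _ape_vector(observed, predicted, min_abs_observed)
    if not include.any():
        raise ValueError("no evaluable samples: all observed values ~ 0")
    return float(np.mean(apes))


@dataclass
class EvaluationReport:
    """Per-sample and summary errors of one model on one row set."""

    herb: str
    endpoint: str
    protocol: str
    n_test: int
    per_sample_ape: np.ndarray
    ape_times: np.ndarray  # sampling times of the evaluable samples
    n_excluded: int
    rmse: float
    mape: float
    split_seed: int | None = None
    observed: np.ndarray = field(default=None, repr=False)
    predicted: np.ndarray = field(default=None, repr=False)

    @property
    def max_ape(self) -> float:
        return float(np.max(self.per_sample_ape)) if self.per_sample_ape.size else np.nan


def evaluate_model(
    model: SVRModel,
    test: PKPDDataset,
    endpoint: str,
    protocol: str = "held-out",
    split_seed: int | None = None,
    min_abs_observed: float = MIN_ABS_OBSERVED,
) -> EvaluationReport:
    """Score a trained model on the rows of ``test`` for one endpoint.

    RMSE uses every row; APE/MAPE use only rows whose observed value
    clears the ``min_abs_observed`` floor (excluded rows are counted and
    warned about).  ``protocol`` is a label recorded in the report,
    typically ``"held-out"`` or ``"in-sample"``.
    """
    if test.n_times == 0:
        raise ValueError("empty test set")
    observed = test.endpoint(endpoint)
    predicted = model.predict(test.concentrations)
    apes, include = _ape_vector(observed, predicted, min_abs_observed)
    return EvaluationReport(
        herb=test.herb_label,
        endpoint=endpoint,
        protocol=protocol,
        n_test=test.n_times,
        per_sample_ape=apes,
        ape_times=test.times[include],
        n_excluded=int((~include).sum()),
        rmse=rmse(observed, predicted),
        mape=float(np.mean(apes)) if include.any() else float("nan"),
        split_seed=split_seed,
        observed=observed,
        predicted=predicted,
    )
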