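"""Derivative-based attribution of PD effect to chemical components.

Differentiating the trained kernel expansion with respect to input
feature k gives, for the Gaussian kernel,

    ∂f/∂x_k (x) = Σ_i β_i · exp(-‖x-x_i‖²/(2σ²)) · (x_ik − x_k)/σ² ,

an analytic per-point sensitivity.  Averaging these over every row of a
herb's table yields one weight per component, and the weight vector —
optionally normalized — is that component's signed contribution to the
endpoint the model was trained on.  A positive contribution toward TXB2
points in the hemostatic direction; toward 6-keto-PGF1α, in the
circulation-promoting direction.  These are model sensitivities, not
causal effects.

Gradients are taken in standardized feature space by default so that
components whose serum concentrations differ by two orders of magnitude
are compared on a common scale; raw-space gradients (chain rule: divide
by the per-feature scale) are available on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .svr_core import SVRModel, cross_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityReport",
    "gradient_at_point",
    "gradient_matrix",
    "feature_weights",
    "contributions",
]


@dataclass
class SensitivityReport:
    """Per-sample gradients and the aggregated component attributions."""

    gradients: np.ndarray  # N×K, ∂f/∂x_k at each evaluation row
    weights: np.ndarray  # length K, signed mean sensitivity
    contributions: np.ndarray  # length K, weights under the normalization
    normalization_mode: str
    space: str
    endpoint: str = ""
    herb: str = ""
    component_names: list[str] | None = None


def _scaled_gradients(model: SVRModel, Z: np.ndarray) -> np.ndarray:
    """Gradient of the decision function w.r.t. scaled coordinates."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != len(model.scaler.center):
        raise ValueError(
            f"expected {len(model.scaler.center)} features, got {Z.shape[1]}"
        )
    if model.n_support == 0:
        return np.zeros_like(Z)
    K = cross_kernel(Z, model.support_vectors, model.sigma)  # N×M
    weighted = K * model.dual_coefs[None, :]
    # Σ_i βK·sv_ik  −  (Σ_i βK)·x_k
    grads = weighted @ model.support_vectors - weighted.sum(axis=1)[:, None] * Z
    return grads / model.sigma**2


def gradient_at_point(
    model: SVRModel, x: np.ndarray, space: str = "scaled", raw_input: bool = True
) -> np.ndarray:
    """Analytic gradient of the decision function at one point.

    ``x`` is a raw-space row by default (matching :meth:`SVRModel.predict`);
    pass ``raw_input=False`` for a point already in scaled coordinates.
    ``space`` selects the coordinates the derivative refers to.
    """
    x = np.asarray(x, dtype=float).ravel()
    z = model.scaler.transform(x[None, :]) if raw_input else x[None, :]
    g = _scaled_gradients(model, z)[0]
    if space == "raw":
        g = g / model.scaler.scale
    elif space != "scaled":
        raise ValueError(f"unknown space {space!r}")
    return g


def gradient_matrix(
    model: SVRModel, X: np.ndarray, space: str = "scaled"
) -> np.ndarray:
    """Gradients at every raw-space row of X (N×K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = _scaled_gradients(model, model.scaler.transform(X))
    if space == "raw":
        G = G / model.scaler.scale[None, :]
    elif space != "scaled":
        raise ValueError(f"unknown space {space!r}")
    # a constant column carries no signal; pin exactly to zero
    G[:, model.scaler.zero_variance] = 0.0
    return G


def feature_weights(
    model: SVRModel,
    X: np.ndarray,
    aggregation: str = "signed",
    space: str = "scaled",
) -> np.ndarray:
    """Average sensitivity of the output to each feature over the rows of X.

    ``signed`` (default) averages the raw derivatives, retaining the
    direction of the effect; ``absolute`` averages their magnitudes.
    """
    if np.atleast_2d(np.asarray(X)).shape[0] == 0:
        raise ValueError("cannot aggregate over an empty row set")
    G = gradient_matrix(model, X, space=space)
    if aggregation == "signed":
        return G.mean(axis=0)
    if aggregation == "absolute":
        return np.abs(G).mean(axis=0)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def contributions(
    model: SVRModel,
    X: np.ndarray,
    normalization: str = "l1",
    space: str = "scaled",
    endpoint: str = "",
    herb: str = "",
    component_names: list[str] | None = None,
) -> SensitivityReport:
    """Signed per-component contribution to the modeled endpoint.

    Contributions are the signed weights rescaled by the chosen positive
    normalizer (``none`` → raw weights, ``l1`` → divide by Σ|w|, ``max``
    → divide by max|w|), so the sign pattern is identical across modes.
    Zero-variance components are exactly zero by construction.
    """
    G = gradient_matrix(model, X, space=space)
    weights = G.mean(axis=0)
    total = float(np.sum(np.abs(weights)))
    if normalization == "none":
        contr = weights.copy()
    elif normalization == "l1":
        contr = weights / total if total > 0 else np.zeros_like(weights)
    elif normalization == "max":
        m = float(np.max(np.abs(weights)))
        contr = weights / m if m > 0 else np.zeros_like(weights)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if total == 0 and normalization in ("l1", "max"):
        logger.warning(
            "all sensitivity weights are zero; contributions set to zero"
        )
    return SensitivityReport(
        gradients=G,
        weights=weights,
        contributions=contr,
        normalization_mode=normalization,
        space=space,
        endpoint=endpoint,
        herb=herb,
        component_names=component_names,
    )
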