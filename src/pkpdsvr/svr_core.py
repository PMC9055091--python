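"""ε-support-vector regression with a Gaussian RBF kernel.

The regression function is the kernel expansion

    f(x) = Σ_i β_i K(x_i, x) + b,      K(x, x') = exp(-‖x-x'‖² / (2σ²)),

obtained by solving the ε-insensitive dual problem

    min_β  ½ βᵀKβ − yᵀβ + ε Σ_i |β_i|
    s.t.   Σ_i β_i = 0,   |β_i| ≤ c,

where β_i = α_i − α_i* collapses the usual pair of Lagrange multipliers.
The solver is a pairwise coordinate-descent (SMO-style) routine: every
update moves a pair (β_i, β_j) along e_i − e_j, which preserves the
equality constraint, and performs an exact piecewise-quadratic line
search that accounts for the |β| kinks and the box.  For a convex
problem over this polytope, pairwise stationarity implies global
optimality, so the loop terminates when no pair admits an improving
step.

Training samples with β_i ≠ 0 are the support vectors; only they enter
the decision function.  Features are standardized before training by
default — the raw concentration columns span two orders of magnitude,
which would otherwise let a handful of components dominate every RBF
distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = [
    "FeatureScaler",
    "SVRModel",
    "rbf_kernel",
    "gram_matrix",
    "cross_kernel",
    "train_svr",
    "predict",
    "dual_objective",
    "sigma_to_gamma",
    "gamma_to_sigma",
]

# KKT slack accepted when classifying multipliers as free/bound.
KKT_TOL = 1e-6


def sigma_to_gamma(sigma: float) -> float:
    """Convert a kernel width σ to the γ of exp(-γ‖x-x'‖²)."""
    return 1.0 / (2.0 * float(sigma) ** 2)


def gamma_to_sigma(gamma: float) -> float:
    return 1.0 / np.sqrt(2.0 * float(gamma))


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not sigma > 0:
        raise ValueError(f"kernel width sigma must be > 0, got {sigma}")
    return sigma


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian similarity exp(-‖x-y‖²/(2σ²)) between two vectors."""
    sigma = _check_sigma(sigma)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # ‖x-y‖² via the expansion; clip the tiny negatives it can produce
    xx = np.sum(X**2, axis=1)[:, None]
    yy = np.sum(Y**2, axis=1)[None, :]
    d2 = xx + yy - 2.0 * (X @ Y.T)
    return np.maximum(d2, 0.0)


def gram_matrix(X: np.ndarray, sigma: float) -> np.ndarray:
    """N×N Gaussian kernel matrix of the rows of X (unit diagonal, PSD)."""
    sigma = _check_sigma(sigma)
    X = np.asarray(X, dtype=float)
    K = np.exp(-_sq_dists(X, X) / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return K


def cross_kernel(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """|X|×|Y| kernel matrix between two row sets."""
    sigma = _check_sigma(sigma)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    return np.exp(-_sq_dists(X, Y) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# feature scaling
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature standardization state fitted on the training rows.

    Zero-variance columns are centered and given scale 1 so they map to
    an identically-zero column; the flag lets downstream attribution
    pin their weight to exactly zero.
    """

    center: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        center = X.mean(axis=0)
        sd = X.std(axis=0)
        zero = sd == 0.0
        scale = np.where(zero, 1.0, sd)
        return cls(center=center, scale=scale, zero_variance=zero)

    @classmethod
    def identity(cls, n_features: int) -> "FeatureScaler":
        return cls(
            center=np.zeros(n_features),
            scale=np.ones(n_features),
            zero_variance=np.zeros(n_features, dtype=bool),
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.center) / self.scale


# ---------------------------------------------------------------------------
# dual solver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _smo(K, y, C, eps, gain_tol, max_sweeps):  # pragma: no cover - jitted
    n = y.shape[0]
    beta = np.zeros(n)
    g = np.zeros(n)  # g = K @ beta
    edges = np.empty(4)
    for _ in range(max_sweeps):
        sweep_gain = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                bi = beta[i]
                bj = beta[j]
                lo = max(-C - bi, bj - C)
                hi = min(C - bi, bj + C)
                if hi <= lo:
                    continue
                eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
                a = (g[i] - y[i]) - (g[j] - y[j])
                # knots where the |β| terms kink, restricted to [lo, hi]
                t1 = -bi
                t2 = bj
                if t1 > t2:
                    t1, t2 = t2, t1
                m = 0
                edges[m] = lo
                m += 1
                if lo < t1 < hi:
                    edges[m] = t1
                    m += 1
                if lo < t2 < hi and t2 != t1:
                    edges[m] = t2
                    m += 1
                edges[m] = hi
                m += 1
                best_t = 0.0
                best_phi = 0.0
                for e in range(m):
                    t = edges[e]
                    phi = (
                        0.5 * eta * t * t
                        + a * t
                        + eps
                        * (abs(bi + t) + abs(bj - t) - abs(bi) - abs(bj))
                    )
                    if phi < best_phi:
                        best_phi = phi
                        best_t = t
                if eta > 0.0:
                    for e in range(m - 1):
                        lo_s = edges[e]
                        hi_s = edges[e + 1]
                        mid = 0.5 * (lo_s + hi_s)
                        si = 1.0 if bi + mid > 0.0 else (-1.0 if bi + mid < 0.0 else 0.0)
                        sj = 1.0 if bj - mid > 0.0 else (-1.0 if bj - mid < 0.0 else 0.0)
                        t = -(a + eps * (si - sj)) / eta
                        if t < lo_s:
                            t = lo_s
                        elif t > hi_s:
                            t = hi_s
                        phi = (
                            0.5 * eta * t * t
                            + a * t
                            + eps
                            * (abs(bi + t) + abs(bj - t) - abs(bi) - abs(bj))
                        )
                        if phi < best_phi:
                            best_phi = phi
                            best_t = t
                if best_phi < -gain_tol:
                    t = best_t
                    beta[i] = bi + t
                    beta[j] = bj - t
                    for q in range(n):
                        g[q] += t * (K[q, i] - K[q, j])
                    if -best_phi > sweep_gain:
                        sweep_gain = -best_phi
        if sweep_gain <= gain_tol:
            break
    return beta, g


def fit_dual(
    K: np.ndarray,
    y: np.ndarray,
    penalty: float,
    epsilon: float,
    gain_tol: float | None = None,
    max_sweeps: int = 5000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the dual on a precomputed Gram matrix.

    Returns ``(beta, g, bias)`` with ``g = K @ beta`` (training
    predictions are ``g + bias``).  This is the fast path used by the
    swarm-search fitness, which reuses one squared-distance matrix for
    every kernel width it probes.
    """
    y = np.asarray(y, dtype=float)
    scale = max(1.0, float(np.max(np.abs(y)))) * max(1.0, penalty)
    if gain_tol is None:
        gain_tol = 1e-13 * scale
    K = np.ascontiguousarray(K, dtype=np.float64)
    beta, g = _smo(
        K,
        np.ascontiguousarray(y, dtype=np.float64),
        float(penalty),
        float(epsilon),
        float(gain_tol),
        int(max_sweeps),
    )
    beta, g = _polish_active_set(K, y, float(penalty), float(epsilon), beta, g)
    bias = _solve_bias(beta, g, y, penalty, epsilon)
    return beta, g, bias


def _polish_active_set(
    K: np.ndarray, y: np.ndarray, C: float, eps: float, beta: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Newton finishing step on the active set the sweeps identified.

    With the bound/zero coefficients frozen, stationarity of the free
    ones (plus the Σβ = 0 multiplier) is a linear system; solving it
    removes the slow tail of coordinate descent.  The refined point is
    kept only if it respects the classification and does not worsen the
    dual objective.
    """
    tol = 1e-7 * max(1.0, C)
    free = (np.abs(beta) > tol) & (C - np.abs(beta) > tol)
    if not free.any():
        return beta, g
    s = np.sign(beta)
    fixed_val = np.where(C - np.abs(beta) <= tol, s * C, 0.0)
    idx = np.flatnonzero(free)
    fix = np.flatnonzero(~free)
    m = len(idx)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = K[np.ix_(idx, idx)]
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    rhs = np.zeros(m + 1)
    rhs[:m] = y[idx] - eps * s[idx] - K[np.ix_(idx, fix)] @ fixed_val[fix]
    rhs[m] = -np.sum(fixed_val[fix])
    try:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return beta, g
    refined = fixed_val.copy()
    refined[idx] = sol[:m]
    if not (
        np.all(np.sign(refined[idx]) == s[idx])
        and np.all(np.abs(refined) <= C + 1e-12)
    ):
        return beta, g
    obj_old = 0.5 * beta @ g - y @ beta + eps * np.sum(np.abs(beta))
    g_new = K @ refined
    obj_new = 0.5 * refined @ g_new - y @ refined + eps * np.sum(np.abs(refined))
    if obj_new > obj_old + 1e-12 * max(1.0, abs(obj_old)):
        return beta, g
    return refined, g_new


def _solve_bias(
    beta: np.ndarray, g: np.ndarray, y: np.ndarray, C: float, eps: float
) -> float:
    """KKT-consistent offset.

    Free support vectors pin b exactly (residual sits on the tube edge);
    average over them.  With none, intersect the KKT inequalities of the
    bound/inactive points and take the midpoint of the feasible interval.
    """
    atol = 1e-8 * max(1.0, C)
    r = y - g
    free = (np.abs(beta) > atol) & (np.abs(beta) < C - atol)
    if np.any(free):
        b_vals = np.where(beta[free] > 0, r[free] - eps, r[free] + eps)
        return float(np.mean(b_vals))
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        if beta[i] >= C - atol:  # at +c: residual must exceed the tube
            hi = min(hi, r[i] - eps)
        elif beta[i] <= -C + atol:
            lo = max(lo, r[i] + eps)
        else:  # inactive: residual inside the tube
            lo = max(lo, r[i] - eps)
            hi = min(hi, r[i] + eps)
    if not np.isfinite(lo):
        lo = hi
    if not np.isfinite(hi):
        hi = lo
    if not np.isfinite(lo):  # no constraints at all (empty problem guard)
        return float(np.median(r))
    return float(0.5 * (lo + hi))


def dual_objective(
    K: np.ndarray, y: np.ndarray, epsilon: float, beta: np.ndarray
) -> float:
    """½βᵀKβ − yᵀβ + εΣ|β| — the quantity the solver minimizes."""
    beta = np.asarray(beta, dtype=float)
    return float(
        0.5 * beta @ K @ beta - np.dot(y, beta) + epsilon * np.sum(np.abs(beta))
    )


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class SVRModel:
    """Trained kernel expansion with its preprocessing state.

    ``support_vectors`` live in scaled feature space; :meth:`predict`
    applies the stored scaler to raw inputs, so callers never handle
    scaled coordinates unless they ask for them.
    """

    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    bias: float
    sigma: float
    penalty: float
    epsilon: float
    scaler: FeatureScaler
    degenerate: bool = False

    @property
    def n_support(self) -> int:
        return len(self.dual_coefs)

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1] if self.support_vectors.size else len(self.scaler.center)

    @property
    def gamma(self) -> float:
        return sigma_to_gamma(self.sigma)

    def decision_function(self, X_scaled: np.ndarray) -> np.ndarray:
        """Evaluate f on rows already in scaled feature space."""
        X_scaled = np.atleast_2d(np.asarray(X_scaled, dtype=float))
        if X_scaled.shape[1] != len(self.scaler.center):
            raise ValueError(
                f"expected {len(self.scaler.center)} features, got {X_scaled.shape[1]}"
            )
        if self.n_support == 0:
            return np.full(X_scaled.shape[0], self.bias)
        K = cross_kernel(X_scaled, self.support_vectors, self.sigma)
        return K @ self.dual_coefs + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(self.scaler.transform(np.atleast_2d(X)))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "bias": self.bias,
            "sigma": self.sigma,
            "penalty": self.penalty,
            "epsilon": self.epsilon,
            "scaler": {
                "center": self.scaler.center.tolist(),
                "scale": self.scaler.scale.tolist(),
                "zero_variance": self.scaler.zero_variance.tolist(),
            },
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        sc = d["scaler"]
        n_feat = len(sc["center"])
        sv = np.asarray(d["support_vectors"], dtype=float).reshape(-1, n_feat)
        return cls(
            support_vectors=sv,
            dual_coefs=np.asarray(d["dual_coefs"], dtype=float),
            bias=float(d["bias"]),
            sigma=float(d["sigma"]),
            penalty=float(d["penalty"]),
            epsilon=float(d["epsilon"]),
            scaler=FeatureScaler(
                center=np.asarray(sc["center"], dtype=float),
                scale=np.asarray(sc["scale"], dtype=float),
                zero_variance=np.asarray(sc["zero_variance"], dtype=bool),
            ),
            degenerate=bool(d["degenerate"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SVRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# training / prediction API
# ---------------------------------------------------------------------------

def train_svr(
    X: np.ndarray,
    y: np.ndarray,
    penalty: float,
    sigma: float,
    epsilon: float = 0.1,
    scale: bool = True,
    max_sweeps: int = 5000,
) -> SVRModel:
    """Fit an ε-SVR with Gaussian kernel on (X, y).

    Parameters
    ----------
    penalty : float
        Box constraint c > 0 on the dual coefficients; trades tube
        violations against flatness.
    sigma : float
        Kernel width σ > 0 (length scale in scaled feature space).
    epsilon : float
        Half-width of the insensitive tube in PD units; residuals within
        it cost nothing.
    scale : bool
        Standardize columns on the training rows (default).  Pass False
        when X is already in the space σ refers to.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in training data")
    penalty = float(penalty)
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    sigma = _check_sigma(sigma)
    epsilon = float(epsilon)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    scaler = FeatureScaler.fit(X) if scale else FeatureScaler.identity(X.shape[1])
    Z = scaler.transform(X)
    degenerate = bool(np.all(_sq_dists(Z, Z) < 1e-24))

    K = gram_matrix(Z, sigma)
    beta, g, bias = fit_dual(K, y, penalty, epsilon, max_sweeps=max_sweeps)

    sv_tol = 1e-8 * max(1.0, penalty)
    mask = np.abs(beta) > sv_tol
    return SVRModel(
        support_vectors=Z[mask],
        dual_coefs=beta[mask],
        bias=bias,
        sigma=sigma,
        penalty=penalty,
        epsilon=epsilon,
        scaler=scaler,
        degenerate=degenerate,
    )


def predict(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the kernel expansion on raw-space rows."""
    return model.predict(X)
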