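"""Independent reference computations used only by the tests.

The dense QP oracle solves the ε-SVR dual in its classical 2N-variable
(α, α*) form with a generic NLP solver and exact gradients — a route
entirely separate from the package's pairwise coordinate solver.
"""

import numpy as np
from scipy.optimize import minimize


def solve_dual_qp(K, y, C, eps):
    """Dense solve of min ½(α-α*)ᵀK(α-α*) + εΣ(α+α*) − yᵀ(α-α*).

    Subject to Σ(α-α*) = 0 and 0 ≤ α, α* ≤ C.  Returns β = α − α*.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)

    def objective(u):
        a, astar = u[:n], u[n:]
        beta = a - astar
        g = K @ beta
        val = 0.5 * beta @ g + eps * np.sum(u) - y @ beta
        grad = np.concatenate([g + eps - y, -g + eps + y])
        return val, grad

    cons = {
        "type": "eq",
        "fun": lambda u: np.sum(u[:n]) - np.sum(u[n:]),
        "jac": lambda u: np.concatenate([np.ones(n), -np.ones(n)]),
    }
    res = minimize(
        objective,
        np.zeros(2 * n),
        jac=True,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[cons],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    beta = res.x[:n] - res.x[n:]
    beta = _polish(K, y, C, eps, beta)
    obj = float(0.5 * beta @ K @ beta - y @ beta + eps * np.sum(np.abs(beta)))
    return beta, obj


def _polish(K, y, C, eps, beta, tol=None):
    """Refine an approximate dual solution by solving the KKT system
    on its active-set classification exactly.  Falls back to the input
    if the refined point violates the classification."""
    n = len(y)
    tol = tol if tol is not None else 1e-5 * max(1.0, C)
    free = (np.abs(beta) > tol) & (np.abs(np.abs(beta) - C) > tol)
    if not free.any():
        return beta
    s = np.sign(beta)
    fixed = ~free
    b_fixed = np.where(np.abs(np.abs(beta) - C) <= tol, s * C, 0.0)
    idx = np.flatnonzero(free)
    m = len(idx)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = K[np.ix_(idx, idx)]
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    rhs = np.zeros(m + 1)
    rhs[:m] = y[idx] - eps * s[idx] - K[np.ix_(idx, np.flatnonzero(fixed))] @ b_fixed[fixed]
    rhs[m] = -np.sum(b_fixed[fixed])
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    refined = b_fixed.copy()
    refined[idx] = sol[:m]
    ok = np.all(np.sign(refined[idx]) == s[idx]) and np.all(np.abs(refined) <= C + 1e-12)
    if not ok:
        return beta
    obj_old = 0.5 * beta @ K @ beta - y @ beta + eps * np.sum(np.abs(beta))
    obj_new = 0.5 * refined @ K @ refined - y @ refined + eps * np.sum(np.abs(refined))
    return refined if obj_new <= obj_old + 1e-12 else beta


def rbf_elementwise(x, y, sigma):
    """Second, loop-based Gaussian kernel evaluation."""
    s = 0.0
    for a, b in zip(np.ravel(x), np.ravel(y)):
        s += (a - b) ** 2
    import math

    return math.exp(-s / (2.0 * sigma**2))


def gram_double_loop(X, sigma):
    X = np.asarray(X, dtype=float)
    n = len(X)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = rbf_elementwise(X[i], X[j], sigma)
    return K
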