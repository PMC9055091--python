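"""Particle swarm search for the SVR hyperparameters (c, σ).

Canonical global-best PSO: each particle carries a position in the
2-D (penalty, kernel-width) box and a velocity updated as

    v ← w·v + a·r1·(pbest − x) + a·r2·(gbest − x)

with a shared acceleration coefficient a for the cognitive and social
terms, an inertia weight w decreasing linearly over iterations, a
per-dimension velocity clamp, and positions clipped to the bounds.
The cost being minimized is the mean squared difference between the
observed PD values and the SVR predictions at the candidate (c, σ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .svr_core import fit_dual, train_svr, _sq_dists, FeatureScaler

logger = logging.getLogger(__name__)

__all__ = ["PSOConfig", "PSOResult", "fitness", "make_svr_objective", "pso_optimize"]

#: Lower edge of the search box.  The nominal range starts at 0, but c
#: and σ must stay strictly positive for the dual and the kernel to be
#: defined, so the box is clipped just above zero.
BOUND_FLOOR = 1e-3


@dataclass
class PSOConfig:
    """Swarm settings.

    Defaults follow the study conditions: 20 particles, 200 iterations,
    both dimensions searched on [0, 100] (floored at 1e-3), shared
    acceleration 1.5.  The inertia schedule is the common linear
    0.9 → 0.4 ramp; velocities are clamped to 20% of each dimension's
    range.  ``init_positions`` lets callers inject known-good points
    into the initial swarm.
    """

    n_particles: int = 20
    max_iter: int = 200
    bounds: tuple[tuple[float, float], ...] = ((BOUND_FLOOR, 100.0), (BOUND_FLOOR, 100.0))
    accel_coef: float = 1.5
    inertia: tuple[float, float] = (0.9, 0.4)
    v_max_frac: float = 0.2
    seed: int = 0
    init_positions: Sequence[Sequence[float]] | None = None
    resample_budget: int = 10

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bounds [{lo}, {hi}]")
        if self.accel_coef <= 0:
            raise ValueError("accel_coef must be > 0")


@dataclass
class PSOResult:
    """Best-ever position and the search trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # global-best fitness after init and each iteration
    evaluations: int
    config: PSOConfig = field(repr=False, default=None)


def _mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    d = observed - predicted
    return float(np.mean(d * d))


def fitness(
    params: Sequence[float],
    X: np.ndarray,
    y: np.ndarray,
    epsilon: float = 0.1,
    scheme: str = "train",
    scale: bool = True,
) -> float:
    """Cost of one (c, σ) candidate: train an SVR, score the residuals.

    ``scheme="train"`` scores the mean squared residual on the rows the
    model was trained on (the default; mirrors a fitness summed over the
    whole data set).  ``scheme="cv3"`` scores 3-fold cross-validated
    predictions instead, which penalizes the overfit the in-sample
    scheme invites.  Solver failures return +inf so the particle is
    repelled rather than crashing the search.
    """
    c, sigma = float(params[0]), float(params[1])
    if not (np.isfinite(c) and np.isfinite(sigma)) or c <= 0 or sigma <= 0:
        return np.inf
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    try:
        if scheme == "train":
            model = train_svr(X, y, penalty=c, sigma=sigma, epsilon=epsilon, scale=scale)
            return _mse(y, model.predict(X))
        if scheme == "cv3":
            preds = np.empty_like(y)
            idx = np.arange(len(y))
            for f in range(3):
                test = idx % 3 == f
                if test.all() or (~test).sum() < 2:
                    return np.inf
                model = train_svr(
                    X[~test], y[~test], penalty=c, sigma=sigma, epsilon=epsilon, scale=scale
                )
                preds[test] = model.predict(X[test])
            return _mse(y, preds)
        raise ValueError(f"unknown fitness scheme {scheme!r}")
    except ValueError:
        raise
    except Exception:  # numerical failure at extreme parameters
        logger.warning("SVR fit failed at c=%g sigma=%g; +inf cost", c, sigma)
        return np.inf


def make_svr_objective(
    X: np.ndarray,
    y: np.ndarray,
    epsilon: float = 0.1,
    scheme: str = "train",
    scale: bool = True,
) -> Callable[[Sequence[float]], float]:
    """Build a fast (c, σ) → cost callable for the swarm.

    For the training-set scheme the scaled squared-distance matrix is
    precomputed once; each probe only re-exponentiates it at the new σ
    and re-solves the small dual, which keeps a full 20×200 swarm run
    cheap.  The cross-validation scheme falls back to the general
    :func:`fitness` path.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if scheme != "train":
        return lambda p: fitness(p, X, y, epsilon=epsilon, scheme=scheme, scale=scale)

    scaler = FeatureScaler.fit(X) if scale else FeatureScaler.identity(X.shape[1])
    D2 = _sq_dists(scaler.transform(X), scaler.transform(X))
    np.fill_diagonal(D2, 0.0)

    def objective(params: Sequence[float]) -> float:
        c, sigma = float(params[0]), float(params[1])
        if not (np.isfinite(c) and np.isfinite(sigma)) or c <= 0 or sigma <= 0:
            return np.inf
        try:
            K = np.exp(-D2 / (2.0 * sigma * sigma))
            beta, g, bias = fit_dual(K, y, c, epsilon)
            return _mse(y, g + bias)
        except Exception:
            logger.warning("dual solve failed at c=%g sigma=%g; +inf cost", c, sigma)
            return np.inf

    return objective


def pso_optimize(objective: Callable, config: PSOConfig | None = None) -> PSOResult:
    """Minimize a 2-D objective over the configured box.

    Reproducible for a fixed ``config.seed``: one generator drives the
    swarm initialization and every r1/r2 draw.  The returned history is
    the global-best cost after initialization and after each iteration,
    hence non-increasing.
    """
    config = config or PSOConfig()
    rng = np.random.default_rng(config.seed)
    ndim = len(config.bounds)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    v_max = config.v_max_frac * span

    n = config.n_particles
    evaluations = 0

    def eval_all(pos: np.ndarray) -> np.ndarray:
        nonlocal evaluations
        out = np.empty(len(pos))
        for i, p in enumerate(pos):
            out[i] = objective(p)
            evaluations += 1
        return out

    pos = lo + rng.uniform(size=(n, ndim)) * span
    if config.init_positions is not None:
        inject = np.atleast_2d(np.asarray(config.init_positions, dtype=float))
        if len(inject) > n:
            raise ValueError("more injected positions than particles")
        pos[: len(inject)] = np.clip(inject, lo, hi)
    vel = rng.uniform(-1.0, 1.0, size=(n, ndim)) * v_max
    fit = eval_all(pos)

    for _ in range(config.resample_budget):
        if np.isfinite(fit).any():
            break
        pos = lo + rng.uniform(size=(n, ndim)) * span
        fit = eval_all(pos)
    else:
        raise RuntimeError("objective infinite on every sampled initial swarm")

    pbest_pos = pos.copy()
    pbest_fit = fit.copy()
    g_idx = int(np.argmin(pbest_fit))
    gbest_pos = pbest_pos[g_idx].copy()
    gbest_fit = float(pbest_fit[g_idx])
    history = [gbest_fit]

    w0, w1 = config.inertia
    a = config.accel_coef
    for it in range(config.max_iter):
        w = w0 + (w1 - w0) * (it / max(1, config.max_iter - 1))
        r1 = rng.uniform(size=(n, ndim))
        r2 = rng.uniform(size=(n, ndim))
        vel = w * vel + a * r1 * (pbest_pos - pos) + a * r2 * (gbest_pos - pos)
        vel = np.clip(vel, -v_max, v_max)
        pos = np.clip(pos + vel, lo, hi)
        fit = eval_all(pos)
        improved = fit < pbest_fit
        pbest_pos[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g_idx = int(np.argmin(pbest_fit))
        if pbest_fit[g_idx] < gbest_fit:
            gbest_fit = float(pbest_fit[g_idx])
            gbest_pos = pbest_pos[g_idx].copy()
        history.append(gbest_fit)

    return PSOResult(
        best_position=gbest_pos,
        best_fitness=gbest_fit,
        history=np.asarray(history),
        evaluations=evaluations,
        config=config,
    )
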