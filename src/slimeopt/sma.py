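"""Core slime mould algorithm (SMA).

A population metaheuristic mimicking the oscillatory foraging of slime
mould.  Each generation the population is evaluated and ranked; agents carry
oscillation weights ``W`` that amplify moves of well-fed (low-fitness)
agents and damp poor ones, and every coordinate is updated through one of
three branches: random reinitialisation (probability ``z``), a guided move
around the best-so-far position ``X_b`` scaled by ``vb ~ U[-a, a]``, or a
contraction ``vc * x`` with ``vc ~ U[-b, b]``.  Both ``a`` and ``b`` decay
to zero over the run, shifting the search from exploration to exploitation.

Minimization convention throughout; box bounds only, handled by clipping.
Search effort is fixed in objective-function evaluations, not iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "compute_control_params",
    "compute_p",
    "compute_weights",
    "sma_position_update",
    "run_sma",
    "SMAOptimizer",
]

_EPS = 2.2e-16  # guard added to (bF - wF) in the weight update

Bound = Union[float, Sequence[float], np.ndarray]


@dataclass
class OptimizerConfig:
    """Search-control parameters shared by all SMA variants.

    Parameters
    ----------
    pop_size : int
        Number of agents (default 30).
    max_evals : int
        Total objective-evaluation budget (default 300,000).
    z : float
        Per-agent probability of uniform reinitialisation each generation.
    lower, upper : float or array, optional
        Box bounds; taken from the objective when it carries them.
    dim : int, optional
        Problem dimensionality; taken from the objective when it carries it.
    seed : int
        RNG seed; every random draw in a run derives from it.
    """

    pop_size: int = 30
    max_evals: int = 300_000
    z: float = 0.03
    lower: Optional[Bound] = None
    upper: Optional[Bound] = None
    dim: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 < self.z < 1.0:
            raise ValueError("z must lie in (0, 1)")
        if self.max_evals < self.pop_size:
            raise ValueError("max_evals must cover at least one generation")


@dataclass
class OptimizationResult:
    """Outcome of a seeded optimizer run."""

    best_x: np.ndarray
    best_f: float
    trace: np.ndarray  # best-so-far fitness after each generation
    n_evals: int
    n_generations: int
    seed: int
    events: dict = field(default_factory=dict)  # per-operator fire counts


def compute_control_params(t: int, max_t: int) -> Tuple[float, float]:
    """Oscillation schedules ``a = arctanh(1 - t/max_t)`` and ``b = 1 - t/max_t``.

    ``t`` runs from 1; at ``t = max_t`` both vanish.  The arctanh argument is
    clamped to ``1 - 1/max_t`` so the schedule never diverges.
    """
    if not 1 <= t <= max_t:
        raise ValueError("t must satisfy 1 <= t <= max_t")
    frac = t / max_t
    b = 1.0 - frac
    a = float(np.arctanh(min(b, 1.0 - 1.0 / max_t)))
    return a, b


def compute_p(s_i: float, df: float) -> float:
    """Branch-decision parameter ``p = tanh|S_i - DF|`` in [0, 1)."""
    return float(np.tanh(abs(s_i - df)))


def compute_weights(
    sorted_fitness: np.ndarray, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Oscillation weights for agents given in ascending fitness order.

    The better half receives ``1 + r * log10((bF - S)/(bF - wF + eps) + 1)``
    and the worse half ``1 - r * log10(...)``, with ``r`` a fresh U(0,1) draw
    per element, so better-half weights are >= 1 and worse-half weights <= 1.
    Returns an ``(n, dim)`` matrix whose rows follow the sorted order.
    """
    s = np.asarray(sorted_fitness, dtype=float)
    n = s.shape[0]
    bf, wf = s[0], s[-1]
    # ratio lies in [0, 1] for ascending s; the eps guard can flip its sign
    # when bf ~= wf at double precision, so clamp from below.
    ratio = np.clip((bf - s) / (bf - wf + _EPS), 0.0, None)
    term = np.log10(ratio + 1.0)[:, None]
    r = rng.random((n, dim))
    better = (np.arange(n) < n / 2)[:, None]
    return np.where(better, 1.0 + r * term, 1.0 - r * term)


def sma_position_update(
    positions: np.ndarray,
    fitness: np.ndarray,
    W: np.ndarray,
    x_best: np.ndarray,
    df: float,
    a: float,
    b: float,
    lower: np.ndarray,
    upper: np.ndarray,
    z: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of the three-branch position update, clipped to bounds.

    Per agent: with probability ``z`` reinitialise uniformly in the box;
    otherwise per coordinate, with probability ``p = tanh|S_i - DF|`` move to
    ``X_b + vb * W * (X_A - X_B)`` (``X_A``, ``X_B`` drawn with replacement
    from the population), else contract ``vc * x``.
    """
    n, d = positions.shape
    p = np.tanh(np.abs(fitness - df))[:, None]
    r = rng.random((n, d))
    A = rng.integers(0, n, size=(n, d))
    B = rng.integers(0, n, size=(n, d))
    vb = rng.uniform(-a, a, size=(n, d)) if a > 0 else np.zeros((n, d))
    vc = rng.uniform(-b, b, size=(n, d)) if b > 0 else np.zeros((n, d))
    cols = np.arange(d)[None, :]
    xa = positions[A, cols]
    xb_ = positions[B, cols]
    new = np.where(r < p, x_best[None, :] + vb * W * (xa - xb_), vc * positions)
    reinit = rng.random(n) < z
    k = int(reinit.sum())
    if k:
        # One shared uniform draw per restarted agent (the reference SMA
        # behaviour): restarts land on the diagonal of the box, which seeds
        # coordinate-wise mixing through the X_A/X_B partner draws.
        new[reinit] = lower + rng.random((k, 1)) * (upper - lower)
    np.clip(new, lower, upper, out=new)
    return new


def run_sma(objective, cfg: Optional[OptimizerConfig] = None) -> OptimizationResult:
    """Minimize ``objective`` with the original SMA under ``cfg``.

    Identical to :func:`slimeopt.glsma.run_glsma` with both mutation
    operators disabled (same engine, same draw discipline).
    """
    from .glsma import GLSMAConfig, run_glsma

    cfg = cfg or OptimizerConfig()
    gcfg = GLSMAConfig(
        pop_size=cfg.pop_size, max_evals=cfg.max_evals, z=cfg.z,
        lower=cfg.lower, upper=cfg.upper, dim=cfg.dim, seed=cfg.seed,
        gaussian=False, levy=False,
    )
    return run_glsma(objective, gcfg)


class SMAOptimizer:
    """Thin object wrapper around :func:`run_sma` with sklearn-style params."""

    def __init__(self, **params) -> None:
        self.config = OptimizerConfig(**params)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self.config, k) for k in self.config.__dataclass_fields__}

    def set_params(self, **params) -> "SMAOptimizer":
        self.config = replace(self.config, **params)
        return self

    def optimize(self, objective) -> OptimizationResult:
        return run_sma(objective, self.config)


def resolve_problem(objective, cfg) -> Tuple[Callable, np.ndarray, np.ndarray, int]:
    """Extract a batch evaluator and per-coordinate bounds for a problem.

    Accepts a :class:`~slimeopt.benchmarks.BenchmarkFunction`-like object
    (with ``evaluate_batch``, ``dim``, ``lower``, ``upper``) or a plain
    callable, in which case ``cfg`` must supply ``dim`` and bounds.
    """
    dim = cfg.dim if cfg.dim is not None else getattr(objective, "dim", None)
    if dim is None:
        raise ValueError("dim not set in config and objective carries none")
    lower = cfg.lower if cfg.lower is not None else getattr(objective, "lower", None)
    upper = cfg.upper if cfg.upper is not None else getattr(objective, "upper", None)
    if lower is None or upper is None:
        raise ValueError("bounds not set in config and objective carries none")
    lb = np.broadcast_to(np.asarray(lower, dtype=float), (dim,)).copy()
    ub = np.broadcast_to(np.asarray(upper, dtype=float), (dim,)).copy()
    if np.any(lb >= ub):
        raise ValueError("lower bounds must be strictly below upper bounds")

    if hasattr(objective, "evaluate_batch"):
        def batch(X, rng):
            return np.asarray(objective.evaluate_batch(X, rng=rng), dtype=float)
    else:
        def batch(X, rng):
            return np.array([objective(x) for x in X], dtype=float)

    return batch, lb, ub, dim
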