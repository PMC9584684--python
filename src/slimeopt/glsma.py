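"""Gaussian-mutation and Levy-flight boosted SMA (GLSMA).

Two multiplicative perturbation operators are layered on the core SMA
generation, each guarded by greedy acceptance so no agent ever worsens:

* **Gaussian mutation** — ``x' = x * (1 + g)`` with ``g ~ N(0, 1)`` drawn
  per coordinate, applied every generation to diversify the population.
* **Levy flight** — ``x' = x * (1 + s)`` with heavy-tailed Mantegna steps
  ``s = phi * mu / |v|^(1/beta)`` (``beta = 1.5``), fired when the
  best-so-far fitness has stagnated for ``patience`` consecutive
  generations (or every generation with ``levy_mode="always"``), to escape
  local optima.

Operator evaluations are charged against the evaluation budget, so the
number of SMA generations shrinks accordingly.  Disabling both operators
recovers the original SMA exactly.  Note both operators fix the all-zero
position (``0 * (1 + g) = 0``), a property inherited from their
multiplicative form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .sma import (
    OptimizerConfig,
    OptimizationResult,
    compute_control_params,
    compute_weights,
    resolve_problem,
    sma_position_update,
)

__all__ = [
    "GLSMAConfig",
    "gaussian_perturb",
    "greedy_accept",
    "levy_phi",
    "levy_sample",
    "levy_perturb",
    "run_glsma",
    "GLSMAOptimizer",
]


@dataclass
class GLSMAConfig(OptimizerConfig):
    """:class:`~slimeopt.sma.OptimizerConfig` plus operator controls.

    ``gaussian`` / ``levy`` toggle the two operators independently (giving
    the GSMA, LSMA and plain-SMA ablations), ``beta_levy`` is the Levy
    stability index and ``patience`` the stagnation horizon (generations of
    unimproved best fitness) that triggers a Levy escape.
    """

    beta_levy: float = 1.5
    patience: int = 5
    gaussian: bool = True
    levy: bool = True
    levy_mode: str = "triggered"  # "triggered" | "always"

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 < self.beta_levy <= 2.0:
            raise ValueError("beta_levy must lie in (0, 2]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.levy_mode not in ("triggered", "always"):
            raise ValueError("levy_mode must be 'triggered' or 'always'")


def gaussian_perturb(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian mutation ``x * (1 + g)``, ``g ~ N(0,1)`` per
    coordinate.  Bound clipping is the caller's responsibility."""
    x = np.asarray(x, dtype=float)
    return x * (1.0 + rng.standard_normal(x.shape))


def greedy_accept(x_old, x_new, objective) -> Tuple[np.ndarray, float]:
    """Keep the mutant only on strict improvement; ties keep the incumbent.

    Returns the chosen position and its fitness.
    """
    f_old = float(objective(x_old))
    f_new = float(objective(x_new))
    if f_new < f_old:
        return np.asarray(x_new, dtype=float), f_new
    return np.asarray(x_old, dtype=float), f_old


def levy_phi(beta: float) -> float:
    """Mantegna scale ``phi`` for stability index ``beta`` in (0, 2]."""
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_sample(beta: float, size, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Levy steps ``phi * mu / |v|^(1/beta)``.

    ``mu`` and ``v`` are independent standard normals; the survival function
    of ``|s|`` decays like ``c^-beta`` for large thresholds ``c``.
    """
    phi = levy_phi(beta)
    mu = rng.standard_normal(size)
    v = rng.standard_normal(size)
    return phi * mu / np.abs(v) ** (1.0 / beta)


def levy_perturb(x: np.ndarray, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Levy move ``x * (1 + Levy(beta))`` per coordinate."""
    x = np.asarray(x, dtype=float)
    return x * (1.0 + levy_sample(beta, x.shape, rng))


def _greedy_step(X, F, X_new, batch, rng, lower, upper, evals):
    """Batched greedy acceptance of a perturbed population."""
    np.clip(X_new, lower, upper, out=X_new)
    F_new = batch(X_new, rng)
    acc = F_new < F
    X[acc] = X_new[acc]
    F[acc] = F_new[acc]
    return evals + X.shape[0]


def run_glsma(objective, cfg: Optional[GLSMAConfig] = None) -> OptimizationResult:
    """Minimize ``objective`` with GLSMA under ``cfg``.

    Per generation: evaluate the population, apply Gaussian mutation with
    greedy acceptance, fire a greedy Levy escape on stagnation, then perform
    the SMA position update.  Runs until the evaluation budget cannot cover
    another population evaluation; fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or GLSMAConfig()
    batch, lb, ub, dim = resolve_problem(objective, cfg)
    n = cfg.pop_size
    rng = np.random.default_rng(cfg.seed)

    # Schedule horizon from the per-generation baseline cost; triggered Levy
    # evaluations eat extra budget, so t is capped at max_t.
    per_gen = n * (1 + int(cfg.gaussian) + int(cfg.levy and cfg.levy_mode == "always"))
    max_t = max(1, cfg.max_evals // per_gen)

    X = lb + rng.random((n, dim)) * (ub - lb)
    df = np.inf
    x_best = X[0].copy()
    evals = 0
    t = 0
    stall = 0
    trace = []
    events = {"gaussian": 0, "levy": 0}

    while evals + n <= cfg.max_evals:
        t += 1
        F = batch(X, rng)
        evals += n
        improved = False
        i = int(np.argmin(F))
        if F[i] < df:
            df, x_best, improved = float(F[i]), X[i].copy(), True

        if cfg.gaussian and evals + n <= cfg.max_evals:
            evals = _greedy_step(X, F, gaussian_perturb(X, rng), batch, rng, lb, ub, evals)
            events["gaussian"] += 1
            i = int(np.argmin(F))
            if F[i] < df:
                df, x_best, improved = float(F[i]), X[i].copy(), True

        stall = 0 if improved else stall + 1
        fire_levy = cfg.levy and (
            cfg.levy_mode == "always" or stall >= cfg.patience
        )
        if fire_levy and evals + n <= cfg.max_evals:
            evals = _greedy_step(
                X, F, levy_perturb(X, cfg.beta_levy, rng), batch, rng, lb, ub, evals
            )
            events["levy"] += 1
            i = int(np.argmin(F))
            if F[i] < df:
                df, x_best = float(F[i]), X[i].copy()
            stall = 0

        trace.append(df)

        tt = min(t, max_t)
        a, b = compute_control_params(tt, max_t)
        order = np.argsort(F, kind="stable")
        W = np.empty((n, dim))
        W[order] = compute_weights(F[order], dim, rng)
        X = sma_position_update(X, F, W, x_best, df, a, b, lb, ub, cfg.z, rng)

    return OptimizationResult(
        best_x=x_best, best_f=df, trace=np.asarray(trace), n_evals=evals,
        n_generations=t, seed=cfg.seed, events=events,
    )


class GLSMAOptimizer:
    """Thin object wrapper around :func:`run_glsma` with sklearn-style params."""

    def __init__(self, **params) -> None:
        self.config = GLSMAConfig(**params)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self.config, k) for k in self.config.__dataclass_fields__}

    def set_params(self, **params) -> "GLSMAOptimizer":
        self.config = replace(self.config, **params)
        return self

    def optimize(self, objective) -> OptimizationResult:
        return run_glsma(objective, self.config)
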