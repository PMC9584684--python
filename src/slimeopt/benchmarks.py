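"""The 23 classical box-bounded benchmark functions (F1-F23).

Seven 30-D unimodal functions (F1-F7), six 30-D multimodal functions
(F8-F13) and ten fixed-dimension multimodal functions (F14-F23), each with
its conventional search range and reference global minimum.  All evaluators
are vectorised over a population: ``evaluate_batch`` maps an ``(m, dim)``
array to ``m`` values.  F7 adds uniform [0, 1) observation noise and is the
only stochastic member; it accepts an explicit RNG stream so runs remain
reproducible.

The six-hump camel-back (F16) is implemented in its standard form with the
``-2.1 x1^4`` term; some printings of the benchmark table carry a ``x1^2``
typo there, but the reference minimum -1.0316 identifies the standard
function.  Constant matrices for the foxholes, Kowalik, Hartmann and Shekel
functions are the canonical De Jong / Dixon-Szegő tables
(:mod:`slimeopt._constants`); their minimizers were refined numerically from
the literature starting points and are frozen below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from . import _constants as C

__all__ = ["BenchmarkFunction", "make_classical_suite", "get_function", "global_minimum"]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named box-bounded objective with reference-minimum metadata.

    Parameters
    ----------
    name : str
        Registry key, ``"F1"`` ... ``"F23"``.
    dim : int
        Dimensionality of the search space.
    lower, upper : float
        Scalar box bounds, replicated over every coordinate.
    f_min : float
        Reference global minimum as printed in the classical tables.
    batch : callable
        Vectorised evaluator ``(m, dim) array -> (m,) array``.
    x_min : ndarray, optional
        A known global minimizer (absent for the noisy F7).
    f_min_tol : float
        Certified bound on ``|evaluate(x_min) - f_min)|`` — nonzero where the
        printed reference value is rounded more coarsely than double
        precision.
    stochastic : bool
        True only for F7.
    """

    name: str
    dim: int
    lower: float
    upper: float
    f_min: float
    batch: Callable[..., np.ndarray] = field(repr=False)
    x_min: Optional[np.ndarray] = None
    f_min_tol: float = 1e-9
    stochastic: bool = False

    @property
    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-coordinate (lower, upper) bound vectors."""
        return (np.full(self.dim, self.lower), np.full(self.dim, self.upper))

    def evaluate_batch(self, X: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(
                f"{self.name} expects vectors of length {self.dim}, got {X.shape[1]}"
            )
        if self.stochastic:
            if rng is None:
                rng = np.random.default_rng()
            return self.batch(X, rng)
        return self.batch(X)

    def evaluate(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.shape[0] != self.dim:
            raise ValueError(
                f"{self.name} expects a vector of length {self.dim}, got shape {x.shape}"
            )
        return float(self.evaluate_batch(x[None, :], rng=rng)[0])

    # Convenience for optimizers that take a plain callable.
    __call__ = evaluate


# ---------------------------------------------------------------------------
# evaluators (vectorised over rows)

def _f1(X):
    return np.sum(X**2, axis=1)


def _f2(X):
    a = np.abs(X)
    return np.sum(a, axis=1) + np.prod(a, axis=1)


def _f3(X):
    return np.sum(np.cumsum(X, axis=1) ** 2, axis=1)


def _f4(X):
    return np.max(np.abs(X), axis=1)


def _f5(X):
    return np.sum(
        100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2 + (X[:, :-1] - 1.0) ** 2, axis=1
    )


def _f6(X):
    return np.sum(np.floor(X + 0.5) ** 2, axis=1)


def _f7(X, rng):
    i = np.arange(1, X.shape[1] + 1)
    return np.sum(i * X**4, axis=1) + rng.random(X.shape[0])


def _f8(X):
    return np.sum(-X * np.sin(np.sqrt(np.abs(X))), axis=1)


def _f9(X):
    return np.sum(X**2 - 10.0 * np.cos(2.0 * np.pi * X) + 10.0, axis=1)


def _f10(X):
    # Evaluation order fixed: the two exponential terms first, then +20, +e.
    n = X.shape[1]
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(X**2, axis=1) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * X), axis=1) / n)
        + 20.0
        + np.e
    )


def _f11(X):
    i = np.arange(1, X.shape[1] + 1)
    return (
        np.sum(X**2, axis=1) / 4000.0
        - np.prod(np.cos(X / np.sqrt(i)), axis=1)
        + 1.0
    )


def _u(X, a, k, m):
    """Boundary penalty: k(x-a)^m above a, k(-x-a)^m below -a, 0 between."""
    return np.where(
        X > a, k * (X - a) ** m, np.where(X < -a, k * (-X - a) ** m, 0.0)
    )


def _f12(X):
    n = X.shape[1]
    y = 1.0 + (X + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[:, 0]) ** 2
        + np.sum(
            (y[:, :-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2),
            axis=1,
        )
        + (y[:, -1] - 1.0) ** 2
    )
    return np.pi / n * core + np.sum(_u(X, 10.0, 100.0, 4), axis=1)


def _f13(X):
    core = (
        np.sin(3.0 * np.pi * X[:, 0]) ** 2
        + np.sum(
            (X[:, :-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * X[:, 1:]) ** 2),
            axis=1,
        )
        + (X[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * X[:, -1]) ** 2)
    )
    return 0.1 * core + np.sum(_u(X, 5.0, 100.0, 4), axis=1)


def _f14(X):
    # (m, 2, 25) deviations from the foxholes grid
    d = X[:, :, None] - C.FOXHOLES_A[None, :, :]
    inner = np.arange(1, 26) + np.sum(d**6, axis=1)
    return 1.0 / (1.0 / 500.0 + np.sum(1.0 / inner, axis=1))


def _f15(X):
    a, b = C.KOWALIK_A, C.KOWALIK_B
    x1, x2, x3, x4 = X[:, 0:1], X[:, 1:2], X[:, 2:3], X[:, 3:4]
    model = x1 * (b**2 + b * x2) / (b**2 + b * x3 + x4)
    return np.sum((a - model) ** 2, axis=1)


def _f16(X):
    x1, x2 = X[:, 0], X[:, 1]
    return (
        4.0 * x1**2
        - 2.1 * x1**4
        + x1**6 / 3.0
        + x1 * x2
        - 4.0 * x2**2
        + 4.0 * x2**4
    )


def _f17(X):
    x1, x2 = X[:, 0], X[:, 1]
    return (
        (x2 - 5.1 / (4.0 * np.pi**2) * x1**2 + 5.0 / np.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8.0 * np.pi)) * np.cos(x1)
        + 10.0
    )


def _f18(X):
    x1, x2 = X[:, 0], X[:, 1]
    t1 = 1.0 + (x1 + x2 + 1.0) ** 2 * (
        19.0 - 14.0 * x1 + 3.0 * x1**2 - 14.0 * x2 + 6.0 * x1 * x2 + 3.0 * x2**2
    )
    t2 = 30.0 + (2.0 * x1 - 3.0 * x2) ** 2 * (
        18.0 - 32.0 * x1 + 12.0 * x1**2 + 48.0 * x2 - 36.0 * x1 * x2 + 27.0 * x2**2
    )
    return t1 * t2


def _hartmann(A, c, P):
    def f(X):
        d = X[:, None, :] - P[None, :, :]
        return -np.sum(c * np.exp(-np.sum(A * d**2, axis=2)), axis=1)

    return f


def _shekel(m):
    A, c = C.SHEKEL_A[:m], C.SHEKEL_C[:m]

    def f(X):
        d = X[:, None, :] - A[None, :, :]
        return -np.sum(1.0 / (np.sum(d**2, axis=2) + c), axis=1)

    return f


# ---------------------------------------------------------------------------
# suite construction

# Minimizers of the fixed-dimension functions, refined by local search from
# the literature starting points against these exact evaluators.
_XMIN_F14 = np.array([-31.97833428297458, -31.97833428297458])
_XMIN_F15 = np.array([0.19283344, 0.19083644, 0.12311726, 0.13576523])
_XMIN_F16 = np.array([0.08984201774724806, -0.7126564030207396])
_XMIN_F17 = np.array([np.pi, 2.275])
_XMIN_F18 = np.array([0.0, -1.0])
_XMIN_F19 = np.array([0.11461434, 0.55564885, 0.85254695])
_XMIN_F20 = np.array([0.20168952, 0.15001069, 0.47687398, 0.27533243, 0.31165162, 0.65730054])
_XMIN_F21 = np.array([4.00003715, 4.00013327, 4.00003715, 4.00013327])
_XMIN_F22 = np.array([4.00057291, 4.00069020, 3.99948997, 3.99960619])
_XMIN_F23 = np.array([4.00074671, 4.00059326, 3.99966290, 3.99950981])

_SPEC = [
    # name, dim, lower, upper, f_min, batch, x_min, f_min_tol, stochastic
    ("F1", 30, -100.0, 100.0, 0.0, _f1, np.zeros(30), 1e-9, False),
    ("F2", 30, -10.0, 10.0, 0.0, _f2, np.zeros(30), 1e-9, False),
    ("F3", 30, -100.0, 100.0, 0.0, _f3, np.zeros(30), 1e-9, False),
    ("F4", 30, -100.0, 100.0, 0.0, _f4, np.zeros(30), 1e-9, False),
    ("F5", 30, -30.0, 30.0, 0.0, _f5, np.ones(30), 1e-9, False),
    ("F6", 30, -100.0, 100.0, 0.0, _f6, np.zeros(30), 1e-9, False),
    ("F7", 30, -128.0, 128.0, 0.0, _f7, None, 1e-9, True),
    ("F8", 30, -500.0, 500.0, -418.9829 * 30, _f8, np.full(30, 420.96874636), 5e-3, False),
    ("F9", 30, -5.12, 5.12, 0.0, _f9, np.zeros(30), 1e-9, False),
    ("F10", 30, -32.0, 32.0, 0.0, _f10, np.zeros(30), 1e-9, False),
    ("F11", 30, -600.0, 600.0, 0.0, _f11, np.zeros(30), 1e-9, False),
    ("F12", 30, -50.0, 50.0, 0.0, _f12, np.full(30, -1.0), 1e-9, False),
    ("F13", 30, -50.0, 50.0, 0.0, _f13, np.ones(30), 1e-9, False),
    ("F14", 2, -65.0, 65.0, 1.0, _f14, _XMIN_F14, 2.1e-3, False),
    ("F15", 4, -5.0, 5.0, 0.00030, _f15, _XMIN_F15, 1e-5, False),
    ("F16", 2, -5.0, 5.0, -1.0316, _f16, _XMIN_F16, 1e-4, False),
    ("F17", 2, -5.0, 5.0, 0.398, _f17, _XMIN_F17, 5e-4, False),
    ("F18", 2, -2.0, 2.0, 3.0, _f18, _XMIN_F18, 1e-9, False),
    ("F19", 3, 0.0, 1.0, -3.86, _hartmann(C.HARTMANN3_A, C.HARTMANN3_C, C.HARTMANN3_P), _XMIN_F19, 5e-3, False),
    ("F20", 6, 0.0, 1.0, -3.32, _hartmann(C.HARTMANN6_A, C.HARTMANN6_C, C.HARTMANN6_P), _XMIN_F20, 5e-3, False),
    ("F21", 4, 0.0, 10.0, -10.1532, _shekel(5), _XMIN_F21, 1e-4, False),
    ("F22", 4, 0.0, 10.0, -10.4028, _shekel(7), _XMIN_F22, 5e-4, False),
    ("F23", 4, 0.0, 10.0, -10.5363, _shekel(10), _XMIN_F23, 5e-4, False),
]


def make_classical_suite() -> Dict[str, BenchmarkFunction]:
    """Build the ordered F1-F23 registry."""
    suite: Dict[str, BenchmarkFunction] = {}
    for name, dim, lo, hi, fmin, batch, xmin, tol, stoch in _SPEC:
        suite[name] = BenchmarkFunction(
            name=name, dim=dim, lower=lo, upper=hi, f_min=fmin, batch=batch,
            x_min=xmin, f_min_tol=tol, stochastic=stoch,
        )
    return suite


_SUITE: Optional[Dict[str, BenchmarkFunction]] = None


def get_function(name: str) -> BenchmarkFunction:
    """Look up a suite member by its ``"F<k>"`` key."""
    global _SUITE
    if _SUITE is None:
        _SUITE = make_classical_suite()
    try:
        return _SUITE[name]
    except KeyError:
        raise KeyError(f"unknown benchmark {name!r}; expected F1..F23") from None


def global_minimum(fn: BenchmarkFunction) -> Tuple[float, Optional[np.ndarray]]:
    """Return the reference minimum value and, when known, a minimizer."""
    x = None if fn.x_min is None else fn.x_min.copy()
    return fn.f_min, x
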