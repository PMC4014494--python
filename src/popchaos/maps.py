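"""Benchmark maps and the Benettin tangent-space Lyapunov oracle.

These low-dimensional maps have known (analytic or easily computed)
maximal Lyapunov exponents and serve as the independent yardstick for the
neighbour-divergence estimator: the Benettin method iterates the exact
Jacobian along the orbit, which a time-series estimator never sees.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class IteratedMap:
    """Discrete map with its Jacobian, for orbit generation and the oracle."""

    name: str
    dim: int
    step: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    x0: np.ndarray

    def orbit(self, n: int, n_transient: int = 1000, observable: int = 0) -> np.ndarray:
        """Scalar observable of ``n`` post-transient iterates."""
        x = np.array(self.x0, dtype=float)
        for _ in range(n_transient):
            x = self.step(x)
            _check_bounded(x, self.name)
        out = np.empty(n)
        for i in range(n):
            out[i] = x[observable]
            x = self.step(x)
            _check_bounded(x, self.name)
        return out


def _check_bounded(x: np.ndarray, name: str, limit: float = 1e6) -> None:
    if not np.all(np.isfinite(x)) or np.any(np.abs(x) > limit):
        raise FloatingPointError(f"orbit of map {name!r} diverged")


def logistic_map(r: float, x0: float = 0.3) -> IteratedMap:
    """x -> r x (1 - x) on [0, 1]; chaotic at r=4 with λ = ln 2."""
    return IteratedMap(
        name=f"logistic(r={r})",
        dim=1,
        step=lambda x: r * x * (1.0 - x),
        jacobian=lambda x: np.array([[r * (1.0 - 2.0 * x[0])]]),
        x0=np.array([x0]),
    )


def henon_map(a: float = 1.4, b: float = 0.3,
              x0: tuple[float, float] = (0.1, 0.1)) -> IteratedMap:
    """Hénon map (x, y) -> (1 - a x² + y, b x); λ ≈ 0.419 at the classic parameters."""
    return IteratedMap(
        name=f"henon(a={a},b={b})",
        dim=2,
        step=lambda v: np.array([1.0 - a * v[0] ** 2 + v[1], b * v[0]]),
        jacobian=lambda v: np.array([[-2.0 * a * v[0], 1.0], [b, 0.0]]),
        x0=np.asarray(x0, dtype=float),
    )


def benettin_lyapunov(imap: IteratedMap, n_iter: int = 100_000,
                      n_transient: int = 1000) -> float:
    """Maximal Lyapunov exponent by tangent-vector renormalisation.

    Iterates a unit tangent vector with the exact Jacobian along the orbit,
    accumulating ln of its growth and renormalising each step; the average
    growth rate converges to the maximal exponent. Errors out on divergent
    orbits.
    """
    x = np.array(imap.x0, dtype=float)
    for _ in range(n_transient):
        x = imap.step(x)
        _check_bounded(x, imap.name)
    v = np.full(imap.dim, 1.0 / np.sqrt(imap.dim))
    acc = 0.0
    for _ in range(n_iter):
        v = imap.jacobian(x) @ v
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            # tangent vector annihilated (superstable orbit): -inf exponent
            return float("-inf")
        acc += np.log(norm)
        v /= norm
        x = imap.step(x)
        _check_bounded(x, imap.name)
    return acc / n_iter
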