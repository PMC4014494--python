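"""Recurrence matrices and Poincaré sections on embedded trajectories.

Recurrence plots mark pairs of times whose embedded states fall within an
``eps`` neighbourhood; diagonal line structures are the signature of
deterministic (periodic or nearly periodic) motion, and the classical RQA
determinism fraction DET quantifies them. A Poincaré section reduces an
attractor's dimension by one by collecting its transversal crossings of a
hyper-plane.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import EmbeddedTrajectory


@dataclass
class RecurrenceMatrix:
    """Binary recurrence matrix with its threshold and norm tag."""

    matrix: np.ndarray  # square bool array
    eps: float
    norm: str = "euclidean"

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    def to_coordinates(self) -> np.ndarray:
        """Sparse (i, j) coordinate list of recurrence points."""
        return np.argwhere(self.matrix)


@dataclass
class PoincareSection:
    """Plane crossings of a 3-d embedded trajectory, ordered by time."""

    points: np.ndarray  # shape (k, m-1)
    coordinate: int
    crossing_value: float
    direction: str
    empty_flag: bool = False

    def __len__(self) -> int:
        return int(self.points.shape[0])


_NORMS = {
    "euclidean": "euclidean",
    "max": "chebyshev",
    "chebyshev": "chebyshev",
}


def recurrence_matrix(traj: EmbeddedTrajectory, eps: float = 1.0,
                      norm: str = "euclidean",
                      eps_mode: str = "absolute") -> RecurrenceMatrix:
    """Recurrence matrix R[i,j] = 1 iff ||y_i - y_j|| <= eps.

    ``eps_mode='quantile'`` reinterprets ``eps`` as a fraction in (0, 1] and
    sets the threshold at that quantile of the pairwise distances — useful
    because an absolute threshold of 1 abundance unit is scale-sensitive
    across treatments.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    vec = traj.vectors
    if vec.shape[0] == 0:
        raise ValueError("empty trajectory")
    d = pdist(vec, metric=_NORMS[norm])
    if eps_mode == "quantile":
        if eps > 1:
            raise ValueError("quantile eps must lie in (0, 1]")
        eps = float(np.quantile(d, eps)) if d.size else 0.0
        eps = max(eps, np.finfo(float).tiny)
    elif eps_mode != "absolute":
        raise ValueError(f"unknown eps_mode {eps_mode!r}")
    mat = squareform(d <= eps)
    np.fill_diagonal(mat, True)
    return RecurrenceMatrix(mat.astype(bool), float(eps), norm)


def determinism_score(rm: RecurrenceMatrix, l_min: int = 2) -> float:
    """RQA determinism: fraction of off-diagonal recurrence points on
    diagonal segments of length >= ``l_min``.

    The main diagonal (trivial self-recurrence) is excluded from both
    numerator and denominator. An empty off-diagonal recurrence set yields
    0 with a warning.
    """
    if l_min < 1:
        raise ValueError("l_min must be >= 1")
    m = rm.matrix
    n = m.shape[0]
    total = 0
    on_lines = 0
    for k in range(1, n):
        diag = np.diagonal(m, offset=k)
        c = int(diag.sum())
        if c == 0:
            continue
        total += 2 * c  # matrix is symmetric: offsets ±k
        on_lines += 2 * _points_on_runs(diag, l_min)
    if total == 0:
        warnings.warn("no off-diagonal recurrence points; DET undefined, returning 0")
        return 0.0
    return on_lines / total


def _points_on_runs(diag: np.ndarray, l_min: int) -> int:
    """Number of True entries belonging to runs of length >= l_min."""
    padded = np.concatenate([[0], diag.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    return int(lengths[lengths >= l_min].sum())


def poincare_section(traj: EmbeddedTrajectory, coordinate: int = 0,
                     crossing_value: float | None = None,
                     direction: str = "up") -> PoincareSection:
    """Crossings of the hyper-plane {y[coordinate] = crossing_value}.

    The plane defaults to the median of the chosen coordinate so it cuts
    the attractor transversally. For each consecutive vector pair that
    straddles the plane in the requested direction the remaining
    coordinates are linearly interpolated to the crossing instant. An empty
    section is legal and flagged.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    vec = traj.vectors
    if vec.shape[0] < 2:
        raise ValueError("need at least two trajectory points")
    if not (0 <= coordinate < vec.shape[1]):
        raise ValueError("coordinate index out of range")
    c = float(np.median(vec[:, coordinate])) if crossing_value is None else float(crossing_value)
    g = vec[:, coordinate] - c
    g0, g1 = g[:-1], g[1:]
    up = (g0 < 0) & (g1 >= 0)
    down = (g0 > 0) & (g1 <= 0)
    cross = {"up": up, "down": down, "both": up | down}[direction]
    idx = np.flatnonzero(cross)
    if idx.size == 0:
        other = np.delete(np.arange(vec.shape[1]), coordinate)
        return PoincareSection(np.empty((0, other.size)), coordinate, c,
                               direction, empty_flag=True)
    t = g0[idx] / (g0[idx] - g1[idx])  # linear interpolation in time
    interp = vec[idx] + t[:, None] * (vec[idx + 1] - vec[idx])
    other = np.delete(np.arange(vec.shape[1]), coordinate)
    return PoincareSection(interp[:, other], coordinate, c, direction)
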