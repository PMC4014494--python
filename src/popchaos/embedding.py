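"""Transient removal, autocorrelation and time-delay embedding.

Phase-space reconstruction from a scalar observable follows Takens'
theorem: lagged copies ``y(n) = [x(n), x(n+d), ..., x(n+(m-1)d)]`` span a
space in which the attractor of the underlying dynamics can be unfolded.
``scan_embedding`` reports the standard heuristics (ACF decay delays,
false-nearest-neighbour fractions) for choosing ``(m, d)``; the analysis
pipeline itself fixes m=2, d=1 for scalar work and m=3 for sections.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KDTree
from statsmodels.tsa.stattools import acf as _sm_acf

from .config import AnalysisParams


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension ``m`` and delay ``d`` (in samples)."""

    m: int = 2
    d: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.d < 1:
            raise ValueError("need m >= 1 and d >= 1")

    @property
    def window(self) -> int:
        """Span of one delay vector in samples: (m-1)*d."""
        return (self.m - 1) * self.d


@dataclass
class EmbeddedTrajectory:
    """Delay-coordinate vectors of one scalar series."""

    vectors: np.ndarray  # shape (n_vectors, m)
    params: EmbeddingParams
    source_id: str = ""

    def __len__(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def m(self) -> int:
        return self.params.m

    @property
    def d(self) -> int:
        return self.params.d


def drop_transient(series, n_cut: int = 50) -> np.ndarray:
    """Remove the first ``n_cut`` samples (transient dynamics)."""
    x = np.asarray(series)
    if n_cut < 0:
        raise ValueError("n_cut must be >= 0")
    if x.size <= n_cut:
        raise ValueError(
            f"series of length {x.size} leaves nothing after cutting {n_cut} samples"
        )
    return x[n_cut:]


def autocorrelation(series, max_lag: int) -> np.ndarray:
    """Biased sample ACF r(0..max_lag); r(0)=1 and |r(k)| <= 1.

    Uses the 1/N normalisation (``adjusted=False``), which guarantees the
    boundedness at the price of a small shrinkage at large lags.
    """
    x = np.asarray(series, dtype=float)
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the series length")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("constant series has undefined autocorrelation")
    return _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)


def delay_embed(series, params: EmbeddingParams | None = None,
                source_id: str = "") -> EmbeddedTrajectory:
    """Takens delay embedding; returns N-(m-1)d vectors, no padding."""
    if params is None:
        params = EmbeddingParams()
    x = np.asarray(series, dtype=float)
    n_vec = x.size - params.window
    if n_vec < 1:
        raise ValueError(
            f"series of length {x.size} too short for m={params.m}, d={params.d}"
        )
    idx = np.arange(n_vec)[:, None] + np.arange(params.m)[None, :] * params.d
    return EmbeddedTrajectory(x[idx], params, source_id)


def recommend_delay(series, max_lag: int | None = None) -> dict:
    """Delay heuristics from the ACF: first zero crossing and 1/e decay lag."""
    x = np.asarray(series, dtype=float)
    if max_lag is None:
        max_lag = min(x.size - 1, max(10, x.size // 4))
    r = autocorrelation(x, max_lag)
    nonpos = np.flatnonzero(r[1:] <= 0)
    zero_crossing = int(nonpos[0] + 1) if nonpos.size else int(max_lag)
    below_e = np.flatnonzero(r[1:] < 1.0 / np.e)
    e_folding = int(below_e[0] + 1) if below_e.size else int(max_lag)
    return {"zero_crossing": zero_crossing, "e_folding": e_folding,
            "recommended": min(zero_crossing, max(e_folding, 1))}


def false_nearest_fraction(series, m: int, d: int, ratio: float = 10.0) -> float:
    """Kennel false-nearest-neighbour fraction for embedding dimension ``m``.

    A neighbour in m dimensions is false when adding the (m+1)-th delay
    coordinate stretches the pair by more than ``ratio``.
    """
    x = np.asarray(series, dtype=float)
    n_vec = x.size - m * d  # need the (m+1)-th coordinate too
    if n_vec < 2:
        raise ValueError("series too short for FNN at this (m, d)")
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * d
    emb = x[idx]
    tree = KDTree(emb)
    dist, nbr = tree.query(emb, k=2)
    nbr = nbr[:, 1]
    dist = dist[:, 1]
    extra = np.abs(x[np.arange(n_vec) + m * d] - x[nbr + m * d])
    valid = dist > 0
    if not np.any(valid):
        return 0.0
    return float(np.mean(extra[valid] / dist[valid] > ratio))


def scan_embedding(series, m_candidates=(1, 2, 3, 4, 5),
                   d_candidates=(1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Rank candidate (m, d) pairs by FNN fraction; ties to smaller m then d.

    Advisory only: the report also carries the ACF delay heuristics so a
    user can judge the trade-off, but the pipeline's published defaults are
    not altered by it.
    """
    m_candidates = tuple(m_candidates)
    d_candidates = tuple(d_candidates)
    if not m_candidates or not d_candidates:
        raise ValueError("candidate sets must be non-empty")
    hints = recommend_delay(series)
    rows = []
    for m in m_candidates:
        for d in d_candidates:
            try:
                fnn = false_nearest_fraction(series, m, d)
            except ValueError:
                continue
            rows.append({"m": m, "d": d, "fnn_fraction": fnn,
                         "acf_zero_crossing": hints["zero_crossing"],
                         "acf_e_folding": hints["e_folding"]})
    if not rows:
        raise ValueError("no candidate pair fits the series length")
    df = pd.DataFrame(rows)
    df["score"] = df["fnn_fraction"]
    df = df.sort_values(["score", "m", "d"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
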