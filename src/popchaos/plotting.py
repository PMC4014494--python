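"""Optional diagnostic figures (abundance series, phase portraits,
recurrence plots, Poincaré sections, λ boxplots). Numeric artifacts are the
contract; these are conveniences behind the pipeline's --plots flag."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .embedding import EmbeddingParams, delay_embed, drop_transient
from .geometry import poincare_section, recurrence_matrix


def plot_series(series, ax=None):
    ax = ax or plt.gca()
    ax.plot(series.day, series.total, lw=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("abundance")
    ax.set_title(f"c = {series.concentration:g} µg/l, run {series.run}")
    return ax


def plot_phase_portrait(x, m=2, d=1, ax=None):
    traj = delay_embed(np.asarray(x, float), EmbeddingParams(m, d))
    ax = ax or plt.gca()
    ax.plot(traj.vectors[:, 0], traj.vectors[:, -1], ".", ms=2)
    ax.set_xlabel("x(n)")
    ax.set_ylabel(f"x(n+{(m - 1) * d})")
    return ax


def plot_recurrence(x, m=2, d=1, eps=1.0, ax=None):
    rm = recurrence_matrix(delay_embed(np.asarray(x, float),
                                       EmbeddingParams(m, d)), eps)
    ax = ax or plt.gca()
    ij = rm.to_coordinates()
    ax.plot(ij[:, 1], ij[:, 0], ",k")
    ax.set_aspect("equal")
    ax.set_xlabel("j")
    ax.set_ylabel("i")
    return ax


def plot_poincare(x, d=1, ax=None):
    sec = poincare_section(delay_embed(np.asarray(x, float),
                                       EmbeddingParams(3, d)))
    ax = ax or plt.gca()
    if len(sec):
        ax.plot(sec.points[:, 0], sec.points[:, 1], ".", ms=3)
    ax.set_xlabel("u")
    ax.set_ylabel("v")
    return ax


def plot_lambda_boxplots(table, age_class="total", ax=None):
    sub = table[table["age_class"] == age_class]
    panel = sorted(sub["concentration"].unique())
    data = [sub[sub["concentration"] == c]["lam"].to_numpy() for c in panel]
    ax = ax or plt.gca()
    ax.boxplot(data, tick_labels=[f"{c:g}" for c in panel])
    ax.set_xlabel("concentration (µg/l)")
    ax.set_ylabel("maximal Lyapunov exponent (1/day)")
    return ax


def save_overview(bundle, out_path, example_series=None):
    """One-page overview figure for a result bundle."""
    fig, axes = plt.subplots(1, 2 if example_series is None else 3,
                             figsize=(11, 3.5))
    axes = np.atleast_1d(axes)
    k = 0
    if example_series is not None:
        plot_series(example_series, axes[k]); k += 1
    plot_lambda_boxplots(bundle.lyapunov_table, ax=axes[k]); k += 1
    th = bundle.results.thresholds.get("total")
    txt = bundle.results.summary_table.to_string(index=False)
    axes[k].axis("off")
    axes[k].text(0.0, 0.95, txt, family="monospace", fontsize=6, va="top")
    if th is not None:
        where = "none" if th.threshold is None else f"{th.threshold:g} µg/l"
        axes[k].set_title(f"threshold: {where}", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
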