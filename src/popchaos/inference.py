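"""Distributional statistics over per-run Lyapunov exponents.

One λ per (concentration, age class, run) forms the Lyapunov table. Runs
at different concentrations share their seed, so the design is paired by
run index and each treatment is compared against control (and every other
treatment) with the Wilcoxon signed-rank test. The lowest concentration
whose λ distribution differs significantly from control is reported as the
disturbance threshold: the concentration at which the stressor measurably
suppresses the chaotic component of the dynamics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

SERIES_TYPES = ("neonates", "juveniles", "adults", "total")

#: Columns of a Lyapunov table.
TABLE_COLUMNS = ("concentration", "age_class", "run", "lam", "flagged")


def make_lyapunov_table(records) -> pd.DataFrame:
    """Normalise an iterable of record dicts into a Lyapunov table."""
    df = pd.DataFrame(list(records))
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if "flagged" in missing:
        df["flagged"] = False
        missing.discard("flagged")
    if missing:
        raise ValueError(f"missing Lyapunov-table columns: {sorted(missing)}")
    dup = df.duplicated(subset=["concentration", "age_class", "run"])
    if dup.any():
        raise ValueError("duplicate (concentration, age_class, run) records")
    return df[list(TABLE_COLUMNS)]


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample sd (n-1) of λ per (concentration, age class).

    Flagged-invalid estimates are excluded; every remaining cell needs at
    least two records for the sd to exist.
    """
    valid = table[~table["flagged"].astype(bool)]
    rows = []
    for (conc, ac), grp in valid.groupby(["concentration", "age_class"], sort=True):
        lam = grp["lam"].to_numpy(dtype=float)
        if lam.size < 2:
            raise ValueError(
                f"cell (c={conc}, {ac}) has {lam.size} valid record(s); "
                "need >= 2 for a standard deviation"
            )
        rows.append({"concentration": conc, "age_class": ac,
                     "mean": float(lam.mean()), "sd": float(lam.std(ddof=1)),
                     "n": int(lam.size)})
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(a, b, two_sided: bool = True) -> float:
    """Paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking. The exact null
    distribution is enumerated when n <= 25 with no ties among the absolute
    differences; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size == 0:
        raise ValueError("no paired observations")
    diff = a - b
    diff = diff[diff != 0]
    if diff.size == 0:
        raise ValueError("all paired differences are zero: degenerate test")
    if diff.size < 3:
        raise ValueError("need >= 3 nonzero paired differences")
    has_ties = np.unique(np.abs(diff)).size < diff.size
    method = "exact" if (diff.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(diff, alternative="two-sided" if two_sided else "greater",
                         correction=(method == "approx"), method=method)
    return float(res.pvalue)


def rank_sum_test(a, b, two_sided: bool = True) -> float:
    """Unpaired fallback (Mann-Whitney U) for ensembles without aligned
    run indices; exact for small samples without ties, otherwise the
    tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per sample")
    res = stats.mannwhitneyu(a, b,
                             alternative="two-sided" if two_sided else "greater")
    return float(res.pvalue)


@dataclass
class PairwiseTestMatrix:
    """Upper-triangular Wilcoxon p-values over an ordered concentration panel."""

    panel: tuple[float, ...]
    age_class: str
    pvalues: pd.DataFrame  # square, NaN below diagonal and on it
    n_pairs: pd.DataFrame
    alpha: float = 0.05
    pairing: str = "run_index"

    def p(self, c_a: float, c_b: float) -> float:
        lo, hi = sorted((c_a, c_b))
        return float(self.pvalues.loc[lo, hi])


def pairwise_tests(table: pd.DataFrame, age_class: str = "total",
                   alpha: float = 0.05, exclude_flagged: bool = True,
                   holm: bool = False) -> PairwiseTestMatrix:
    """All unordered concentration pairs, paired by run index.

    Flagged runs are removed pairwise (a run missing at either
    concentration drops from that comparison). Raw p-values by default;
    ``holm=True`` applies the Holm step-down adjustment.
    """
    sub = table[table["age_class"] == age_class]
    if sub.empty:
        raise ValueError(f"no records for age class {age_class!r}")
    panel = tuple(sorted(sub["concentration"].unique()))
    pv = pd.DataFrame(np.nan, index=panel, columns=panel)
    np_ = pd.DataFrame(0, index=panel, columns=panel)
    by_conc = {}
    for c in panel:
        g = sub[sub["concentration"] == c].set_index("run")
        if exclude_flagged:
            g = g[~g["flagged"].astype(bool)]
        by_conc[c] = g["lam"]
    cells = []
    for ca, cb in combinations(panel, 2):
        runs = by_conc[ca].index.intersection(by_conc[cb].index)
        a = by_conc[ca].loc[runs].to_numpy()
        b = by_conc[cb].loc[runs].to_numpy()
        try:
            p = wilcoxon_signed_rank(a, b)
        except ValueError as err:
            warnings.warn(f"pair ({ca}, {cb}): degenerate test ({err})")
            p = np.nan
        cells.append((ca, cb, p, len(runs)))
    if holm:
        ps = np.array([c[2] for c in cells])
        ok = ~np.isnan(ps)
        adj = np.full_like(ps, np.nan)
        if ok.any():
            order = np.argsort(ps[ok])
            m = int(ok.sum())
            stepped = np.maximum.accumulate(
                (m - np.arange(m)) * ps[ok][order]
            ).clip(max=1.0)
            tmp = np.empty(m)
            tmp[order] = stepped
            adj[ok] = tmp
        cells = [(ca, cb, padj, n) for (ca, cb, _, n), padj in zip(cells, adj)]
    for ca, cb, p, n in cells:
        pv.loc[ca, cb] = p
        np_.loc[ca, cb] = n
    return PairwiseTestMatrix(panel, age_class, pv, np_, alpha)


@dataclass
class ThresholdResult:
    """Lowest concentration significantly different from control, if any."""

    age_class: str
    threshold: float | None
    alpha: float
    control: float
    p_vs_control: dict[float, float] = field(default_factory=dict)

    @property
    def detected(self) -> bool:
        return self.threshold is not None


def detect_threshold(matrix: PairwiseTestMatrix, alpha: float = 0.05) -> ThresholdResult:
    """Lowest non-control concentration with p(control, c) < alpha.

    The control is the smallest panel member (normally 0). Returns a
    ``threshold`` of None when no treatment separates from control.
    """
    panel = matrix.panel
    control = panel[0]
    pmap = {}
    threshold = None
    for c in panel[1:]:
        p = matrix.p(control, c)
        pmap[c] = p
        if threshold is None and np.isfinite(p) and p < alpha:
            threshold = c
    return ThresholdResult(matrix.age_class, threshold, alpha, control, pmap)


class ThresholdAnalysis:
    """Model object: full distributional inference over a Lyapunov table.

    ``fit()`` produces per-age-class treatment summaries, pairwise
    signed-rank matrices and disturbance thresholds in one Results object.
    """

    def __init__(self, table: pd.DataFrame, alpha: float = 0.05,
                 exclude_flagged: bool = True, holm: bool = False):
        self.table = make_lyapunov_table(table.to_dict("records")) \
            if isinstance(table, pd.DataFrame) else make_lyapunov_table(table)
        self.alpha = alpha
        self.exclude_flagged = exclude_flagged
        self.holm = holm

    def fit(self) -> "ThresholdResults":
        summary = summarize(self.table)
        matrices, thresholds = {}, {}
        for ac in sorted(self.table["age_class"].unique()):
            m = pairwise_tests(self.table, ac, self.alpha,
                               self.exclude_flagged, self.holm)
            matrices[ac] = m
            thresholds[ac] = detect_threshold(m, self.alpha)
        return ThresholdResults(summary, matrices, thresholds, self.alpha)


@dataclass
class ThresholdResults:
    """Results of `ThresholdAnalysis.fit`."""

    summary_table: pd.DataFrame
    pairwise: dict[str, PairwiseTestMatrix]
    thresholds: dict[str, ThresholdResult]
    alpha: float

    def summary(self) -> str:
        lines = ["Lyapunov ensemble inference", "=" * 60,
                 self.summary_table.to_string(index=False), "-" * 60]
        for ac, th in sorted(self.thresholds.items()):
            where = "none" if th.threshold is None else f"{th.threshold:g} µg/l"
            lines.append(f"threshold [{ac:<9}] (alpha={self.alpha:g}): {where}")
        return "\n".join(lines)
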