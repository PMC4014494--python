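"""Tests for ensemble summaries, signed-rank testing and threshold detection."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from popchaos import (ThresholdAnalysis, detect_threshold, make_lyapunov_table,
                      pairwise_tests, summarize, wilcoxon_signed_rank)
from popchaos.inference import rank_sum_test


def brute_force_signed_rank_p(diffs) -> float:
    """Independent oracle: enumerate all 2^n sign assignments of |d| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((False, True), repeat=d.size):
        ws.append(ranks[np.array(signs)].sum())
    ws = np.array(ws)
    p = 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


def _table(panel, lam_by_conc, age_class="total"):
    records = []
    for c in panel:
        for i, lam in enumerate(lam_by_conc[c]):
            records.append({"concentration": c, "age_class": age_class,
                            "run": i, "lam": lam, "flagged": False})
    return make_lyapunov_table(records)


class TestSummarize:
    def test_constant_cell(self):
        t = _table((0.0,), {0.0: [0.5, 0.5, 0.5]})
        row = summarize(t).iloc[0]
        assert row["mean"] == 0.5 and row["sd"] == 0.0 and row["n"] == 3

    def test_hand_computed_sd(self):
        t = _table((0.0,), {0.0: [0.2, 0.4]})
        row = summarize(t).iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(0.1414, abs=2e-4)

    def test_single_record_cell_rejected(self):
        t = _table((0.0,), {0.0: [0.2]})
        with pytest.raises(ValueError):
            summarize(t)

    def test_flagged_records_excluded(self):
        t = _table((0.0,), {0.0: [0.1, 0.2, 0.3]})
        t.loc[2, "flagged"] = True
        row = summarize(t).iloc[0]
        assert row["n"] == 2 and row["mean"] == pytest.approx(0.15)


class TestWilcoxonSignedRank:
    def test_three_positive_differences(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [0, 0, 0]) == pytest.approx(0.25)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_antisymmetric_differences_balanced(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a - np.array([0.5, -0.5, 1.5, -1.5])
        p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(brute_force_signed_rank_p([0.5, -0.5, 1.5, -1.5]),
                                  abs=1e-9)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_p_matches_enumeration(self, n, rng):
        """Randomised property: exact path equals brute-force enumeration."""
        for _ in range(25):
            d = rng.normal(0.2, 1.0, size=n)  # continuous → no ties a.s.
            p_pkg = wilcoxon_signed_rank(d, np.zeros(n))
            assert p_pkg == pytest.approx(brute_force_signed_rank_p(d), abs=1e-9)

    def test_unpaired_fallback_detects_shift(self, rng):
        a = rng.normal(0.5, 0.05, size=40)
        b = rng.normal(0.3, 0.05, size=35)  # unaligned sizes
        assert rank_sum_test(a, b) < 1e-6
        assert rank_sum_test(a, a) == pytest.approx(1.0, abs=0.1)

    def test_power_increases_with_shift(self, rng):
        n, reps = 100, 120
        rates = []
        for shift in (0.0, 0.02, 0.2):
            hits = 0
            for _ in range(reps):
                base = rng.normal(0, 0.05, size=n)
                hits += wilcoxon_signed_rank(base + shift,
                                             rng.normal(0, 0.05, size=n)) < 0.05
            rates.append(hits / reps)
        assert rates[0] < rates[1] <= rates[2]


class TestPairwiseTests:
    def test_panel_pair_count(self, rng):
        panel = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0)
        lam = {c: list(rng.normal(0.4, 0.05, size=12)) for c in panel}
        m = pairwise_tests(_table(panel, lam))
        finite = np.isfinite(m.pvalues.to_numpy()).sum()
        assert finite == 15  # C(6,2)

    def test_identical_vectors_flag_degenerate(self):
        lam = [0.4, 0.41, 0.39, 0.42]
        t = _table((0.0, 5.0), {0.0: lam, 5.0: lam})
        with pytest.warns(UserWarning, match="degenerate"):
            m = pairwise_tests(t)
        assert np.isnan(m.p(0.0, 5.0))

    def test_large_shift_detected_everywhere(self, rng):
        panel = (0.0, 5.0, 40.0)
        base = rng.normal(0.5, 0.05, size=100)
        lam = {0.0: base, 5.0: base + rng.normal(0, 0.01, 100),
               40.0: base - 0.2 + rng.normal(0, 0.01, 100)}
        m = pairwise_tests(_table(panel, {c: list(v) for c, v in lam.items()}))
        assert m.p(0.0, 40.0) < 1e-6 and m.p(5.0, 40.0) < 1e-6

    def test_holm_adjustment_never_smaller(self, rng):
        panel = (0.0, 5.0, 40.0)
        lam = {c: list(rng.normal(0.4 - 0.002 * c, 0.05, size=30)) for c in panel}
        t = _table(panel, lam)
        raw = pairwise_tests(t, holm=False)
        adj = pairwise_tests(t, holm=True)
        for a, b in itertools.combinations(panel, 2):
            assert adj.p(a, b) >= raw.p(a, b) - 1e-12

    def test_flagged_runs_dropped_pairwise(self, rng):
        panel = (0.0, 5.0)
        lam = {c: list(rng.normal(0.4, 0.05, size=20)) for c in panel}
        t = _table(panel, lam)
        t.loc[(t["concentration"] == 0.0) & (t["run"] < 5), "flagged"] = True
        m = pairwise_tests(t)
        assert int(m.n_pairs.loc[0.0, 5.0]) == 15


class TestDetectThreshold:
    def _matrix(self, pmap, alpha=0.05):
        panel = (0.0,) + tuple(sorted(pmap))
        lam = {c: None for c in panel}
        pv = pd.DataFrame(np.nan, index=panel, columns=panel)
        npairs = pd.DataFrame(0, index=panel, columns=panel)
        for c, p in pmap.items():
            pv.loc[0.0, c] = p
        from popchaos.inference import PairwiseTestMatrix
        return PairwiseTestMatrix(panel, "total", pv, npairs, alpha)

    def test_no_significant_pair(self):
        res = detect_threshold(self._matrix({2.5: 0.3, 5.0: 0.6, 40.0: 0.08}))
        assert res.threshold is None and not res.detected

    def test_only_highest_significant(self):
        res = detect_threshold(self._matrix({2.5: 0.3, 5.0: 0.6, 40.0: 0.001}))
        assert res.threshold == 40.0

    def test_all_significant_returns_lowest(self):
        res = detect_threshold(self._matrix({2.5: 0.01, 5.0: 0.001, 40.0: 1e-9}))
        assert res.threshold == 2.5

    def test_monotone_in_alpha(self):
        m = self._matrix({2.5: 0.04, 5.0: 0.001, 40.0: 1e-9})
        loose = detect_threshold(m, alpha=0.05).threshold
        strict = detect_threshold(m, alpha=0.01).threshold
        assert strict >= loose


class TestThresholdAnalysis:
    def test_end_to_end_summary(self, rng):
        panel = (0.0, 5.0, 40.0)
        base = rng.normal(0.5, 0.05, size=40)
        lam = {0.0: base, 5.0: base + rng.normal(0, 0.02, 40),
               40.0: base - 0.25}
        res = ThresholdAnalysis(_table(panel, {c: list(v) for c, v in
                                               lam.items()})).fit()
        assert res.thresholds["total"].threshold == 40.0
        text = res.summary()
        assert "threshold" in text and "40" in text
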