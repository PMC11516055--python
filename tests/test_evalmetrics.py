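"""Scoring/ranking metrics against brute-force oracles and worked examples."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dynabind.evalmetrics import (
    UndefinedMetricError, casf_report, kendall_tau, pearson_r,
    predictive_index, rmse_and_sd, spearman_rho,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))


def rank_average_ties(v):
    v = np.asarray(v, float)
    ranks = np.empty(len(v))
    order = np.argsort(v, kind="stable")
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based positions
        i = j
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(rank_average_ties(x), rank_average_ties(y))


def kendall_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    C = D = T = U = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue  # tied in both: excluded from T and U alike
            if dx == 0:
                T += 1
            elif dy == 0:
                U += 1
            elif np.sign(dx) == np.sign(dy):
                C += 1
            else:
                D += 1
    return (C - D) / np.sqrt((C + D + T) * (C + D + U))


def pi_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    num = den = 0.0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            w = abs(y[i] - y[j])
            s = 1.0 if np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]) > 0 else 0.0
            num += w * s
            den += w
    return num / den


def sd_oracle(y_true, y_pred):
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    b, a = np.polyfit(y_pred, y_true, 1)
    resid = y_true - (a + b * y_pred)
    return float(np.sqrt(np.sum(resid ** 2) / (len(y_true) - 1)))


# ---------------------------------------------------------------------------


class TestWorkedExamples:
    def test_pearson_values(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        assert pearson_r(x, [1, 2, 4]) == pytest.approx(pearson_oracle(x, [1, 2, 4]), abs=1e-12)
        assert pearson_r(x, [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_rmse_and_sd_values(self):
        rmse, sd = rmse_and_sd([1.0, 2.0], [1.0, 2.0])
        assert rmse == 0.0
        assert sd == pytest.approx(0.0, abs=1e-12)
        rmse, _ = rmse_and_sd([1.0, 2.0], [2.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(2.5), abs=1e-12)
        # a constant shift is absorbed by the regression line
        y = np.array([1.0, 2.0, 3.5, 5.0])
        rmse, sd = rmse_and_sd(y, y + 1.0)
        assert rmse == pytest.approx(1.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_spearman_values(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        x = np.array([0.3, 1.1, 2.0, 5.5])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_kendall_values(self):
        assert kendall_tau([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3, abs=1e-12)
        assert kendall_tau([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        # tie in x: T=1, U=0 -> 2 / sqrt(6)
        assert kendall_tau([1, 1, 2], [1, 2, 3]) == pytest.approx(2 / np.sqrt(6), abs=1e-12)

    def test_predictive_index_values(self):
        assert predictive_index([1.0, 2.0, 3.0], [4.0, 5.0, 9.0]) == pytest.approx(1.0)
        assert predictive_index([0.5, 0.6, 0.2], [1.0, 2.0, 4.0]) == pytest.approx(1 / 6, abs=1e-12)
        # fully reversed: every weighted pair scores 0 under the {1, 0} form
        assert predictive_index([3.0, 2.0, 1.0], [1.0, 2.0, 4.0]) == 0.0
        # the {1, -1} variant gives -1 for the fully reversed ordering
        assert predictive_index([3.0, 2.0, 1.0], [1.0, 2.0, 4.0],
                                discordant_value=-1.0) == pytest.approx(-1.0)


class TestErrors:
    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedMetricError):
            spearman_rho([2.0, 2.0], [1.0, 2.0])
        with pytest.raises(UndefinedMetricError):
            kendall_tau([2.0, 2.0], [1.0, 2.0])
        with pytest.raises(UndefinedMetricError):
            predictive_index([1.0, 2.0], [3.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_and_sd([1.0, 2.0], [1.0, 2.0, 3.0])


def random_vectors_with_ties(n_vectors: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    for _ in range(n_vectors):
        n = int(rng.integers(3, 21))
        if rng.random() < 0.5:  # induce ties by quantization
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
        else:
            x = rng.normal(size=n)
            y = rng.normal(size=n)
        yield x, y


class TestOracleEquivalence:
    """Implementations agree with brute-force pair enumeration to 1e-10."""

    def test_all_metrics_match_oracles(self):
        checked = {"pearson": 0, "spearman": 0, "kendall": 0, "pi": 0, "sd": 0}
        for x, y in random_vectors_with_ties(1000, seed=123):
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-10)
                assert spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-10)
                assert kendall_tau(x, y) == pytest.approx(kendall_oracle(x, y), abs=1e-10)
                checked["pearson"] += 1
                checked["spearman"] += 1
                checked["kendall"] += 1
            if np.ptp(y) > 0:
                assert predictive_index(x, y) == pytest.approx(pi_oracle(x, y), abs=1e-10)
                checked["pi"] += 1
            if np.ptp(x) > 0:
                rmse, sd = rmse_and_sd(y, x)
                assert rmse == pytest.approx(float(np.sqrt(np.mean((y - x) ** 2))), abs=1e-10)
                assert sd == pytest.approx(sd_oracle(y, x), abs=1e-10)
                checked["sd"] += 1
        assert min(checked.values()) > 300  # the sweep actually exercised everything

    def test_bounds_and_sign_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            x, y = rng.normal(size=n), rng.normal(size=n)
            tau = kendall_tau(x, y)
            rho = spearman_rho(x, y)
            assert -1 <= tau <= 1 and -1 <= rho <= 1
            pi = predictive_index(x, y)
            assert 0 <= pi <= 1


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=3, max_size=15),
           st.lists(st.integers(min_value=0, max_value=6), min_size=3, max_size=15))
    def test_rank_metrics_bounded_and_oracle_consistent(xs, ys):
        """tau and rho stay in [-1, 1] and match pair enumeration, ties included."""
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float)
        y = np.array(ys[:n], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        tau = kendall_tau(x, y)
        rho = spearman_rho(x, y)
        assert -1 <= tau <= 1 and -1 <= rho <= 1
        assert tau == pytest.approx(kendall_oracle(x, y), abs=1e-10)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-10)
except ImportError:  # hypothesis is an optional test dependency
    pass


class TestCasfReport:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["complex_id", "target_id", "y_true", "y_pred"])

    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        rows = [(f"c{i}", f"t{i // 5}", v, v)
                for i, v in enumerate(rng.uniform(2, 11, size=25))]
        rep = casf_report(self._table(rows))
        assert rep.pearson == pytest.approx(1.0)
        assert rep.rmse == 0.0 and rep.sd == pytest.approx(0.0, abs=1e-9)
        assert rep.spearman_mean == pytest.approx(1.0)
        assert rep.kendall_mean == pytest.approx(1.0)
        assert rep.pi_mean == pytest.approx(1.0)
        assert rep.n_targets == 5 and rep.n_complexes == 25

    def test_intra_target_ranking_vs_pooled_scoring(self):
        """Per-target order perfect, inter-target scale scrambled: ranking
        means stay 1 while the pooled Pearson drops below 1."""
        rows = []
        for t, (scale, shift) in enumerate([(1.0, 0.0), (-2.0, 20.0)]):
            for k in range(5):
                y = 4.0 + k
                rows.append((f"c{t}_{k}", f"t{t}", y, scale * y + shift))
        rep = casf_report(self._table(rows))
        assert rep.spearman_mean == pytest.approx(abs(rep.spearman_mean))
        # target 1 has a negative within-target slope, so flip it for "correct"
        rows = []
        for t in range(2):
            for k in range(5):
                y = 4.0 + k
                pred = y if t == 0 else 0.1 * y - 3.0  # order kept, scale scrambled
                rows.append((f"c{t}_{k}", f"t{t}", y, pred))
        rep = casf_report(self._table(rows))
        assert rep.spearman_mean == pytest.approx(1.0)
        assert rep.kendall_mean == pytest.approx(1.0)
        assert rep.pi_mean == pytest.approx(1.0)
        assert rep.pearson < 1.0 - 1e-6

    def test_single_target(self):
        rows = [(f"c{k}", "t0", 4.0 + k, 4.0 + k + 0.1 * (-1) ** k) for k in range(5)]
        rep = casf_report(self._table(rows))
        assert rep.n_targets == 1
        assert rep.spearman_mean == pytest.approx(
            spearman_rho([r[3] for r in rows], [r[2] for r in rows]))

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = [(f"c{i}", f"t{i // 5}", float(rng.uniform(2, 11)), float(rng.uniform(2, 11)))
                for i in range(20)]
        rep1 = casf_report(self._table(rows))
        rep2 = casf_report(self._table(rows[::-1]))
        assert rep1.pearson == pytest.approx(rep2.pearson, abs=1e-12)
        assert rep1.spearman_mean == pytest.approx(rep2.spearman_mean, abs=1e-12)
        assert rep1.pi_mean == pytest.approx(rep2.pi_mean, abs=1e-12)

    def test_degenerate_target_skipped_with_warning(self):
        rows = [("c0", "t0", 5.0, 6.0), ("c1", "t0", 5.0, 7.0),  # all-tied y_true
                ("c2", "t1", 4.0, 4.1), ("c3", "t1", 6.0, 5.9), ("c4", "t1", 8.0, 8.2)]
        with pytest.warns(UserWarning):
            rep = casf_report(self._table(rows))
        assert rep.n_targets == 2
        assert np.isfinite(rep.spearman_mean)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            casf_report(self._table([]))
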