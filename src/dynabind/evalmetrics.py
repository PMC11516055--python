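"""CASF-style scoring and ranking metrics.

Scoring power (inter-target): Pearson r, RMSE, and SD — the standard
deviation of the residuals about the least-squares regression line of the
measured affinities on the predictions, per the CASF convention. Ranking
power (intra-target): Spearman rho, tie-corrected Kendall tau, and the
predictive index (PI), computed per protein target and arithmetically
averaged over targets. Affinities are on the pKi scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedMetricError",
    "pearson_r",
    "rmse_and_sd",
    "spearman_rho",
    "kendall_tau",
    "predictive_index",
    "MetricReport",
    "casf_report",
]


class UndefinedMetricError(ValueError):
    """A metric's preconditions (variance, untied pairs ...) are not met."""


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected equal-length 1-D sequences, got {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Linear correlation coefficient."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Pearson r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def rmse_and_sd(y_true: Sequence[float], y_pred: Sequence[float]) -> tuple[float, float]:
    """Root-mean-square error and the CASF regression-residual SD.

    SD fits the least-squares line y_true ~ a + b * y_pred and reports
    sqrt(sum((y_true - (a + b * y_pred))^2) / (N - 1)); a constant offset in
    the predictions therefore inflates RMSE but not SD.
    """
    y_true, y_pred = _check_xy(y_true, y_pred)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_pred) == 0:
        resid = y_true - np.mean(y_true)
    else:
        b, a = np.polyfit(y_pred, y_true, 1)
        resid = y_true - (a + b * y_pred)
    sd = float(np.sqrt(np.sum(resid ** 2) / (len(y_true) - 1)))
    return rmse, sd


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation (Pearson r of average ranks)."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Spearman rho undefined for all-tied input")
    return float(stats.spearmanr(x, y).statistic)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall tau.

    (C - D) / sqrt((C + D + T)(C + D + U)) with C/D the concordant and
    discordant pair counts and T/U the pairs tied only in x / only in y.
    Delegates to scipy's tau-b, which computes exactly this form.
    """
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Kendall tau undefined for all-tied input")
    return float(stats.kendalltau(x, y).statistic)


def predictive_index(x: Sequence[float], y: Sequence[float],
                     discordant_value: float = 0.0) -> float:
    """Affinity-difference-weighted ranking agreement.

    PI = sum_{j>i} w_ij S_ij / sum_{j>i} w_ij with w_ij = |y_i - y_j| and
    S_ij = 1 when the prediction pair (x_i, x_j) orders the same way as the
    measured pair, else ``discordant_value`` (0 as printed; set -1 for the
    variant used in PI's original formulation). Pairs tied in x score
    ``discordant_value``; pairs tied in y carry zero weight.
    """
    x, y = _check_xy(x, y)
    n = len(x)
    num = 0.0
    den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            w = abs(y[i] - y[j])
            if w == 0:
                continue
            s_xy = np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
            num += w * (1.0 if s_xy > 0 else discordant_value)
            den += w
    if den == 0:
        raise UndefinedMetricError("PI undefined: all measured affinities equal")
    return float(num / den)


@dataclass
class MetricReport:
    """Scoring metrics pooled over complexes; ranking metrics averaged per target."""

    pearson: float
    rmse: float
    sd: float
    spearman_mean: float
    kendall_mean: float
    pi_mean: float
    n_complexes: int
    n_targets: int
    per_target: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"scoring (n={self.n_complexes}):  Pearson r {self.pearson:.3f}   "
            f"RMSE {self.rmse:.3f}   SD {self.sd:.3f}\n"
            f"ranking (targets={self.n_targets}): Spearman {self.spearman_mean:.3f}   "
            f"Kendall {self.kendall_mean:.3f}   PI {self.pi_mean:.3f}"
        )


def casf_report(tbl: pd.DataFrame) -> MetricReport:
    """Full scoring + ranking report from a prediction table.

    ``tbl`` needs columns complex_id, target_id, y_true, y_pred. Scoring
    metrics pool all rows; ranking metrics are computed within each target
    and averaged with equal target weight. Targets where a ranking metric is
    undefined are skipped for that metric with a warning.
    """
    need = {"complex_id", "target_id", "y_true", "y_pred"}
    if not need <= set(tbl.columns):
        raise ValueError(f"prediction table needs columns {sorted(need)}")
    if len(tbl) == 0:
        raise ValueError("empty prediction table")
    if tbl["complex_id"].duplicated().any():
        raise ValueError("complex_id values must be unique")

    y_true = tbl["y_true"].to_numpy(dtype=float)
    y_pred = tbl["y_pred"].to_numpy(dtype=float)
    r = pearson_r(y_true, y_pred)
    rmse, sd = rmse_and_sd(y_true, y_pred)

    rows = []
    for target, sub in tbl.groupby("target_id", sort=True):
        xt = sub["y_pred"].to_numpy(dtype=float)
        yt = sub["y_true"].to_numpy(dtype=float)
        rec: dict = {"target_id": target, "n": len(sub)}
        for name, fn in (("spearman", spearman_rho), ("kendall", kendall_tau),
                         ("pi", lambda a, b: predictive_index(a, b))):
            try:
                rec[name] = fn(xt, yt)
            except (UndefinedMetricError, ValueError) as exc:
                warnings.warn(f"target {target}: {name} skipped ({exc})", stacklevel=2)
                rec[name] = np.nan
        rows.append(rec)
    per_target = pd.DataFrame(rows)

    return MetricReport(
        pearson=r, rmse=rmse, sd=sd,
        spearman_mean=float(per_target["spearman"].mean()),
        kendall_mean=float(per_target["kendall"].mean()),
        pi_mean=float(per_target["pi"].mean()),
        n_complexes=len(tbl),
        n_targets=len(per_target),
        per_target=per_target,
    )
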