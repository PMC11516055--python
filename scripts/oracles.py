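"""Brute-force reference implementations of the evaluation metrics.

Deliberately naive (pair enumeration, explicit rank construction) and kept
independent of the library code they are used to check.
"""

from __future__ import annotations

import numpy as np


def pearson_oracle(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))


def rank_average_ties(v) -> np.ndarray:
    v = np.asarray(v, float)
    ranks = np.empty(len(v))
    order = np.argsort(v, kind="stable")
    sorted_v = v[order]
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def spearman_oracle(x, y) -> float:
    return pearson_oracle(rank_average_ties(x), rank_average_ties(y))


def kendall_oracle(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    C = D = T = U = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                T += 1
            elif dy == 0:
                U += 1
            elif np.sign(dx) == np.sign(dy):
                C += 1
            else:
                D += 1
    return (C - D) / np.sqrt((C + D + T) * (C + D + U))


def pi_oracle(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    num = den = 0.0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            w = abs(y[i] - y[j])
            s = 1.0 if np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]) > 0 else 0.0
            num += w * s
            den += w
    return num / den


def sd_oracle(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    b, a = np.polyfit(y_pred, y_true, 1)
    resid = y_true - (a + b * y_pred)
    return float(np.sqrt(np.sum(resid ** 2) / (len(y_true) - 1)))
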