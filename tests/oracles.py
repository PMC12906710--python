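"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a statistic from its textbook definition with
plain loops, deliberately sharing no code with the implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, rankdata


def ssgsea_walk(values: np.ndarray, member: np.ndarray, alpha: float) -> float:
    """ECDF-difference walk for one unit: loop translation of the definition."""
    g = len(values)
    rho = rankdata(values)  # 1 = lowest, ties averaged
    order = np.argsort(-values, kind="stable")
    size = int(member.sum())
    denom_in = float((rho[member] ** alpha).sum())
    denom_out = g - size
    es = 0.0
    in_acc = 0.0
    out_acc = 0
    for pos in order:
        if member[pos]:
            in_acc += rho[pos] ** alpha
        else:
            out_acc += 1
        es += in_acc / denom_in - out_acc / denom_out
    return es


def auc_pair_counting(target: np.ndarray, rest: np.ndarray) -> float:
    """AUC by exhaustive win/tie counting over all target-rest pairs."""
    wins = 0.0
    for t in target:
        for r in rest:
            if t > r:
                wins += 1.0
            elif t == r:
                wins += 0.5
    return wins / (len(target) * len(rest))


def km_product_limit(times: np.ndarray, events: np.ndarray) -> dict[float, float]:
    """Survival probability at each event time by the product-limit formula."""
    s = 1.0
    out: dict[float, float] = {}
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def logrank_risk_tables(
    times_a: np.ndarray, events_a: np.ndarray, times_b: np.ndarray, events_b: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank statistic from explicit risk tables."""
    all_event_times = np.unique(
        np.concatenate([times_a[events_a == 1], times_b[events_b == 1]])
    )
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n_a = int((times_a >= t).sum())
        n_b = int((times_b >= t).sum())
        n = n_a + n_b
        d_a = int(((times_a == t) & (events_a == 1)).sum())
        d_b = int(((times_b == t) & (events_b == 1)).sum())
        d = d_a + d_b
        if n == 0 or n == 1:
            continue
        o_minus_e += d_a - d * n_a / n
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, df=1))


def cca_eigendecomposition(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations via eig(Sxx^-1 Sxy Syy^-1 Syx), descending."""
    n = len(X)
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Yc = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.inv(Sxx) @ Sxy @ np.linalg.inv(Syy) @ Sxy.T
    eigvals = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    r = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eigvals[:r], 0.0, 1.0))


def soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)
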