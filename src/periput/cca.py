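"""Canonical correlation analysis between putrescine-metabolism scores
and pathway-activity scores.

Classical (Hotelling) CCA computed from the SVD of the whitened
cross-covariance: columns are standardized, the within-block
covariances are ridge-stabilized (wide pathway panels can approach the
sample size), and canonical correlations are clipped to [0, 1].
"Weights" are the canonical coefficients of each variate; structure
correlations (loadings) are reported alongside for interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CCAResult:
    correlations: np.ndarray
    x_weights: pd.DataFrame  # p x r canonical coefficients
    y_weights: pd.DataFrame  # q x r
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    ridge: float
    n_units: int


def _as_frame(a, prefix: str) -> pd.DataFrame:
    if isinstance(a, pd.DataFrame):
        return a
    a = np.asarray(a, dtype=float)
    return pd.DataFrame(a, columns=[f"{prefix}{j}" for j in range(a.shape[1])])


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 1e-12, None)
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def cca(X, Y, ridge: float = 1e-6) -> CCAResult:
    """Canonical correlations and weights between two score blocks.

    ``X`` and ``Y`` are units x variables (aligned rows).  Constant
    columns are an error (named); fewer units than ``p + q + 2`` only
    warns.
    """
    Xf, Yf = _as_frame(X, "x"), _as_frame(Y, "y")
    if len(Xf) != len(Yf):
        raise ValueError("X and Y must have the same number of units")
    n, p = Xf.shape
    q = Yf.shape[1]
    if n < p + q + 2:
        logger.warning("only %d units for p=%d, q=%d variables; estimates may be unstable", n, p, q)
    for frame, side in ((Xf, "X"), (Yf, "Y")):
        sd = frame.std(ddof=1)
        constant = sd[sd == 0].index.tolist()
        if constant:
            raise ValueError(f"constant column(s) in {side}: {constant}")

    Xs = (Xf - Xf.mean()) / Xf.std(ddof=1)
    Ys = (Yf - Yf.mean()) / Yf.std(ddof=1)
    Xv, Yv = Xs.to_numpy(), Ys.to_numpy()
    Sxx = Xv.T @ Xv / (n - 1) + ridge * np.eye(p)
    Syy = Yv.T @ Yv / (n - 1) + ridge * np.eye(q)
    Sxy = Xv.T @ Yv / (n - 1)
    A = _inv_sqrt(Sxx)
    B = _inv_sqrt(Syy)
    U, s, Vt = np.linalg.svd(A @ Sxy @ B)
    r = min(p, q)
    corrs = np.clip(s[:r], 0.0, 1.0)
    a = A @ U[:, :r]
    b = B @ Vt.T[:, :r]
    # deterministic sign: largest-magnitude Y coefficient positive per variate
    for j in range(r):
        lead = np.argmax(np.abs(b[:, j]))
        if b[lead, j] < 0:
            b[:, j] *= -1
            a[:, j] *= -1

    cols = [f"cv{j + 1}" for j in range(r)]
    x_scores = Xv @ a
    y_scores = Yv @ b

    def _loadings(block: np.ndarray, scores: np.ndarray, index) -> pd.DataFrame:
        block_sd = block.std(axis=0, ddof=1)
        score_sd = scores.std(axis=0, ddof=1)
        cov = block.T @ scores / (n - 1)
        return pd.DataFrame(cov / np.outer(block_sd, score_sd), index=index, columns=cols)

    return CCAResult(
        correlations=corrs,
        x_weights=pd.DataFrame(a, index=Xf.columns, columns=cols),
        y_weights=pd.DataFrame(b, index=Yf.columns, columns=cols),
        x_loadings=_loadings(Xv, x_scores, Xf.columns),
        y_loadings=_loadings(Yv, y_scores, Yf.columns),
        ridge=ridge,
        n_units=n,
    )


def top_weighted(result: CCAResult, k: int = 20) -> list[str]:
    """Pathway names ranked by |first-variate Y coefficient|, top ``k``.

    Ties break alphabetically for determinism.
    """
    q = result.y_weights.shape[0]
    if k > q:
        raise ValueError(f"k={k} exceeds the {q} available pathways")
    if k == 0:
        return []
    w = result.y_weights["cv1"].abs()
    order = sorted(w.index, key=lambda name: (-w[name], str(name)))
    return [str(name) for name in order[:k]]


def pearson_panel(X, Y_selected) -> pd.DataFrame:
    """Pairwise Pearson correlations between two score blocks (p x k).

    Zero-variance columns yield NaN entries.  Requires >= 3 units.
    """
    Xf, Yf = _as_frame(X, "x"), _as_frame(Y_selected, "y")
    if len(Xf) != len(Yf):
        raise ValueError("X and Y must have the same number of units")
    if len(Xf) < 3:
        raise ValueError("need at least 3 units for correlations")
    Xv, Yv = Xf.to_numpy(float), Yf.to_numpy(float)
    xc = Xv - Xv.mean(axis=0)
    yc = Yv - Yv.mean(axis=0)
    xsd = Xv.std(axis=0, ddof=1)
    ysd = Yv.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ yc / (len(Xf) - 1)) / np.outer(xsd, ysd)
    corr[np.broadcast_to((xsd == 0)[:, None], corr.shape)] = np.nan
    corr[np.broadcast_to((ysd == 0)[None, :], corr.shape)] = np.nan
    return pd.DataFrame(np.clip(corr, -1.0, 1.0), index=Xf.columns, columns=Yf.columns)
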