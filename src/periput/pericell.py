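"""Per-cell putrescine accumulation (S_PA) and the per-sample
pericellular index (Pi), with its association to T-cell function.

``Exp_in`` sums the log-normalized expression of the biosynthesis genes
(ODC1, AGMAT, PAOX) per cell; ``Exp_loss`` sums the loss genes (SRM,
OAZ1/2/3, NQO1).  The accumulation score is the ratio
``S_PA = Exp_in / Exp_loss`` with two conventions: cells without any
biosynthesis expression score exactly 0 (the dominant case in T cells),
and a small ``eps`` guards the denominator otherwise.

The pericellular index of a sample is ``Pi = S_1 / N``: the summed S_PA
over all *non*-CXCR6+CD8+ cells (every broad type) divided by the number
of CXCR6+CD8+ T cells.  Samples without target cells are flagged
invalid.  The association between Pi and the per-sample medians of the
T-cell functional scores in CXCR6+CD8+ cells is estimated with a
cross-validated LASSO (Pi as response, standardized), alongside plain
Pearson/Spearman correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .genesets import PUT_BIOSYNTHESIS, PUT_LOSS

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1e-8


def exp_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-cell Exp_in / Exp_loss sums from a log-normalized matrix.

    Genes missing from the matrix contribute 0 (with a warning).
    """
    genes = {str(g).upper(): g for g in expr.index}

    def _sum(symbols: tuple[str, ...], label: str) -> np.ndarray:
        present = [genes[s] for s in symbols if s in genes]
        missing = [s for s in symbols if s not in genes]
        if missing:
            logger.warning("%s genes missing from matrix (contribute 0): %s", label, missing)
        if not present:
            return np.zeros(expr.shape[1])
        return expr.loc[present].to_numpy(dtype=float).sum(axis=0)

    return pd.DataFrame(
        {
            "exp_in": _sum(PUT_BIOSYNTHESIS, "biosynthesis"),
            "exp_loss": _sum(PUT_LOSS, "loss"),
        },
        index=expr.columns,
    )


def spa(exp_in: pd.Series, exp_loss: pd.Series, eps: float = DEFAULT_EPS) -> pd.Series:
    """Per-cell putrescine accumulation score ``Exp_in / Exp_loss``.

    Zero where ``Exp_in`` is zero; otherwise the denominator is guarded
    by ``eps`` so cells with no loss-gene expression stay finite.
    """
    e_in = np.asarray(exp_in, dtype=float)
    e_loss = np.asarray(exp_loss, dtype=float)
    if (e_in < 0).any() or (e_loss < 0).any():
        raise ValueError("expression sums must be nonnegative")
    out = np.where(e_in == 0, 0.0, e_in / (e_loss + eps))
    index = exp_in.index if isinstance(exp_in, pd.Series) else None
    return pd.Series(out, index=index, name="s_pa")


def pi_per_sample(spa_values: pd.Series, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-sample pericellular putrescine records (S_1, N, Pi, valid).

    ``S_1`` sums S_PA over cells with ``cxcr6_status != 'pos'`` (all
    broad types included), ``N`` counts the CXCR6+CD8+ cells, and
    ``Pi = S_1 / N`` when ``N > 0``.
    """
    if len(spa_values) != len(ann):
        raise ValueError("S_PA vector and annotation differ in length")
    if "cxcr6_status" not in ann.columns:
        raise ValueError("annotation lacks cxcr6_status; run label_cxcr6_cd8 first")
    values = np.asarray(spa_values, dtype=float)
    rows = []
    for sample, grp in ann.groupby("sample_id", observed=True, sort=True):
        if len(grp) == 0:
            raise ValueError(f"sample {sample!r} has zero cells")
        loc = ann.index.get_indexer(grp.index)
        pos = (grp["cxcr6_status"] == "pos").to_numpy()
        s1 = float(values[loc][~pos].sum())
        n = int(pos.sum())
        rows.append(
            {
                "sample_id": sample,
                "S_1": s1,
                "N": n,
                "Pi": s1 / n if n > 0 else np.nan,
                "valid": n > 0,
            }
        )
    return pd.DataFrame(rows)


def functional_medians(scores: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median functional score over CXCR6+CD8+ cells.

    One row per sample and one column per score row; samples without
    target cells are NaN.
    """
    if "cxcr6_status" not in ann.columns:
        raise ValueError("annotation lacks cxcr6_status")
    samples = sorted(ann["sample_id"].astype(str).unique())
    out = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample_id"), columns=scores.index)
    pos = ann["cxcr6_status"] == "pos"
    for sample, grp in ann.loc[pos].groupby("sample_id", observed=True):
        cells = grp.index
        out.loc[str(sample)] = scores[cells].median(axis=1)
    return out


@dataclass
class AssociationResult:
    """LASSO association of Pi with functional-set medians."""

    coefficients: pd.Series
    alpha_selected: float
    alpha_min: float
    selection: str
    alphas: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    pearson: pd.Series
    spearman: pd.Series
    n_samples: int
    cv_folds: int
    seed: int
    intercept: float = field(default=0.0)


def lasso_coefficients(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Coordinate-descent L1 fit at one penalty (``alpha=0`` = least squares).

    Uses the 1/(2n) squared-error + alpha * L1 objective; the design is
    used as given (no internal standardization).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(X)), X]), y, rcond=None)
        return coef[1:]
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=100_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_


def lasso_association(
    pi: pd.DataFrame,
    medians: pd.DataFrame,
    cv_folds: int = 5,
    seed: int = 0,
    selection: str = "min",
    response_transform: str = "log1p",
    n_alphas: int = 100,
) -> AssociationResult:
    """Cross-validated LASSO of (standardized) Pi on functional medians.

    Only valid Pi records with complete medians enter.  Pi is a ratio of
    sums and varies multiplicatively across samples, so by default the
    response is ``log1p(Pi)`` before standardization (``"identity"``
    keeps the raw scale).  The penalty grid is log-spaced from the
    smallest all-zero penalty downward; the CV mean-squared-error curve
    selects its minimizer (``"min"``, default) or the sparsest penalty
    within one standard error of it (``"1se"``, the conventional
    parsimony rule).  Descriptive Pearson and Spearman
    correlations of raw Pi with each median are reported alongside.
    """
    if selection not in {"min", "1se"}:
        raise ValueError("selection must be 'min' or '1se'")
    if response_transform not in {"log1p", "identity"}:
        raise ValueError("response_transform must be 'log1p' or 'identity'")
    valid = pi.loc[pi["valid"].astype(bool)].set_index("sample_id")
    joined = valid[["Pi"]].join(medians, how="inner").dropna()
    n = len(joined)
    if n < cv_folds:
        raise ValueError(f"only {n} valid samples with complete medians; need >= {cv_folds}")
    feature_names = list(medians.columns)
    X = joined[feature_names].to_numpy(dtype=float)
    y_raw = joined["Pi"].to_numpy(dtype=float)
    y = np.log1p(np.clip(y_raw, 0.0, None)) if response_transform == "log1p" else y_raw

    def _standardize(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (a - a.mean(axis=0)) / sd

    Xs, ys = _standardize(X), _standardize(y)
    alpha_max = np.abs(Xs.T @ ys).max() / n
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_alphas)

    folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.empty((cv_folds, n_alphas))
    for k, (train, test) in enumerate(folds.split(Xs)):
        _, coefs, _ = lasso_path(Xs[train], ys[train], alphas=alphas)
        pred = Xs[test] @ coefs + ys[train].mean()
        mse[k] = ((pred - ys[test, None]) ** 2).mean(axis=0)
    mse_mean = mse.mean(axis=0)
    mse_se = mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mse_mean))
    alpha_min = float(alphas[i_min])
    if selection == "min":
        alpha_sel = alpha_min
    else:
        within = mse_mean <= mse_mean[i_min] + mse_se[i_min]
        alpha_sel = float(alphas[np.argmax(within)])  # alphas descend: first hit is largest

    model = Lasso(alpha=alpha_sel, fit_intercept=True, max_iter=100_000)
    model.fit(Xs, ys)

    pearson = {}
    spearman = {}
    for j, name in enumerate(feature_names):
        if np.std(X[:, j]) == 0:
            pearson[name] = np.nan
            spearman[name] = np.nan
        else:
            pearson[name] = float(pearsonr(y_raw, X[:, j]).statistic)
            spearman[name] = float(spearmanr(y_raw, X[:, j]).statistic)

    return AssociationResult(
        coefficients=pd.Series(model.coef_, index=feature_names, name="coefficient"),
        alpha_selected=alpha_sel,
        alpha_min=alpha_min,
        selection=selection,
        alphas=alphas,
        cv_mse_mean=mse_mean,
        cv_mse_se=mse_se,
        pearson=pd.Series(pearson, name="pearson"),
        spearman=pd.Series(spearman, name="spearman"),
        n_samples=n,
        cv_folds=cv_folds,
        seed=seed,
        intercept=float(model.intercept_),
    )
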