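"""Normalization and single-sample gene-set enrichment scoring.

Expression matrices are ``pandas.DataFrame`` objects with genes as rows
and units (cells or bulk samples) as columns.  The enrichment engine is
the ssGSEA walk statistic: per unit, genes receive rank values
``rho`` (1 = lowest expression, ties by average rank); walking down the
list in decreasing expression order, the score is the summed difference
between the weighted in-set ECDF (weights ``rho ** alpha``) and the
uniform out-of-set ECDF:

    ES = sum_k [ P_in(k) - P_out(k) ]

with ``alpha = 0.25`` by default.  The engine is rank-based, so any
strictly increasing per-unit transform of expression leaves scores
unchanged.  The same engine scores single cells and bulk samples; for
bulk matrices the conventional matrix-range normalization
(ES / (max ES - min ES)) can be switched on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25

#: Row labels of the derived per-unit putrescine indices.
EXTRACELLULAR = "S_extracellular"
ACCUMULATION = "S_accumulation"


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Per-unit library-size normalization: ``ln(1 + scale * c / total)``.

    Units with zero total counts yield all-zero columns (with a warning).
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts matrix contains negative values")
    totals = values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d unit(s) have zero total counts; output set to zero", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    out = np.log1p(scale * values / safe)
    out[:, zero] = 0.0
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def bulk_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Bulk normalization: per gene, ``log2(x + 1)`` then z-score across units.

    Genes with zero variance map to z = 0.  Requires >= 2 units.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring requires at least two units")
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    logged = np.log2(values + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def ssgsea(
    expr: pd.DataFrame,
    coll: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every set in ``coll`` for every unit of ``expr``.

    Sets are intersected with the matrix genes; a set that empties or
    that covers *all* matrix genes is an error (the out-of-set ECDF is
    undefined).  Units whose expression is entirely tied score 0 by
    convention.  With ``normalize=True`` the final matrix is divided by
    its overall range (max - min).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = [str(g).upper() for g in expr.index]
    n_genes = len(genes)
    if n_genes < 2:
        raise ValueError("need at least two genes to score")
    gene_pos = {g: i for i, g in enumerate(genes)}

    memberships: list[tuple[str, np.ndarray]] = []
    for s in coll:
        idx = [gene_pos[g] for g in s.genes if g in gene_pos]
        if not idx:
            raise ValueError(f"gene set {s.name!r} has no genes in the matrix")
        if len(idx) == n_genes:
            raise ValueError(f"gene set {s.name!r} covers every gene in the matrix")
        member = np.zeros(n_genes, dtype=bool)
        member[idx] = True
        memberships.append((s.name, member))

    values = expr.to_numpy(dtype=float)
    ranks = rankdata(values, axis=0)  # 1 = lowest, ties by average rank
    # positions of genes in decreasing-expression order, per unit
    order = np.argsort(-values, axis=0, kind="stable")
    tied_units = values.max(axis=0) == values.min(axis=0)

    weights = ranks ** alpha
    scores = np.empty((len(memberships), values.shape[1]))
    for row, (_, member) in enumerate(memberships):
        w = np.where(member[:, None], weights, 0.0)
        w_ord = np.take_along_axis(w, order, axis=0)
        p_in = np.cumsum(w_ord, axis=0) / w_ord.sum(axis=0, keepdims=True)
        out_ord = np.take_along_axis(
            np.broadcast_to(~member[:, None], values.shape).copy(), order, axis=0
        )
        p_out = np.cumsum(out_ord, axis=0) / (n_genes - int(member.sum()))
        scores[row] = (p_in - p_out).sum(axis=0)
    scores[:, tied_units] = 0.0

    if normalize:
        spread = scores.max() - scores.min()
        if spread > 0:
            scores = scores / spread
    return pd.DataFrame(scores, index=[name for name, _ in memberships], columns=expr.columns)


def derive_put_indices(scores: pd.DataFrame) -> pd.DataFrame:
    """Append the derived putrescine indices to a score matrix.

    ``S_extracellular = S_Trans / S_In`` (NaN where ``S_In <= 0``: the
    ratio is not interpretable at non-positive biosynthesis enrichment)
    and ``S_accumulation = S_In - S_Loss``.
    """
    required = ("put_biosynthesis", "put_loss", "put_transport")
    missing = [r for r in required if r not in scores.index]
    if missing:
        raise ValueError(f"score matrix lacks required rows: {missing}")
    s_in = scores.loc["put_biosynthesis"]
    s_loss = scores.loc["put_loss"]
    s_trans = scores.loc["put_transport"]
    with np.errstate(invalid="ignore", divide="ignore"):
        extracellular = s_trans / s_in
    extracellular = extracellular.where(s_in > 0)
    accumulation = s_in - s_loss
    out = scores.copy()
    out.loc[EXTRACELLULAR] = extracellular
    out.loc[ACCUMULATION] = accumulation
    return out
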