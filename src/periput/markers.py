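"""CXCR6+CD8+ T-cell labeling, ROC marker selection, DEG screening, and
tumor-vs-normal responsiveness (D_median).

The marker scan is a one-vs-rest rank-sum classifier: per gene, the AUC
of expression for target cells against all other cells (midrank ties),
combined with the detection-percentage difference.  Genes pass with
AUC > 0.85 and a signed percentage difference > 0.55; the canonical
lineage markers (CD3D/CD3E/CD8A/CD8B/CXCR6) are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FORCED_MARKERS = ("CD3D", "CD3E", "CD8A", "CD8B", "CXCR6")

BROAD_TYPES = ("Epithelial", "Endothelial", "TNKILC", "B", "Plasma", "Myeloid", "Mast", "FibroGlial")
T_SUBSETS = ("CD4T", "CD8T", "gdT", "NK", "ILC")


@dataclass(frozen=True)
class DMedianRecord:
    """Median score difference (tumor - normal) for one set and cell group."""

    gene_set: str
    cell_group: str
    d_median: float
    n_tumor: int
    n_normal: int


def label_cxcr6_cd8(counts: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Assign ``cxcr6_status`` from CXCR6 detection in CD8+ T cells.

    CD8T cells with any CXCR6 counts are ``pos``, CD8T cells without are
    ``neg``, every other cell is ``na``.  The detection threshold
    (count > 0) is the standard single-cell positivity rule.
    """
    genes = {str(g).upper(): g for g in counts.index}
    if "CXCR6" not in genes:
        raise ValueError("CXCR6 is not present in the count matrix")
    if "t_subset" not in ann.columns:
        raise ValueError("annotation lacks a t_subset column")
    cxcr6 = counts.loc[genes["CXCR6"]].reindex(ann.index).to_numpy(dtype=float)
    cd8 = (ann["t_subset"] == "CD8T").to_numpy()
    status = np.where(cd8 & (cxcr6 > 0), "pos", np.where(cd8, "neg", "na"))
    out = ann.copy()
    out["cxcr6_status"] = status
    return out


def pct_expressed(counts: pd.DataFrame, mask: np.ndarray | pd.Series, gene: str) -> float:
    """Fraction of masked cells with any counts of ``gene``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cell mask")
    genes = {str(g).upper(): g for g in counts.index}
    key = gene.upper()
    if key not in genes:
        raise KeyError(gene)
    row = counts.loc[genes[key]].to_numpy(dtype=float)
    return float((row[mask] > 0).mean())


def _auc_target_vs_rest(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rank-sum AUC per row of ``values`` (genes x cells), midrank ties."""
    n1 = int(target.sum())
    n2 = int((~target).sum())
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, target].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def auc_marker_scan(
    expr: pd.DataFrame,
    target_mask: np.ndarray | pd.Series,
    auc_min: float = 0.85,
    diff_min: float = 0.55,
    forced: tuple[str, ...] = FORCED_MARKERS,
) -> pd.DataFrame:
    """One-vs-rest ROC marker scan over every gene.

    Returns a frame (gene, auc, pct_target, pct_rest, pct_diff,
    selected) sorted by AUC descending.  A gene is selected when
    ``auc > auc_min`` and ``pct_diff > diff_min``, or when it is in the
    ``forced`` lineage-marker list.
    """
    target = np.asarray(target_mask, dtype=bool)
    if target.sum() < 2 or (~target).sum() < 2:
        raise ValueError("target and rest must each contain >= 2 cells")
    values = expr.to_numpy(dtype=float)
    auc = _auc_target_vs_rest(values, target)
    detected = values > 0
    pct_target = detected[:, target].mean(axis=1)
    pct_rest = detected[:, ~target].mean(axis=1)
    pct_diff = pct_target - pct_rest
    upper = pd.Index(expr.index.astype(str).str.upper())
    forced_mask = upper.isin([g.upper() for g in forced])
    selected = ((auc > auc_min) & (pct_diff > diff_min)) | forced_mask
    table = pd.DataFrame(
        {
            "gene": expr.index,
            "auc": auc,
            "pct_target": pct_target,
            "pct_rest": pct_rest,
            "pct_diff": pct_diff,
            "forced": forced_mask,
            "selected": selected,
        }
    )
    return table.sort_values("auc", ascending=False, kind="mergesort").reset_index(drop=True)


def deg_screen(
    expr: pd.DataFrame,
    mask_a: np.ndarray | pd.Series,
    mask_b: np.ndarray | pd.Series,
    min_pct: float = 0.3,
) -> pd.DataFrame:
    """Two-group differential expression screen on log-normalized values.

    Genes are tested only when detected in at least ``min_pct`` of one
    group; the test is a two-sided rank-sum with Benjamini-Hochberg
    adjustment, and the fold change is the difference of group means.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.sum() < 3 or b.sum() < 3:
        raise ValueError("each group needs >= 3 cells")
    if (a & b).any():
        raise ValueError("groups overlap")
    values = expr.to_numpy(dtype=float)
    pct_a = (values[:, a] > 0).mean(axis=1)
    pct_b = (values[:, b] > 0).mean(axis=1)
    testable = (pct_a >= min_pct) | (pct_b >= min_pct)
    if not testable.any():
        logger.warning("no genes pass min_pct=%.2f; returning empty table", min_pct)
        return pd.DataFrame(columns=["gene", "lfc", "pct_a", "pct_b", "p_value", "p_adj"])
    sub = values[testable]
    res = mannwhitneyu(sub[:, a], sub[:, b], axis=1, alternative="two-sided")
    lfc = sub[:, a].mean(axis=1) - sub[:, b].mean(axis=1)
    p_adj = multipletests(res.pvalue, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": expr.index[testable],
            "lfc": lfc,
            "pct_a": pct_a[testable],
            "pct_b": pct_b[testable],
            "p_value": res.pvalue,
            "p_adj": p_adj,
        }
    )
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def proportion_table(ann: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-sample CXCR6+CD8+ fractions with tumor-vs-normal rank tests.

    For every sample the fraction of CXCR6+CD8+ cells among all cells
    and among CD8+ T cells (NaN when a sample has no CD8T cell).  Tests
    compare Tumor against Normal samples: a paired Wilcoxon signed-rank
    across subjects carrying both tissues, and an unpaired rank-sum over
    all samples.  Border-tissue samples are excluded from testing.
    """
    required = {"sample_id", "subject_id", "tissue", "cxcr6_status", "t_subset"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation lacks columns: {sorted(required - set(ann.columns))}")
    rows = []
    for sample, grp in ann.groupby("sample_id", observed=True, sort=True):
        n_cd8 = int((grp["t_subset"] == "CD8T").sum())
        n_pos = int((grp["cxcr6_status"] == "pos").sum())
        rows.append(
            {
                "sample_id": sample,
                "subject_id": grp["subject_id"].iloc[0],
                "tissue": grp["tissue"].iloc[0],
                "n_cells": len(grp),
                "frac_total": n_pos / len(grp),
                "frac_cd8": n_pos / n_cd8 if n_cd8 > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    tests: dict[str, dict] = {}
    tn = table[table["tissue"].isin(["Tumor", "Normal"])]
    for col in ("frac_total", "frac_cd8"):
        sub = tn.dropna(subset=[col])
        tumor = sub.loc[sub["tissue"] == "Tumor", col]
        normal = sub.loc[sub["tissue"] == "Normal", col]
        entry: dict = {"n_tumor": len(tumor), "n_normal": len(normal)}
        if len(tumor) and len(normal):
            entry["unpaired_p"] = float(
                mannwhitneyu(tumor, normal, alternative="two-sided").pvalue
            )
        # one sample per (subject, tissue); subjects with both tissues pair up
        wide = sub.pivot_table(index="subject_id", columns="tissue", values=col, aggfunc="mean")
        if {"Tumor", "Normal"}.issubset(wide.columns):
            pairs = wide.dropna(subset=["Tumor", "Normal"])
            entry["n_pairs"] = len(pairs)
            diffs = pairs["Tumor"] - pairs["Normal"]
            if len(pairs) and not np.allclose(diffs, 0):
                entry["paired_p"] = float(
                    wilcoxon(pairs["Tumor"], pairs["Normal"], zero_method="wilcox").pvalue
                )
            elif len(pairs):
                entry["paired_p"] = 1.0
        else:
            entry["n_pairs"] = 0
            logger.warning("no subjects with paired tissues for %s; paired test omitted", col)
        tests[col] = entry
    return table, tests


def d_median(
    scores: pd.DataFrame,
    ann: pd.DataFrame,
    gene_set: str,
    cell_group: np.ndarray | pd.Series | None = None,
    paired_only: bool = False,
    group_label: str = "all",
) -> DMedianRecord:
    """Tumor-vs-normal responsiveness of a gene-set score within a group.

    ``D_median = median(score | tumor cells) - median(score | normal
    cells)`` over cells of the group.  With ``paired_only`` the
    comparison is restricted to subjects contributing both tissues.
    """
    if gene_set not in scores.index:
        raise KeyError(gene_set)
    mask = np.ones(len(ann), dtype=bool) if cell_group is None else np.asarray(cell_group, bool)
    sub = ann.loc[mask]
    values = scores.loc[gene_set].reindex(sub.index)
    if paired_only:
        per_subject = sub.groupby("subject_id", observed=True)["tissue"].agg(set)
        paired_subjects = per_subject[per_subject.apply(lambda t: {"Tumor", "Normal"} <= t)].index
        keep = sub["subject_id"].isin(paired_subjects)
        sub, values = sub.loc[keep], values.loc[keep]
    tumor = values[(sub["tissue"] == "Tumor").to_numpy()]
    normal = values[(sub["tissue"] == "Normal").to_numpy()]
    if len(tumor) == 0 or len(normal) == 0:
        raise ValueError("both tissue groups must be non-empty within the cell group")
    return DMedianRecord(
        gene_set=gene_set,
        cell_group=group_label,
        d_median=float(np.median(tumor) - np.median(normal)),
        n_tumor=len(tumor),
        n_normal=len(normal),
    )
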