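"""Per-cell quality control, noise-gene stripping, and group downsampling.

QC metrics are computed on the raw (pre-strip) count matrix: stripping
mitochondrial/ribosomal genes first would zero the very ratios the
filter needs.  Exclusion thresholds follow the strict-inequality
convention (a cell is removed when a ratio *exceeds* its maximum or the
feature count falls *below* the minimum), so boundary cells are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Hemoglobin genes are matched by an explicit symbol list rather than the
#: "HB" prefix, which would also catch unrelated genes such as HBEGF.
HEMOGLOBIN_GENES = frozenset(
    {"HBA1", "HBA2", "HBB", "HBD", "HBE1", "HBG1", "HBG2", "HBM", "HBQ1", "HBZ"}
)

MITO_PREFIX = "MT-"
RIBO_PREFIXES = ("RPL", "RPS")


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds for one filtering profile."""

    mito_max: float
    ribo_max: float
    hb_max: float
    n_count_max: int
    n_feature_min: int
    n_feature_max: int
    profile: str = "custom"

    def __post_init__(self) -> None:
        if self.n_feature_min >= self.n_feature_max:
            raise ValueError("n_feature_min must be < n_feature_max")
        if min(self.mito_max, self.ribo_max, self.hb_max) <= 0 or self.n_count_max <= 0:
            raise ValueError("all maxima must be positive")


#: The two filtering profiles: the merged multi-cohort profile and the
#: more permissive profile used for the mismatch-repair cohort.
PROFILES: dict[str, QCThresholds] = {
    "integrated": QCThresholds(0.15, 0.50, 0.01, 10_000, 400, 6_000, "integrated"),
    "mmr": QCThresholds(0.30, 0.50, 0.01, 10_000, 400, 7_000, "mmr"),
}


def _gene_classes(genes: pd.Index) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    upper = np.array([str(g).upper() for g in genes])
    mito = np.char.startswith(upper, MITO_PREFIX)
    ribo = np.char.startswith(upper, RIBO_PREFIXES[0]) | np.char.startswith(upper, RIBO_PREFIXES[1])
    hb = np.isin(upper, list(HEMOGLOBIN_GENES))
    return mito, ribo, hb


def compute_qc_metrics(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell QC metrics from a raw genes x cells count matrix.

    Returns a frame indexed by cell with columns ``n_count``,
    ``n_feature``, ``mito_ratio``, ``ribo_ratio``, ``hb_ratio`` and a
    ``zero_total`` flag (ratios for empty cells are set to 0).
    """
    if counts.shape[0] == 0:
        raise ValueError("count matrix has zero genes")
    values = counts.to_numpy(dtype=float)
    mito, ribo, hb = _gene_classes(counts.index)
    n_count = values.sum(axis=0)
    n_feature = (values > 0).sum(axis=0)
    zero_total = n_count == 0
    safe = np.where(zero_total, 1.0, n_count)
    return pd.DataFrame(
        {
            "n_count": n_count,
            "n_feature": n_feature,
            "mito_ratio": np.where(zero_total, 0.0, values[mito].sum(axis=0) / safe),
            "ribo_ratio": np.where(zero_total, 0.0, values[ribo].sum(axis=0) / safe),
            "hb_ratio": np.where(zero_total, 0.0, values[hb].sum(axis=0) / safe),
            "zero_total": zero_total,
        },
        index=counts.columns,
    )


def filter_cells(metrics: pd.DataFrame, thr: QCThresholds) -> tuple[pd.Series, dict[str, int]]:
    """Keep-mask and per-rule exclusion counts for one threshold profile.

    A cell is kept iff all five rules hold: mito/ribo/hemoglobin ratios
    at or below their maxima, total counts at or below ``n_count_max``,
    and feature count within ``[n_feature_min, n_feature_max]``.
    """
    required = {"mito_ratio", "ribo_ratio", "hb_ratio", "n_count", "n_feature"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame lacks columns: {sorted(required - set(metrics.columns))}")
    rules = {
        "mito": metrics["mito_ratio"] > thr.mito_max,
        "ribo": metrics["ribo_ratio"] > thr.ribo_max,
        "hb": metrics["hb_ratio"] > thr.hb_max,
        "n_count": metrics["n_count"] > thr.n_count_max,
        "n_feature": (metrics["n_feature"] < thr.n_feature_min)
        | (metrics["n_feature"] > thr.n_feature_max),
    }
    excluded = pd.DataFrame(rules)
    keep = ~excluded.any(axis=1)
    summary = {f"excluded_{k}": int(v.sum()) for k, v in rules.items()}
    summary["kept"] = int(keep.sum())
    summary["total"] = int(len(keep))
    return keep, summary


def strip_noise_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove mitochondrial (MT-) and ribosomal (RPL/RPS) genes.

    Must be applied *after* :func:`compute_qc_metrics`; raises if the
    result would be empty.
    """
    mito, ribo, _ = _gene_classes(counts.index)
    keep = ~(mito | ribo)
    if not keep.any():
        raise ValueError("stripping noise genes would remove every gene")
    return counts.loc[counts.index[keep]]


def downsample_per_group(
    ann: pd.DataFrame, group_key: str, cap: int, seed: int
) -> pd.Series:
    """Boolean keep-mask capping every group at ``cap`` cells.

    Groups at or below the cap are kept whole; larger groups are
    subsampled uniformly without replacement, deterministically for a
    fixed seed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if group_key not in ann.columns:
        raise KeyError(f"unknown group key {group_key!r}")
    rng = np.random.default_rng(seed)
    keep = pd.Series(True, index=ann.index)
    # sort group labels so the draw order (hence the mask) is deterministic
    for group in sorted(ann[group_key].astype(str).unique()):
        members = ann.index[ann[group_key].astype(str) == group]
        if len(members) > cap:
            kept = rng.choice(len(members), size=cap, replace=False)
            drop = np.setdiff1d(np.arange(len(members)), kept)
            keep.loc[members[drop]] = False
    return keep
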