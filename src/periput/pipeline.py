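"""End-to-end orchestration: QC, scoring, labeling, markers, Pi,
association, survival, and CCA from a single configuration.

Every tabular artifact is CSV/TSV with a commented provenance header
line (JSON: stage, parameters, seed, input hashes) so each stage can be
re-run in isolation.  A failure at stage *k* preserves the artifacts of
stages before *k*.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread

from . import cca as cca_mod
from . import genesets, markers, pericell, qc, scoring, survival

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts: str
    annotation: str
    outdir: str
    gene_sets: str | None = None  # GMT; defaults to the built-in collections
    survival: str | None = None  # CSV sample_id,time,event[,feature]
    survival_enabled: bool = True
    qc_profile: str = "integrated"
    # explicit threshold override (QCThresholds fields); takes precedence over
    # the named profile — needed for targeted panels whose feature counts sit
    # far below whole-transcriptome expectations
    qc_thresholds: dict | None = None
    downsample_cap: int = 10_000
    alpha: float = scoring.DEFAULT_ALPHA
    normalize_scores: bool = False
    auc_min: float = 0.85
    diff_min: float = 0.55
    eps: float = pericell.DEFAULT_EPS
    cv_folds: int = 5
    cca_population: str = "Epithelial"
    cca_k: int = 10
    cca_ridge: float = 1e-6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# fixed per-stage seed offsets so stages can be re-run independently
STAGE_SEEDS = {"qc": 11, "pi": 13}


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _provenance(stage: str, config: PipelineConfig, **params) -> str:
    record = {
        "stage": stage,
        "seed": config.seed,
        "params": params,
        "version": "periput-0.1.0",
    }
    return json.dumps(record, sort_keys=True)


def write_csv(df: pd.DataFrame, path: Path, provenance: str, sep: str = ",", index=True) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep=sep, index=index)
    return path


def read_csv(path: str | Path, sep: str = ",", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def load_counts(path: str | Path) -> pd.DataFrame:
    """Load a genes x cells count matrix (MTX directory or CSV)."""
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        d = path if path.is_dir() else path.parent
        mat = mmread(str(d / "matrix.mtx")).toarray()
        genes_list = (d / "features.tsv").read_text().splitlines()
        cells = (d / "barcodes.tsv").read_text().splitlines()
        return pd.DataFrame(mat, index=genes_list, columns=cells)
    return pd.read_csv(path, index_col=0, comment="#")


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Report-only consistency checks (unit ids, gene-set overlap, survival ids)."""
    report: list[dict] = []

    def entry(level: str, message: str) -> None:
        report.append({"level": level, "message": message})

    try:
        counts = load_counts(config.counts)
    except Exception as exc:  # noqa: BLE001 - report, don't raise
        entry("error", f"cannot load counts: {exc}")
        return report
    try:
        ann = read_csv(config.annotation, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        entry("error", f"cannot load annotation: {exc}")
        return report

    missing = set(counts.columns) - set(ann.index)
    extra = set(ann.index) - set(counts.columns)
    if missing:
        entry("error", f"{len(missing)} cell id(s) in matrix missing from annotation")
    if extra:
        entry("warning", f"{len(extra)} annotated cell id(s) absent from matrix")

    coll = _load_genesets(config)
    universe = {str(g).upper() for g in counts.index}
    for s in coll:
        overlap = sum(g in universe for g in s.genes)
        if overlap == 0:
            entry("error", f"gene set {s.name!r} has zero overlap with the matrix")

    if config.survival_enabled and config.survival:
        try:
            surv = read_csv(config.survival)
            if "sample_id" in ann.columns:
                uncovered = set(ann["sample_id"].astype(str)) - set(surv["sample_id"].astype(str))
                if uncovered:
                    entry("warning", f"{len(uncovered)} sample(s) lack survival records")
        except Exception as exc:  # noqa: BLE001
            entry("error", f"cannot load survival table: {exc}")
    return report


def _load_genesets(config: PipelineConfig) -> genesets.GeneSetCollection:
    put = genesets.builtin_put_genesets()
    if config.gene_sets:
        extra = genesets.parse_gmt(config.gene_sets, category="t_function")
    else:
        extra = genesets.builtin_tcell_genesets()
    return genesets.GeneSetCollection(tuple(put) + tuple(extra))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    t0 = time.time()

    def _stage(name):
        logger.info("[%s] starting (t=%.1fs)", name, time.time() - t0)

    stage = "load"
    try:
        counts = load_counts(config.counts)
        ann = read_csv(config.annotation, sep="\t", index_col=0)
        ann = ann.loc[[c for c in counts.columns if c in ann.index]]
        counts = counts[ann.index]
        coll = _load_genesets(config)
        put_sets = genesets.builtin_put_genesets()
        functional = coll.subset([s.name for s in coll if s.category == "t_function"])

        stage = "qc"
        _stage(stage)
        metrics = qc.compute_qc_metrics(counts)
        if config.qc_thresholds is not None:
            thresholds = qc.QCThresholds(**config.qc_thresholds)
        else:
            thresholds = qc.PROFILES[config.qc_profile]
        keep, summary = qc.filter_cells(metrics, thresholds)
        if not keep.any():
            raise ValueError("QC filtering removed every cell; check the threshold profile")
        ds = qc.downsample_per_group(
            ann.loc[keep[keep].index], "broad_type", config.downsample_cap,
            config.seed + STAGE_SEEDS["qc"],
        )
        kept_cells = ds[ds].index
        qc_frame = metrics.assign(kept=keep & metrics.index.isin(kept_cells))
        manifest["qc_summary"] = str(
            write_csv(qc_frame, outdir / "qc_summary.csv",
                      _provenance("qc", config, profile=config.qc_profile, **summary))
        )
        counts = counts[kept_cells]
        ann = ann.loc[kept_cells]

        stage = "strip"
        _stage(stage)
        stripped = qc.strip_noise_genes(counts)

        stage = "lognormalize"
        _stage(stage)
        lognorm = scoring.lognormalize(stripped)

        stage = "labeling"
        _stage(stage)
        ann = markers.label_cxcr6_cd8(stripped, ann)
        manifest["labels"] = str(
            write_csv(ann, outdir / "labels.tsv", _provenance("labeling", config), sep="\t")
        )

        stage = "scoring"
        _stage(stage)
        scores = scoring.ssgsea(lognorm, coll, alpha=config.alpha, normalize=config.normalize_scores)
        scores = scoring.derive_put_indices(scores)
        manifest["scores"] = str(
            write_csv(scores, outdir / "scores.csv",
                      _provenance("scoring", config, alpha=config.alpha,
                                  normalize=config.normalize_scores,
                                  sets=_hash_file(config.gene_sets) if config.gene_sets else "builtin"))
        )

        stage = "markers"
        _stage(stage)
        target = (ann["cxcr6_status"] == "pos").to_numpy()
        marker_table = markers.auc_marker_scan(
            lognorm, target, auc_min=config.auc_min, diff_min=config.diff_min
        )
        manifest["markers"] = str(
            write_csv(marker_table, outdir / "markers.csv",
                      _provenance("markers", config, auc_min=config.auc_min,
                                  diff_min=config.diff_min), index=False)
        )

        stage = "pi"
        _stage(stage)
        exp = pericell.exp_scores(lognorm)
        spa_values = pericell.spa(exp["exp_in"], exp["exp_loss"], eps=config.eps)
        pi = pericell.pi_per_sample(spa_values, ann)
        manifest["pi"] = str(
            write_csv(pi, outdir / "pi.csv", _provenance("pi", config, eps=config.eps), index=False)
        )
        medians = pericell.functional_medians(scores.loc[functional.names], ann)
        manifest["functional_medians"] = str(
            write_csv(medians, outdir / "functional_medians.csv", _provenance("pi", config))
        )

        stage = "association"
        _stage(stage)
        assoc = pericell.lasso_association(
            pi, medians, cv_folds=config.cv_folds, seed=config.seed + STAGE_SEEDS["pi"]
        )
        assoc_table = pd.DataFrame(
            {
                "coefficient": assoc.coefficients,
                "pearson": assoc.pearson,
                "spearman": assoc.spearman,
            }
        )
        manifest["association"] = str(
            write_csv(assoc_table, outdir / "association.csv",
                      _provenance("association", config, alpha_selected=assoc.alpha_selected,
                                  cv_folds=config.cv_folds, selection=assoc.selection))
        )

        stage = "survival"
        _stage(stage)
        if config.survival_enabled:
            if not config.survival or not Path(config.survival).exists():
                raise FileNotFoundError(f"survival CSV not found: {config.survival!r}")
            surv = read_csv(config.survival)
            res = survival.median_split_logrank(surv)
            payload = {
                "provenance": json.loads(_provenance("survival", config)),
                "chi_square": res["logrank"].chi_square,
                "p_value": res["logrank"].p_value,
                "n_high": res["logrank"].n_a,
                "n_low": res["logrank"].n_b,
            }
            path = outdir / "survival.json"
            path.write_text(json.dumps(payload, indent=2))
            manifest["survival"] = str(path)
        else:
            manifest["survival"] = "skipped"

        stage = "cca"
        _stage(stage)
        pop = (ann["broad_type"] == config.cca_population).to_numpy()
        if pop.sum() < 10:
            raise ValueError(f"fewer than 10 {config.cca_population!r} cells for CCA")
        put_rows = ["put_biosynthesis", "put_loss", "put_transport",
                    scoring.EXTRACELLULAR, scoring.ACCUMULATION]
        X = scores.loc[put_rows, ann.index[pop]].T.fillna(0.0)
        # derived indices can be invalid (hence constant) in populations with
        # non-positive biosynthesis enrichment; drop degenerate columns
        degenerate = X.columns[X.std(ddof=1) == 0].tolist()
        if degenerate:
            logger.warning("dropping constant score column(s) from CCA: %s", degenerate)
            X = X.drop(columns=degenerate)
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 non-degenerate putrescine score columns for CCA")
        Y = scores.loc[functional.names, ann.index[pop]].T
        res = cca_mod.cca(X, Y, ridge=config.cca_ridge)
        top = cca_mod.top_weighted(res, k=min(config.cca_k, Y.shape[1]))
        cca_table = res.y_weights.assign(
            loading_cv1=res.y_loadings["cv1"],
            top=[name in top for name in res.y_weights.index],
        )
        manifest["cca"] = str(
            write_csv(cca_table, outdir / "cca.csv",
                      _provenance("cca", config, ridge=config.cca_ridge,
                                  correlations=[round(float(c), 6) for c in res.correlations]))
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs; %d artifacts", time.time() - t0, len(manifest))
    return manifest
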