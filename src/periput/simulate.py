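"""Synthetic multi-sample cohorts with the statistical structure the
putrescine analysis assumes.

The single-cell generator draws negative-binomial counts over a compact
gene panel (lineage markers, the 15 putrescine-metabolism genes, ten
8-gene functional signatures, and background genes).  Three latent,
per-sample quantities plant the effects the pipeline must recover
through its own scoring path:

* a putrescine burden ``P_s ~ N(0, put_burden_sd)`` shifting the
  log-mean of biosynthesis genes by ``+P_s`` and loss genes by
  ``-P_s/2`` in every non-CXCR6+CD8+ cell, so the pericellular index
  Pi tracks the burden;
* a cytotoxicity level ``C_s = coupling_beta * P_s + eta_s`` (noise sd
  ``functional_noise_sd``) shifting cytotoxic genes in CXCR6+CD8+
  cells — a negative ``coupling_beta`` plants the suppressive effect;
* a transport burden shifting the transport genes in all cells, which
  the bulk arm converts into a survival hazard.

Tissues alternate Tumor/Normal with paired subjects; the CXCR6+ fraction
of CD8+ T cells is higher in tumors by default.  Effects enter only as
log-mean shifts before the count noise, never as post-hoc score edits,
and the generator records the realized (pre-count-noise) Pi-cytotoxicity
rank correlation in the ground-truth ledger so recovery can be judged
against what was actually planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite
from scipy.stats import spearmanr

from .genesets import PUT_BIOSYNTHESIS, PUT_LOSS, PUT_TRANSPORT, T_FUNCTIONAL_SETS
from .markers import BROAD_TYPES, FORCED_MARKERS, T_SUBSETS
from .scoring import bulk_normalize, ssgsea
from . import genesets

DEFAULT_TYPE_PROPORTIONS = {
    "Epithelial": 0.30,
    "TNKILC": 0.25,
    "Myeloid": 0.12,
    "B": 0.10,
    "Endothelial": 0.07,
    "Plasma": 0.06,
    "FibroGlial": 0.06,
    "Mast": 0.04,
}

DEFAULT_T_SUBSET_PROPORTIONS = {
    "CD4T": 0.35,
    "CD8T": 0.40,
    "gdT": 0.08,
    "NK": 0.12,
    "ILC": 0.05,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts."""

    n_samples: int = 80
    cells_per_sample: int = 250
    tissue_labels: tuple[str, ...] | None = None
    cell_type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    t_subset_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_T_SUBSET_PROPORTIONS)
    )
    cxcr6_frac_tumor: float = 0.45
    cxcr6_frac_normal: float = 0.30
    put_burden_sd: float = 1.0
    coupling_beta: float = -0.8
    functional_noise_sd: float = 1.0
    transport_burden_sd: float = 0.5
    nb_dispersion: float = 0.5
    library_size_mean: int = 2500
    n_background_genes: int = 120
    planted_marker_gene: str | None = None
    hazard_log_hr: float = 0.0
    survival_scale: float = 1.0
    censoring_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.cells_per_sample < 1 or self.library_size_mean < 1:
            raise ValueError("counts must be positive")
        if self.cells_per_sample < len(self.cell_type_proportions):
            raise ValueError("cells_per_sample is smaller than the number of cell types")
        for name, props in (
            ("cell_type_proportions", self.cell_type_proportions),
            ("t_subset_proportions", self.t_subset_proportions),
        ):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name} has negative entries")
        for frac in (self.cxcr6_frac_tumor, self.cxcr6_frac_normal):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("CXCR6 fractions must lie in [0, 1]")
        if self.put_burden_sd <= 0 or self.nb_dispersion < 0:
            raise ValueError("put_burden_sd must be positive and nb_dispersion nonnegative")
        if self.survival_scale <= 0:
            raise ValueError("survival_scale must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be nonnegative")
        if self.tissue_labels is not None:
            labels = tuple(self.tissue_labels)
            if len(labels) != self.n_samples:
                raise ValueError("tissue_labels length must equal n_samples")
            bad = set(labels) - {"Tumor", "Border", "Normal"}
            if bad:
                raise ValueError(f"unknown tissue labels: {sorted(bad)}")
            self.tissue_labels = labels


@dataclass
class SimTruth:
    """Ground-truth ledger; fully determined by (config, seed)."""

    seed: int
    put_burden: dict[str, float]
    cytotox_latent: dict[str, float]
    transport_latent: dict[str, float]
    realized_spearman: float | None
    realized_cxcr6_frac_tumor: float | None
    realized_cxcr6_frac_normal: float | None
    coupling_beta: float
    hazard_log_hr: float
    transport_z: dict[str, float] | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


MARKER_ON_LOGMEAN = np.log(3.0)
MARKER_OFF_LOGMEAN = np.log(0.02)
CYTOTOX_CD8_BASELINE = 0.7  # cytotoxic-gene baseline lift in CD8T/NK cells
LOGNORM_SCALE = 1e4


def _gene_panel(rng: np.random.Generator, n_background: int) -> pd.DataFrame:
    """Gene panel with per-gene baseline log-mean counts."""
    rows: list[tuple[str, str, float]] = []
    for g in FORCED_MARKERS:
        rows.append((g, "marker", MARKER_OFF_LOGMEAN))
    # putrescine genes get absolute low means (counts of order 1) so the
    # log-normalized expression responds near-linearly to burden shifts and
    # a realistic fraction of cells has no biosynthesis signal at all
    for g in PUT_BIOSYNTHESIS:
        rows.append((g, "put_bio", np.log(0.5)))
    for g in PUT_LOSS:
        rows.append((g, "put_loss", np.log(1.0)))
    for g in PUT_TRANSPORT:
        rows.append((g, "put_trans", np.log(0.8)))
    for set_name, members in T_FUNCTIONAL_SETS.items():
        for g in members:
            rows.append((g, set_name, np.log(0.5)))
    for i in range(n_background):
        rows.append((f"BG{i + 1:04d}", "background", float(rng.normal(np.log(0.4), 0.6))))
    panel = pd.DataFrame(rows, columns=["gene", "group", "base_logmean"]).set_index("gene")
    if panel.index.duplicated().any():
        raise AssertionError("gene panel has duplicate symbols")
    return panel


def _assign_labels(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell sample/subject/tissue/type/subset/CXCR6 assignments."""
    if config.tissue_labels is not None:
        tissues = list(config.tissue_labels)
    else:
        tissues = ["Tumor" if i % 2 == 0 else "Normal" for i in range(config.n_samples)]
    type_names = list(config.cell_type_proportions)
    type_p = np.array([config.cell_type_proportions[t] for t in type_names])
    sub_names = list(config.t_subset_proportions)
    sub_p = np.array([config.t_subset_proportions[t] for t in sub_names])

    records: list[dict] = []
    for s in range(config.n_samples):
        sample_id = f"S{s + 1:03d}"
        subject_id = f"P{s // 2 + 1:03d}"
        tissue = tissues[s]
        counts = rng.multinomial(config.cells_per_sample, type_p)
        types = np.repeat(type_names, counts)
        rng.shuffle(types)
        subsets = np.full(len(types), "na", dtype=object)
        tnk = types == "TNKILC"
        subsets[tnk] = np.array(sub_names, dtype=object)[
            rng.choice(len(sub_names), size=int(tnk.sum()), p=sub_p)
        ]
        frac = config.cxcr6_frac_tumor if tissue == "Tumor" else config.cxcr6_frac_normal
        cd8 = subsets == "CD8T"
        pos = np.zeros(len(types), dtype=bool)
        pos[cd8] = rng.random(int(cd8.sum())) < frac
        if frac > 0:
            if not cd8.any():  # guarantee the compartment exists
                types[0] = "TNKILC"
                subsets[0] = "CD8T"
                cd8 = subsets == "CD8T"
            if not pos.any():
                pos[np.flatnonzero(cd8)[0]] = True
        for i in range(len(types)):
            records.append(
                {
                    "cell_id": f"{sample_id}_C{i + 1:04d}",
                    "sample_id": sample_id,
                    "subject_id": subject_id,
                    "tissue": tissue,
                    "broad_type": types[i],
                    "t_subset": subsets[i],
                    "cxcr6_true": "pos" if pos[i] else ("neg" if cd8[i] else "na"),
                }
            )
    return pd.DataFrame(records).set_index("cell_id")


def _expected_spa(mu: np.ndarray, panel: pd.DataFrame) -> np.ndarray:
    """Pre-count-noise S_PA per cell from the expected-count matrix."""
    totals = mu.sum(axis=0)
    expr = np.log1p(LOGNORM_SCALE * mu / totals)
    bio = expr[(panel["group"] == "put_bio").to_numpy()].sum(axis=0)
    loss = expr[(panel["group"] == "put_loss").to_numpy()].sum(axis=0)
    return bio / (loss + 1e-8)


def simulate_sc_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a single-cell cohort: (counts genes x cells, annotation, truth)."""
    rng = np.random.default_rng(config.seed)
    panel = _gene_panel(rng, config.n_background_genes)
    ann = _assign_labels(config, rng)
    samples = sorted(ann["sample_id"].unique())
    n_cells = len(ann)
    n_genes = len(panel)

    p_s = pd.Series(rng.normal(0.0, config.put_burden_sd, len(samples)), index=samples)
    eta = pd.DataFrame(
        rng.normal(0.0, config.functional_noise_sd, (len(samples), len(T_FUNCTIONAL_SETS))),
        index=samples,
        columns=list(T_FUNCTIONAL_SETS),
    )
    cytotox_latent = config.coupling_beta * p_s + eta["t_cytotoxicity"]
    transport_latent = pd.Series(
        rng.normal(0.0, config.transport_burden_sd, len(samples)), index=samples
    )

    sample_idx = ann["sample_id"].map({s: i for i, s in enumerate(samples)}).to_numpy()
    target = (ann["cxcr6_true"] == "pos").to_numpy()
    subset = ann["t_subset"].to_numpy()
    is_t = np.isin(subset, ("CD4T", "CD8T", "gdT"))

    logmu = np.tile(panel["base_logmean"].to_numpy()[:, None], (1, n_cells))
    gidx = {g: i for i, g in enumerate(panel.index)}
    # lineage markers: high only in their defining populations
    for g in ("CD3D", "CD3E"):
        logmu[gidx[g]] = np.where(is_t, MARKER_ON_LOGMEAN, MARKER_OFF_LOGMEAN)
    for g in ("CD8A", "CD8B"):
        logmu[gidx[g]] = np.where(subset == "CD8T", MARKER_ON_LOGMEAN, MARKER_OFF_LOGMEAN)
    logmu[gidx["CXCR6"]] = np.where(target, MARKER_ON_LOGMEAN, MARKER_OFF_LOGMEAN)

    group = panel["group"].to_numpy()
    bio_rows = group == "put_bio"
    loss_rows = group == "put_loss"
    trans_rows = group == "put_trans"
    cyto_rows = group == "t_cytotoxicity"

    p_cells = p_s.to_numpy()[sample_idx]
    logmu[np.ix_(bio_rows, ~target)] += p_cells[~target]
    logmu[np.ix_(loss_rows, ~target)] += -p_cells[~target] / 2.0
    logmu[trans_rows] += transport_latent.to_numpy()[sample_idx]
    logmu[np.ix_(cyto_rows, subset == "CD8T")] += CYTOTOX_CD8_BASELINE
    logmu[np.ix_(cyto_rows, subset == "NK")] += CYTOTOX_CD8_BASELINE
    for set_name in T_FUNCTIONAL_SETS:
        shift = (cytotox_latent if set_name == "t_cytotoxicity" else eta[set_name]).to_numpy()
        logmu[np.ix_(group == set_name, target)] += shift[sample_idx[target]]

    mu = np.exp(logmu)
    # library scaling applies to the functional/background panel; lineage
    # markers and putrescine genes keep absolute means so detection rates and
    # burden responses stay as designed regardless of panel size
    absolute_rows = np.isin(group, ("marker", "put_bio", "put_loss", "put_trans"))
    mu[~absolute_rows] *= config.library_size_mean / mu[~absolute_rows].sum(axis=0).mean()
    mu *= np.exp(rng.normal(0.0, 0.3, n_cells))[None, :]  # per-cell size factors

    # realized planted association: expected (pre-count-noise) Pi vs C_s
    spa_expected = _expected_spa(mu, panel)
    proxy_pi = np.zeros(len(samples))
    for i in range(len(samples)):
        in_sample = sample_idx == i
        n_target = int((in_sample & target).sum())
        if n_target > 0:
            proxy_pi[i] = spa_expected[in_sample & ~target].sum() / n_target
        else:
            proxy_pi[i] = np.nan
    ok = ~np.isnan(proxy_pi)
    realized = (
        float(spearmanr(proxy_pi[ok], cytotox_latent.to_numpy()[ok]).statistic)
        if ok.sum() >= 3
        else None
    )

    if config.nb_dispersion > 0:
        theta = 1.0 / config.nb_dispersion
        lam = rng.gamma(theta, mu / theta)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=panel.index.copy(), columns=ann.index.copy())
    if config.planted_marker_gene:
        counts_df.loc[config.planted_marker_gene] = _planted_marker_counts(rng, target)

    cd8 = np.isin(subset, ("CD8T",))
    tumor = (ann["tissue"] == "Tumor").to_numpy()
    normal = (ann["tissue"] == "Normal").to_numpy()

    def _frac(mask: np.ndarray) -> float | None:
        denom = int((cd8 & mask).sum())
        return float((target & cd8 & mask).sum() / denom) if denom else None

    truth = SimTruth(
        seed=config.seed,
        put_burden=p_s.round(10).to_dict(),
        cytotox_latent=cytotox_latent.round(10).to_dict(),
        transport_latent=transport_latent.round(10).to_dict(),
        realized_spearman=realized,
        realized_cxcr6_frac_tumor=_frac(tumor),
        realized_cxcr6_frac_normal=_frac(normal),
        coupling_beta=config.coupling_beta,
        hazard_log_hr=config.hazard_log_hr,
    )
    return counts_df, ann, truth


def _planted_marker_counts(rng: np.random.Generator, target: np.ndarray) -> np.ndarray:
    """A target-specific gene: 90% vs 5% detection, 4-fold mean shift."""
    detected = np.where(target, rng.random(len(target)) < 0.90, rng.random(len(target)) < 0.05)
    mean = np.where(target, 8.0, 2.0)
    return np.where(detected, 1 + rng.poisson(mean - 1.0), 0).astype(np.int64)


def pseudobulk(counts: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Sum raw counts per sample (genes x samples)."""
    samples = sorted(ann["sample_id"].unique())
    sample_idx = ann["sample_id"].map({s: i for i, s in enumerate(samples)}).to_numpy()
    order = np.argsort(sample_idx, kind="stable")
    boundaries = np.searchsorted(sample_idx[order], np.arange(len(samples)))
    out = np.add.reduceat(counts.to_numpy()[:, order], boundaries, axis=1)
    return pd.DataFrame(out.astype(float), index=counts.index, columns=samples)


def simulate_bulk_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a bulk survival cohort: (expression, survival table, truth).

    Bulk profiles are pseudobulk sums over simulated cells; survival
    times are exponential with log-hazard proportional to the sample's
    standardized transport enrichment score (computed through the
    package's own normalization and scoring path), with independent
    exponential censoring.
    """
    counts, ann, truth = simulate_sc_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    bulk = pseudobulk(counts, ann)
    cpm = bulk / bulk.sum(axis=0) * 1e6
    scores = ssgsea(bulk_normalize(cpm), genesets.builtin_put_genesets(), normalize=True)
    trans = scores.loc["put_transport"]
    z = (trans - trans.mean()) / trans.std(ddof=0)

    scale = config.survival_scale * np.exp(-config.hazard_log_hr * z.to_numpy())
    event_times = rng.exponential(scale)
    if config.censoring_rate > 0:
        censor_times = rng.exponential(config.survival_scale / config.censoring_rate, len(z))
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed, events = event_times, np.ones(len(z), dtype=int)

    table = pd.DataFrame(
        {
            "sample_id": z.index,
            "time": observed,
            "event": events,
            "feature": z.to_numpy(),
        }
    ).reset_index(drop=True)
    truth.transport_z = z.round(10).to_dict()
    return bulk, table, truth


def as_anndata(counts: pd.DataFrame, ann: pd.DataFrame):
    """Package a cohort as an AnnData (cells x genes, counts in .X)."""
    import anndata as ad

    return ad.AnnData(
        X=sparse.csr_matrix(counts.to_numpy().T),
        obs=ann.copy(),
        var=pd.DataFrame(index=counts.index.copy()),
    )


def write_sc_cohort(
    outdir: str | Path, counts: pd.DataFrame, ann: pd.DataFrame, truth: SimTruth
) -> dict[str, str]:
    """Write MTX + features/barcodes TSV, annotation TSV, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(counts.to_numpy()))
    (outdir / "features.tsv").write_text("\n".join(map(str, counts.index)) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(map(str, counts.columns)) + "\n")
    ann.to_csv(outdir / "annotation.tsv", sep="\t")
    truth.to_json(outdir / "truth.json")
    return {
        "matrix": str(outdir / "matrix.mtx"),
        "features": str(outdir / "features.tsv"),
        "barcodes": str(outdir / "barcodes.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "truth": str(outdir / "truth.json"),
    }


def write_bulk_cohort(
    outdir: str | Path, expr: pd.DataFrame, surv: pd.DataFrame, truth: SimTruth
) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr.to_csv(outdir / "bulk_expression.csv")
    surv.to_csv(outdir / "survival.csv", index=False)
    truth.to_json(outdir / "truth.json")
    return {
        "expression": str(outdir / "bulk_expression.csv"),
        "survival": str(outdir / "survival.csv"),
        "truth": str(outdir / "truth.json"),
    }
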