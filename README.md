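# periput

Putrescine-metabolism scoring for tumor transcriptomics, and its link
to the anti-tumor function of CXCR6⁺CD8⁺ T cells.

Putrescine (PUT), the entry polyamine of the ornithine pathway, shapes
the tumor microenvironment: beyond its role in tumor cell proliferation,
extracellular putrescine can suppress cytotoxic T-cell activity. This
package provides the scoring machinery to study that axis in single-cell
and bulk RNA-seq cohorts:

* **Gene-program scores.** Three putrescine programs — biosynthesis
  (*ODC1, AGMAT, PAOX*), loss (*SRM, OAZ1/2/3, NQO1*), and transport
  (*SLC22A1–3, SLC7A1, ATP13A2/3, GPC1*) — scored per cell or bulk
  sample with the ssGSEA walk statistic
  `ES = Σ_k (P_in(k) − P_out(k))` (rank-weighted in-set ECDF vs uniform
  out-of-set ECDF, α = 0.25), giving S_In, S_Loss, S_Trans and the
  derived indices S_extracellular = S_Trans/S_In and
  S_accumulation = S_In − S_Loss.
* **Pericellular putrescine.** Per cell,
  S_PA = Exp_in/Exp_loss (sums of log-normalized biosynthesis and loss
  gene expression); per sample, the pericellular index
  **Pi = S_1/N** — summed S_PA over all non-CXCR6⁺CD8⁺ cells divided by
  the number of CXCR6⁺CD8⁺ T cells — whose association with the
  functional state of those T cells (cytotoxicity, exhaustion, tissue
  residency, …) is estimated by cross-validated LASSO plus plain
  correlation panels.
* **CXCR6⁺CD8⁺ machinery.** Quality control with two named threshold
  profiles, one-vs-rest ROC marker selection (AUC > 0.85,
  detection-difference > 0.55), DEG screening, tumor-vs-normal
  responsiveness (D_median), and per-sample proportion tests.
* **Outcome links.** Median-split Kaplan–Meier / log-rank survival
  analysis of scores, and canonical correlation analysis attributing
  pathway activity to the putrescine programs.
* **Synthetic cohorts.** A seeded generator that plants known effects
  (tumor-enriched CXCR6⁺CD8⁺ compartment, negative burden–cytotoxicity
  coupling, transport-driven hazard) as log-mean shifts before negative
  binomial count noise, with a ground-truth ledger for recovery testing.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from periput import genesets, markers, pericell, scoring, simulate, survival

cfg = simulate.SimConfig(seed=42)          # 80 samples x 250 cells
counts, ann, truth = simulate.simulate_sc_cohort(cfg)
ann = markers.label_cxcr6_cd8(counts, ann)

lognorm = scoring.lognormalize(counts)
exp = pericell.exp_scores(lognorm)
spa = pericell.spa(exp["exp_in"], exp["exp_loss"])
pi = pericell.pi_per_sample(spa, ann)

pos = ann.index[ann.cxcr6_status == "pos"]
func = scoring.ssgsea(lognorm[pos], genesets.builtin_tcell_genesets())
med = pericell.functional_medians(func, ann)
joined = pi.set_index("sample_id").join(med)
rho = spearmanr(joined["Pi"], joined["t_cytotoxicity"]).statistic
print(f"Spearman(Pi, median cytotoxicity) = {rho:.3f} "
      f"(planted: {truth.realized_spearman:.3f})")

assoc = pericell.lasso_association(pi, med, seed=42)
print(f"LASSO cytotoxicity coefficient = {assoc.coefficients['t_cytotoxicity']:.3f}")

bulk_cfg = simulate.SimConfig(n_samples=300, cells_per_sample=25,
                              hazard_log_hr=np.log(2), seed=42)
_, surv, _ = simulate.simulate_bulk_cohort(bulk_cfg)
res = survival.median_split_logrank(surv)
print(f"median-split log-rank: chi2 = {res['logrank'].chi_square:.1f}, "
      f"p = {res['logrank'].p_value:.2e}")
```

prints

```
Spearman(Pi, median cytotoxicity) = -0.567 (planted: -0.471)
LASSO cytotoxicity coefficient = -0.245
median-split log-rank: chi2 = 56.3, p = 6.09e-14
```

The negative Spearman and LASSO coefficient recover the planted
suppression of cytotoxicity by pericellular putrescine; the log-rank
test separates the survival strata split at the median transport score
(hazard ratio 2 per score SD was planted). Note that raw Pi values span
orders of magnitude: a cell expressing biosynthesis but no loss genes
is ε-guarded (S_PA ≈ Exp_in/ε), so downstream statistics use ranks or a
log response, never the raw Pi scale.

A command-line interface mirrors the library
(`periput simulate|qc|score|markers|pi|survive|cca|validate|run-all`);
`periput run-all --config cfg.yaml` executes the whole pipeline and
writes nine CSV/JSON artifacts with provenance headers plus a manifest.

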