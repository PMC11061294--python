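# ct5hmc

Cell-type-aware analysis of DNA methylation (5mC) and hydroxymethylation
(5hmC) in bulk tumor methylomes, built for paired bisulfite (BS) /
oxidative-bisulfite (oxBS) array studies of pediatric CNS tumors and
non-tumor brain tissue. It is aimed at epigenomics analysts who have
probe-level beta values, per-sample cell-type compositions (e.g. from
single-nuclei RNA-seq), and bulk expression counts, and who want to ask:
how dysregulated is each tumor epigenome, which CpGs change, *in which cell
type* do they change, in what genomic contexts, and with what expression
consequences.

## What it computes

**5mC/5hmC inference.** BS betas measure m + h and oxBS betas measure m.
The per-entry constrained MLE of the binomial likelihood

L(m, h) = n_bs·[β_bs·log(m+h) + (1−β_bs)·log(1−m−h)] + n_ox·[β_ox·log m + (1−β_ox)·log(1−m)],
  subject to m ≥ 0, h ≥ 0, m + h ≤ 1

has the closed form m̂ = β_ox, ĥ = β_bs − β_ox when β_bs ≥ β_ox, and
otherwise the boundary solution ĥ = 0, m̂ = (n_bs β_bs + n_ox β_ox)/(n_bs + n_ox).

**Methylation dysregulation index (MDI).** Per sample s,
MDI_s = mean_c |β_sc − ref_c| where ref_c is the per-probe median of the
non-tumor samples — overall and per genomic context — plus the companion
statistics (two-sample KS, Kruskal-Wallis, Wilcoxon rank-sum, Spearman,
single-pass Grubbs outlier test, OLS of MDI on context and tumor type).

**EWAS with stepwise composition adjustment.** Per probe,
β ~ group + sex + age + purity (+ k cell-type fractions, k = 0..5), with
limma-style empirical-Bayes variance moderation (moderated t on d + d0
degrees of freedom) and BH q-values.

**Cell-type attribution (CellDMC-style).** Per probe,
β_i = Σ_k w_ik a_k + Σ_k (w_ik x_i) b_k + γᵀz_i, with no global intercept;
b_k is the tumor-associated change within cell type k (neuronal-like vs
aggregated progenitor-like NSC+RGC+OPC+UBC by default).

**Context enrichment.** Mantel-Haenszel common odds ratio of hit × context
stratified by Infinium probe design type (I/II), with
Robins-Breslow-Greenland CIs and the MH chi-square p-value, plus Spearman
trends of context proportions across the stepwise series.

**Expression integration.** Median-of-ratios size factors, per-gene
gamma-Poisson GLM (log link, Wald test, BH), Pearson correlation of dhmCpG
effects with gene log2 fold changes, promoter/gene-body odds ratios by
direction of expression change, and binned-control module scores.

**Nuclei demultiplexing.** QC filter (2000 ≤ features ≤ 10000, mito ≤ 5%)
and the integrative HTO + genotype consolidation rule table.

**Synthetic cohorts.** A generator producing all of the above inputs with
planted, auditable ground truth (per-cell-type profiles with 5hmC ≈ 6% of
5mC, Dirichlet compositions, Beta measurement noise, NB counts, corrupted
demultiplexing calls).

## Worked example

```python
import numpy as np
import ct5hmc as c

cfg = c.CohortConfig(
    n_probes=4000, n_genes=400, seed=7, measurement_precision=1000.0,
    groups={"NonTumor": 15, "EMB": 15},
    dirichlet_concentrations={              # non-tumor NEU-rich, tumor progenitor-shifted
        "NonTumor": (12, 1.5, 1.5, 1.5, 1.5, 4),
        "EMB": (2.5, 6, 3, 5, 4, 4),
    },
)
# plant Δ5hmC = +0.25 in the progenitor-like cell types at 150 probes
prof = c.simulate_reference_profiles(cfg)
prog = ["NSC", "RGC", "OPC", "UBC"]
slack = (1.0 - prof["5mC"] - prof["5hmC"])[prog].min(axis=1)
probes = list(np.random.default_rng(0).choice(slack[slack >= 0.3].index, 150, replace=False))
truth = c.make_truth_table(
    [{"probe_id": p, "cell_type": ct, "group": "EMB",
      "delta_5hmC": 0.25, "delta_5mC": 0.0} for p in probes for ct in prog])
cohort = c.simulate_cohort(cfg, truth=truth)

mc, hc, _ = c.estimate_modifications(cohort.bs, cohort.ox)
ref = c.reference_medians(hc, cohort.sheet.index[cohort.sheet.group == "NonTumor"])
mdi = c.compute_mdi(hc, ref)
series = c.stepwise_series(hc, cohort.sheet, cohort.composition, "EMB")
dm = c.CellDMC().fit(hc, c.aggregate_celltypes(cohort.composition),
                     (cohort.sheet["group"] == "EMB").astype(float), sheet=cohort.sheet)
```

Output (printed by the corresponding summaries):

```
mean 5hmC / mean 5mC = 0.067
mean 5hmC MDI by group:
EMB         0.0218
NonTumor    0.0082
stepwise dhmCpG counts (q < 0.05): {0: 1812, 1: 177, 2: 176, 3: 178, 4: 161, 5: 152}
cell-type attribution (dhmCpGs per super-type): {'neuronal_like': 0, 'progenitor_like': 144, 'other': 0}
planted progenitor-like effects recovered: 134/150
```

Reading it: genome-wide 5hmC sits at ~6.7% of 5mC; tumor samples deviate
from the non-tumor reference about 2.7x more than non-tumor samples deviate
from each other; the unadjusted EWAS reports 1812 "differential" CpGs, but
once all five cell-type proportions enter the model the count collapses to
152 — close to the 150 truly planted effects, the rest of the unadjusted
hits being composition confounding; and the interaction model attributes
the signal to the progenitor-like super-type (144 hits, 134 of them
planted probes), with none mis-attributed to neurons.

A shell-level pipeline does the same end to end:

```bash
ct5hmc run --config pipeline.yaml      # simulate -> infer -> MDI -> EWAS -> DMCT -> enrich -> DE
ct5hmc oxbs-mle --bs bs.tsv.gz --ox ox.tsv.gz --n-bs 100 --n-ox 100 \
                --out-5mc 5mc.tsv.gz --out-5hmc 5hmc.tsv.gz
```

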