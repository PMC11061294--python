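# Methods

This note records the models implemented in `ct5hmc`, the defaults and why
they were chosen, the conventions adopted where the underlying methods
leave choices open, and what the synthetic-cohort tests do and do not
demonstrate.

## Measurement model and 5mC/5hmC inference

Tandem conversion yields two beta values per probe per sample: bisulfite
(BS) leaves both 5mC and 5hmC protected, so E[β_bs] = m + h; oxidative
bisulfite (oxBS) converts 5hmC, so E[β_ox] = m. Inference maximizes a
binomial pseudo-count log-likelihood

    L(m, h) = n_bs[β_bs log(m+h) + (1−β_bs) log(1−m−h)]
            + n_ox[β_ox log m    + (1−β_ox) log(1−m)]

over the simplex {m ≥ 0, h ≥ 0, m + h ≤ 1}, with the 0·log 0 = 0
convention at the boundary. The solution is closed-form: the interior
optimum (m, h) = (β_ox, β_bs − β_ox) whenever β_bs ≥ β_ox, else h = 0 and
m is the depth-weighted average (n_bs β_bs + n_ox β_ox)/(n_bs + n_ox).
The pseudo-counts n_bs = n_ox = 100 are effective depths standing in for
array intensity totals, which beta values do not carry; they only matter on
the boundary branch, where they weight the pooled 5mC estimate. A
grid-search oracle (`grid_search_mle`) maximizes the same objective by
brute force — one-dimensional in m because the BS term depends on (m, h)
only through m + h — and the test suite requires agreement to 1e-3 over
random inputs.

## Dysregulation index

MDI_s = mean over probes of |β_sc − ref_c|, with ref the per-probe median
over non-tumor samples. Mean absolute deviation was fixed as the
aggregation because it is the simplest summary consistent with "epigenome-
wide alteration relative to non-tumor tissue", it is bounded in [0, 1], and
it satisfies an exact partition identity (overall MDI = probe-count-
weighted mean of per-context MDIs over any partition) that makes per-context
decompositions internally consistent. Median aggregation is available via
`aggregation="median"`. Missing betas are excluded pairwise and the probe
count used is reported per record rather than imputed. The Grubbs outlier
test is two-sided, single-pass (no iterative removal), with the t-based
critical value ((n−1)/√n)·√(t²/(n−2+t²)), t = t_{α/(2n), n−2}.

## EWAS with empirical-Bayes moderation

Each tumor group is contrasted with non-tumor tissue in its own per-probe
OLS on beta values (no M-value transform): intercept, group indicator, sex
(F = 0), mean-centered age, purity, then k cell-type proportions in a
configurable order (default NEU, NSC, OPC, RGC, UBC) for the stepwise
series k = 0..5. Tumor location is deliberately not a covariate. Constant
columns (e.g. sex in a single-sex subset) are dropped with a warning;
near-collinear designs raise, naming the closest-to-aliased columns.

Residual variances are shrunk by the classical scaled-inverse-chi-square
empirical Bayes scheme: d0 and s0² are estimated by matching the first two
moments of log s² against the log-F distribution (with the trigamma-inverse
Newton iteration), the posterior variance is (d0 s0² + d s²)/(d0 + d), and
the moderated t is referred to t with d + d0 degrees of freedom. `prior_df`
can override the estimate (0 disables moderation — the moderated t then
equals the ordinary t exactly, which the tests assert). "q-values" are
Benjamini-Hochberg by default; a Storey variant rescales by the fixed-
lambda (0.5) estimate of the null proportion. BH was made the default
because it is deterministic and conservative.

Probes with missing betas are fit on complete cases with per-probe residual
degrees of freedom; probes with fewer complete cases than columns are
flagged, not silently dropped.

## Cell-type interaction model

The attribution model per probe is

    β_i = Σ_k w_ik a_k + Σ_k (w_ik x_i) b_k + γᵀ z_i + ε_i

with x the 0/1 tumor indicator, w the super-type fractions and z additive
covariates (sex, centered age, purity; configurable, on by default). There
is no global intercept: on the simplex the composition block spans the
constant, and a remainder column is appended whenever fractions sum to less
than one, so adding an intercept would create exact collinearity. b_k is
the within-cell-type-k beta difference between tumor and non-tumor;
per-cell-type t-tests with BH adjustment within each cell type declare
cell-type-specific differential modification. Granular types are first
aggregated (NEU → neuronal-like; NSC, RGC, OPC, UBC → progenitor-like) to
keep 2K + covariates well below n in small cohorts. Fitting is
unconstrained OLS — fitted per-cell-type betas are estimates and may leave
[0, 1]; they are not clipped. A super-type whose fraction is (numerically)
constant across samples makes its interaction unidentifiable and raises an
error naming it.

## Stratified enrichment

Enrichment of a hit set in a genomic context is tested on 2×2 tables built
within Infinium design-type strata (Type I / Type II), because the two
chemistries differ in context distribution and dynamic range. The common
odds ratio is OR_MH = Σ_s(a_s d_s/n_s) / Σ_s(b_s c_s/n_s); the 95% CI uses
the Robins-Breslow-Greenland variance of log OR_MH; the p-value comes from
the MH chi-square without continuity correction (a correction is available
but off by default, the uncorrected statistic being the standard choice for
the common-odds-ratio test at these counts). Empty strata are skipped; a
zero denominator reports an infinite OR with a one-sided CI. The enrichment
universe is the set of analyzable probes for the assay, not the array
manifest, since hits can only arise from tested probes. Direction-specific
enrichment filters the hit set by the sign of the effect before
tabulation.

## Differential expression and integration

The NB fit is a per-gene gamma-Poisson GLM with log link and
median-of-ratios size-factor offsets, implemented directly so that every
step is oracle-checkable: IRLS with weights μ/(1 + αμ); per-gene dispersion
by a residual-degrees-of-freedom-corrected moment estimator after a Poisson
first pass, optionally shrunk (weight 0.25 by default) toward a parametric
trend α(μ) = a0 + a1/μ; Wald statistic on the group coefficient referred to
t with n − p degrees of freedom (slightly conservative at small n, which
the null-FDR tests confirm); BH adjustment. Deviations from full-featured
count packages are deliberate and documented: no independent filtering, no
fold-change shrinkage, no full empirical-Bayes dispersion machinery. In the
Poisson limit (α = 0) the Wald statistics coincide with a Poisson GLM, and
on small fixtures the fold changes track an independent reference
implementation; both are asserted in tests.

Integration pairs differentially modified CpGs with mapped genes (one row
per CpG; genes with several CpGs contribute several rows) and reports
Pearson r overall and among genes significant at p_adj < 0.05. The
promoter/gene-body analysis cross-tabulates expression direction
(increased/decreased) against context membership (promoter = TSS200 ∪
TSS1500; gene body flag), with the Woolf CI, Haldane-Anscombe 0.5
correction only when a cell is zero, and Fisher's exact p on the
uncorrected table.

Module scores use binned controls: genes are ranked by average expression
into 24 bins and each set gene draws 100 control genes from its bin
(excluding set genes, iterated in sorted order so scores are independent of
gene-set ordering); the per-cell score is mean(set) − mean(control pool).
The expression matrix convention is log1p of depth-normalized counts.
Per-cell-type group contrasts use the Wilcoxon rank-sum test.

## Nuclei QC and demultiplexing

Nuclei are kept iff 2000 ≤ features ≤ 10000 and mitochondrial percentage
≤ 5 (the removal rule is strict inequality on each side, so the boundary
values are kept). Consolidation is HTO-first: a singlet HTO call confirmed
by the same genotype call is kept (R1); contradicted, discarded (R2); HTO
Doublet/Negative with a genotype singlet falls back to the genotype (R3);
both uninformative, discarded (R4). The case not covered by those rules — a
singlet HTO with an Unassigned/Doublet genotype (R5) — is discarded by
default, symmetric with the conflict rule, with a `trust_hto` option to
keep the HTO call instead. The rule table is total over both call
vocabularies and is exercised exhaustively in tests.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure the analysis assumes:
bimodal per-probe 5mC with correlated cell-type variation; 5hmC drawn
proportional to 5mC with exponential probe-level variation, calibrated by a
deterministic rescale-and-clip loop so the genome-wide mean(h)/mean(m)
tracks the configured prevalence (6% by default, matching the low
genome-wide prevalence of 5hmC relative to 5mC in brain tumor tissue);
Dirichlet compositions per group (defaults make non-tumor tissue
neuron-rich and tumors progenitor-shifted — qualitative placeholders, since
only qualitative composition differences are available to anchor them);
Beta-distributed measurement noise with a single precision pseudo-count
shared by BS and oxBS (default 200, i.e. per-probe SD ≈ 0.035 at
intermediate betas, a plausible array-scale noise level); NB counts with
configurable dispersion (default 0.1, typical of bulk RNA-seq); and
demultiplexing calls corrupted from truth at configurable rates. Default
group sizes mirror a small pediatric cohort (non-tumor 2; ATC 8, EMB 6,
EPN 10, GNN 8); recovery and calibration tests override them to the sizes
stated with each test. Sex, age and purity are drawn independently of group
— the clean regime; composition confounding is induced explicitly by
giving groups different Dirichlet concentrations.

Planted effects are applied per cell type (or "bulk" for all cell types)
and clipped to the simplex, with every clipped entry reported, so truth
tables remain auditable; recovery simulations plant at probes with
headroom so the realized delta equals the requested one. Planted
differential expression should be balanced (or sparse) across directions:
strongly one-sided DE contaminates median-of-ratios size factors, a real
property of that normalization, not an artifact of the generator.

What passing tests do not show: the generator has no probe-level
correlation structure (neighboring CpGs are independent), no Type I/II
chemistry differences beyond the stratification label, no batch or slide
effects, no purity-composition coupling, and measurement noise is exactly
Beta with a shared precision. Calibration and sensitivity measured here are
therefore best-case values for data meeting the model's assumptions, not
predictions for any particular real cohort, and the headline numbers from
real tumor cohorts (hit counts, specific odds ratios, correlations) are not
reproducible from synthetic data.

## Numerical conventions

Beta means are clipped to [1e-6, 1 − 1e-6] before Beta noise sampling;
composition rows must sum to 1 within 1e-6; gzip outputs are written with a
fixed header timestamp so re-runs are byte-identical; per-stage RNG seeds
derive from the master seed by hashing the stage name (kept below 2^31), so
stages can be re-run independently and reproducibly. IRLS runs at most 50
iterations with relative tolerance 1e-8; non-converged genes are flagged.
Problem sizes in the test and acceptance simulations (10,000 probes for
calibration, 2,000 for attribution and the end-to-end run, 2,000 genes,
2,000 Monte-Carlo replicates for the MH type-I check) were chosen as the
smallest scales at which the measured rates stabilize.
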