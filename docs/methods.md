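# Methods

This note records the statistical model implemented by `genoboost`, the
numerical choices behind it, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Boosting model

The predictor is `F(x) = F_cov(x) + Σ_t γ f_t(g_t(x))`, a covariate-only
logistic linear predictor plus a sum of shrunken single-variant score
functions. Each `f_t` maps the dosage of one variant (minor-allele count,
0/1/2) to a real score. Fitting is LogitBoost-style: at each iteration the
logistic log-loss is locally approximated by the weighted least-squares
surrogate in the working response `z` and weight `w = p(1-p)`, the surrogate
is minimized in closed form per variant, and the variant with the smallest
surrogate loss is added with learning rate `γ`.

Key property: with the unclipped working response, `w·z` equals `y* − p`
(the negative gradient of the log-loss with respect to the per-sample
score), so the non-additive per-class score `s_k = U_k / W_k` is exactly a
damped one-dimensional Newton step for genotype class `k`, and the additive
`(c, α)` solve is the damped two-parameter Newton step restricted to the
line `f(g) = c + αg`. Newton directions on a convex loss are descent
directions; with `γ ≤ 0.5` we observe strictly decreasing training log-loss
on every tested cohort, and the test suite asserts it at `γ = 0.1` over 200
iterations.

### Working-response clipping

A `z_max` clip on the working response is a traditional LogitBoost
stabilization and is available in `HyperParams`, but the default is *no
clipping*. Clipping `z` while leaving `w = p(1-p)` intact replaces a
poorly fit sample's gradient contribution `y* − p` with `z_max·p(1-p)`,
which vanishes as `p → 0`; a class dominated by well-fit samples can then
receive a step that *increases* the loss on its few badly fit members
without compensation — we observed sustained log-loss ascent on seeded
cohorts with `z_max = 4`. Probabilities are internally clipped to
`[1e-8, 1 − 1e-8]` only to keep `w·z` finite near separation; the weight
floor `w_floor = 1e-10` guards empty-class divisions and never binds under
the probability clip.

### Degenerate variants

A variant with fewer than two populated genotype classes is skipped during
selection in both model kinds: its only expressible effect is a constant
shift of `F`, which is an intercept, not a genetic effect (such variants
are also removed by the MAF filter under default QC). In the non-additive
solver an *empty* class still receives a score so the function is total —
the heterozygote score for an empty homozygote class, the homozygote
midpoint for an empty heterozygote class — which leaves the surrogate loss
unchanged because the class carries zero weight.

### s2 regularization

`s2_clip` clamps the homozygous-minor score to `|s₂ − s₀| ≤ s2_clip`. The
clamp is defined relative to the homozygous-major baseline `s₀` rather
than to zero because the raw triplet contains an arbitrary level: only
score *differences* are identified, and `s₂ − s₀` is the homozygous-minor
effect. Default: off (`None`); at biobank-scale MAF spectra the clamp
matters mainly for variants with a handful of minor homozygotes.

### Batch screening

For panels of ≤ 10,000 variants every iteration scans all variants. Above
that, a full scan runs at iteration 0 and every `m_batch` (default 50)
iterations; between full scans selection is restricted to the `m_batch`
best variants of the last full scan. The refresh rule is a documented
approximation chosen for determinism and simplicity; results at desk scale
are unaffected because desk-scale panels take the full-scan path.

### Selection determinism

Loss ties break toward the smallest variant index; all randomness lives in
the data and split seeds, so refits are bit-reproducible.

## Covariate model

`F_cov` is a logistic regression of case status on covariates, fit by
Newton–Raphson with step-halving whenever a step would decrease the
likelihood (the guard that matters under quasi-separation). Covariates are
variance-standardized internally for conditioning; coefficients are
reported back on the natural scale. Fits that stop on the iteration cap
are flagged `converged=False` and keep the last damped iterate. The same
routine provides the Wald tests of the GWAS-coding comparator. No Firth
penalization is implemented: under *perfect* separation (e.g. an extremely
penetrant recessive genotype where every minor homozygote is a case) the
Wald statistic degenerates and that coding is dropped with a warning —
a known fidelity gap relative to GWAS pipelines with Firth fallback.

## Cross-validation and model choice

Samples are split 80/20 into development and held-out test sets, the
development set into five phenotype-blind folds. Because boosting is a
deterministic prefix algorithm, one run at the largest `T` yields the model
at every smaller `T` by truncating the learner list; the grid over
`γ ∈ {0.05, 0.1, 0.2, 0.5}` × 29 iteration counts
(5, 10…100, 200…1000, 2000…10000) × {additive, non-additive} = 232 cells
therefore costs 8 boosting runs per fold. The validation metric is the
covariate-adjusted pseudo-R² on the held-out fold, with model coefficients
for the metric fit on that fold. Ties break toward smaller `T`, then
smaller `γ` (the sparser, more regularized model). Per-fold winners are
retained; the reported best cell maximizes the mean validation metric
across folds, and fold 0 is the default primary fold for interpretation.

## Evaluation metrics

* **Covariate-adjusted pseudo-R²** (Nagelkerke / Cragg–Uhler): likelihood
  ratios are computed in log space and exponentiated only inside the `2/n`
  power, so the metric is stable at any sample size. Coefficients of the
  covariate-only and covariate+PGS models are fit on the validation set and
  frozen before test-set evaluation; fitting on the evaluation set itself
  is allowed for toy usage but warns.
* **Top-q% odds ratio**: samples ranked by genotype-only PGS, top
  `ceil(q·n)` versus remainder, `q ∈ {1, 3, 5, 10}%`. A zero contingency
  cell raises an explicit error rather than returning infinity.
* **AUC** (Mann–Whitney) and **AUPRC** (non-interpolated average
  precision), via scikit-learn.

## Mode-of-inheritance classification

The cumulative triplet is summarized by `θ = (S₁ − S₀)/(S₂ − S₀)` with the
*signed* span — the triplet is not re-oriented. Bands (defaults
`tau_add = 0.125`, `tau_over = 0.25`, `zero_tol = 1e-8`):

| condition | label |
| --- | --- |
| all three scores within `zero_tol` | null |
| `|θ − 0.5| ≤ tau_add` | additive |
| `0.5 + tau_add < θ ≤ 1 + tau_over` | dominant |
| `−tau_over ≤ θ < 0.5 − tau_add` | recessive |
| `S₁` above both homozygote scores (incl. tied homozygotes) | over-dominant |
| `S₁` below both | over-recessive |

Two properties motivated the signed-θ form: (1) the labels are invariant to
adding a constant to the triplet and to positive rescaling; (2) reversing
the triplet — an allele flip — maps dominant ↔ recessive and fixes
additive and both over-modes, matching how a GWAS would relabel the same
locus after swapping the counted allele. Re-orienting the triplet so
`S₂ ≥ S₀` inside the classifier would destroy property (2) (reversal would
become a no-op), so a dominant *protective* minor allele is labeled
dominant, not recessive-of-the-major-allele. The over-modes are decided by
the heterozygote's position relative to both homozygotes rather than by θ
alone because for a negative span `θ > 1` means the heterozygote lies
*below* both homozygotes. The band half-widths are configuration: they set
the granularity at which "deviation from additivity" is called, and no
claim is made that they reproduce any particular published threshold.

The GWAS comparator fits one logistic regression per coding (additive `g`;
dominant `1{g≥1}`; recessive `1{g=2}`; heterozygote-only `1{g=1}`), takes
the two-sided Wald p-value of the genotype term, and maps the most
significant coding to a label; a winning heterozygote-only coding is
over-dominant for a risk-increasing coefficient (minor-allele orientation
fixed at load time) and over-recessive otherwise. A 3-class comparison
(`coarse_label`) collapsing over-modes into dominant/recessive is provided
alongside the 5-class one, since published confusion matrices are sometimes
reported at the coarser granularity.

## Synthetic cohorts

The generator emulates: biallelic SNVs in Hardy–Weinberg proportions with
per-variant allele frequency uniform on a configurable MAF interval;
liability-threshold binary phenotypes with configurable polygenicity
(`n_causal`), liability-scale heritability `h2`, prevalence, and per-variant
inheritance mode through mode-specific encodings (additive `g`, dominant
`1{g≥1}`, recessive `1{g=2}`, over-modes `±1{g=1}`), each standardized
in-sample; effect sizes `β ~ N(0, h2/n_causal)`, so heritability is split
evenly among causal variants; and case status assigned by the empirical
liability quantile, which fixes the realized case count exactly (removing
binomial prevalence noise from recovery experiments) at the cost of a
microscopic dependence between samples.

It deliberately does **not** emulate: linkage disequilibrium, population
structure or relatedness, genotyping missingness patterns, imputation
uncertainty, or variant–variant interaction. Passing recovery tests on
these cohorts therefore demonstrates correctness of the fitting machinery
under the generative model, not performance on real biobank data, where LD
spreads signal across correlated variants and selection is correspondingly
less interpretable.

Defaults (used by the bundled experiments): n = 2000 samples, 500 variants,
10 causal variants, `h2 = 0.5`, prevalence 0.3, MAF ∈ [0.05, 0.5]. These
sizes give clear signal margins while keeping each experiment in the
seconds range on one CPU. The polygenicity study grid
(`n_causal ∈ {10, 100, 1000, 5000}` × `h2 ∈ {0.2, 0.5}`) is this package's
own stand-in design for a polygenicity sweep; it is not a reproduction of
any published simulation protocol.

## Genotype I/O and QC

PLINK 1 SNP-major bed/bim/fam is read and written directly (2-bit codes:
00 hom-A1, 01 missing, 10 het, 11 hom-A2). Columns whose counted allele is
the major allele are flipped on load and the flip recorded, so `S₂` always
refers to the homozygous-*minor* genotype. Default QC keeps variants with
MAF > 1%, Hardy–Weinberg 1-df chi-square goodness-of-fit p > 1e-6,
missingness < 5%, and unambiguous A/C/G/T biallelic alleles. The
chi-square HWE test (not the exact test) was chosen because it is
deterministic, adequate at the common-variant frequencies in scope, and
configurable; monomorphic variants return p = 1 and are removed by the MAF
filter instead. Missing genotypes are excluded from the sufficient
statistics and contribute zero to predicted scores; no imputation is
performed.

## Limitations

* Binary phenotypes only; no quantitative-trait loss.
* No LD awareness: correlated variants compete for selection greedily.
* No Firth fallback in any logistic fit (see above).
* The additive PGS-catalog-style export collapses each triplet to
  `(S₂ − S₀)/2` per allele and discards the dominance deviation (a warning
  is emitted).
* Batch screening above 10,000 variants uses an approximate refresh rule.
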