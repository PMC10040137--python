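# Methods

This note documents the models and procedures implemented in `duomethyl`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Synthetic paired methylome generator

The generator produces maternal and neonatal beta matrices with the joint
structure the downstream analyses assume, plus a complete truth table. All
modelling happens on the logit scale; emitted betas are the inverse logit,
clipped to (1e-6, 1−1e-6) so ranks and logits stay finite.

**Per-site model (autosomes and X-escape sites).** For site *j*, mother *i*:

    logit(β_m) = μ_j + a_j (age_i − age_mid) + g_mij + Σ_k λ_jk L_ik + ε,
    ε ~ N(0, noise_sd²),   Var(g_mij) = h²_j σ²_tot,j

with σ²_tot,j = noise_sd² / (1 − h²_j), so `noise_sd` is exactly the
residual SD and h² is the additive-genetic fraction of the age- and
batch-free variance. The newborn's genetic value is

    g_c = 0.5 g_m + e,   Var(e) = 0.75 Var(g_m).

Fathers are unobserved; under this standard additive model the mother–child
correlation of the latent values is exactly h²/2 — the closed-form oracle
used throughout the tests. h² is capped at 0.98 to keep σ²_tot finite.
Male newborns additionally receive `sex_effect_j` on the flagged
sex-differential autosomal sites.

**X inactivation.** A configurable fraction of X sites (default 0.8) is
XCI-subject. Mothers and daughters emit the balanced allele average

    β = 0.5 [inv-logit(active draw) + inv-logit(inactive draw)],

where the active draw carries the genetics/batch/noise structure above
(active-allele μ drawn low, island-promoter-like: N(−2.0, 0.7)) and the
inactive draw is centred at a high per-site mean μ_inactive ~ N(+2.0, 0.7)
— the inactive X is predominantly methylated. Sons are hemizygous and emit
the single active-allele draw. Consequences, all asserted by tests: female
and maternal X betas centre near 0.5 while male betas sit near the active
level; mother–male ΔDNAm on XCI sites is strongly negative while
mother–female Δ centres on zero; per-sample mean X beta separates the sexes
(used for the QC sex check); and mother–daughter X profiles correlate more
strongly than mother–son profiles because the across-site variation of
μ_inactive appears in both female generations but not in sons. Skewed XCI
and imprinting are out of scope.

**Latent structure.** K latent factors (default 2) have N(0,1) scores per
individual and sparse N(0, loading_sd) loadings. Switches support: binary
scores (plate-like batches), scores shared within a pair (co-placement), and
newborn-only factors (cord-blood plates distinct from maternal plates). The
batch-recovery experiments use a newborn-only binary factor with fixed
loading 1.0 on 40% of sites.

**Defaults and what they emulate.** 200 pairs / 5,000 sites (scaled per
experiment); 54.5% male newborns; maternal age uniform on 15–46 y; ~65%
Black, ~11% smoking, preterm more frequent among male newborns (21% vs 11%),
~30% C-section — the covariate mix of an urban US birth cohort. The default
h² distribution (60% mass on Uniform(0, 0.05), 40% on Uniform(0.05, 0.95))
mimics the long right tail of published mQTL heritability catalogues.
Clinical covariates other than maternal age have no methylation effect by
default, so they act as pure adjustment variables and nulls stay null.

**What the generator does not emulate** — and hence what passing tests do
not establish about real arrays: probe-type chemistry and dye bias,
detection-failure patterns, cell-composition mixtures with reference
profiles (latent factors are a linear proxy), population structure beyond a
binary indicator, imprinting, and environment shared within a pair (exposed
as `share_latent_within_pair` rather than asserted).

## Quality control

Site filters: detection p > 0.01 in strictly more than 5% of samples
("over" read as a strict inequality), plus an external mask file for
SNP-overlapping/cross-hybridising probes (one ID per line) — masks are
curated lists, not an algorithm. Sample filters: missingness strictly above
2% of sites; and a methylation-predicted sex check via an exact 1-D
two-means split of mean X beta (higher cluster = female, per the
allele-average model), with the split threshold recorded in the QC report.
Sites with residual missingness are handled listwise per analysis;
imputation is deliberately out of scope.

**Inverse normal transform.** Φ⁻¹((r − 3/8)/(n + 1/4)) on average ranks —
the Blom offset, the conventional choice where no specific rank-to-normal
map is mandated. Ties share average ranks; constant vectors are an error
(or a flagged site inside matrix-level routines). The transform is applied
to the non-missing entries of each site's vector after listwise deletion.

## Paired correlations and the permutation null

Spearman ρ per pair over all, autosomal, and X site subsets (average ranks
for ties; pairwise deletion of missing betas). The null preserves the
between-site correlation structure while destroying relatedness: within
each newborn-sex stratum, a derangement reassigns newborns to unrelated
mothers; per newborn, the background value is the mean ρ over `n_iter`
(default 10) iterations — the across-iteration mean, not the pooled set.
Derangements are drawn by rejection sampling (expected ≲ e draws); a
stratum of one admits no derangement and errors. Matched vs background uses
the paired t on per-newborn differences (a zero-variance difference vector
is flagged and reported as p = 1 rather than an exception); between-sex
contrasts use the Welch t, the safer default when variances differ.

## Surrogate variables

`estimate_n_sv` residualises the outcome matrix on the known design and
counts leading singular values exceeding the 95th percentile of their
counterparts under row-wise permutation of the residuals (parallel
analysis, default 10–20 permutations). The count is data-driven; a fixed
override is available in the pipeline config.

`estimate_svs` iterates: residualise → SVD → per-site weights → weighted
SVD, until the sine of the largest principal angle between successive SV
subspaces falls below `tol` (1e-4; max 50 iterations; non-convergence
returns the best iterate with a warning, never silently).

Two choices here deserve emphasis:

- **The design protects the exposure.** Newborn sex is part of the design
  used for residualisation and weighting. Without it, the leading SV of the
  Δ outcome is simply the male X-methylation deficit, and adjusting for it
  annihilates the very signal being tested.
- **Weights and reconstruction.** Weights are
  w_j = [F_sv/(F_sv + 1)] · 1/(1 + F_cov) — a bounded surrogate for
  "associated with the latent structure AND not with the design": the
  second factor removes sites carrying true design signal from the
  decomposition. The iteration runs on residuals, but the returned SVs are
  rebuilt from the weighted, row-centred *raw* outcome. Residual-space SVs
  are orthogonal to the design by construction, so the component of a
  nuisance factor that happens to correlate with the exposure in a finite
  sample could never be adjusted away; reconstruction from raw data
  captures the whole nuisance direction. Tests verify both faces: an
  injected batch is recovered (|r| > 0.8) and post-adjustment genomic
  inflation of null sites returns to [0.9, 1.1], while the XCI sex signal
  survives adjustment.

Two SV sets are estimated per run — one with the neonatal matrix as
outcome (for the site EWAS), one with Δ as outcome (for the sex EWAS) —
with K chosen separately for each.

## Site EWAS

Per site, maternal and neonatal vectors are INT-transformed separately,
then OLS under the full and reduced models (see README for the formulas;
SVs enter as main effects only — maternal×SV terms are deliberately
excluded). The LRT statistic is n·log(RSS_reduced/RSS_full) on χ² with df
equal to the column difference (7 with the five clinical covariates:
maternal main effect + maternal×sex + five maternal×covariate terms; 8 with
parity enabled). The Gaussian OLS likelihood makes this identical to
2·Δlog-likelihood, asserted against an independent log-likelihood oracle to
1e-8. The interaction test is the Wald t of the maternal×sex coefficient,
algebraically identical to the single-constraint F (also asserted).
Race enters as a binary Black/non-Black indicator; parity is an optional
sensitivity toggle. Rank-deficient or constant sites are flagged with
missing statistics, never dropped silently. With ~300 samples the χ²
calibration is mildly liberal (null p < 0.05 fraction ≈ 0.06, within the
accepted band); the finite-sample alternative (F calibration) is not what
the method specifies.

BH-FDR is computed jointly over all tested sites, autosomes and X together,
for both the LRT and the interaction p-values (the spec leaves the
interaction FDR scope open; the joint choice is recorded in output
metadata).

## Δ EWAS and summaries

Descriptive Δ summaries are pooled over site×pair observations on the raw
beta scale, by sex × chromosome class (pooling choice labelled in output);
the regression uses INT(Δ) per site on sex + covariates + SVs. The sex
coefficient's sign convention (0 = female, 1 = male) makes β > 0 mean
"mother–male difference larger". Constant-Δ sites are reported with missing
statistics and a flag.

## Replication and enrichment

Discovery-significant sites are inner-joined to the replication table;
replication significance is re-assessed by BH within the overlapping sites.
Direction concordance among replication-significant sites is tested by a
1-df chi-square goodness-of-fit of (consistent, inconsistent) counts
against 50:50 — the no-shared-direction null; the contingency structure of
the original analysis is not published, so this reading is recorded in the
output. Percentages are half-up rounded to one decimal, matching printed
convention.

Heritability strata report the *median* h² of the top-N sites by ascending
p against the genome-wide median, autosomes only (heritability catalogues
cover autosomes). Pathway over-representation is the one-sided
hypergeometric upper tail against a universe defaulting to all genes
mappable from the analysed sites (the conservative EWAS-background choice;
overridable); gene sets come from GMT files, multi-gene site annotations
split on the manifest semicolon convention. Enrichment only — depletion is
not tested.

## Pipeline, seeding, numerics

One global seed fans out to per-stage seeds by hashing the stage name, so
stages re-run independently yet reproducibly; the manifest records config
hash, per-stage seeds, wall times, and SHA-256 checksums of every output.
Result TSVs are byte-identical across same-seed runs. Floating output uses
%.10g; probabilities are clipped at 1e-300 before logs; SVD sign
indeterminacy is fixed by making each component's largest-magnitude entry
positive.

## Experiment sizes

The validation experiments use 200–400 pairs and 2,000–5,000 sites —
cohort-realistic sample sizes with site counts chosen so that null
calibration (2,000 tests), rank-recovery (2,000 sites), and the X/autosome
contrast (1,000 X + 4,000 autosomal) are each well-resolved while the whole
suite runs in well under a minute per experiment. The h²-recovery
experiment sweeps h² ~ Uniform(0, 0.95) across sites rather than using the
default mixture: recovery of a *ranking* is only informative where the
parameter actually varies, and inside the default near-zero band
(h² < 0.05) true correlations differ by less than the n = 300 sampling
error of a correlation coefficient, so ranks there are noise by
construction. The mean-recovery experiment pins h² = 0.8 and checks the
observed mean correlation against the h²/2 = 0.40 closed form.

## Known limitations

Gaussian OLS only (no robust/sandwich errors, no mixed models); beta-scale
analysis (no M-values); the permutation null reassigns mothers to newborns
(per-newborn averaging; the mirror-image choice is not implemented);
hypergeometric ORA ignores gene length and probe density bias; the
generator's latent factors are linear and its covariates effect-free by
default, so confounding-by-measured-covariates scenarios must be
constructed by the user.
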