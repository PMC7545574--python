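# Methods

This note documents the models implemented in `micromr`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Synthetic cohort generator (`micromr.simulate`)

The generator emulates a community-based cohort with paired genotype-array
and 16S microbiome data plus external disease GWAS summary statistics.
Everything is driven by one integer seed; each operation draws from an
independent, reproducible stream derived from it.

**Genotypes.** Dosages in [0, 2] arise from two independent haplotypes.
Each haplotype is a latent standard Gaussian with AR(1)-structured
correlation inside LD blocks (blocks are mutually independent), thresholded
at `Φ⁻¹(MAF)` to give allele indicators. Thresholding attenuates
correlation — severely at low MAF — so the latent adjacent correlation is
calibrated per variant pair by inverting the tetrachoric relationship
(bivariate normal CDF via Owen's T, Brent root-finding) so that the
realized *genotype* correlation matches the requested `ld_rho`. Because a
frequency mismatch between neighbours caps the attainable phi coefficient,
MAF is drawn per block with a small (SD 0.01) within-block jitter; variants
in tight LD sharing a frequency history is also how real haplotypes behave.
Allele pairs exclude strand-ambiguous A/T and C/G combinations, as array
designs do. The genetic map is a constant 1 cM/Mb (configurable); variants
sit 5 kb apart on one chromosome, so a 20-variant block spans 0.1 cM — one
clumping window.

**Taxa.** Common taxa: log abundance = genetic value + Gaussian noise, with
the genetic fraction of variance exactly `taxon_h2` in-sample. The genetic
value sums `n_causal_per_taxon` standardized dosages with equal-magnitude,
random-sign weights: every causal variant contributes the same variance
share, giving uniform instrument strength. (Gaussian weights were
considered and rejected: a few variants then dominate, leaving too few
usable instruments for any downstream MR demonstration; realistic effect-
size spectra are out of scope.) Rare taxa: presence from a probit liability
threshold hitting a target prevalence drawn from `rare_prevalence_range`,
with abundance log-normal conditional on presence and independent of it —
matching the downstream binary treatment of rare taxa. Counts come from one
multinomial draw per sample at 10,000 reads (the rarefaction depth used
throughout). Note that observed abundances are compositional: with very few
taxa the shared denominator leaks between taxa and attenuates heritability
estimates; at the 40–114-taxon scales used here the effect is negligible.

**Disease and instruments.** Cohort disease status follows a logistic model
on `n_disease_taxa` (default 16) Z-scored common taxa with equal
coefficients (default 0.3 per SD), intercept calibrated to an 11.5 % case
fraction. External disease instruments carry log-odds effects drawn from
`instrument_beta_range` with sampling noise matching a GWAS of
`outcome_gwas_n = 100,000` (case fraction 0.2); a configurable fraction is
marked pleiotropic in the ground truth. For the forward direction,
`taxon_outcome_summary_stats` builds a quantitative-trait GWAS in which each
variant's true effect is `causal_effect` times its empirical (LD-aware)
marginal effect on the taxon's genetic value, with noise at the precision
of a `trait_gwas_n`-subject study.

**Pathway features.** Each predicted disease/pathway feature is a
non-negative noisy linear combination (uniform weights in [0.5, 1.5]) of
one of several disjoint taxon subsets; features sharing a subset share a
ground-truth cluster label. Default noise SD is 5 % of the systematic SD.

**What passing tests do not show.** The generator has no population
stratification (off by default by design), no phylogenetic correlation
among taxa, no read-level sequencing error, and equal causal effect sizes.
Parameter recovery here demonstrates correctness of the estimators under
their assumptions, not robustness to the full messiness of real cohorts.

## Heritability (`micromr.genetics`)

GREML with a single GRM. One eigendecomposition `K = UΛUᵀ` rotates the
model so the covariance is diagonal; the restricted likelihood, its
gradient, and the average-information matrix are then O(n p²) per
iteration, and the estimates equal the dense formulation to machine
precision (verified against a dense-matrix oracle at 1e-8). Updates are
AI steps with step-halving, falling back to EM when the AI step fails;
convergence at relative log-likelihood change < 1e-6, cap 100 iterations;
components floored at 1e-8 of the phenotypic variance with a boundary flag.
A GRM numerically proportional to the identity is flagged
non-identifiable. SE of h² by the delta method from the inverse AI matrix.

Mixed-model association (leave-one-chromosome MLMA) is deliberately
replaced by fixed-effect regression with the top five genetic PCs as
covariates: the synthetic cohorts carry no cryptic relatedness, where the
two coincide. This is a documented divergence from the cohort-scale
practice the pipeline mirrors. Genomic inflation is the median-χ² λ_GC
(reference-free), not an LD-score regression intercept.

The polygenic-score validation model is a Gaussian linear model on the
Z-scored log abundance. A negative-binomial GLM on raw counts is available
(`outcome_kind="negative-binomial"`) for fidelity, but a count model
applied to a Z-scored quantity is internally inconsistent, so it is not the
primary route.

## Mendelian randomization (`micromr.mr`)

Per-instrument inputs are allele-harmonized: outcome effects are flipped
when the outcome's effect allele is the exposure's other allele;
palindromic variants are oriented by allele frequency only when both EAFs
are outside [0.42, 0.58], otherwise dropped; incompatible allele sets are
dropped with a count.

* IVW: weighted regression through the origin, weights `se_y⁻²`;
  multiplicative random-effects SE inflation `max(1, Q/(k−1))` by default
  (fixed-effect via flag); a single instrument degrades to the Wald ratio.
* Weighted median: per-instrument ratios weighted by inverse delta-method
  variance; the estimate interpolates where the cumulative normalized
  weight (midpoint convention) crosses 0.5; SE by parametric bootstrap
  (default 1000 draws, seeded).
* Egger: WLS with intercept after orienting exposure effects non-negative;
  SEs scaled by a residual overdispersion factor floored at 1; t reference
  with k−2 df. Note Egger requires spread in instrument strengths and
  precisely estimated exposure effects; calibration studies therefore use
  small exposure-side SEs.
* PRESSO-style test: the observed weighted RSS of leave-one-out IVW
  predictions is compared to a parametric null (default 1000 simulated
  instrument sets under the fitted causal model); empirical p with +1
  smoothing, so min p = 1/(n_sim+1). Per-instrument outliers at the
  Bonferroni-adjusted level; the corrected estimate is IVW without them.
  Detecting an outlier at k = 30 instruments requires
  n_sim ≥ k/0.05 − 1 ≈ 600; the default 1000 leaves headroom.

**Instrument exclusion.** Forward-direction instruments associated with the
outcome at `p < 0.05/n` are excluded, where `n` is the number of
independent lead variants selected in the polygenic-score stage — pooled
across exposures, not this pair's instrument count. The distinction
matters: with the per-pair denominator the screen truncates every
per-instrument outcome association at roughly z = 2.7 while joint
Bonferroni significance needs z > 3.35, which makes the screen
self-defeating precisely when a true causal effect exists. The per-pair
count remains the default of `select_instruments` when no pooled count is
supplied. Reverse-direction instrument sets are thinned to pairwise
r² < 0.1 in the cohort LD reference, keeping the smaller-p member; missing
variants may be replaced by the best proxy with r² > 0.9, else discarded.

**Classification.** *Significant*: IVW p below 0.05/62 (forward; 58 traits
plus 4 diseases) or 0.05/n_eff (reverse, with n_eff the effective number of
independent taxa at that taxonomic level). *Potential causal*: Bonferroni
failed but all four methods nominally p < 0.05. Otherwise *null*. Forward
effects are reported per 1 SD of log-transformed abundance; reverse effects
per log-odds of disease (odds ratio of presence for binary taxa).

## Taxon-table processing (`micromr.features`)

Rarefaction is one seeded multivariate-hypergeometric draw per sample
(without replacement); samples below depth are dropped and reported.
Shannon is base 2; Chao1 uses the classic `S + F1²/(2F2)` with the
`F1(F1−1)/2` correction when F2 = 0. Zeros before the log transform are
replaced by half the taxon's minimum nonzero relative abundance
(configurable); the paper-scale pipeline is silent on this point. The
effective-number statistic is computed on Z-scored columns by default
(covariance = correlation), making it scale-free; the raw-covariance
variant is exposed via `standardize=False` since the matrix scaling is an
open question. Enterotyping: pairwise square-root Jensen–Shannon divergence
(base 2), PAM over candidate k, k chosen by the Calinski–Harabasz index on
the relative-abundance matrix.

## Disease features (`micromr.disease`)

PAM is the classic BUILD + SWAP (best improving exchange per pass,
tie-break by lowest object index). Because SWAP is a local search that
reaches the exhaustive optimum on only ~85–90 % of small random instances,
four additional seeded random initializations are polished and the best
kept — fully deterministic, and ≥95 % oracle agreement on 12-object
instances. Silhouette widths use the displayed formula with singleton
clusters assigned width 0 (the R `cluster` convention); k is the argmax of
the average width, ties to the smaller k. Jaccard similarity counts
unordered object pairs co-clustered in both/either partition; the
degenerate all-singletons case is defined as 1 with a warning.

Disease features are clustered on Euclidean distance between Z-scored
feature profiles (features are the objects, i.e. the transposed table);
clustering cohort-average profiles instead is a caller-side one-liner. The
MRS learns, on a training table, the taxa with |Spearman ρ| strictly above
0.2 against the target feature, their direction (sign of ρ), and their 5 %
empirical quantile cutoffs (type-7 interpolation); cutoffs are frozen in
the model so the score is reusable on new samples.

## Pipeline and study conditions

`run_pipeline` chains: simulation → rarefaction/alpha
diversity/partition/transform/effective number → GRM + GREML → PC-adjusted
GWAS of a target taxon → clumping → polygenic score → forward MR against a
simulated trait GWAS → reverse MR from disease instruments → pathway
clustering with silhouette k selection and Jaccard versus ground truth →
MRS construction and logistic test. Every output table carries a
`# provenance:` line (config hash, seed); reruns with the same
configuration are identical.

The bundled demonstration conditions (n = 500 samples, 2000 variants, 40
common + 10 rare taxa, h² = 0.5, 10 causal variants per taxon, trait GWAS
n = 1000, causal effect 0.3) were fixed by power analysis: 10 causal
variants at h² = 0.5 give ~85 % discovery power per variant at p < 5×10⁻⁵
and n = 500 (≈8 instruments), and a trait GWAS of 1000 subjects puts each
instrument's outcome association near z ≈ 2 — individually below the
exclusion screen, jointly well past the forward Bonferroni bound. Larger
trait GWAS sizes or causal effects *reduce* end-to-end power by pushing
single instruments over the exclusion screen. Test and acceptance problem
sizes throughout (e.g. GREML at n = 1000, m = 500; 100-replicate MR
calibrations) are chosen so the whole suite runs in a few minutes on one
CPU while keeping Monte-Carlo error well inside the asserted bounds.

## Known limitations

* The GRM-based SE of h² reflects the simulated LD structure; with ~100
  independent LD blocks it is markedly smaller than what a sparse-signal
  real genome would give at the same n.
* Winner's curse in discovery-cohort instrument effects biases IVW toward
  zero in the single-cohort pipeline (no replication re-estimation step).
* MR-Egger is underpowered at near-uniform instrument strengths — a direct
  consequence of the uniform-effects design choice above.
* The PRESSO outlier test needs `n_sim` large enough for the Bonferroni
  threshold to be attainable (see above); the implementation warns below
  100 but does not auto-scale.
* Logistic scans report separation as per-variant NA rather than applying a
  penalized (Firth-type) fit.
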