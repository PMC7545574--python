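# micromr

Host genetics × gut microbiome analysis in Python: SNP-based heritability of
taxon abundances, microbiome GWAS, polygenic-score instruments, bidirectional
two-sample Mendelian randomization (MR), and disease–microbiome feature
analysis (k-medoids clustering, cluster comparison, microbiome risk score).

The package is aimed at statistical geneticists and microbiome
epidemiologists who want the full chain — from a taxon count table and a
dosage matrix to a causal classification — as tested, seedable library code.
Because real cohort data of this kind are access-restricted, `micromr` ships
a synthetic-cohort generator with known ground truth (LD-structured
genotypes, heritable log-normal common taxa, zero-inflated rare taxa,
disease GWAS instruments, pathway features), so every statistical claim the
package makes is demonstrated by parameter recovery on data it can generate
itself.

## The statistics at the core

* **Heritability.** Single-component GREML: `y = Xb + g + e`,
  `g ~ N(0, σ_g² K)` with `K` the genetic relationship matrix
  `K_jk = m⁻¹ Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / 2p_i(1−p_i)`.
  Average-information REML with an EM fallback; a single eigendecomposition
  of `K` makes each iteration O(n). Reported `h² = σ_g²/(σ_g²+σ_e²)` with a
  delta-method SE.
* **Microbiome GWAS.** Taxa present in ≥90 % of samples are analysed on the
  Z-scored log abundance (linear model); rarer taxa as presence/absence
  (logistic IRLS). Covariates: top genetic PCs, age, sex, batch. Inflation is
  summarised by `λ_GC = median(χ²)/0.4549`.
* **Effective number of independent taxa.** `(Σλ)²/Σλ²` over the eigenvalues
  of the taxa-by-taxa covariance of the (Z-scored) abundance matrix; used as
  the Bonferroni divisor for correlated taxa.
* **Instruments.** Greedy LD clumping (p < 5×10⁻⁵, r² < 0.1 within 0.1 cM),
  beta-weighted polygenic scores, LD proxies at r² > 0.9.
* **MR.** IVW (multiplicative random effects), weighted median (bootstrap
  SE), MR-Egger (oriented, overdispersion-scaled), and an MR-PRESSO-style
  global/outlier test with parametric simulation. Two-tier calls:
  *significant* (IVW below the direction-specific Bonferroni bound — 0.05/62
  forward, 0.05/n_eff reverse) or *potential causal* (all four methods
  p < 0.05).
* **Disease features.** PAM (BUILD + SWAP with deterministic restarts) with
  the average silhouette width `sw_i = (M_i − N_i)/max(M_i, N_i)` selecting
  k; partitions compared by the pairwise co-membership Jaccard coefficient
  `J = a/(a+b+c)`; a microbiome risk score that sums ±1 per selected taxon
  (|Spearman ρ| > 0.2), zeroed below the taxon's 5 % abundance quantile, and
  is tested against disease by covariate-adjusted logistic regression.

## Worked example

```python
from micromr.simulate import SimulationConfig
from micromr.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(
        n_samples=500, n_variants=2000, n_taxa_common=40, n_taxa_rare=10,
        taxon_h2=0.5, n_causal_per_taxon=10, trait_gwas_n=1000, seed=0),
    out_dir="demo_out", trait_causal_effect=0.3, mr_seed=0)
res = run_pipeline(cfg)
print(res["h2_estimate"], res["forward_mr"]["classification"],
      res["k_opt"], res["mrs_odds_ratio"])
```

prints (seed 0):

```
0.5810778345163433 significant 5 2.140067715544762
```

i.e. the GREML estimate of the target taxon's heritability is 0.58
(true value 0.5, SE ≈ 0.06), the taxon→trait forward MR is classified
*significant* (a real causal effect of 0.3 was simulated), the silhouette
criterion recovers the 5 ground-truth pathway clusters, and the microbiome
risk score carries an odds ratio of 2.14 per score unit for the simulated
disease. The same pipeline is exposed on the command line:

```bash
micromr simulate --out data/ --seed 1
micromr features alpha --taxa data/taxa.tsv --out alpha.tsv
micromr pipeline --config pipeline.yaml
```

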