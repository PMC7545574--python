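"""Synthetic cohort generator with known ground truth.

Produces every input the pipeline consumes — LD-structured biallelic
genotypes, log-normal common-taxon and zero-inflated rare-taxon abundance
tables with controllable SNP heritability, covariates, binary disease
status, outcome-GWAS summary statistics with optionally pleiotropic
instruments, and pathway-abundance features that are noisy linear functions
of taxon subsets.  A single integer seed fully determines all outputs.

Genotypes come from a latent Gaussian with AR(1)-structured correlation
inside LD blocks, thresholded to alleles and summed over two independent
haplotypes.  Thresholding attenuates correlation, so the latent adjacent
correlation is calibrated per variant pair (tetrachoric inversion through
the Owen's-T bivariate normal CDF) to make the realized *genotype*
correlation match the requested ``ld_rho``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import GenotypeMatrix, TaxonTable, SUMMARY_STAT_COLUMNS

_BASES = np.array(list("ACGT"))


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the cohort being emulated where stated (1475
    participants with both genetic and microbiome data; 114 common and 88
    rare taxa; MAF > 0.05; 10,000-read sequencing depth; 1 cM = 1 Mb map)
    and otherwise sit at values realistic for a 16S microbiome GWAS.
    """

    n_samples: int = 1475
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.8
    map_cm_per_mb: float = 1.0
    n_taxa_common: int = 114
    n_taxa_rare: int = 88
    taxon_h2: float = 0.45
    n_causal_per_taxon: int = 20
    rare_prevalence_range: tuple[float, float] = (0.10, 0.85)
    n_instruments: int = 10
    instrument_beta_range: tuple[float, float] = (0.05, 0.15)
    pleiotropy_fraction: float = 0.0
    causal_effect: float = 0.0
    seed: int = 0
    # sequencing / GWAS scale
    depth: int = 10_000
    outcome_gwas_n: int = 100_000      # disease GWAS behind reverse-MR instruments
    trait_gwas_n: int = 5_000          # downstream quantitative-trait GWAS (forward MR)
    outcome_case_fraction: float = 0.2
    # disease model for the cohort bundle
    n_disease_taxa: int = 16
    disease_taxon_effect: float = 0.3
    disease_prevalence: float = 0.115

    def validate(self) -> None:
        if min(self.n_samples, self.n_variants, self.ld_block_size,
               self.n_causal_per_taxon, self.depth) <= 0:
            raise InvalidConfigError("all counts must be positive")
        if self.ld_block_size > self.n_variants:
            raise InvalidConfigError("ld_block_size exceeds n_variants")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise InvalidConfigError("ld_rho must be in [0, 1)")
        if not (0 <= self.taxon_h2 < 1):
            raise InvalidConfigError("taxon_h2 must be in [0, 1)")
        lo, hi = self.rare_prevalence_range
        if not (0 < lo <= hi < 0.9):
            raise InvalidConfigError("rare_prevalence_range must lie in (0, 0.9)")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise InvalidConfigError("pleiotropy_fraction must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator for one operation stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    causal_variants: dict[str, list[str]] = field(default_factory=dict)
    true_h2: dict[str, float] = field(default_factory=dict)
    prevalence: dict[str, float] = field(default_factory=dict)
    genetic_values: pd.DataFrame | None = None
    mr_effects: dict[str, float] = field(default_factory=dict)
    pleiotropic_instruments: dict[str, float] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    disease_taxa: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "genetic_values"}
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genotypes


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 < h, Z2 < k) for standard bivariate normal, via Owen's T."""
    if abs(rho) < 1e-14:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    if abs(h) < 1e-12 and abs(k) < 1e-12:
        return 0.25 + np.arcsin(rho) / (2 * np.pi)
    s = np.sqrt(1 - rho * rho)
    if abs(h) < 1e-12:
        h = 1e-12
    if abs(k) < 1e-12:
        k = 1e-12
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    beta = 0.5 if h * k < 0 else 0.0
    return (0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
            - special.owens_t(h, a_h) - special.owens_t(k, a_k) - beta)


def _indicator_corr(rho: float, p1: float, p2: float, t1: float, t2: float) -> float:
    """Correlation of the allele indicators I(Z1<t1), I(Z2<t2)."""
    p11 = _bvn_cdf(t1, t2, rho)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _calibrate_latent_rho(target: float, p1: float, p2: float,
                          t1: float, t2: float) -> float:
    """Latent correlation giving indicator correlation == target (capped)."""
    if target <= 0:
        return 0.0
    hi = 0.9999
    if _indicator_corr(hi, p1, p2, t1, t2) <= target:
        return hi
    f = lambda r: _indicator_corr(r, p1, p2, t1, t2) - target
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))


def _nonpalindromic_allele_pairs(rng: np.random.Generator, m: int) -> np.ndarray:
    """Random effect/other allele index pairs excluding strand-ambiguous
    complements (A/T and C/G), as genotyping arrays are designed to do."""
    comp = np.array([3, 2, 1, 0])  # A<->T, C<->G
    first = rng.integers(0, 4, size=m)
    second = (first + 1 + rng.integers(0, 3, size=m)) % 4
    bad = second == comp[first]
    while bad.any():
        second[bad] = (first[bad] + 1 + rng.integers(0, 3, size=int(bad.sum()))) % 4
        bad = second == comp[first]
    return np.column_stack([first, second])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-structured dosage matrix in [0, 2] with variant metadata.

    Variants sit on one chromosome, 5 kb apart, in LD blocks of
    ``ld_block_size``; adjacent variants within a block have genotype
    correlation ~ ``ld_rho``; blocks are mutually independent.  cM positions
    follow the configured constant-rate map.  Variants whose realized MAF
    falls below 0.01 are redrawn.
    """
    config.validate()
    rng = config.rng(1)
    n, m, b = config.n_samples, config.n_variants, config.ld_block_size
    # variants in tight LD share an allele-frequency history: draw MAF per
    # block with small within-block jitter (a frequency mismatch bounds the
    # attainable genotype correlation well below ld_rho otherwise)
    n_blocks = int(np.ceil(m / b))
    if config.ld_rho > 0:
        block_maf = rng.uniform(*config.maf_range, size=n_blocks)
        jitter = rng.normal(0.0, 0.01, size=m)
        maf = np.clip(np.repeat(block_maf, b)[:m] + jitter, *config.maf_range)
    else:
        maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf)

    # latent adjacent correlations (0 at block starts)
    a = np.zeros(m)
    if config.ld_rho > 0:
        for j in range(1, m):
            if j % b == 0:
                continue
            a[j] = _calibrate_latent_rho(config.ld_rho, maf[j - 1], maf[j],
                                         thresh[j - 1], thresh[j])

    def draw_haplotype() -> np.ndarray:
        eps = rng.standard_normal((n, m))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            if a[j] == 0.0:
                z[:, j] = eps[:, j]
            else:
                z[:, j] = a[j] * z[:, j - 1] + np.sqrt(1 - a[j] ** 2) * eps[:, j]
        return (z < thresh).astype(np.int8)

    dosages = (draw_haplotype() + draw_haplotype()).astype(float)

    # enforce realized MAF >= 0.01 (rare at these parameters; redraw per column)
    for _ in range(20):
        freq = dosages.mean(axis=0) / 2.0
        bad = np.flatnonzero(np.minimum(freq, 1 - freq) < 0.01)
        if bad.size == 0:
            break
        for j in bad:
            hap = (rng.standard_normal((n, 2)) < thresh[j]).astype(np.int8)
            dosages[:, j] = hap.sum(axis=1)

    pos_bp = 1 + 5000 * np.arange(m)
    # avoid palindromic (A/T, C/G) pairs, mimicking array design
    pairs = _nonpalindromic_allele_pairs(rng, m)
    variants = pd.DataFrame({
        "variant_id": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": "1",
        "pos_bp": pos_bp,
        "pos_cm": pos_bp * config.map_cm_per_mb / 1e6,
        "effect_allele": _BASES[pairs[:, 0]],
        "other_allele": _BASES[pairs[:, 1]],
        "maf": maf,
    })
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# taxon table


def _genetic_value(G: GenotypeMatrix, causal_idx: np.ndarray, h2: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Standardized genetic value with empirical variance exactly h2."""
    X = G.dosages[:, causal_idx]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    # equal-magnitude, random-sign effects: every causal variant contributes
    # the same share of genetic variance (uniform instrument strength)
    w = rng.choice([-1.0, 1.0], size=len(causal_idx))
    gv = Z @ w
    s = gv.std()
    if s == 0 or h2 == 0:
        return np.zeros(G.n_samples)
    return gv * (np.sqrt(h2) / s)


def _spread_causal_indices(rng: np.random.Generator, m: int, block: int,
                           k: int) -> np.ndarray:
    """Pick k causal variants, at most one per LD block where possible."""
    n_blocks = int(np.ceil(m / block))
    if k <= n_blocks:
        blocks = rng.choice(n_blocks, size=k, replace=False)
    else:
        blocks = rng.integers(0, n_blocks, size=k)
    idx = []
    for bl in blocks:
        lo, hi = bl * block, min((bl + 1) * block, m)
        idx.append(int(rng.integers(lo, hi)))
    return np.unique(np.array(sorted(idx)))


def simulate_taxon_table(G: GenotypeMatrix, config: SimulationConfig
                         ) -> tuple[TaxonTable, GroundTruth]:
    """Count table with genetically driven common taxa and zero-inflated
    rare taxa.

    Common taxa: log-abundance = genetic value + Gaussian noise with the
    genetic fraction of variance equal to ``taxon_h2`` (empirically exact).
    Rare taxa: presence from a probit liability threshold hitting a target
    prevalence drawn from ``rare_prevalence_range``, abundance log-normal
    conditional on presence.  Counts are one multinomial draw per sample at
    the configured sequencing depth.
    """
    config.validate()
    if G.n_samples == 0 or G.n_variants == 0:
        raise InvalidConfigError("empty genotype matrix")
    rng = config.rng(2)
    n = G.n_samples
    gt = GroundTruth()
    log_expected = {}
    h2 = config.taxon_h2
    gvs = {}

    for t in range(config.n_taxa_common):
        name = f"genus|g__Common{t + 1:03d}"
        cidx = _spread_causal_indices(rng, G.n_variants, config.ld_block_size,
                                      config.n_causal_per_taxon)
        gv = _genetic_value(G, cidx, h2, rng)
        noise = rng.standard_normal(n)
        if h2 < 1:
            noise *= np.sqrt(1 - h2) / max(noise.std(), 1e-12)
        mu = rng.normal(-5.0, 1.0)
        log_expected[name] = mu + gv + noise
        gvs[name] = gv
        gt.causal_variants[name] = list(G.variants["variant_id"].iloc[cidx])
        gt.true_h2[name] = h2

    presence = {}
    for t in range(config.n_taxa_rare):
        name = f"genus|g__Rare{t + 1:03d}"
        prev = rng.uniform(*config.rare_prevalence_range)
        cidx = _spread_causal_indices(rng, G.n_variants, config.ld_block_size,
                                      config.n_causal_per_taxon)
        gv = _genetic_value(G, cidx, h2, rng)
        liab = gv + rng.standard_normal(n) * np.sqrt(max(1 - h2, 1e-12))
        present = liab > stats.norm.ppf(1 - prev) * liab.std()
        mu = rng.normal(-7.0, 1.0)
        log_expected[name] = mu + rng.standard_normal(n)
        presence[name] = present
        gvs[name] = gv
        gt.causal_variants[name] = list(G.variants["variant_id"].iloc[cidx])
        gt.true_h2[name] = h2
        gt.prevalence[name] = float(prev)

    expected = pd.DataFrame({k: np.exp(v) for k, v in log_expected.items()},
                            index=G.sample_ids)
    for name, present in presence.items():
        expected[name] = expected[name].to_numpy() * present

    probs = expected.div(expected.sum(axis=1), axis=0).to_numpy()
    counts = np.vstack([rng.multinomial(config.depth, p) for p in probs])
    table = TaxonTable(pd.DataFrame(counts, index=G.sample_ids,
                                    columns=expected.columns), is_counts=True)
    gt.genetic_values = pd.DataFrame(gvs, index=G.sample_ids)
    return table, gt


# ---------------------------------------------------------------------------
# summary statistics


def _gwas_se(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    """Approximate SE of a logistic GWAS log-odds effect."""
    return 1.0 / np.sqrt(2 * maf * (1 - maf) * n * case_fraction * (1 - case_fraction))


def simulate_outcome_summary_stats(config: SimulationConfig,
                                   G: GenotypeMatrix | None = None
                                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Disease-GWAS summary statistics for instrument variants.

    Returns ``n_instruments`` variants with true log-odds effects on a
    latent disease liability (drawn from ``instrument_beta_range``) and
    sampling noise consistent with a GWAS of ``outcome_gwas_n`` subjects.
    A fraction ``pleiotropy_fraction`` of instruments also receives a direct
    effect on downstream taxa, recorded in the ground truth.
    """
    config.validate()
    if config.n_instruments < 3:
        raise InvalidConfigError("need at least 3 instruments")
    rng = config.rng(3)
    k = config.n_instruments
    if G is not None:
        stride = max(G.n_variants // k, 1)
        idx = np.arange(k) * stride
        idx = idx[idx < G.n_variants]
        meta = G.variants.iloc[idx].reset_index(drop=True)
        maf = G.realized_maf()[idx]
    else:
        maf = rng.uniform(*config.maf_range, size=k)
        pairs = _nonpalindromic_allele_pairs(rng, k)
        meta = pd.DataFrame({
            "variant_id": [f"d_rs{j + 1:04d}" for j in range(k)],
            "chrom": "2", "pos_bp": 1 + 100_000 * np.arange(k),
            "pos_cm": (1 + 100_000 * np.arange(k)) * config.map_cm_per_mb / 1e6,
            "effect_allele": _BASES[pairs[:, 0]],
            "other_allele": _BASES[pairs[:, 1]],
        })
    beta_true = rng.uniform(*config.instrument_beta_range, size=len(meta))
    se = _gwas_se(maf, config.outcome_gwas_n, config.outcome_case_fraction)
    beta_hat = beta_true + se * rng.standard_normal(len(meta))
    p = 2 * stats.norm.sf(np.abs(beta_hat / se))
    out = pd.DataFrame({
        "variant_id": meta["variant_id"], "chrom": meta["chrom"],
        "pos_bp": meta["pos_bp"], "pos_cm": meta["pos_cm"],
        "effect_allele": meta["effect_allele"], "other_allele": meta["other_allele"],
        "eaf": maf, "beta": beta_hat, "se": se, "p": p,
        "n": config.outcome_gwas_n,
    })[SUMMARY_STAT_COLUMNS]
    gt = GroundTruth()
    gt.mr_effects = dict(zip(meta["variant_id"], beta_true))
    n_pleio = int(round(config.pleiotropy_fraction * len(meta)))
    if n_pleio:
        chosen = rng.choice(len(meta), size=n_pleio, replace=False)
        for j in chosen:
            gt.pleiotropic_instruments[meta["variant_id"].iloc[j]] = float(
                rng.normal(0.0, 0.1))
    return out, gt


def simulate_instrument_pair(n_instruments: int = 30, true_effect: float = 0.3,
                             seed: int = 0, se_x_scale: float = 0.02,
                             se_y_scale: float = 0.02,
                             pleiotropy_fraction: float = 0.0,
                             pleiotropy_mean: float = 0.0,
                             pleiotropy_sd: float = 0.0,
                             outlier_idx: int | None = None,
                             outlier_size: float = 0.0,
                             positive_exposure: bool = False
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired exposure/outcome summary statistics with a known causal effect.

    The workhorse for estimator-calibration studies: exposure effects are
    drawn ~ U(0.1, 0.3) with sign flips, outcome effects are
    ``true_effect * beta_x`` plus optional pleiotropy (a direct effect with
    mean ``pleiotropy_mean``) and sampling noise.  ``outlier_idx`` plants a
    single gross direct effect of ``outlier_size`` (in units of the outcome
    SE) for outlier-detection studies.
    """
    rng = np.random.default_rng(seed)
    k = n_instruments
    signs = np.ones(k) if positive_exposure else rng.choice([-1.0, 1.0], size=k)
    bx_true = rng.uniform(0.1, 0.3, size=k) * signs
    se_x = np.full(k, se_x_scale)
    se_y = np.full(k, se_y_scale)
    alpha = np.zeros(k)
    n_pleio = int(round(pleiotropy_fraction * k))
    if n_pleio:
        idx = rng.choice(k, size=n_pleio, replace=False)
        alpha[idx] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_pleio)
    if outlier_idx is not None:
        alpha[outlier_idx] += outlier_size * se_y[outlier_idx]
    bx = bx_true + se_x * rng.standard_normal(k)
    by = true_effect * bx_true + alpha + se_y * rng.standard_normal(k)

    def frame(beta, se):
        p = 2 * stats.norm.sf(np.abs(beta / se))
        return pd.DataFrame({
            "variant_id": [f"iv{j + 1:03d}" for j in range(k)],
            "chrom": "3", "pos_bp": 1 + 200_000 * np.arange(k),
            "pos_cm": (1 + 200_000 * np.arange(k)) / 1e6,
            "effect_allele": "A", "other_allele": "G",
            "eaf": 0.3, "beta": beta, "se": se, "p": p, "n": 50_000,
        })[SUMMARY_STAT_COLUMNS]

    return frame(bx, se_x), frame(by, se_y)


def taxon_outcome_summary_stats(G: GenotypeMatrix, gt: GroundTruth, taxon: str,
                                config: SimulationConfig,
                                causal_effect: float | None = None
                                ) -> pd.DataFrame:
    """Outcome-trait GWAS summary statistics under 'taxon causes trait'.

    The true marginal effect of each variant on the trait is
    ``causal_effect`` times its empirical marginal effect on the taxon's
    genetic value (LD-aware), plus noise at the precision of a quantitative
    GWAS with ``trait_gwas_n`` subjects — sized so single instruments sit in
    the limited-power regime while the joint IVW signal is detectable.  Used
    to exercise the forward MR arm with a known effect size.
    """
    if gt.genetic_values is None or taxon not in gt.genetic_values:
        raise KeyError(f"no genetic values recorded for taxon {taxon!r}")
    ce = config.causal_effect if causal_effect is None else causal_effect
    rng = config.rng(4)
    gv = gt.genetic_values[taxon].to_numpy()
    X = G.dosages
    var_g = X.var(axis=0)
    var_g[var_g == 0] = np.nan
    # empirical marginal per-dosage effect of each variant on the taxon
    beta_marg = ((X - X.mean(axis=0)).T @ (gv - gv.mean())) / (G.n_samples * var_g)
    beta_marg = np.nan_to_num(beta_marg)
    maf = np.clip(G.realized_maf(), 0.01, 0.5)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.trait_gwas_n)
    beta_hat = ce * beta_marg + se * rng.standard_normal(G.n_variants)
    p = 2 * stats.norm.sf(np.abs(beta_hat / se))
    out = G.variants[["variant_id", "chrom", "pos_bp", "pos_cm",
                      "effect_allele", "other_allele"]].copy()
    out["eaf"] = X.mean(axis=0) / 2.0
    out["beta"], out["se"], out["p"] = beta_hat, se, p
    out["n"] = config.trait_gwas_n
    return out[SUMMARY_STAT_COLUMNS]


# ---------------------------------------------------------------------------
# pathway features


def simulate_pathway_table(T: TaxonTable, config: SimulationConfig,
                           n_clusters: int = 5, features_per_cluster: int = 4,
                           noise_sd: float = 0.05
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Predicted disease/pathway abundance features.

    Each feature is a non-negative noisy linear combination of one of
    ``n_clusters`` disjoint taxon subsets; features sharing a subset share a
    ground-truth cluster label.  ``noise_sd`` is relative to each feature's
    systematic standard deviation.
    """
    config.validate()
    rel = T.to_relative().data
    n_taxa = rel.shape[1]
    if n_taxa < 2 * n_clusters:
        raise InvalidConfigError("too few taxa to form disjoint pathway subsets")
    rng = config.rng(5)
    subset_size = max(n_taxa // n_clusters, 2)
    order = rng.permutation(n_taxa)
    gt = GroundTruth()
    cols = {}
    for c in range(n_clusters):
        members = order[c * subset_size:(c + 1) * subset_size]
        for f in range(features_per_cluster):
            name = f"disease_{c + 1:02d}_{f + 1}"
            w = rng.uniform(0.5, 1.5, size=len(members))
            base = rel.iloc[:, members].to_numpy() @ w
            noise = rng.standard_normal(len(base)) * noise_sd * max(base.std(), 1e-12)
            cols[name] = np.maximum(base + noise, 0.0)
            gt.cluster_labels[name] = c
    return pd.DataFrame(cols, index=rel.index), gt


# ---------------------------------------------------------------------------
# full cohort bundle


@dataclass
class CohortBundle:
    genotypes: GenotypeMatrix
    taxa: TaxonTable
    covariates: pd.DataFrame
    disease: pd.Series                 # binary status
    disease_liability: pd.Series       # continuous scale underlying status
    outcome_stats: pd.DataFrame
    pathways: pd.DataFrame
    ground_truth: GroundTruth


def simulate_covariates(config: SimulationConfig, sample_ids: list[str]
                        ) -> pd.DataFrame:
    rng = config.rng(6)
    n = len(sample_ids)
    return pd.DataFrame({
        "age": rng.uniform(40, 75, size=n).round(1),
        "sex": rng.integers(0, 2, size=n),
        "energy_intake": rng.normal(2000, 400, size=n).round(0),
        "alcohol": rng.exponential(5.0, size=n).round(2),
        "bmi": rng.normal(23.5, 3.0, size=n).round(2),
        "batch": rng.integers(0, 3, size=n),
    }, index=sample_ids)


def simulate_cohort(config: SimulationConfig, out_dir=None) -> CohortBundle:
    """Full synthetic dataset: genotypes, taxa, covariates, disease status
    driven by a logistic model on designated taxa, outcome summary
    statistics and pathway features; optionally written to ``out_dir`` in
    the pipeline's file dialects.
    """
    from . import io as mio
    from .features import transform_common_abundance, prevalence_partition

    config.validate()
    G = simulate_genotypes(config)
    taxa, gt = simulate_taxon_table(G, config)
    cov = simulate_covariates(config, G.sample_ids)

    rng = config.rng(7)
    common, _ = prevalence_partition(taxa, threshold=0.9)
    z = transform_common_abundance(common)
    n_dis = min(config.n_disease_taxa, z.shape[1])
    chosen = list(z.columns[rng.permutation(z.shape[1])[:n_dis]])
    gamma = config.disease_taxon_effect
    liability = z[chosen].to_numpy() @ np.full(n_dis, gamma) if n_dis else np.zeros(len(z))
    # calibrate intercept so the case fraction hits the configured prevalence
    b0 = float(stats.norm.ppf(config.disease_prevalence) * 1.7)  # probit-ish start
    for _ in range(50):
        pr = 1 / (1 + np.exp(-(b0 + liability)))
        diff = pr.mean() - config.disease_prevalence
        if abs(diff) < 1e-6:
            break
        b0 -= diff / max(np.mean(pr * (1 - pr)), 1e-6)
    pr = 1 / (1 + np.exp(-(b0 + liability)))
    disease = pd.Series((rng.uniform(size=len(pr)) < pr).astype(int),
                        index=G.sample_ids, name="disease")
    gt.disease_taxa = {t: gamma for t in chosen}

    outcome_stats, gt_iv = simulate_outcome_summary_stats(config, G)
    gt.mr_effects.update(gt_iv.mr_effects)
    gt.pleiotropic_instruments.update(gt_iv.pleiotropic_instruments)
    pathways, gt_path = simulate_pathway_table(taxa, config)
    gt.cluster_labels.update(gt_path.cluster_labels)

    bundle = CohortBundle(G, taxa, cov, disease,
                          pd.Series(liability, index=G.sample_ids, name="liability"),
                          outcome_stats, pathways, gt)
    if out_dir is not None:
        mio.write_cohort(bundle, out_dir)
    return bundle
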