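"""End-to-end orchestration of the analysis stages on a (synthetic or
loaded) cohort: taxon-table processing -> heritability & GWAS -> clumping &
polygenic scores -> bidirectional MR -> disease clustering & microbiome
risk score.  Outputs carry provenance metadata and the run is deterministic
under a fixed configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disease as dz
from . import features as ft
from . import genetics as gn
from . import io as mio
from . import mr as mrmod
from .containers import SUMMARY_STAT_COLUMNS
from .simulate import SimulationConfig, simulate_cohort, taxon_outcome_summary_stats


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "pipeline_out"
    target_taxon_index: int = 0       # common taxon carrying the forward MR effect
    trait_causal_effect: float = 0.3  # taxon -> trait effect for the simulated GWAS
    clump_p: float = 5e-5
    clump_r2: float = 0.1
    clump_window_cm: float = 0.1
    mr_n_sim: int = 1000
    mr_seed: int | None = None
    n_pcs: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.simulation.validate()
        if self.mr_seed is None:
            raise PipelineConfigError(
                "mr_seed must be set explicitly: every stochastic stage "
                "needs its own seed")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic end-to-end analysis; returns a result
    dict and writes provenance-stamped tables under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = mio.config_hash(asdict(config))
    prov = mio.provenance_line(config=chash, seed=config.simulation.seed,
                               stage="pipeline")
    log: list[str] = []
    results: dict = {"config_hash": chash}

    # --- stage 1: simulate cohort -----------------------------------------
    bundle = simulate_cohort(config.simulation, out_dir=out / "data")
    G, taxa = bundle.genotypes, bundle.taxa
    log.append(f"simulated cohort: n={G.n_samples}, m={G.n_variants}, "
               f"taxa={len(taxa.taxon_ids)}")

    # --- stage 2: microbiome features -------------------------------------
    depth = int(min(taxa.data.sum(axis=1)))
    rarefied, dropped = ft.rarefy(taxa, depth=depth, seed=config.simulation.seed)
    alpha = ft.alpha_diversity(rarefied)
    common, rare = ft.prevalence_partition(taxa, threshold=0.9)
    z = ft.transform_common_abundance(common)
    n_eff = ft.effective_number_independent_taxa(z.to_numpy())
    results["n_common"], results["n_rare"] = z.shape[1], rare.shape[1]
    results["n_eff_taxa"] = n_eff
    log.append(f"prevalence partition at 0.90: {z.shape[1]} common, "
               f"{rare.shape[1]} rare; effective number of taxa = {n_eff:.2f}")
    mio.write_frame(alpha.to_frame(), out / "alpha_diversity.tsv", prov)

    # --- stage 3: heritability + GWAS of the target taxon ------------------
    target = z.columns[config.target_taxon_index]
    grm, pcs = gn.compute_grm(G, n_pcs=config.n_pcs)
    cov_h2 = bundle.covariates[["age", "sex"]].to_numpy(dtype=float)
    greml = gn.greml_heritability(grm, z[target].to_numpy(), cov_h2)
    results["target_taxon"] = target
    results["h2_estimate"], results["h2_se"] = greml.h2, greml.se
    log.append(f"GREML h2({target}) = {greml.h2:.3f} (SE {greml.se:.3f})")

    X_scan = np.column_stack([pcs.to_numpy(),
                              bundle.covariates[["age", "sex", "batch"]]
                              .to_numpy(dtype=float)])
    assoc = gn.association_scan(G, z[target].to_numpy(), X_scan, model="linear")
    results["lambda_gc"] = gn.genomic_inflation(assoc["p"].to_numpy())
    mio.write_summary_stats(assoc[SUMMARY_STAT_COLUMNS],
                            out / "gwas_target_taxon.tsv", prov)

    # --- stage 4: clumping + polygenic score -------------------------------
    leads = gn.ld_clump(assoc, G, p_thresh=config.clump_p,
                        r2_thresh=config.clump_r2,
                        window_cm=config.clump_window_cm)
    results["n_leads"] = len(leads)
    log.append(f"clumping (p<{config.clump_p}, r2<{config.clump_r2}, "
               f"{config.clump_window_cm} cM): {len(leads)} lead variants")
    if leads:
        prs = gn.build_polygenic_score(leads, assoc, G)
        prs_test = gn.test_polygenic_score(prs.scores, z[target].to_numpy(),
                                           X_scan, "continuous")
        results["prs_p"] = prs_test["p"]

    # --- stage 5: forward MR (taxon -> trait) ------------------------------
    # exclusion-screen denominator: the pooled independent lead set across
    # the exposures carried into the polygenic-score stage (the target plus
    # the next few common taxa), not just this pair's instruments
    pooled_leads = set(leads)
    for other in z.columns[1:5]:
        a_other = gn.association_scan(G, z[other].to_numpy(), X_scan)
        pooled_leads |= set(gn.ld_clump(a_other, G, p_thresh=config.clump_p,
                                        r2_thresh=config.clump_r2,
                                        window_cm=config.clump_window_cm))
    results["n_pooled_leads"] = len(pooled_leads)

    results["forward_mr"] = None
    if leads:
        trait_stats = taxon_outcome_summary_stats(
            G, bundle.ground_truth, target, config.simulation,
            causal_effect=config.trait_causal_effect)
        try:
            iv_ids = mrmod.select_instruments(
                assoc[assoc["variant_id"].isin(leads)], trait_stats,
                direction="forward",
                n_independent=max(len(pooled_leads), len(leads)),
                pair_label=f"{target}->trait")
            h = mrmod.harmonize_instruments(assoc, trait_stats,
                                            exposure_name=target,
                                            outcome_name="trait",
                                            instrument_ids=iv_ids)
        except mrmod.EmptyInstrumentSetError as exc:
            log.append(f"forward MR skipped: {exc}")
            h = None
        if h is not None:
            fwd = mrmod.run_mr(h, n_sim=config.mr_n_sim, seed=config.mr_seed,
                               effect_units="trait units per 1-SD log abundance")
            results["forward_mr"] = {
                "classification": fwd.classification,
                "p": {m: e.p for m, e in fwd.estimates.items()},
                "estimate": {m: e.estimate for m, e in fwd.estimates.items()},
            }
            fwd.to_frame().to_csv(out / "mr_forward.tsv", sep="\t", index=False)
            log.append(f"forward MR {target} -> trait: {fwd.classification}")

    # --- stage 6: reverse MR (disease -> taxon) ----------------------------
    rev_ids = mrmod.select_instruments(bundle.outcome_stats,
                                       bundle.outcome_stats,
                                       direction="reverse", ld_reference=G,
                                       pair_label="disease->taxon")
    rev_outcome = gn.association_scan(
        G, z[target].to_numpy(), X_scan, model="linear")
    h_rev = mrmod.harmonize_instruments(
        bundle.outcome_stats, rev_outcome, exposure_name="disease",
        outcome_name=target, direction="disease_to_microbiome",
        instrument_ids=rev_ids)
    rev = mrmod.run_mr(h_rev, n_sim=config.mr_n_sim, seed=config.mr_seed,
                       n_eff_taxa=n_eff,
                       effect_units="SD log abundance per log-odds of disease")
    results["reverse_mr"] = {"classification": rev.classification,
                             "p": {m: e.p for m, e in rev.estimates.items()}}
    rev.to_frame().to_csv(out / "mr_reverse.tsv", sep="\t", index=False)

    # --- stage 7: disease clustering + MRS ---------------------------------
    feat = bundle.pathways
    zfeat = (feat - feat.mean()) / feat.std(ddof=1).replace(0, 1.0)
    k_opt, sol = dz.choose_k_by_silhouette(zfeat.T, k_range=range(2, 9))
    truth = pd.Series(bundle.ground_truth.cluster_labels)
    jac = dz.jaccard_cluster_similarity(sol.labels, truth.loc[sol.labels.index])
    results["k_opt"], results["cluster_jaccard_vs_truth"] = k_opt, jac
    log.append(f"PAM k={k_opt}, Jaccard vs ground truth = {jac:.3f}")

    mrs_model = dz.build_mrs(taxa, bundle.disease_liability)
    mrs = dz.score_and_test_mrs(mrs_model, taxa, bundle.disease,
                                bundle.covariates[["age", "sex", "energy_intake",
                                                   "alcohol", "bmi"]])
    results["mrs_n_taxa"] = len(mrs_model.taxa)
    results["mrs_odds_ratio"], results["mrs_p"] = mrs["odds_ratio"], mrs["p"]
    log.append(f"MRS: {len(mrs_model.taxa)} taxa, OR={mrs['odds_ratio']:.3f} "
               f"(p={mrs['p']:.2e})")

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, default=str)
    with open(out / "pipeline.log", "w") as fh:
        fh.write(prov + "\n" + "\n".join(log) + "\n")
    return results
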