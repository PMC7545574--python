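"""GRM, REML heritability, association scans, genomic inflation, clumping
and polygenic scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micromr.containers import GenotypeMatrix
from micromr.genetics import (association_scan, build_polygenic_score,
                              compute_grm, genomic_inflation,
                              greml_heritability, ld_clump, reml_loglik)
from micromr.genetics import test_polygenic_score as score_association
from micromr.simulate import SimulationConfig, simulate_genotypes


def make_genotypes(dosages, mafs=None, cm=None, chrom=None, alleles=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    mafs = mafs if mafs is not None else dosages.mean(axis=0) / 2
    cm = cm if cm is not None else np.arange(m) * 0.01
    alleles = alleles or [("A", "G")] * m
    var = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)],
        "chrom": chrom or ["1"] * m,
        "pos_bp": (np.asarray(cm) * 1e6).astype(int) + 1,
        "pos_cm": cm,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "maf": mafs,
    })
    return GenotypeMatrix([f"s{i}" for i in range(n)], var, dosages)


class TestGRM:
    def test_mean_diagonal_near_one_under_hwe(self, rng):
        p = rng.uniform(0.1, 0.5, size=2000)
        dos = rng.binomial(2, p, size=(500, 2000)).astype(float)
        G = make_genotypes(dos, cm=np.arange(2000) * 0.01)
        grm, _ = compute_grm(G)
        assert 0.95 <= np.mean(np.diag(grm)) <= 1.05
        np.testing.assert_allclose(grm, grm.T)

    def test_duplicate_individual_detected_by_off_diagonal(self, rng):
        dos = rng.binomial(2, 0.3, size=(50, 800)).astype(float)
        dos[1] = dos[0]
        grm, _ = compute_grm(make_genotypes(dos))
        assert abs(grm[0, 1] - grm[0, 0]) < 0.05

    def test_pc1_separates_subpopulations(self, rng):
        p1, p2 = rng.uniform(0.1, 0.5, 500), None
        p2 = np.clip(p1 + rng.choice([-0.2, 0.2], size=500), 0.05, 0.95)
        dos = np.vstack([rng.binomial(2, p1, size=(60, 500)),
                         rng.binomial(2, p2, size=(60, 500))]).astype(float)
        _, pcs = compute_grm(make_genotypes(dos))
        pc1 = pcs["PC1"].to_numpy()
        assert (pc1[:60].mean() - pc1[60:].mean()) ** 2 > \
            4 * (pc1[:60].var() + pc1[60:].var())


class TestGreml:
    def test_null_phenotype_within_two_se_of_zero(self, small_cohort):
        G, _, _ = small_cohort
        rng = np.random.default_rng(5)
        grm, _ = compute_grm(G)
        y = rng.standard_normal(G.n_samples)
        res = greml_heritability(grm, y)
        assert res.h2 <= 2 * res.se + 1e-6

    def test_recovers_simulated_heritability(self):
        from micromr.features import (prevalence_partition,
                                      transform_common_abundance)
        from micromr.simulate import simulate_taxon_table
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(n_samples=800, n_variants=400,
                                   n_taxa_common=30, n_taxa_rare=5,
                                   taxon_h2=0.5, seed=seed)
            G = simulate_genotypes(cfg)
            T, _ = simulate_taxon_table(G, cfg)
            z = transform_common_abundance(prevalence_partition(T)[0])
            grm, _ = compute_grm(G)
            res = greml_heritability(grm, z.iloc[:, 0].to_numpy())
            hits += abs(res.h2 - 0.5) <= 2 * res.se
        assert hits >= 4

    def test_noise_free_phenotype_hits_upper_boundary(self, small_cohort):
        G, _, truth = small_cohort
        grm, _ = compute_grm(G)
        gv = truth.genetic_values.iloc[:, 0].to_numpy()
        res = greml_heritability(grm, gv)
        assert res.h2 > 0.98 and res.boundary

    def test_identity_grm_flagged_non_identifiable(self, rng):
        y = rng.standard_normal(120)
        res = greml_heritability(np.eye(120), y)
        assert res.non_identifiable

    def test_rotated_loglik_matches_dense_oracle(self, rng):
        """Rotated-space REML likelihood == direct dense evaluation."""
        for _ in range(10):
            n = 50
            A = rng.standard_normal((n, 2 * n))
            grm = A @ A.T / (2 * n)
            y = rng.standard_normal(n)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            sg, se = rng.uniform(0.2, 2.0, size=2)
            # dense oracle: -0.5 (log|V| + log|X'V^-1 X| + y'Py)
            V = sg * grm + se * np.eye(n)
            Vi = np.linalg.inv(V)
            XtVX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XtVX) @ X.T @ Vi
            dense = -0.5 * (np.linalg.slogdet(V)[1]
                            + np.linalg.slogdet(XtVX)[1] + y @ P @ y)
            ours = reml_loglik(grm, y, X[:, 1:], sg, se)
            assert ours == pytest.approx(dense, abs=1e-8)


class TestAssociationScan:
    def test_linear_betas_match_normal_equations_oracle(self, rng):
        n, m = 80, 10
        dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        G = make_genotypes(dos)
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        res = association_scan(G, y, X, model="linear")
        for j in range(m):
            D = np.column_stack([np.ones(n), X, dos[:, j]])
            beta = np.linalg.solve(D.T @ D, D.T @ y)
            resid = y - D @ beta
            sigma2 = resid @ resid / (n - D.shape[1])
            se = np.sqrt(sigma2 * np.linalg.inv(D.T @ D)[-1, -1])
            assert res["beta"].iloc[j] == pytest.approx(beta[-1], abs=1e-8)
            assert res["se"].iloc[j] == pytest.approx(se, abs=1e-8)

    def test_null_scan_lambda_near_one(self, rng):
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 2000),
                           size=(400, 2000)).astype(float)
        G = make_genotypes(dos)
        res = association_scan(G, rng.standard_normal(400), model="linear")
        assert 0.9 <= genomic_inflation(res["p"].to_numpy()) <= 1.1

    def test_causal_variant_attains_minimum_p(self, rng):
        dos = rng.binomial(2, 0.3, size=(1000, 50)).astype(float)
        y = 1.0 * dos[:, 17] + rng.standard_normal(1000)
        res = association_scan(make_genotypes(dos), y)
        assert res["p"].idxmin() == 17

    def test_permutation_destroys_significance(self, rng):
        dos = rng.binomial(2, 0.3, size=(500, 30)).astype(float)
        y = 1.5 * dos[:, 3] + rng.standard_normal(500)
        G = make_genotypes(dos)
        assert association_scan(G, y)["p"].min() < 5e-8
        yp = rng.permutation(y)
        assert association_scan(G, yp)["p"].min() > 5e-8

    def test_logistic_recovers_log_odds(self, rng):
        n = 4000
        g = rng.binomial(2, 0.4, size=n).astype(float)
        eta = -1.0 + 0.6 * g
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = association_scan(make_genotypes(g[:, None]), y, model="logistic")
        assert res["beta"].iloc[0] == pytest.approx(0.6, abs=3 * res["se"].iloc[0])

    def test_logistic_separation_reported_not_fatal(self):
        g = np.array([0, 0, 0, 0, 2, 2, 2, 2], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        dos = np.column_stack([g, np.array([0, 1] * 4, dtype=float)])
        res = association_scan(make_genotypes(dos), y, model="logistic")
        assert np.isnan(res["beta"].iloc[0])
        assert res["note"].iloc[0] == "separation_or_nonconvergence"
        assert np.isfinite(res["p"].iloc[1])


class TestGenomicInflation:
    def test_uniform_p_calibrates_to_one(self, rng):
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_constant_half_gives_exactly_one(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_scaled_chi2_recovered(self, rng):
        chi2 = stats.chi2.rvs(1, size=50_000, random_state=rng) * 1.3
        p = stats.chi2.sf(chi2, 1)
        assert genomic_inflation(p) == pytest.approx(1.3, abs=0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.concatenate([np.full(200, 0.5), [0.0]]))


def brute_force_clump(assoc, G, p_thresh, r2_thresh, window_cm):
    """Literal restatement of the greedy rule for oracle comparison."""
    rows = assoc.dropna(subset=["p"])
    rows = rows[rows["p"] < p_thresh]
    meta = G.variants.set_index("variant_id")
    remaining = sorted(rows["variant_id"],
                       key=lambda v: (rows.set_index("variant_id").at[v, "p"],
                                      str(meta.at[v, "chrom"]),
                                      meta.at[v, "pos_bp"]))
    leads = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead)
        li = int(G.index_of([lead])[0])
        keep = []
        for v in remaining:
            vi = int(G.index_of([v])[0])
            same = meta.at[v, "chrom"] == meta.at[lead, "chrom"]
            close = abs(meta.at[v, "pos_cm"] - meta.at[lead, "pos_cm"]) <= window_cm
            r = np.corrcoef(G.dosages[:, li], G.dosages[:, vi])[0, 1] ** 2
            if not (same and close and r >= r2_thresh):
                keep.append(v)
        remaining = keep
    return leads


class TestClump:
    def _correlated_triple(self, rng, r=0.7, n=400):
        base = rng.binomial(1, 0.3, size=(n, 2)).astype(float)
        cols = []
        for _ in range(3):
            flip = rng.uniform(size=(n, 2)) < (1 - r) / 2
            cols.append(np.abs(base - flip).sum(axis=1))
        return np.column_stack(cols)

    def test_window_example_single_lead(self, rng):
        dos = self._correlated_triple(rng)
        G = make_genotypes(dos, cm=[0.0, 0.02, 0.04])
        assoc = G.variants[["variant_id"]].copy()
        assoc["p"] = [1e-6, 1e-5, 1e-4]
        leads = ld_clump(assoc, G, p_thresh=5e-5)
        assert leads == ["v0"]  # 1e-4 fails p, 1e-5 clumped by the lead

    def test_no_ld_keeps_every_significant_variant(self, rng):
        dos = rng.binomial(2, 0.3, size=(2000, 6)).astype(float)
        G = make_genotypes(dos, cm=np.arange(6) * 0.001)
        assoc = G.variants[["variant_id"]].copy()
        assoc["p"] = [1e-6, 1e-6, 2e-3, 1e-7, 4e-5, 0.5]
        leads = ld_clump(assoc, G, p_thresh=5e-5)
        assert set(leads) == {"v0", "v1", "v3", "v4"}

    def test_identical_variants_collapse_to_one_lead(self, rng):
        col = rng.binomial(2, 0.4, size=300).astype(float)
        G = make_genotypes(np.column_stack([col, col]), cm=[0.0, 0.01])
        assoc = G.variants[["variant_id"]].copy()
        assoc["p"] = [1e-6, 1e-6]
        assert len(ld_clump(assoc, G)) == 1

    def test_matches_brute_force_oracle_on_random_instances(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            cfg = SimulationConfig(n_samples=150, n_variants=20,
                                   ld_block_size=5, ld_rho=0.7, seed=seed)
            G = simulate_genotypes(cfg)
            assoc = G.variants[["variant_id"]].copy()
            assoc["p"] = 10 ** rng.uniform(-8, -2, size=20)
            got = ld_clump(assoc, G, p_thresh=5e-4, r2_thresh=0.2,
                           window_cm=0.05)
            want = brute_force_clump(assoc, G, 5e-4, 0.2, 0.05)
            assert got == want


class TestPolygenicScore:
    def test_single_variant_score_values(self):
        dos = np.array([[0.0], [1.0], [2.0]])
        G = make_genotypes(dos)
        assoc = G.variants[["variant_id", "effect_allele", "other_allele"]].copy()
        assoc["beta"] = [0.5]
        prs = build_polygenic_score(["v0"], assoc, G)
        assert list(prs.scores) == [0.0, 0.5, 1.0]

    def test_allele_flip_harmonized(self, rng):
        dos = rng.binomial(2, 0.4, size=(20, 3)).astype(float)
        G1 = make_genotypes(dos)
        assoc = G1.variants[["variant_id", "effect_allele", "other_allele"]].copy()
        assoc["beta"] = [0.2, -0.4, 0.1]
        flipped = make_genotypes(2.0 - dos,
                                 alleles=[("G", "A")] * 3)
        s1 = build_polygenic_score(list(assoc["variant_id"]), assoc, G1)
        s2 = build_polygenic_score(list(assoc["variant_id"]), assoc, flipped)
        np.testing.assert_allclose(s1.scores, s2.scores)

    def test_missing_variant_dropped_with_count(self, rng):
        dos = rng.binomial(2, 0.4, size=(10, 1)).astype(float)
        G = make_genotypes(dos)
        assoc = pd.DataFrame({"variant_id": ["v0", "ghost"],
                              "effect_allele": ["A", "A"],
                              "other_allele": ["G", "G"],
                              "beta": [0.1, 0.9]})
        with pytest.warns(UserWarning, match="dropped"):
            prs = build_polygenic_score(["v0", "ghost"], assoc, G)
        assert prs.n_dropped == 1

    def test_discovery_target_split_recovers_association(self):
        from micromr.features import (prevalence_partition,
                                      transform_common_abundance)
        from micromr.simulate import simulate_taxon_table
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(n_samples=700, n_variants=300,
                                   n_taxa_common=20, n_taxa_rare=5,
                                   taxon_h2=0.5, n_causal_per_taxon=8,
                                   seed=seed)
            G = simulate_genotypes(cfg)
            T, _ = simulate_taxon_table(G, cfg)
            z = transform_common_abundance(prevalence_partition(T)[0])
            disc, targ = slice(0, 350), slice(350, 700)
            Gd = G.subset_samples(G.sample_ids[disc])
            Gt = G.subset_samples(G.sample_ids[targ])
            assoc = association_scan(Gd, z.iloc[disc, 0].to_numpy())
            leads = ld_clump(assoc, Gd, p_thresh=5e-4)
            if not leads:
                continue
            prs = build_polygenic_score(leads, assoc, Gt)
            res = score_association(prs.scores, z.iloc[targ, 0].to_numpy())
            wins += (res["estimate"] > 0) and (res["p"] < 0.05)
        assert wins >= 8

    def test_outcome_equals_score_gives_unit_slope(self, rng):
        s = pd.Series(rng.standard_normal(100))
        res = score_association(s, s.to_numpy())
        assert res["estimate"] == pytest.approx(1.0, abs=1e-8)
        assert res["p"] < 1e-20

    def test_binary_outcome_reports_odds_ratio(self, rng):
        s = pd.Series(rng.standard_normal(800))
        y = (rng.uniform(size=800) < 1 / (1 + np.exp(-s))).astype(float)
        res = score_association(s, y, outcome_kind="binary")
        assert res["odds_ratio"] > 1 and res["p"] < 0.01
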