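"""Disease-microbiome feature analysis.

Covers the feature-level half of the pipeline: Spearman screening of
predicted disease/pathway abundance against taxa with an
effective-number-of-tests Bonferroni mask, PAM (k-medoids) clustering of
diseases with silhouette-based selection of k, Jaccard comparison of two
cluster solutions, and the microbiome risk score (MRS): taxa passing
|rho| > 0.2 contribute +/-1 by association direction, zeroed below their
5% abundance quantile, and the summed score is tested against disease
status by covariate-adjusted logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .containers import ClusterSolution, TaxonTable, ValidationError


# ---------------------------------------------------------------------------
# correlation screening


def correlate_features(P: pd.DataFrame, T: pd.DataFrame, n_eff: float,
                       n_features: int | None = None,
                       alpha: float = 0.05, order_rows: bool = False):
    """Spearman correlation of every disease/pathway feature with every taxon.

    Returns (rho, p, mask) frames, features x taxa.  The mask applies the
    Bonferroni bound ``p < alpha / (n_eff * n_features)`` where ``n_eff`` is
    the effective number of independent taxa at the level analysed and
    ``n_features`` defaults to the number of disease features (the Fig-5 rule
    0.05 / (5.6 x 22) ~ 4e-4 at genus level with 22 diseases).
    """
    common = P.index.intersection(T.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 shared samples")
    P, T = P.loc[common], T.loc[common]
    if n_features is None:
        n_features = P.shape[1]
    rho = pd.DataFrame(np.nan, index=P.columns, columns=T.columns)
    pval = pd.DataFrame(np.nan, index=P.columns, columns=T.columns)
    for f in P.columns:
        x = P[f].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue  # rho undefined for constant feature
        for t in T.columns:
            y = T[t].to_numpy(dtype=float)
            if np.std(y) == 0:
                continue
            r, p = stats.spearmanr(x, y)
            rho.at[f, t], pval.at[f, t] = r, p
    threshold = alpha / (n_eff * n_features)
    mask = pval < threshold
    if order_rows and P.shape[1] > 2:
        prof = rho.fillna(0.0).to_numpy()
        order = leaves_list(linkage(prof, method="average"))
        rho, pval, mask = rho.iloc[order], pval.iloc[order], mask.iloc[order]
    return rho, pval, mask


# ---------------------------------------------------------------------------
# PAM (k-medoids)


def _as_distance(D) -> tuple[np.ndarray, list]:
    if isinstance(D, pd.DataFrame):
        arr = D.to_numpy(dtype=float)
        ids = list(D.index)
        if D.shape[0] == D.shape[1] and np.allclose(arr, arr.T, atol=1e-10) and \
                np.allclose(np.diag(arr), 0.0, atol=1e-10):
            return arr, ids
        # feature matrix: Euclidean distances between rows
        return squareform(pdist(arr)), ids
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2:
        raise ValueError("distance input must be 2-D")
    if arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T, atol=1e-10) and \
            np.allclose(np.diag(arr), 0.0, atol=1e-10):
        return arr, list(range(arr.shape[0]))
    if arr.shape[0] == arr.shape[1]:
        raise ValueError("square input is not a valid (symmetric, zero-diagonal) "
                         "distance matrix")
    return squareform(pdist(arr)), list(range(arr.shape[0]))


def _pam_objective(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _swap_phase(Dm: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improvement SWAP until no (medoid, non-medoid) exchange lowers
    the objective; ties broken by lowest candidate index."""
    n = Dm.shape[0]
    medoids = list(medoids)
    best_obj = _pam_objective(Dm, medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi in range(len(medoids)):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                obj = _pam_objective(Dm, trial)
                if obj < best_obj - 1e-12:
                    if best_swap is None or obj < best_swap[0] - 1e-12 or \
                            (abs(obj - best_swap[0]) <= 1e-12 and c < best_swap[2]):
                        best_swap = (obj, mi, c)
        if best_swap is not None:
            best_obj, mi, c = best_swap
            medoids[mi] = c
            improved = True
    return medoids, best_obj


def pam_cluster(D, k: int, n_restarts: int = 4, seed: int = 0) -> ClusterSolution:
    """Partitioning Around Medoids: BUILD + SWAP with deterministic restarts.

    BUILD greedily seeds k medoids; SWAP repeatedly applies the best
    improving (medoid, non-medoid) exchange until none lowers the total
    dissimilarity of objects to their nearest medoid (ties broken by lowest
    object index).  Because SWAP is a local search, ``n_restarts`` extra
    seeded random initializations are also polished and the best solution
    kept (fully deterministic).  Accepts a square distance matrix or an
    objects x features matrix (Euclidean).
    """
    Dm, ids = _as_distance(D)
    n = Dm.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} objects")

    # BUILD
    medoids = [int(np.argmin(Dm.sum(axis=1)))]
    while len(medoids) < k:
        cur = Dm[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - Dm, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    medoids, best_obj = _swap_phase(Dm, medoids)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts if k < n else 0):
        start = list(rng.choice(n, size=k, replace=False))
        cand, obj = _swap_phase(Dm, start)
        if obj < best_obj - 1e-12:
            medoids, best_obj = cand, obj

    medoids = sorted(medoids)
    assign = np.argmin(Dm[:, medoids], axis=1)
    labels = pd.Series(assign, index=ids)
    return ClusterSolution(labels=labels, medoids=[ids[m] for m in medoids],
                           objective=_pam_objective(Dm, medoids))


def silhouette_widths(D, labels: pd.Series) -> pd.Series:
    """Per-object silhouette ``sw_i = (M_i - N_i) / max(M_i, N_i)``.

    ``N_i`` is the mean dissimilarity to the other members of i's cluster,
    ``M_i`` the smallest mean dissimilarity to any other cluster.  Objects in
    singleton clusters get silhouette 0.
    """
    Dm, ids = _as_distance(D)
    lab = labels.loc[ids].to_numpy() if isinstance(labels, pd.Series) else np.asarray(labels)
    uniq = np.unique(lab)
    sw = np.zeros(len(ids))
    for i in range(len(ids)):
        own = lab[i]
        mask_own = (lab == own)
        if mask_own.sum() == 1:
            sw[i] = 0.0
            continue
        n_i = Dm[i, mask_own].sum() / (mask_own.sum() - 1)
        m_i = min(Dm[i, lab == other].mean() for other in uniq if other != own)
        sw[i] = (m_i - n_i) / max(m_i, n_i) if max(m_i, n_i) > 0 else 0.0
    return pd.Series(sw, index=ids)


def choose_k_by_silhouette(D, k_range=range(2, 11)) -> tuple[int, ClusterSolution]:
    """Run PAM for each candidate k; pick the k maximizing the average
    silhouette width ('pamk'-style selection; ties go to the smaller k)."""
    k_range = [k for k in k_range]
    if not k_range:
        raise ValueError("empty k range")
    Dm, ids = _as_distance(D)
    n = len(ids)
    best = None
    for k in k_range:
        if k >= n:
            continue
        Did = pd.DataFrame(Dm, index=ids, columns=ids)
        try:
            sol = pam_cluster(Did, k)
        except ValidationError:   # k exceeds the number of distinct objects
            continue
        sw = silhouette_widths(Did, sol.labels)
        avg = float(sw.mean())
        sol.silhouette, sol.avg_silhouette = sw, avg
        if best is None or avg > best[0] + 1e-12:
            best = (avg, k, sol)
    if best is None:
        raise ValueError("no candidate k is smaller than the number of objects")
    _, k_opt, sol = best
    return k_opt, sol


# ---------------------------------------------------------------------------
# Jaccard cluster similarity


def jaccard_cluster_similarity(A: ClusterSolution | pd.Series,
                               B: ClusterSolution | pd.Series) -> float:
    """Pairwise co-membership Jaccard coefficient ``J = a / (a + b + c)``.

    Over all unordered object pairs: ``a`` co-clustered in both solutions,
    ``b`` only in A, ``c`` only in B.  Identical partitions give 1; if both
    partitions are all singletons (a + b + c = 0) the similarity is defined
    as 1 with a warning.
    """
    la = A.labels if isinstance(A, ClusterSolution) else A
    lb = B.labels if isinstance(B, ClusterSolution) else B
    if set(la.index) != set(lb.index):
        raise ValidationError("cluster solutions label different object sets")
    lb = lb.loc[la.index]
    ca = pd.crosstab(la.to_numpy(), lb.to_numpy()).to_numpy()

    def pairs(x):
        return (x * (x - 1) // 2).sum()

    a = pairs(ca)
    same_a = pairs(ca.sum(axis=1))
    same_b = pairs(ca.sum(axis=0))
    b, c = same_a - a, same_b - a
    denom = a + b + c
    if denom == 0:
        import warnings
        warnings.warn("both partitions are all singletons; Jaccard defined as 1")
        return 1.0
    return float(a / denom)


# ---------------------------------------------------------------------------
# microbiome risk score


@dataclass
class MRSModel:
    directions: pd.Series      # taxon -> +1 / -1 (sign of training Spearman rho)
    cutoffs: pd.Series         # taxon -> 5%-quantile abundance cutoff
    rho: pd.Series             # training correlations of the selected taxa
    rho_threshold: float = 0.2
    quantile: float = 0.05

    @property
    def taxa(self) -> list[str]:
        return list(self.directions.index)


class EmptyModelError(ValueError):
    pass


def build_mrs(T: TaxonTable, target: pd.Series, rho_threshold: float = 0.2,
              quantile: float = 0.05) -> MRSModel:
    """Select taxa with |Spearman rho| strictly above ``rho_threshold``
    against the target feature; store each taxon's direction (sign of rho)
    and its empirical ``quantile`` abundance cutoff (type-7 interpolation).
    """
    rel = T.to_relative().data
    common = rel.index.intersection(target.index)
    rel, tgt = rel.loc[common], target.loc[common].to_numpy(dtype=float)
    rhos, cuts = {}, {}
    for taxon in rel.columns:
        x = rel[taxon].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(tgt) == 0:
            continue
        r, _ = stats.spearmanr(x, tgt)
        if np.isfinite(r) and abs(r) > rho_threshold:
            rhos[taxon] = float(r)
            cuts[taxon] = float(np.quantile(x, quantile))
    if not rhos:
        raise EmptyModelError(
            f"no taxon exceeds |rho| > {rho_threshold} with the target")
    rho = pd.Series(rhos)
    return MRSModel(directions=np.sign(rho).astype(int), cutoffs=pd.Series(cuts),
                    rho=rho, rho_threshold=rho_threshold, quantile=quantile)


def score_mrs(model: MRSModel, T: TaxonTable) -> pd.Series:
    """Apply an MRS model: each selected taxon contributes 0 below its
    stored cutoff, otherwise its direction (+1/-1); the score is the sum."""
    rel = T.to_relative().data
    missing = [t for t in model.taxa if t not in rel.columns]
    if missing:
        raise ValidationError(f"taxa missing from table: {missing}")
    score = np.zeros(rel.shape[0])
    for taxon in model.taxa:
        x = rel[taxon].to_numpy(dtype=float)
        score += np.where(x < model.cutoffs[taxon], 0, model.directions[taxon])
    return pd.Series(score, index=rel.index, name="mrs")


def score_and_test_mrs(model: MRSModel, T: TaxonTable, outcome: pd.Series,
                       X: pd.DataFrame | None = None) -> dict:
    """Score samples and test MRS against binary disease status by logistic
    regression (adjusted for the supplied covariates); returns the per-unit
    odds ratio with 95% CI."""
    import statsmodels.api as sm

    scores = score_mrs(model, T)
    common = scores.index.intersection(outcome.index)
    s = scores.loc[common].to_numpy(dtype=float)
    y = outcome.loc[common].to_numpy(dtype=float)
    cols = [s]
    if X is not None:
        cols.append(X.loc[common].to_numpy(dtype=float))
    design = sm.add_constant(np.column_stack(cols), prepend=False)
    fit = sm.Logit(y, design).fit(disp=0)
    beta, se, p = fit.params[0], fit.bse[0], fit.pvalues[0]
    return {"scores": scores, "odds_ratio": float(np.exp(beta)),
            "ci": (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
            "beta": float(beta), "se": float(se), "p": float(p),
            "n": int(len(common)), "n_cases": int(y.sum())}
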