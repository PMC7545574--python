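"""Host-genetics toolbox: genetic relationship matrix, single-component
REML heritability, covariate-adjusted association scans, genomic inflation,
LD clumping and polygenic scores.

The heritability estimator is a from-scratch average-information (AI) REML
for the model ``y = Xb + g + e`` with ``g ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)``, where ``K`` is the GRM.  A single eigendecomposition
of ``K`` rotates the model to a diagonal covariance, making every REML
iteration O(n) — the estimates are identical to the dense formulation.

Mixed-model association is approximated by fixed-effect regression with the
leading genetic principal components as covariates (the cohorts simulated
here carry no cryptic relatedness, so the fixed-effect approximation is the
appropriate scan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import GenotypeMatrix

_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


# ---------------------------------------------------------------------------
# GRM


def compute_grm(G: GenotypeMatrix, n_pcs: int = 5) -> tuple[np.ndarray, pd.DataFrame]:
    """GCTA-style GRM and leading genetic principal components.

    ``GRM[j, k] = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
    with ``p_i`` the empirical effect-allele frequency.  Monomorphic variants
    are excluded with a warning.  PCs are eigenvectors of the GRM scaled by
    the square root of their eigenvalues.
    """
    X = G.dosages
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("GRM needs at least 2 samples and 1 variant")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variants from GRM")
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = Z.shape[1]
    grm = (Z @ Z.T) / m
    evals, evecs = linalg.eigh(grm)
    order = np.argsort(evals)[::-1][:n_pcs]
    pcs = evecs[:, order] * np.sqrt(np.clip(evals[order], 0, None))
    pc_df = pd.DataFrame(pcs, index=G.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(len(order))])
    return grm, pc_df


# ---------------------------------------------------------------------------
# GREML


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float] | None = None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class GremlResult:
    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    boundary: bool = False
    non_identifiable: bool = False


class _RotatedREML:
    """REML machinery after rotating by the GRM eigenvectors.

    In the rotated basis the covariance is ``diag(sg * lam + se)``, so the
    restricted log-likelihood, its gradient and the AI matrix are all O(n p^2).
    """

    def __init__(self, grm: np.ndarray, y: np.ndarray, X: np.ndarray):
        lam, U = linalg.eigh(grm)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = self.Xt.shape

    def _solve(self, sg: float, se: float):
        d = sg * self.lam + se
        Xd = self.Xt / d[:, None]
        C = self.Xt.T @ Xd                     # X' V^-1 X
        b = Xd.T @ self.yt
        Cinv = linalg.inv(C)
        Py = self.yt / d - Xd @ (Cinv @ b)     # P y in rotated coords
        return d, Xd, C, Cinv, Py

    def loglik(self, sg: float, se: float) -> float:
        d, _, C, _, Py = self._solve(sg, se)
        yPy = float(self.yt @ Py)
        sign, logdetC = np.linalg.slogdet(C)
        return -0.5 * (np.log(d).sum() + logdetC + yPy)

    def _P(self, v: np.ndarray, d, Xd, Cinv) -> np.ndarray:
        return v / d - Xd @ (Cinv @ (Xd.T @ v))

    def grad_ai(self, sg: float, se: float):
        d, Xd, C, Cinv, Py = self._solve(sg, se)
        # tr(P A) = tr(V^-1 A) - tr(Cinv X' V^-1 A V^-1 X), A in {K, I}
        a_list = (self.lam, np.ones(self.n))
        grad = np.empty(2)
        u = [a * Py for a in a_list]
        for i, a in enumerate(a_list):
            trVA = float((a / d).sum())
            XaX = self.Xt.T @ (self.Xt * (a / d ** 2)[:, None])
            trP = trVA - float(np.trace(Cinv @ XaX))
            yPAPy = float(Py @ u[i])
            grad[i] = -0.5 * (trP - yPAPy)
        AI = np.empty((2, 2))
        Pu = [self._P(ui, d, Xd, Cinv) for ui in u]
        for i in range(2):
            for j in range(2):
                AI[i, j] = 0.5 * float(u[i] @ Pu[j])
        return grad, AI, Py


def reml_loglik(grm: np.ndarray, y: np.ndarray, X: np.ndarray | None,
                sigma_g2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood (up to a constant) of the GREML model at
    given variance components; evaluated through the eigen-rotated
    representation."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    ones = np.ones((n, 1))
    X = ones if X is None else np.column_stack([ones, np.asarray(X, dtype=float)])
    return _RotatedREML(grm, y, X).loglik(sigma_g2, sigma_e2)


def greml_heritability(grm: np.ndarray, y: np.ndarray, X: np.ndarray | None = None,
                       max_iter: int = 100, tol: float = 1e-6) -> GremlResult:
    """Estimate the SNP heritability ``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.

    AI-REML with step halving and an EM fallback; variance components are
    constrained to be non-negative (truncated at a small floor with a
    boundary flag).  ``X`` are fixed-effect covariates; an intercept is added.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if grm.shape != (n, n):
        raise ValueError("GRM shape does not match phenotype length")
    ones = np.ones((n, 1))
    X = ones if X is None else np.column_stack([ones, np.asarray(X, dtype=float)])

    rot = _RotatedREML(grm, y, X)
    non_ident = float(np.ptp(rot.lam)) < 1e-10  # GRM proportional to I
    vp = float(np.var(y, ddof=1))
    floor = 1e-8 * vp
    sg, se = vp / 2, vp / 2
    trace = [rot.loglik(sg, se)]
    converged = False
    for _ in range(max_iter):
        grad, AI, _ = rot.grad_ai(sg, se)
        step = None
        try:
            step = linalg.solve(AI, grad, assume_a="pos")
        except linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            # EM fallback keeps components positive
            step = np.array([sg ** 2, se ** 2]) * grad * 2.0 / n
        new = None
        for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = np.array([sg, se]) + damp * step
            cand = np.maximum(cand, floor)
            ll = rot.loglik(*cand)
            if np.isfinite(ll) and (ll >= trace[-1] - 1e-10):
                new, ll_new = cand, ll
                break
        if new is None:  # EM step as a last resort
            em = np.array([sg, se]) + np.array([sg ** 2, se ** 2]) * grad * 2.0 / n
            new = np.maximum(em, floor)
            ll_new = rot.loglik(*new)
        rel = abs(ll_new - trace[-1]) / max(1.0, abs(trace[-1]))
        sg, se = float(new[0]), float(new[1])
        trace.append(ll_new)
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"REML did not converge in {max_iter} iterations", trace)

    boundary = (sg <= floor * 1.01) or (se <= floor * 1.01)
    _, AI, _ = rot.grad_ai(sg, se)
    h2 = sg / (sg + se)
    try:
        cov = linalg.inv(AI)
        g = np.array([se, -sg]) / (sg + se) ** 2  # delta method for sg/(sg+se)
        se_h2 = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except linalg.LinAlgError:
        se_h2 = float("nan")
    return GremlResult(h2=float(h2), se=se_h2, sigma_g2=sg, sigma_e2=se,
                       loglik=trace[-1], loglik_trace=trace, converged=converged,
                       boundary=boundary, non_identifiable=non_ident)


# ---------------------------------------------------------------------------
# association scan


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 25,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray] | None:
    """Newton/IRLS logistic fit; returns (beta, se) or None on separation."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if w.max() < 1e-12:
            return None
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            delta = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            return None
        beta = beta + delta
        if np.abs(delta).max() < tol:
            if np.abs(beta).max() > 15:  # quasi-separation
                return None
            try:
                cov = linalg.inv(H)
            except linalg.LinAlgError:
                return None
            return beta, np.sqrt(np.diag(cov))
    return None


def association_scan(G: GenotypeMatrix, y: np.ndarray, X: np.ndarray | None = None,
                     model: str = "linear") -> pd.DataFrame:
    """Per-variant Wald tests of phenotype on dosage plus covariates.

    ``model='linear'``: exact OLS via projection onto the covariate
    complement.  ``model='logistic'``: per-variant IRLS; variants with
    (quasi-)separation are reported as NA with a reason and the scan
    continues.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = G.n_samples
    if y.size != n:
        raise ValueError("phenotype length does not match genotype samples")
    ones = np.ones((n, 1))
    Xf = ones if X is None else np.column_stack([ones, np.asarray(X, dtype=float)])
    p_cov = Xf.shape[1]
    out = G.variants[["variant_id", "chrom", "pos_bp", "pos_cm",
                      "effect_allele", "other_allele"]].copy()
    out["eaf"] = G.dosages.mean(axis=0) / 2.0
    beta = np.full(G.n_variants, np.nan)
    se = np.full(G.n_variants, np.nan)
    pval = np.full(G.n_variants, np.nan)
    note = np.array([""] * G.n_variants, dtype=object)

    if model == "linear":
        Q, _ = np.linalg.qr(Xf)
        y_r = y - Q @ (Q.T @ y)
        G_r = G.dosages - Q @ (Q.T @ G.dosages)
        gMg = (G_r ** 2).sum(axis=0)
        ok = gMg > 1e-12
        note[~ok] = "monomorphic_after_adjustment"
        df = n - p_cov - 1
        gy = G_r.T @ y_r
        beta[ok] = gy[ok] / gMg[ok]
        rss = (y_r @ y_r) - beta[ok] ** 2 * gMg[ok]
        sigma2 = np.maximum(rss, 0.0) / df
        se[ok] = np.sqrt(sigma2 / gMg[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[ok] / se[ok]
        pval[ok] = 2 * stats.t.sf(np.abs(t), df)
    elif model == "logistic":
        yb = y.astype(float)
        if not set(np.unique(yb)) <= {0.0, 1.0}:
            raise ValueError("logistic scan requires a 0/1 phenotype")
        for j in range(G.n_variants):
            g = G.dosages[:, j]
            if g.std() < 1e-12:
                note[j] = "monomorphic"
                continue
            fit = _logistic_irls(np.column_stack([Xf, g]), yb)
            if fit is None:
                note[j] = "separation_or_nonconvergence"
                continue
            b, s = fit
            beta[j], se[j] = b[-1], s[-1]
            pval[j] = 2 * stats.norm.sf(abs(b[-1] / s[-1]))
    else:
        raise ValueError(f"unknown model {model!r}")

    # p-values of exactly 0 are numerically impossible downstream (log, chi2)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    out["beta"], out["se"], out["p"] = beta, se, pval
    out["n"] = n
    out["model"] = model
    out["note"] = note
    return out


def genomic_inflation(p_values: np.ndarray) -> float:
    """Median-based genomic inflation factor lambda_GC.

    ``lambda = median(qchisq(1 - p, 1)) / 0.4549``.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for lambda_GC")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


# ---------------------------------------------------------------------------
# LD clumping and polygenic scores


def ld_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation between two dosage columns (PLINK convention)."""
    a, b = G.dosages[:, i], G.dosages[:, j]
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_clump(assoc: pd.DataFrame, G: GenotypeMatrix, p_thresh: float = 5e-5,
             r2_thresh: float = 0.1, window_cm: float = 0.1) -> list[str]:
    """Greedy LD clumping: smallest p first, peers within ``window_cm``
    and ``r2 >= r2_thresh`` are claimed by the lead.

    Ties on p are broken by genomic coordinate (smaller first).  Returns lead
    variant ids in selection order.
    """
    cand = assoc.dropna(subset=["p"])
    cand = cand[cand["p"] < p_thresh]
    if cand.empty:
        return []
    gidx = G.index_of(cand["variant_id"])
    meta = G.variants.iloc[gidx]
    order = np.lexsort((meta["pos_bp"].to_numpy(), meta["chrom"].astype(str).to_numpy(),
                        cand["p"].to_numpy()))
    queue = list(np.asarray(gidx)[order])
    info = G.variants
    leads: list[str] = []
    claimed: set[int] = set()
    for idx in queue:
        if idx in claimed:
            continue
        leads.append(info.at[idx, "variant_id"])
        claimed.add(idx)
        chrom, cm = info.at[idx, "chrom"], info.at[idx, "pos_cm"]
        for other in queue:
            if other in claimed:
                continue
            if info.at[other, "chrom"] != chrom:
                continue
            if abs(info.at[other, "pos_cm"] - cm) > window_cm:
                continue
            if ld_r2(G, idx, other) >= r2_thresh:
                claimed.add(other)
    return leads


@dataclass
class PolygenicScore:
    weights: dict[str, float]          # variant id -> beta (per effect allele)
    effect_alleles: dict[str, str]
    scores: pd.Series                  # per-sample score
    n_dropped: int = 0


def build_polygenic_score(leads: list[str], assoc: pd.DataFrame,
                          G_target: GenotypeMatrix) -> PolygenicScore:
    """Weighted score ``sum_i beta_i * dosage_i`` with allele harmonization.

    Weights are the discovery betas of the lead variants.  If the target's
    effect allele is the discovery other allele, the dosage is flipped
    (``2 - d``).  Leads missing from the target, or with incompatible
    alleles, are dropped and counted.
    """
    a = assoc.set_index("variant_id")
    tmeta = G_target.variants.set_index("variant_id")
    score = np.zeros(G_target.n_samples)
    weights: dict[str, float] = {}
    alleles: dict[str, str] = {}
    dropped = 0
    for vid in leads:
        if vid not in a.index or vid not in tmeta.index:
            dropped += 1
            continue
        beta = float(a.at[vid, "beta"])
        ea, oa = a.at[vid, "effect_allele"], a.at[vid, "other_allele"]
        tea, toa = tmeta.at[vid, "effect_allele"], tmeta.at[vid, "other_allele"]
        j = int(tmeta.index.get_loc(vid))
        d = G_target.dosages[:, j]
        if (ea, oa) == (tea, toa):
            pass
        elif (ea, oa) == (toa, tea):
            d = 2.0 - d
        else:
            dropped += 1
            continue
        score += beta * d
        weights[vid] = beta
        alleles[vid] = ea
    if dropped:
        warnings.warn(f"{dropped} lead variant(s) dropped from polygenic score")
    return PolygenicScore(weights=weights, effect_alleles=alleles,
                          scores=pd.Series(score, index=G_target.sample_ids),
                          n_dropped=dropped)


def test_polygenic_score(score: pd.Series, outcome: np.ndarray,
                         X: np.ndarray | None = None,
                         outcome_kind: str = "continuous") -> dict:
    """Association of a polygenic score with a taxon outcome.

    ``continuous``: Gaussian linear model on the (Z-scored log) abundance.
    ``binary``: logistic regression, reporting the odds ratio per score unit.
    ``negative-binomial``: NB2 GLM on raw counts (fidelity option).
    """
    import statsmodels.api as sm

    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    if s.size != y.size:
        raise ValueError("score and outcome are not aligned on samples")
    design = s[:, None] if X is None else np.column_stack([s, np.asarray(X, dtype=float)])
    design = sm.add_constant(design, prepend=False)
    try:
        if outcome_kind == "continuous":
            fit = sm.OLS(y, design).fit()
        elif outcome_kind == "binary":
            fit = sm.Logit(y, design).fit(disp=0)
        elif outcome_kind == "negative-binomial":
            fit = sm.GLM(y, design, family=sm.families.NegativeBinomial()).fit()
        else:
            raise ValueError(f"unknown outcome kind {outcome_kind!r}")
    except Exception as exc:  # noqa: BLE001 - surface model diagnostics
        raise RuntimeError(f"polygenic-score model failed to converge: {exc}") from exc
    est, se_, p = fit.params[0], fit.bse[0], fit.pvalues[0]
    res = {"estimate": float(est), "se": float(se_), "p": float(p),
           "n": int(y.size), "kind": outcome_kind}
    if outcome_kind == "binary":
        res["odds_ratio"] = float(np.exp(est))
    return res
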