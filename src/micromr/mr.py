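"""Two-sample Mendelian randomization.

Implements the full bidirectional workflow: instrument selection and
exclusion, LD proxies, allele harmonization, and four estimators — IVW
(multiplicative random effects by default), weighted median, MR-Egger and
an MR-PRESSO global/outlier test — plus the two-tier significance
classification (Bonferroni-significant vs "potential causal": nominal
p < 0.05 in all four methods).

Effect-unit conventions: forward results are the change in outcome per 1-SD
of log-transformed taxon abundance; reverse results on binary taxa are the
log odds of presence per log-odds of disease liability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, HarmonizedInstruments, validate_summary_stats
from .genetics import ld_r2

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_EAF_WINDOW = (0.42, 0.58)  # palindromic variants with EAF inside are ambiguous

#: Forward-direction Bonferroni denominator: 58 complex traits + 4 diseases.
N_FORWARD_TESTS = 62


class InsufficientInstrumentsError(ValueError):
    pass


class EmptyInstrumentSetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# instrument selection and proxies


def select_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame,
                       direction: str = "forward",
                       ld_reference: GenotypeMatrix | None = None,
                       r2_thresh: float = 0.1,
                       n_independent: int | None = None,
                       pair_label: str = "") -> list[str]:
    """Apply the instrument inclusion/exclusion rules.

    forward (microbiome -> trait): start from the clumped exposure leads and
    drop any instrument whose *outcome* association has ``p < 0.05 / n``,
    the exclusion-restriction screen; ``n`` (``n_independent``) is the
    number of independent genetic variants selected in the polygenic-score
    stage — the pooled lead set across exposures when available, defaulting
    to the instrument count of this pair.

    reverse (disease -> microbiome): keep replicated disease variants thinned
    to pairwise ``r2 < r2_thresh`` in the cohort LD reference, retaining the
    smaller exposure p of any correlated pair.
    """
    exposure = validate_summary_stats(exposure)
    ids = list(exposure["variant_id"])
    if direction == "forward":
        k = n_independent if n_independent is not None else len(ids)
        out = outcome.set_index("variant_id")
        keep = []
        for vid in ids:
            if vid in out.index and out.at[vid, "p"] < 0.05 / k:
                continue
            keep.append(vid)
    elif direction == "reverse":
        if ld_reference is None:
            raise ValueError("reverse-direction selection needs an LD reference")
        order = exposure.sort_values(["p", "chrom", "pos_bp"]).reset_index(drop=True)
        chosen_idx: list[int] = []
        keep = []
        ref_ids = set(ld_reference.variants["variant_id"])
        for _, row in order.iterrows():
            vid = row["variant_id"]
            if vid not in ref_ids:
                keep.append(vid)  # no LD information; retain
                continue
            gi = int(ld_reference.index_of([vid])[0])
            if all(ld_r2(ld_reference, gi, prev) < r2_thresh for prev in chosen_idx):
                chosen_idx.append(gi)
                keep.append(vid)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not keep:
        raise EmptyInstrumentSetError(
            f"no instruments survive selection for {pair_label or 'pair'}")
    return keep


def find_proxy(variant_id: str, ld_reference: GenotypeMatrix,
               available_ids, r2_min: float = 0.9) -> str | None:
    """Best LD proxy (``r2 > r2_min``) for a variant missing from the outcome.

    Candidates are reference variants present in ``available_ids``; returns
    the highest-r2 one, or None (the variant is then discarded).
    """
    ref_ids = list(ld_reference.variants["variant_id"])
    if variant_id not in ref_ids:
        return None
    qi = int(ld_reference.index_of([variant_id])[0])
    best, best_r2 = None, r2_min
    avail = set(available_ids) - {variant_id}
    for j, vid in enumerate(ref_ids):
        if vid not in avail:
            continue
        r2 = ld_r2(ld_reference, qi, j)
        if r2 > best_r2:
            best, best_r2 = vid, r2
    return best


# ---------------------------------------------------------------------------
# harmonization


def harmonize_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame,
                          exposure_name: str = "exposure",
                          outcome_name: str = "outcome",
                          direction: str = "microbiome_to_trait",
                          instrument_ids=None) -> HarmonizedInstruments:
    """Align outcome effects to the exposure effect allele.

    If the outcome's effect allele is the exposure's other allele, the
    outcome beta is sign-flipped and its EAF complemented.  Palindromic
    variants (A/T, C/G) are oriented by allele frequency when both EAFs are
    clearly away from 0.5 (outside [0.42, 0.58]); otherwise dropped.
    Variants with incompatible allele sets are dropped with a count.
    """
    exp = validate_summary_stats(exposure).set_index("variant_id")
    out = validate_summary_stats(outcome).set_index("variant_id")
    ids = instrument_ids if instrument_ids is not None else exp.index
    lo, hi = _EAF_WINDOW
    rows = []
    n_pal, n_bad = 0, 0
    for vid in ids:
        if vid not in exp.index or vid not in out.index:
            continue
        e, o = exp.loc[vid], out.loc[vid]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        b_out, eaf_out = float(o["beta"]), float(o["eaf"])
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            b_out, eaf_out = -b_out, 1.0 - eaf_out
        else:
            n_bad += 1
            continue
        if (ea_e, oa_e) in _PALINDROMIC:
            eaf_e = float(e["eaf"])
            if lo <= eaf_e <= hi or lo <= eaf_out <= hi:
                n_pal += 1
                continue
            if (eaf_e < lo) != (eaf_out < lo):  # frequencies disagree: strand flip
                b_out = -b_out
        rows.append((vid, float(e["beta"]), float(e["se"]), b_out, float(o["se"])))
    if not rows:
        raise EmptyInstrumentSetError(
            f"no harmonizable instruments for {exposure_name} -> {outcome_name}")
    vids, bx, sx, by, sy = zip(*rows)
    return HarmonizedInstruments(list(vids), np.array(bx), np.array(sx),
                                 np.array(by), np.array(sy),
                                 exposure=exposure_name, outcome=outcome_name,
                                 direction=direction,
                                 n_dropped_palindromic=n_pal,
                                 n_dropped_incompatible=n_bad)


# ---------------------------------------------------------------------------
# estimators


@dataclass
class MREstimate:
    method: str
    estimate: float
    se: float
    p: float
    n_instruments: int
    extra: dict = field(default_factory=dict)


def mr_ivw(h: HarmonizedInstruments, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    ``theta = sum(w bx by) / sum(w bx^2)`` with ``w = se_y^-2``.  Under
    heterogeneity (Cochran's Q/(k-1) > 1) the SE is inflated multiplicatively
    (random-effects).  A single instrument falls back to the Wald ratio.
    """
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    if np.any(sy <= 0):
        raise ValueError("outcome SEs must be positive")
    k = h.n_instruments
    if k == 1:
        est = float(by[0] / bx[0])
        se = float(abs(sy[0] / bx[0]))
        p = 2 * stats.norm.sf(abs(est / se))
        return MREstimate("IVW", est, se, float(p), 1, {"wald_ratio": True})
    w = sy ** -2
    sxx = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by) / sxx)
    se_fixed = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - est * bx) ** 2))
    phi = max(1.0, q / (k - 1)) if random_effects else 1.0
    se = float(se_fixed * np.sqrt(phi))
    p = 2 * stats.norm.sf(abs(est / se))
    return MREstimate("IVW", est, se, float(p), k,
                      {"cochran_q": q, "overdispersion": phi})


def _ratio_estimates(h: HarmonizedInstruments) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and their first-order delta-method SEs."""
    bx, sx, by, sy = (h.beta_exposure, h.se_exposure, h.beta_outcome, h.se_outcome)
    r = by / bx
    se = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    return r, se


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the point where the cumulative
    normalized weight crosses 0.5."""
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w     # midpoint convention
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    i = int(np.searchsorted(cum, 0.5))
    lo, hi = i - 1, i
    return float(v[lo] + (v[hi] - v[lo]) * (0.5 - cum[lo]) / (cum[hi] - cum[lo]))


def mr_weighted_median(h: HarmonizedInstruments, n_boot: int = 1000,
                       seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-instrument ratios are weighted by the inverse variance of the
    delta-method ratio SE; consistent when at least half the weight comes
    from valid instruments.
    """
    if h.n_instruments < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    r, se_r = _ratio_estimates(h)
    est = _weighted_median(r, se_r ** -2)
    rng = np.random.default_rng(seed)
    k = h.n_instruments
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = h.beta_exposure + h.se_exposure * rng.standard_normal(k)
        by = h.beta_outcome + h.se_outcome * rng.standard_normal(k)
        rb = by / bx
        sb = np.sqrt(h.se_outcome ** 2 / bx ** 2 + by ** 2 * h.se_exposure ** 2 / bx ** 4)
        boots[b] = _weighted_median(rb, sb ** -2)
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else (0.0 if est != 0 else 1.0)
    return MREstimate("weighted_median", float(est), se, float(p), k)


def mr_egger(h: HarmonizedInstruments) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas *with*
    an intercept, after orienting all exposure betas to be non-negative.

    The intercept estimates directional pleiotropy; SEs carry a
    multiplicative overdispersion factor floored at 1.  p-values use the
    t distribution with k - 2 df.
    """
    if h.n_instruments < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    sign = np.where(h.beta_exposure < 0, -1.0, 1.0)
    bx = h.beta_exposure * sign
    by = h.beta_outcome * sign
    w = h.se_outcome ** -2
    if np.ptp(bx) < 1e-12:
        raise ValueError("all exposure betas equal after orientation; Egger collinear")
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    k = h.n_instruments
    phi = max(1.0, float(np.sum(w * resid ** 2) / (k - 2)))
    cov = np.linalg.inv(A) * phi
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=k - 2)
    return MREstimate("egger", float(coef[1]), float(se[1]), float(pvals[1]), k,
                      {"intercept": float(coef[0]), "intercept_se": float(se[0]),
                       "intercept_p": float(pvals[0]), "overdispersion": phi})


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized via sum updates."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(h: HarmonizedInstruments, n_sim: int = 1000, seed: int = 0,
              alpha_outlier: float = 0.05) -> MREstimate:
    """MR-PRESSO global heterogeneity test with outlier detection.

    The observed statistic is the weighted residual sum of squares of
    leave-one-out IVW predictions; its null distribution is simulated
    parametrically (``n_sim`` draws of instrument effects under the fitted
    no-pleiotropy model).  Empirical p-values use +1 smoothing, so the
    smallest attainable p is ``1/(n_sim + 1)``.  Outliers are instruments
    whose per-instrument RSS exceeds its simulated null at the
    Bonferroni-adjusted level; the corrected estimate is IVW without them.
    """
    if h.n_instruments < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        import warnings
        warnings.warn(f"MR-PRESSO with n_sim={n_sim} < 100 is unreliable")
    rng = np.random.default_rng(seed)
    k = h.n_instruments
    bx, sx, by, sy = (h.beta_exposure, h.se_exposure, h.beta_outcome, h.se_outcome)
    w = sy ** -2
    theta_loo = _loo_ivw(bx, by, w)
    rss_i_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(rss_i_obs.sum())

    # parametric null: outcome effects generated by the LOO causal model
    bx_sim = bx + sx * rng.standard_normal((n_sim, k))
    by_sim = theta_loo * bx + sy * rng.standard_normal((n_sim, k))
    theta_sim = _loo_ivw(bx_sim, by_sim, w)
    rss_i_sim = w * (by_sim - theta_sim * bx_sim) ** 2
    rss_sim = rss_i_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_i = (1 + (rss_i_sim >= rss_i_obs).sum(axis=0)) / (n_sim + 1)
    outliers = [h.variant_ids[i] for i in np.flatnonzero(p_i < alpha_outlier / k)]

    if outliers and len(outliers) < k - 1:
        keep = np.array([v not in outliers for v in h.variant_ids])
        corrected = mr_ivw(h.subset(keep))
        est, se, p = corrected.estimate, corrected.se, corrected.p
    else:
        ivw = mr_ivw(h)
        est, se, p = ivw.estimate, ivw.se, ivw.p
    return MREstimate("presso", est, se, p, k,
                      {"global_p": global_p, "outliers": outliers,
                       "outlier_p": dict(zip(h.variant_ids, p_i))})


# ---------------------------------------------------------------------------
# combined run and classification


@dataclass
class MRResult:
    exposure: str
    outcome: str
    direction: str
    estimates: dict[str, MREstimate]
    classification: str = "null"
    effect_units: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, e in self.estimates.items():
            rows.append({"exposure": self.exposure, "outcome": self.outcome,
                         "direction": self.direction, "method": m,
                         "estimate": e.estimate, "se": e.se, "p": e.p,
                         "n_instruments": e.n_instruments,
                         "classification": self.classification,
                         **{k: v for k, v in e.extra.items()
                            if np.isscalar(v)}})
        return pd.DataFrame(rows)


def classify_mr_result(p_values: dict[str, float], direction: str = "forward",
                       n_tests_forward: int = N_FORWARD_TESTS,
                       n_eff_taxa: float | None = None) -> str:
    """Two-tier significance rule.

    ``significant``: IVW p below the Bonferroni bound for the direction
    (forward: 0.05 / 62 outcomes; reverse: 0.05 / effective number of
    independent taxa at the taxonomic level).  ``potential_causal``: fails
    Bonferroni but all four methods have p < 0.05.  Otherwise ``null``.
    """
    if "IVW" not in p_values:
        raise ValueError("classification requires an IVW p-value")
    if direction == "forward":
        bound = 0.05 / n_tests_forward
    elif direction == "reverse":
        if n_eff_taxa is None:
            raise ValueError("reverse-direction classification needs n_eff_taxa")
        bound = 0.05 / n_eff_taxa
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if p_values["IVW"] < bound:
        return "significant"
    methods = ("IVW", "weighted_median", "egger", "presso")
    if all(m in p_values and p_values[m] < 0.05 for m in methods):
        return "potential_causal"
    return "null"


def run_mr(h: HarmonizedInstruments, n_sim: int = 1000, seed: int = 0,
           n_eff_taxa: float | None = None, effect_units: str = "") -> MRResult:
    """Run all four estimators on a harmonized instrument set and classify."""
    direction = "forward" if h.direction == "microbiome_to_trait" else "reverse"
    est: dict[str, MREstimate] = {"IVW": mr_ivw(h)}
    if h.n_instruments >= 3:
        est["weighted_median"] = mr_weighted_median(h, seed=seed)
        est["egger"] = mr_egger(h)
    if h.n_instruments >= 4:
        est["presso"] = mr_presso(h, n_sim=n_sim, seed=seed)
    pvals = {m: e.p for m, e in est.items()}
    cls = classify_mr_result(pvals, direction=direction, n_eff_taxa=n_eff_taxa)
    return MRResult(h.exposure, h.outcome, direction, est, cls, effect_units)
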