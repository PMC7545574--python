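"""Taxon-table processing: rarefaction, alpha diversity, prevalence
partition, abundance transforms, the effective-number-of-tests statistic and
enterotyping.

Alpha diversity follows the QIIME 1 conventions (Shannon in bits, classic
Chao1 with the ``F2 = 0`` correction).  The effective number of independent
taxa is the eigenvalue-dispersion statistic ``(sum(lambda))^2 / sum(lambda^2)``
computed on the covariance of the (by default Z-scored) abundance columns;
it equals the taxon count for mutually independent taxa and 1 for a rank-one
table, and is the divisor used in Bonferroni corrections throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import calinski_harabasz_score

from .containers import TaxonTable, ValidationError


class DegenerateInputError(ValueError):
    """Raised on constant / zero-variance inputs where a statistic is undefined."""


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(table: TaxonTable, depth: int = 10_000, seed: int = 0) -> tuple[TaxonTable, list[str]]:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped; their ids are
    returned alongside the rarefied table.  Each retained sample sums to
    exactly ``depth`` (one multivariate-hypergeometric draw per sample).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    if not table.is_counts:
        raise ValueError("rarefaction requires a count table")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    row = 0
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
        row += 1
    data = pd.DataFrame(out, index=[s for s, k in zip(table.sample_ids, keep) if k],
                        columns=table.data.columns)
    return TaxonTable(data, is_counts=True), dropped


# ---------------------------------------------------------------------------
# alpha diversity


@dataclass
class AlphaDiversity:
    """Per-sample alpha-diversity indices (Shannon in bits, Chao1, observed)."""

    shannon: pd.Series
    chao1: pd.Series
    observed: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shannon": self.shannon, "chao1": self.chao1,
                             "observed_otus": self.observed})


def _shannon_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: TaxonTable) -> AlphaDiversity:
    """Shannon (base 2), Chao1 and observed-taxon count per sample."""
    if not table.is_counts:
        raise ValueError("alpha diversity requires a count table")
    counts = table.data.to_numpy()
    if counts.size == 0 or (counts.sum(axis=1) == 0).any():
        bad = table.data.index[counts.sum(axis=1) == 0][0] if counts.size else "<empty>"
        raise DegenerateInputError(f"sample {bad!r} is empty; diversity undefined")
    idx = table.data.index
    return AlphaDiversity(
        shannon=pd.Series([_shannon_bits(r) for r in counts], index=idx),
        chao1=pd.Series([_chao1(r) for r in counts], index=idx),
        observed=pd.Series((counts > 0).sum(axis=1), index=idx),
    )


# ---------------------------------------------------------------------------
# prevalence partition and abundance transform


def prevalence_partition(table: TaxonTable, threshold: float = 0.9
                         ) -> tuple[TaxonTable, pd.DataFrame]:
    """Split taxa into common (prevalence >= threshold) and rare.

    Common taxa keep their abundances; rare taxa are returned as a binary
    presence/absence frame for logistic modelling.  The boundary is
    inclusive: a taxon present in exactly ``threshold`` of samples is common.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"prevalence threshold must be in (0, 1], got {threshold}")
    prev = table.prevalence()
    common_cols = prev.index[prev >= threshold]
    rare_cols = prev.index[prev < threshold]
    common = TaxonTable(table.data[common_cols].copy(), is_counts=table.is_counts)
    rare = (table.data[rare_cols] > 0).astype(int)
    return common, rare


def transform_common_abundance(common: TaxonTable, pseudocount: str | float = "half-min"
                               ) -> pd.DataFrame:
    """Z-score the log relative abundance of each common taxon.

    Zeros are replaced before the log with half the minimum nonzero relative
    abundance of that taxon (or an explicit ``pseudocount``).  Output columns
    have mean 0 and SD 1.
    """
    rel = common.to_relative().data
    out = {}
    for taxon in rel.columns:
        a = rel[taxon].to_numpy(dtype=float).copy()
        if (a == 0).any():
            nonzero = a[a > 0]
            if nonzero.size == 0:
                raise DegenerateInputError(f"taxon {taxon!r} absent from every sample")
            pc = nonzero.min() / 2.0 if pseudocount == "half-min" else float(pseudocount)
            a[a == 0] = pc
        la = np.log(a)
        sd = la.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError(f"taxon {taxon!r} has zero log-abundance variance")
        out[taxon] = (la - la.mean()) / sd
    return pd.DataFrame(out, index=rel.index)


# ---------------------------------------------------------------------------
# effective number of independent taxa


def effective_number_independent_taxa(M: np.ndarray | pd.DataFrame,
                                      standardize: bool = True) -> float:
    """Eigenvalue-based effective number of independent tests.

    Eigendecomposes the taxa-by-taxa covariance matrix of the samples x taxa
    matrix ``M`` and returns ``(sum lambda)^2 / sum lambda^2``, a value in
    ``[1, n_taxa]``.  With ``standardize`` (default) columns are Z-scored
    first, making the statistic scale-free (covariance == correlation).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 taxa")
    sd = M.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise DegenerateInputError("constant matrix; effective number undefined")
    if standardize:
        # constant columns carry no signal; drop them rather than divide by 0
        M = M[:, sd > 0]
        M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    cov = np.cov(M, rowvar=False)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    return float(lam.sum() ** 2 / (lam ** 2).sum())


# ---------------------------------------------------------------------------
# enterotyping


@dataclass
class EnterotypeAssignment:
    labels: pd.Series                 # sample id -> 1-based enterotype label
    k: int
    ch_scores: dict[int, float]       # candidate k -> Calinski-Harabasz index
    medoid_samples: list[str]


def jsd_distance_matrix(rel: pd.DataFrame) -> np.ndarray:
    """Pairwise square-root Jensen-Shannon divergence between sample compositions."""
    X = rel.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jensenshannon(X[i], X[j], base=2.0)
    return D


def assign_enterotypes(table: TaxonTable, k_candidates=range(2, 11),
                       ) -> EnterotypeAssignment:
    """Cluster samples on genus-level composition: JSD distance + PAM,
    with k chosen by the Calinski-Harabasz index.
    """
    from .disease import pam_cluster  # shared k-medoids engine

    rel = table.to_relative().data
    if rel.shape[0] < 3:
        raise ValidationError("enterotyping needs at least 3 samples")
    D = jsd_distance_matrix(rel)
    ids = list(rel.index)
    best = None
    ch_scores: dict[int, float] = {}
    X = rel.to_numpy(dtype=float)
    for k in k_candidates:
        if k >= len(ids):
            continue
        try:
            sol = pam_cluster(pd.DataFrame(D, index=ids, columns=ids), k)
        except ValidationError:   # k exceeds the number of distinct profiles
            continue
        labels = sol.labels.to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        ch = calinski_harabasz_score(X, labels)
        ch_scores[k] = ch
        if best is None or ch > best[0]:
            best = (ch, k, sol)
    if best is None:
        raise ValidationError("no candidate k produced a valid clustering")
    _, k_opt, sol = best
    labels = pd.Series(sol.labels.to_numpy() + 1, index=ids)
    return EnterotypeAssignment(labels=labels, k=k_opt, ch_scores=ch_scores,
                                medoid_samples=list(sol.medoids))
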