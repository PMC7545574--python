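"""Core in-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around numpy arrays / pandas frames:
the heavy lifting lives in the analysis modules, these classes only enforce
the structural invariants (non-negative abundances, dosages in [0, 2],
unique identifiers) that every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAXONOMIC_LEVELS = ("phylum", "class", "order", "family", "genus", "species")

#: Columns of a summary-statistics table, in canonical order.
SUMMARY_STAT_COLUMNS = [
    "variant_id", "chrom", "pos_bp", "pos_cm",
    "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n",
]

VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when a container's structural invariants are violated."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages[i, j]`` is the expected count of the effect allele of variant
    ``j`` carried by sample ``i``; values lie in [0, 2].  ``variants`` holds
    one row per variant with columns ``variant_id, chrom, pos_bp, pos_cm,
    effect_allele, other_allele, maf``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in genotype matrix")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r}")
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValidationError("dosages outside [0, 2]")
        # positions must be sorted within chromosome for windowed clumping
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing:
                raise ValidationError(f"positions not sorted on chrom {chrom}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def realized_maf(self) -> np.ndarray:
        """Allele frequency of the effect allele, folded to the minor side."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def index_of(self, variant_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["variant_id"])}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in genotype matrix") from exc

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants.copy(), self.dosages[idx])


@dataclass
class TaxonTable:
    """Samples x taxa table of counts or relative abundances.

    Taxon identifiers carry their taxonomic level as ``"level|name"``
    (e.g. ``"genus|g__Bacteroides"``); bare names default to genus.
    """

    data: pd.DataFrame  # index = sample ids, columns = taxon ids
    is_counts: bool = True

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in taxon table")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and vals.min() < 0:
            raise ValidationError("negative abundance values")
        if not self.is_counts and vals.size:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def levels(self) -> pd.Series:
        """Taxonomic level of each taxon, parsed from the ``level|name`` id."""
        def parse(tid: str) -> str:
            if "|" in tid:
                lvl = tid.split("|", 1)[0]
                if lvl in TAXONOMIC_LEVELS:
                    return lvl
            return "genus"
        return pd.Series([parse(t) for t in self.data.columns], index=self.data.columns)

    def to_relative(self) -> "TaxonTable":
        if not self.is_counts:
            return self
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return TaxonTable(self.data.div(totals, axis=0), is_counts=False)

    def prevalence(self) -> pd.Series:
        return (self.data > 0).mean(axis=0)


def validate_summary_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a per-variant summary-statistics table."""
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"summary stats missing columns {missing}")
    df = df[SUMMARY_STAT_COLUMNS].copy()
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].astype(str).isin(list(VALID_BASES))
        if bad.any():
            raise ValidationError(
                f"non-single-base {col} {df.loc[bad, col].iloc[0]!r} "
                f"for variant {df.loc[bad, 'variant_id'].iloc[0]!r}"
            )
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "variant_id"].iloc[0]
        raise ValidationError(f"non-positive SE for variant {bad!r}")
    return df


@dataclass
class HarmonizedInstruments:
    """Allele-aligned exposure/outcome effect pairs for two-sample MR."""

    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure: str = "exposure"
    outcome: str = "outcome"
    direction: str = "microbiome_to_trait"
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        k = len(self.variant_ids)
        for arr in (self.beta_exposure, self.se_exposure, self.beta_outcome, self.se_outcome):
            if arr.shape != (k,):
                raise ValidationError("instrument arrays must share length")
        if k < 1:
            raise ValidationError("at least one harmonized instrument required")

    @property
    def n_instruments(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: np.ndarray) -> "HarmonizedInstruments":
        keep = np.asarray(keep)
        return HarmonizedInstruments(
            [v for v, k in zip(self.variant_ids, keep) if k],
            self.beta_exposure[keep], self.se_exposure[keep],
            self.beta_outcome[keep], self.se_outcome[keep],
            self.exposure, self.outcome, self.direction,
        )


@dataclass
class ClusterSolution:
    """A k-medoids partition of a set of objects (features or samples)."""

    labels: pd.Series            # object id -> cluster label (0..k-1)
    medoids: list                # object ids of the k medoids
    objective: float             # sum of within-cluster dissimilarities to medoids
    silhouette: pd.Series | None = None   # per-object silhouette width
    avg_silhouette: float | None = None

    def __post_init__(self) -> None:
        k = len(self.medoids)
        if k < 1:
            raise ValidationError("cluster solution needs at least one medoid")
        counts = self.labels.value_counts()
        if len(counts) != k:
            raise ValidationError("every cluster must be non-empty")

    @property
    def k(self) -> int:
        return len(self.medoids)
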