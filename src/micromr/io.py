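"""File formats: plain-TSV-first readers/writers for every table the
pipeline exchanges, an optional VCF (DS dosage) route for genotypes, and
dataset-level loading with cross-file validation.

Every table written here carries a ``# provenance:`` comment line (config
hash, seed, stage) and round-trips losslessly through the matching reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (GenotypeMatrix, TaxonTable, ValidationError,
                         validate_summary_stats)


def provenance_line(**kv) -> str:
    parts = " ".join(f"{k}={v}" for k, v in sorted(kv.items()))
    return f"# provenance: {parts}"


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, index_label, provenance: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# taxon / pathway / covariate tables


def write_taxon_table(table: TaxonTable, path, provenance: str | None = None) -> None:
    _write_tsv(table.data, path, "sample_id", provenance)


def read_taxon_table(path, is_counts: bool = True, taxa_as_rows: bool = False
                     ) -> TaxonTable:
    """Read a taxon TSV (samples as rows; ``taxa_as_rows`` accepts the
    BIOM-style transposed orientation)."""
    df = _read_tsv(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated sample id {dup!r}")
    if taxa_as_rows:
        df = df.T
    df.index.name = None
    df.columns.name = None
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValidationError(f"{path}: non-numeric column {bad[0]!r}")
    return TaxonTable(df, is_counts=is_counts)


def write_frame(df: pd.DataFrame, path, provenance: str | None = None,
                index_label: str = "sample_id") -> None:
    _write_tsv(df, path, index_label, provenance)


def read_frame(path) -> pd.DataFrame:
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# summary statistics


def write_summary_stats(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    df = validate_summary_stats(df)
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "variant_id": str})
    return validate_summary_stats(df)


# ---------------------------------------------------------------------------
# genotypes: TSV pair and VCF with DS


def write_genotypes_tsv(G: GenotypeMatrix, dosage_path, variant_path,
                        provenance: str | None = None) -> None:
    dos = pd.DataFrame(G.dosages, index=G.sample_ids,
                       columns=G.variants["variant_id"])
    _write_tsv(dos, dosage_path, "sample_id", provenance)
    _write_tsv(G.variants.set_index("variant_id"), variant_path, "variant_id",
               provenance)


def read_genotypes_tsv(dosage_path, variant_path) -> GenotypeMatrix:
    dos = _read_tsv(dosage_path)
    var = _read_tsv(variant_path).reset_index()
    if list(dos.columns) != list(var["variant_id"]):
        raise ValidationError("dosage columns do not match variant metadata order")
    var["chrom"] = var["chrom"].astype(str)
    return GenotypeMatrix(list(dos.index.astype(str)), var,
                          dos.to_numpy(dtype=float))


def write_genotypes_vcf(G: GenotypeMatrix, path, provenance: str | None = None) -> None:
    """Plain-text VCF with a per-sample DS (dosage) FORMAT field."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if provenance:
            fh.write(f"##{provenance.lstrip('# ')}\n")
        chroms = pd.unique(G.variants["chrom"].astype(str))
        for c in chroms:
            mx = int(G.variants.loc[G.variants["chrom"].astype(str) == c, "pos_bp"].max())
            fh.write(f"##contig=<ID={c},length={mx + 1000}>\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j, row in G.variants.iterrows():
            ds = "\t".join(f"{d:g}" for d in G.dosages[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos_bp'])}\t{row['variant_id']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t"
                     f"CM={row['pos_cm']:.6f}\tDS\t" + ds + "\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a DS-dosage VCF (cyvcf2 when available, text fallback)."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    v = VCF(str(path))
    samples = list(v.samples)
    rows, dosages = [], []
    for rec in v:
        ds = rec.format("DS")
        if ds is None:
            raise ValidationError(f"{path}: record {rec.ID} lacks DS field")
        cm = rec.INFO.get("CM")
        rows.append({"variant_id": rec.ID, "chrom": str(rec.CHROM),
                     "pos_bp": rec.POS,
                     "pos_cm": float(cm) if cm is not None else np.nan,
                     "effect_allele": rec.ALT[0], "other_allele": rec.REF})
        dosages.append(np.asarray(ds, dtype=float).ravel())
    var = pd.DataFrame(rows)
    dos = np.column_stack(dosages) if dosages else np.zeros((len(samples), 0))
    var["maf"] = np.minimum(dos.mean(axis=0) / 2.0, 1 - dos.mean(axis=0) / 2.0) \
        if len(var) else []
    return GenotypeMatrix(samples, var, dos)


def _read_vcf_text(path) -> GenotypeMatrix:
    samples, rows, dosages = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            info = dict(kv.split("=") for kv in f[7].split(";") if "=" in kv)
            fmt = f[8].split(":")
            di = fmt.index("DS")
            rows.append({"variant_id": f[2], "chrom": f[0], "pos_bp": int(f[1]),
                         "pos_cm": float(info.get("CM", "nan")),
                         "effect_allele": f[4], "other_allele": f[3]})
            dosages.append([float(s.split(":")[di]) for s in f[9:]])
    var = pd.DataFrame(rows)
    dos = np.array(dosages).T if dosages else np.zeros((len(samples), 0))
    var["maf"] = np.minimum(dos.mean(axis=0) / 2.0, 1 - dos.mean(axis=0) / 2.0) \
        if len(var) else []
    return GenotypeMatrix(samples, var, dos)


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort(bundle, out_dir, seed=None) -> dict[str, str]:
    """Write a full synthetic cohort in the pipeline dialects; returns the
    path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = provenance_line(stage="simulate", seed=seed if seed is not None else "NA",
                           config=config_hash(str(sorted(bundle.ground_truth.true_h2))))
    paths = {
        "dosages": out / "genotypes.tsv", "variants": out / "variants.tsv",
        "vcf": out / "genotypes.vcf", "taxa": out / "taxa.tsv",
        "covariates": out / "covariates.tsv", "phenotypes": out / "phenotypes.tsv",
        "outcome_stats": out / "outcome_stats.tsv", "pathways": out / "pathways.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_genotypes_tsv(bundle.genotypes, paths["dosages"], paths["variants"], prov)
    write_genotypes_vcf(bundle.genotypes, paths["vcf"], prov)
    write_taxon_table(bundle.taxa, paths["taxa"], prov)
    write_frame(bundle.covariates, paths["covariates"], prov)
    write_frame(pd.DataFrame({"disease": bundle.disease,
                              "liability": bundle.disease_liability}),
                paths["phenotypes"], prov)
    write_summary_stats(bundle.outcome_stats, paths["outcome_stats"], prov)
    write_frame(bundle.pathways, paths["pathways"], prov)
    with open(paths["ground_truth"], "w") as fh:
        fh.write(bundle.ground_truth.to_json())
    return {k: str(v) for k, v in paths.items()}


def load_dataset(paths: dict) -> dict:
    """Load and cross-validate a dataset directory.

    ``paths`` maps the keys produced by :func:`write_cohort` to file paths;
    any subset may be present.  Sample ids must agree across files; the
    returned dict carries the loaded objects plus a ``report`` of warnings.
    """
    out: dict = {"report": []}
    if "dosages" in paths:
        out["genotypes"] = read_genotypes_tsv(paths["dosages"], paths["variants"])
    elif "vcf" in paths:
        out["genotypes"] = read_genotypes_vcf(paths["vcf"])
    if "taxa" in paths:
        out["taxa"] = read_taxon_table(paths["taxa"])
    if "covariates" in paths:
        out["covariates"] = read_frame(paths["covariates"])
    if "phenotypes" in paths:
        out["phenotypes"] = read_frame(paths["phenotypes"])
    if "outcome_stats" in paths:
        out["outcome_stats"] = read_summary_stats(paths["outcome_stats"])
    if "pathways" in paths:
        out["pathways"] = read_frame(paths["pathways"])

    id_sets = {}
    if "genotypes" in out:
        id_sets["genotypes"] = list(out["genotypes"].sample_ids)
    if "taxa" in out:
        id_sets["taxa"] = list(out["taxa"].sample_ids)
    for key in ("covariates", "phenotypes", "pathways"):
        if key in out:
            id_sets[key] = list(out[key].index.astype(str))
    if id_sets:
        ref_key, ref = next(iter(id_sets.items()))
        for key, ids in id_sets.items():
            if set(ids) != set(ref):
                raise ValidationError(
                    f"sample ids in {key} do not match {ref_key}")
            if ids != ref:
                out["report"].append(f"{key}: sample order differs; reordered")
    return out
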