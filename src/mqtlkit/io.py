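"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: genotypes as HapMap-dialect TSV (or VCF v4.2 via
cyvcf2 when available), LC-MS feature tables and metabolite matrices as TSV,
gene models as GFF3, known QTLs as BED, pathway sets as GMT, phenotypes as
long-format TSV. Every writer can emit a sidecar JSON recording the seed and
parameters that produced the file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

from .containers import (
    ExpressionMatrix,
    FeatureTable,
    GeneModelSet,
    GenotypeMatrix,
    MetaboliteMatrix,
    PhenotypeTable,
)

# dosage -> HapMap genotype string; 1 renders as het (ref/alt)
_HAPMAP_MISSING = "NN"


def write_sidecar(path: str | Path, seed: int | None, params: Mapping) -> Path:
    """Write ``<path>.json`` recording provenance for the file at ``path``."""
    side = Path(str(path) + ".json")
    payload = {"file": Path(path).name, "seed": seed, "params": dict(params)}
    side.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return side


# ---------------------------------------------------------------------------
# genotypes: HapMap-dialect TSV
# ---------------------------------------------------------------------------

def write_hapmap(genotypes: GenotypeMatrix, path: str | Path,
                 seed: int | None = None, **params) -> Path:
    """HapMap-dialect TSV: rs, alleles, chrom, pos, then one column per line.

    Dosage encoding: 0 -> ref/ref, 1 -> ref/alt, 2 -> alt/alt, missing -> NN,
    written as two-letter genotype strings (e.g. ``AT``).
    """
    path = Path(path)
    var = genotypes.variants
    dose = genotypes.dosages.to_numpy(dtype=float).T  # snps x lines
    ref = var["ref"].to_numpy()
    alt = var["alt"].to_numpy()
    rows = []
    for j, snp in enumerate(var.index):
        calls = []
        for d in dose[j]:
            if np.isnan(d):
                calls.append(_HAPMAP_MISSING)
            elif d == 0:
                calls.append(ref[j] + ref[j])
            elif d == 1:
                calls.append(ref[j] + alt[j])
            else:
                calls.append(alt[j] + alt[j])
        rows.append([snp, f"{ref[j]}/{alt[j]}", var["chrom"].iloc[j],
                     int(var["pos"].iloc[j])] + calls)
    out = pd.DataFrame(rows, columns=["rs", "alleles", "chrom", "pos"] + genotypes.line_ids)
    out.to_csv(path, sep="\t", index=False)
    write_sidecar(path, seed, params)
    return path


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["rs", "alleles", "chrom", "pos"]]
    lines = [c for c in df.columns if c not in ("rs", "alleles", "chrom", "pos")]
    ref = meta["alleles"].str.split("/").str[0].to_numpy()
    alt = meta["alleles"].str.split("/").str[1].to_numpy()
    calls = df[lines].to_numpy(dtype=str)
    dose = np.full(calls.shape, np.nan)
    for j in range(calls.shape[0]):
        dose[j] = [np.nan if c == _HAPMAP_MISSING
                   else (c.count(alt[j]) if ref[j] != alt[j] else 0.0)
                   for c in calls[j]]
    dosages = pd.DataFrame(dose.T, index=lines, columns=meta["rs"])
    dosages.columns.name = None
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(dose, axis=1) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)
    variants = pd.DataFrame(
        {"chrom": meta["chrom"].to_numpy(), "pos": meta["pos"].to_numpy(),
         "ref": ref, "alt": alt, "maf": maf},
        index=pd.Index(meta["rs"], name=None))
    return GenotypeMatrix(dosages, variants)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF v4.2 file (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is normally present
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path))
    lines = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            continue
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
    dose = np.array(rows)
    dosages = pd.DataFrame(dose.T, index=lines, columns=ids)
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(dose, axis=1) / 2.0
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
         "maf": np.minimum(p_alt, 1 - p_alt)}, index=ids)
    return GenotypeMatrix(dosages, variants)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path,
              seed: int | None = None, **params) -> Path:
    """Minimal VCF v4.2 writer (GT-only, unphased)."""
    path = Path(path)
    var = genotypes.variants
    dose = genotypes.dosages.to_numpy(dtype=float).T
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.line_ids) + "\n")
        for j, snp in enumerate(var.index):
            calls = ["./." if np.isnan(d) else gt_map[float(d)] for d in dose[j]]
            fh.write("\t".join([str(var['chrom'].iloc[j]), str(int(var['pos'].iloc[j])),
                                str(snp), str(var['ref'].iloc[j]), str(var['alt'].iloc[j]),
                                ".", "PASS", ".", "GT"] + calls) + "\n")
    write_sidecar(path, seed, params)
    return path


# ---------------------------------------------------------------------------
# feature tables and metabolite matrices
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path,
                        seed: int | None = None, **params) -> Path:
    path = Path(path)
    out = pd.concat(
        [table.meta[["mz", "rt", "mode"]].rename(columns={"rt": "rt_min"}),
         table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    write_sidecar(path, seed, dict(params, condition=table.condition))
    return path


def read_feature_table(path: str | Path, condition: str) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    df.index.name = None
    meta = df[["mz", "rt_min", "mode"]].rename(columns={"rt_min": "rt"})
    intensities = df.drop(columns=["mz", "rt_min", "mode"])
    return FeatureTable(meta=meta, intensities=intensities, condition=condition)


def write_metabolite_matrix(matrix: MetaboliteMatrix, path: str | Path,
                            seed: int | None = None, **params) -> Path:
    """TSV (lines x metabolites) plus companion ``<path>.groups.json``."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "line"
    out.to_csv(path, sep="\t")
    groups = Path(str(path) + ".groups.json")
    groups.write_text(json.dumps(
        {"condition": matrix.condition, "log_transformed": matrix.log_transformed,
         "group_map": matrix.group_map}, indent=2) + "\n")
    write_sidecar(path, seed, dict(params, condition=matrix.condition))
    return path


def read_metabolite_matrix(path: str | Path, condition: str | None = None) -> MetaboliteMatrix:
    values = pd.read_csv(path, sep="\t", index_col="line")
    values.index.name = None
    groups = Path(str(path) + ".groups.json")
    group_map: dict[str, list[str]] = {}
    log_transformed = False
    if groups.exists():
        payload = json.loads(groups.read_text())
        group_map = payload.get("group_map", {})
        log_transformed = bool(payload.get("log_transformed", False))
        condition = condition or payload.get("condition")
    if condition is None:
        raise ValueError("condition not given and no companion groups JSON found")
    return MetaboliteMatrix(values=values, condition=condition,
                            group_map=group_map, log_transformed=log_transformed)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     seed: int | None = None, **params) -> Path:
    """Genes x lines TSV, the conventional orientation for expression files."""
    path = Path(path)
    out = expr.values.T.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    write_sidecar(path, seed, dict(params, condition=expr.condition))
    return path


def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None
    return ExpressionMatrix(values=df.T, condition=condition)


# ---------------------------------------------------------------------------
# gene models (GFF3), known QTLs (BED), pathways (GMT), phenotypes
# ---------------------------------------------------------------------------

def write_gff3(genes: GeneModelSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in genes.genes.iterrows():
            strand = row.get("strand", "+")
            fh.write(f"{row['chrom']}\tmqtlkit\tgene\t{int(row['start'])}\t"
                     f"{int(row['end'])}\t.\t{strand}\t.\tID={gid}\n")
    return path


def read_gff3(path: str | Path, feature_type: str = "gene") -> GeneModelSet:
    """Read gene spans from GFF3 (1-based inclusive coordinates)."""
    try:
        df = pr.read_gff3(str(path), as_df=True)
    except Exception as exc:
        raise ValueError(f"malformed GFF3 file {path}: {exc}") from exc
    df = df[df["Feature"] == feature_type]
    if "ID" not in df.columns:
        raise ValueError(f"GFF3 {path}: gene records lack ID attributes")
    # pyranges converts to 0-based half-open; convert back to 1-based closed
    genes = pd.DataFrame({
        "chrom": df["Chromosome"].astype(str).to_numpy(),
        "start": df["Start"].to_numpy() + 1,
        "end": df["End"].to_numpy(),
        "strand": df.get("Strand", pd.Series(["+"] * len(df))).to_numpy(),
    }, index=pd.Index(df["ID"], name=None))
    return GeneModelSet(genes=genes)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ intervals, returned 1-based closed (chrom, start, end, name)."""
    df = pr.read_bed(str(path), as_df=True)
    out = pd.DataFrame({
        "chrom": df["Chromosome"].astype(str).to_numpy(),
        "start": df["Start"].to_numpy() + 1,  # 0-based half-open -> 1-based closed
        "end": df["End"].to_numpy(),
    })
    if "Name" in df.columns:
        out["name"] = df["Name"].to_numpy()
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT pathway sets: name <tab> description <tab> gene ids..."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs >= 3 fields: {line[:60]!r}")
        pathways[parts[0]] = set(parts[2:])
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")
    return path


def write_phenotypes(pheno: PhenotypeTable, path: str | Path,
                     seed: int | None = None, **params) -> Path:
    path = Path(path)
    pheno.table.to_csv(path, sep="\t", index=False)
    write_sidecar(path, seed, params)
    return path


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(table=pd.read_csv(path, sep="\t"))
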