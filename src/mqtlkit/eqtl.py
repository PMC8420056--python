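"""Expression QTL mapping and cis/trans, shared/dynamic classification.

Reuses the mixed-model association engine on log2(x+1) expression traits.
Significant SNPs are merged per gene with the same 10-kb single-linkage
rule as mQTLs; a locus is *cis* when its lead SNP lies within 20 kb up- or
downstream of the gene span (gene orientation is ignored), *trans*
otherwise; a locus is *shared* when the same gene has an overlapping
significant locus in the other growth condition, else *dynamic*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneModelSet, GenotypeMatrix
from .gwas import cluster_mqtl, prepare_scan, mlm_scan


@dataclass
class EQTLRecord:
    """One significant expression locus for one gene under one condition."""

    gene_id: str
    lead_snp: str
    chrom: str
    pos: int
    start: int          # merged locus span (bp, 1-based closed)
    end: int
    p: float
    condition: str
    kind: str = ""      # cis | trans
    sharing: str = ""   # shared | dynamic


def classify_cis_trans(record: EQTLRecord, gene_models: GeneModelSet,
                       window: int = 20_000) -> str:
    """cis iff the lead SNP lies within [start - window, end + window] of its gene."""
    chrom, start, end = gene_models.span(record.gene_id)
    if record.chrom != chrom:
        return "trans"
    return "cis" if start - window <= record.pos <= end + window else "trans"


def eqtl_scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    K: pd.DataFrame | np.ndarray,
    threshold: float = 4.2e-8,
    n_pc: int = 5,
    gap: int = 10_000,
    gene_models: GeneModelSet | None = None,
    cis_window: int = 20_000,
    log_transform: bool = True,
) -> list[EQTLRecord]:
    """Mixed-model scan of every expression trait; one record per locus.

    Expression is log2(x+1)-transformed before scanning unless
    ``log_transform`` is False. Zero-variance genes are skipped with a
    warning. When ``gene_models`` is given, records are labeled cis/trans.
    """
    sc = prepare_scan(genotypes, K, n_pc)
    vals = expression.values
    if log_transform:
        vals = np.log2(vals + 1.0)
    records: list[EQTLRecord] = []
    for gene in vals.columns:
        y = vals[gene].reindex(sc.line_ids)
        if float(y.std()) == 0.0:
            warnings.warn(f"gene {gene!r} has zero-variance expression; skipped")
            continue
        res = mlm_scan(genotypes, y, K, n_pc, scan_context=sc,
                       trait_name=gene, condition=expression.condition)
        sig = res[res["p"] <= threshold].reset_index(names="snp")
        if sig.empty:
            continue
        for locus in cluster_mqtl(sig, gap=gap):
            rec = EQTLRecord(
                gene_id=gene, lead_snp=locus.peak_snp, chrom=locus.chrom,
                pos=int(sig.set_index("snp").loc[locus.peak_snp, "pos"]),
                start=locus.start, end=locus.end, p=locus.peak_p,
                condition=expression.condition)
            if gene_models is not None:
                rec.kind = classify_cis_trans(rec, gene_models, cis_window)
            records.append(rec)
    return records


def classify_sharing(records_ww: list[EQTLRecord],
                     records_ds: list[EQTLRecord]) -> None:
    """Label every record shared/dynamic in place.

    A locus is shared iff the same gene has a significant locus in the
    other condition whose merged interval overlaps by >= 1 bp on the same
    chromosome.
    """
    def index(records: list[EQTLRecord]) -> dict[str, list[EQTLRecord]]:
        d: dict[str, list[EQTLRecord]] = {}
        for r in records:
            d.setdefault(r.gene_id, []).append(r)
        return d

    by_ww, by_ds = index(records_ww), index(records_ds)
    for records, other in ((records_ww, by_ds), (records_ds, by_ww)):
        for r in records:
            mates = other.get(r.gene_id, [])
            r.sharing = "shared" if any(
                m.chrom == r.chrom and m.start <= r.end and m.end >= r.start
                for m in mates) else "dynamic"


def records_to_frame(records: list[EQTLRecord]) -> pd.DataFrame:
    rows = [{"gene_id": r.gene_id, "lead_snp": r.lead_snp, "chrom": r.chrom,
             "pos": r.pos, "start": r.start, "end": r.end, "p": r.p,
             "condition": r.condition, "kind": r.kind, "sharing": r.sharing}
            for r in records]
    return pd.DataFrame(rows, columns=["gene_id", "lead_snp", "chrom", "pos",
                                       "start", "end", "p", "condition",
                                       "kind", "sharing"])
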