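"""Structure- and kinship-corrected single-marker association scans.

The scan follows the P3D/EMMAX strategy used by the standard mixed-model
GWAS tools: the polygenic variance components are estimated once per trait
by REML under the null model (intercept + genotype principal components as
fixed effects, VanRaden kinship as the random-effect covariance), and each
SNP is then tested by generalized least squares at the fixed variance
ratio. Significant SNPs are merged into metabolite QTLs (mQTLs) by a
single-linkage 10-kb rule, and candidate genes are assigned when a member
significant SNP falls inside the gene body.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixed import MixedModelContext, gls_marker_scan
from .containers import GeneModelSet, GenotypeMatrix


# ---------------------------------------------------------------------------
# kinship and structure
# ---------------------------------------------------------------------------

def kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden centered kinship K = WW' / (2 sum p(1-p)), W = dosage - 2p.

    Missing dosages are mean-imputed per SNP (which zeroes their centered
    contribution). Monomorphic-only input is an error.
    """
    M = genotypes.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(M, axis=0)
    M = np.where(np.isnan(M), col_mean, M)
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; kinship undefined")
    W = M[:, poly] - 2 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    K = W @ W.T / denom
    return pd.DataFrame(K, index=genotypes.line_ids, columns=genotypes.line_ids)


def genotype_pcs(genotypes: GenotypeMatrix, n_pc: int = 5) -> pd.DataFrame:
    """Top principal components of the centered dosage matrix (structure Q)."""
    M = genotypes.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(M, axis=0)
    M = np.where(np.isnan(M), col_mean, M) - col_mean
    n_pc = min(n_pc, min(M.shape) - 1)
    if n_pc <= 0:
        return pd.DataFrame(index=genotypes.line_ids)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    return pd.DataFrame(U[:, :n_pc] * s[:n_pc], index=genotypes.line_ids,
                        columns=[f"PC{i + 1}" for i in range(n_pc)])


# ---------------------------------------------------------------------------
# the mixed-model scan
# ---------------------------------------------------------------------------

@dataclass
class ScanContext:
    """Precomputed quantities reused across traits sharing genotypes/K/PCs."""

    genotypes: GenotypeMatrix
    K: np.ndarray
    X0: np.ndarray
    ctx: MixedModelContext
    G: np.ndarray           # mean-imputed dosages, lines x snps
    G_rot: np.ndarray       # U' G, rotated once
    X0_rot: np.ndarray
    snp_ok: np.ndarray      # polymorphic mask
    line_ids: list[str] = field(default_factory=list)


def prepare_scan(genotypes: GenotypeMatrix, K: pd.DataFrame | np.ndarray,
                 n_pc: int = 5) -> ScanContext:
    """Build the shared scan context (eigendecompositions, rotated dosages)."""
    if isinstance(K, pd.DataFrame):
        K = K.loc[genotypes.line_ids, genotypes.line_ids].to_numpy(dtype=float)
    M = genotypes.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(M, axis=0)
    G = np.where(np.isnan(M), col_mean, M)
    snp_ok = G.std(axis=0) > 1e-12
    pcs = genotype_pcs(genotypes, n_pc).to_numpy(dtype=float)
    X0 = np.column_stack([np.ones(G.shape[0]), pcs])
    ctx = MixedModelContext(K, X0)
    return ScanContext(genotypes=genotypes, K=K, X0=X0, ctx=ctx, G=G,
                       G_rot=ctx.rotate(G), X0_rot=ctx.rotate(X0),
                       snp_ok=snp_ok, line_ids=genotypes.line_ids)


def mlm_scan(
    genotypes: GenotypeMatrix,
    trait: pd.Series,
    K: pd.DataFrame | np.ndarray,
    n_pc: int = 5,
    scan_context: ScanContext | None = None,
    trait_name: str = "trait",
    condition: str | None = None,
) -> pd.DataFrame:
    """Single-trait mixed-model association scan (P3D).

    Returns one row per tested SNP: beta, se, p (two-sided Wald t),
    pve (squared standardized effect on the whitened scale), plus
    chrom/pos. SNPs monomorphic in the analyzed lines are skipped and
    recorded with ``tested = False``.
    """
    sc = scan_context if scan_context is not None else prepare_scan(genotypes, K, n_pc)
    y = trait.reindex(sc.line_ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait has missing values for analyzed lines")
    if y.std() == 0:
        raise ValueError("trait is constant; nothing to map")
    delta, sg2, se2 = sc.ctx.reml(y)
    scale = 1.0 / np.sqrt(sc.ctx.d + delta)
    U = sc.ctx.U
    y_star = U @ (scale * (U.T @ y))
    X_star = U @ (scale[:, None] * sc.X0_rot)
    G_star = U @ (scale[:, None] * sc.G_rot)
    res = gls_marker_scan(y_star, X_star, G_star)
    var = sc.genotypes.variants
    out = pd.DataFrame({
        "chrom": var["chrom"].to_numpy(), "pos": var["pos"].to_numpy(),
        "beta": res["beta"], "se": res["se"], "p": res["p"],
        "pve": res["pve"],
        "tested": res["tested"] & sc.snp_ok,
    }, index=var.index)
    out.loc[~out["tested"], ["beta", "se", "p", "pve"]] = np.nan
    out["trait"] = trait_name
    if condition is not None:
        out["condition"] = condition
    out.attrs["variance_components"] = {"delta": delta, "sg2": sg2, "se2": se2}
    return out


def scan_traits(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    K: pd.DataFrame | np.ndarray,
    n_pc: int = 5,
    condition: str | None = None,
    p_keep: float | None = None,
) -> pd.DataFrame:
    """Scan many traits (columns of ``traits``) against the same genotypes.

    The kinship eigendecomposition and dosage rotation are shared across
    traits. With ``p_keep`` set, only rows with p <= p_keep are retained
    (plus the per-trait variance components in ``attrs``), keeping the
    result small for thousands of traits.
    """
    sc = prepare_scan(genotypes, K, n_pc)
    frames = []
    for name in traits.columns:
        y = traits[name].dropna()
        if y.std() == 0:
            warnings.warn(f"trait {name!r} constant; skipped")
            continue
        if len(y) < len(sc.line_ids):
            # subset of lines: fall back to a trait-specific context
            sub = genotypes.dosages.index.intersection(y.index)
            sub_geno = GenotypeMatrix(genotypes.dosages.loc[sub],
                                      genotypes.variants)
            res = mlm_scan(sub_geno, y, kinship(sub_geno), n_pc,
                           trait_name=name, condition=condition)
        else:
            res = mlm_scan(genotypes, y, K, n_pc, scan_context=sc,
                           trait_name=name, condition=condition)
        res = res.reset_index(names="snp")
        if p_keep is not None:
            res = res[res["p"] <= p_keep]
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["snp", "chrom", "pos", "beta", "se",
                                     "p", "pve", "tested", "trait"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def suggestive_threshold(meff: int | float) -> float:
    """Suggestive genome-wide p threshold 1/Meff."""
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return 1.0 / meff


def effective_marker_count(genotypes: GenotypeMatrix, window: int = 200,
                           var_explained: float = 0.995) -> int:
    """simpleM-style effective number of independent markers.

    Per chromosome, SNPs are processed in windows of ``window`` markers;
    each window contributes the smallest k whose top-k correlation-matrix
    eigenvalues reach ``var_explained`` of the trace. The total is bounded
    by the SNP count below and the chromosome count above zero.
    """
    M = genotypes.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(M, axis=0)
    M = np.where(np.isnan(M), col_mean, M)
    chrom_arr = genotypes.variants["chrom"].to_numpy()
    total = 0
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        for start in range(0, len(idx), window):
            block = M[:, idx[start:start + window]]
            sd = block.std(axis=0)
            block = block[:, sd > 0]
            if block.shape[1] == 0:
                continue
            R = np.corrcoef(block, rowvar=False)
            if R.ndim == 0:
                total += 1
                continue
            ev = np.sort(np.linalg.eigvalsh(R))[::-1]
            cum = np.cumsum(ev) / np.sum(ev)
            total += int(np.searchsorted(cum, var_explained) + 1)
    return total


# ---------------------------------------------------------------------------
# mQTL clustering and annotation
# ---------------------------------------------------------------------------

@dataclass
class MQTL:
    """A merged locus of significant SNPs for one or more metabolite traits."""

    chrom: str
    start: int
    end: int
    peak_snp: str
    peak_p: float
    member_snps: list[str]
    traits: list[str]
    conditions: list[str]
    candidate_genes: list[str] = field(default_factory=list)
    known_overlap: bool | None = None


def cluster_mqtl(significant: pd.DataFrame, gap: int = 10_000) -> list[MQTL]:
    """Merge significant SNPs into mQTLs by the single-linkage < ``gap`` rule.

    ``significant`` needs columns snp, chrom, pos, p, trait (condition
    optional). Consecutive position-sorted SNPs on a chromosome join the
    same cluster iff their gap is strictly less than ``gap`` bp; clusters
    never span chromosomes. The peak SNP has the smallest p (ties broken by
    smaller position).
    """
    if significant.empty:
        return []
    out: list[MQTL] = []
    uniq = (significant.groupby(["chrom", "pos", "snp"], sort=True)
            .agg(p=("p", "min")).reset_index())
    for chrom, sub in uniq.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap)
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = sub.iloc[a:b]
            members = list(chunk["snp"])
            rows = significant[significant["snp"].isin(members)]
            peak = chunk.sort_values(["p", "pos"]).iloc[0]
            out.append(MQTL(
                chrom=str(chrom), start=int(chunk["pos"].min()),
                end=int(chunk["pos"].max()), peak_snp=str(peak["snp"]),
                peak_p=float(peak["p"]), member_snps=members,
                traits=sorted(rows["trait"].unique()) if "trait" in rows else [],
                conditions=sorted(rows["condition"].unique())
                if "condition" in rows.columns else [],
            ))
    return out


def assign_candidate_genes(mqtls: list[MQTL], genes: GeneModelSet,
                           significant: pd.DataFrame | None = None) -> list[MQTL]:
    """Fill candidate_genes: genes containing >= 1 member significant SNP.

    Membership is 1-based inclusive on the gene span. ``significant``
    supplies member SNP positions; when omitted, positions are parsed from
    the mQTL member list against the gene table's coordinate space is not
    possible, so ``significant`` is required whenever members are not
    position-named.
    """
    gdf = genes.genes
    pos_of: dict[str, tuple[str, int]] = {}
    if significant is not None:
        for _, row in significant.drop_duplicates("snp").iterrows():
            pos_of[str(row["snp"])] = (str(row["chrom"]), int(row["pos"]))
    for q in mqtls:
        hits: set[str] = set()
        on_chrom = gdf[gdf["chrom"] == q.chrom]
        for snp in q.member_snps:
            chrom, pos = pos_of.get(snp, (q.chrom, None))
            if pos is None:
                continue
            inside = on_chrom[(on_chrom["start"] <= pos) & (pos <= on_chrom["end"])]
            hits.update(inside.index)
        q.candidate_genes = sorted(hits)
    return mqtls


def qtl_overlap(mqtls: list[MQTL], known: pd.DataFrame) -> tuple[pd.Series, float]:
    """Co-localization of each mQTL with known QTL intervals (>= 1 bp overlap).

    ``known`` is 1-based closed (chrom, start, end), e.g. from
    :func:`mqtlkit.io.read_bed`. Returns the per-mQTL boolean series (index
    = ``chrom:start-end``) and the overlapping fraction.
    """
    flags = {}
    for q in mqtls:
        sub = known[known["chrom"].astype(str) == q.chrom]
        hit = bool(((sub["start"] <= q.end) & (sub["end"] >= q.start)).any())
        flags[f"{q.chrom}:{q.start}-{q.end}"] = hit
        q.known_overlap = hit
    ser = pd.Series(flags, dtype=bool)
    frac = float(ser.mean()) if len(ser) else math.nan
    return ser, frac


def mqtls_to_frame(mqtls: list[MQTL]) -> pd.DataFrame:
    """Flatten MQTL records to a DataFrame for TSV export."""
    rows = []
    for q in mqtls:
        rows.append({
            "chrom": q.chrom, "start": q.start, "end": q.end,
            "peak_snp": q.peak_snp, "peak_p": q.peak_p,
            "n_snps": len(q.member_snps),
            "member_snps": ",".join(q.member_snps),
            "traits": ",".join(q.traits),
            "conditions": ",".join(q.conditions),
            "candidate_genes": ",".join(q.candidate_genes),
            "known_overlap": q.known_overlap,
        })
    return pd.DataFrame(rows)
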