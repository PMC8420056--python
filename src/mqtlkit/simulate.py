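"""Synthetic genotypes, metabolomes, expression and phenotypes with ground truth.

Every generator draws from its own ``numpy.random.default_rng(seed)`` so
identical inputs plus seed give byte-identical outputs, and emits a
:class:`~mqtlkit.containers.SyntheticTruth` recording exactly which signals
were injected, so every downstream stage has a recoverable answer.

The genotype generator follows a Balding-Nichols-style divergence model:
subpopulation allele frequencies are drawn around a shared ancestral
frequency with divergence Fst, which creates both the population structure
(Q) and the kinship (K) confounding that the mixed-model scan must correct.
Linkage disequilibrium comes from an autoregressive latent process along
each haplotype that resets at block boundaries, so |r| decays with distance
within a block and blocks are independent.

Metabolite intensities are log-normal: the field does not agree on a noise
model for LC-MS intensities and log-normal is the standard working
assumption; all injected effects (SNP dosage effects scaled to a target
PVE, drought shifts in log2 units) act on the log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    FeatureTable,
    GeneModelSet,
    GenotypeMatrix,
    MetaboliteMatrix,
    PhenotypeTable,
    SyntheticTruth,
)

_BASES = np.array(list("ACGT"))


def _line_ids(n_lines: int, subpop: np.ndarray) -> list[str]:
    # subpopulation is encoded in the line id (P<k>_L<i>) so downstream
    # structure checks need no side channel
    return [f"P{s + 1}_L{i:04d}" for i, s in enumerate(subpop)]


def line_subpopulations(line_ids: list[str]) -> np.ndarray:
    """Recover subpopulation labels encoded in generated line ids."""
    return np.array([int(l.split("_")[0][1:]) for l in line_ids])


def generate_genotypes(
    n_lines: int,
    n_snps: int,
    n_subpops: int = 3,
    ld_block_len: int = 20_000,
    maf_min: float = 0.05,
    seed: int = 0,
    fst: float = 0.15,
    n_chromosomes: int = 10,
    mean_spacing: int = 2_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Structured biallelic dosages with LD blocks and subpopulations.

    Returns the genotype matrix (SNPs failing the realized-MAF filter are
    dropped, so the emitted SNP count can be below ``n_snps``) and its
    variant table. Lines are fully inbred in spirit but heterozygotes occur;
    dosages are haplotype sums in {0,1,2}.

    Parameters
    ----------
    ld_block_len
        Block length in bp; latent haplotype correlation decays as
        ``exp(-d / (ld_block_len / 2))`` within a block and is zero across
        block boundaries. ``ld_block_len=1`` makes every SNP independent.
    fst
        Balding-Nichols divergence of subpopulation allele frequencies.
    """
    if n_lines < 10:
        raise ValueError("n_lines must be >= 10")
    if n_snps < 1 or n_subpops < 1 or ld_block_len < 1:
        raise ValueError("n_snps, n_subpops and ld_block_len must be positive")
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)

    # positions on n_chromosomes chromosomes, strictly increasing
    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    chroms, positions, block_ids = [], [], []
    block_counter = 0
    for c in range(n_chromosomes):
        gaps = rng.integers(max(1, mean_spacing // 4), mean_spacing * 2,
                            size=per_chrom[c])
        pos = np.cumsum(gaps)
        chroms.extend([f"chr{c + 1}"] * per_chrom[c])
        positions.extend(pos.tolist())
        block_ids.extend((block_counter + pos // ld_block_len).tolist())
        block_counter = (block_ids[-1] + 1) if per_chrom[c] else block_counter
    positions = np.asarray(positions)
    block_ids = np.asarray(block_ids)

    # ancestral and subpopulation allele frequencies (Balding-Nichols beta)
    p0 = rng.uniform(0.1, 0.9, size=n_snps)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    p_sub = rng.beta(a, b, size=(n_subpops, n_snps))
    p_sub = np.clip(p_sub, 0.01, 0.99)

    subpop = np.sort(rng.integers(0, n_subpops, size=n_lines))
    n_hap = 2 * n_lines
    hap_pop = np.repeat(subpop, 2)

    # latent AR(1) per haplotype along each chromosome, reset at block edges
    decay = max(ld_block_len / 2.0, 1e-9)
    Z = np.empty((n_hap, n_snps))
    Z[:, 0] = rng.standard_normal(n_hap)
    for j in range(1, n_snps):
        new_block = (block_ids[j] != block_ids[j - 1]) or (chroms[j] != chroms[j - 1])
        rho = 0.0 if new_block else np.exp(-(positions[j] - positions[j - 1]) / decay)
        Z[:, j] = rho * Z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_hap)

    from scipy.stats import norm

    thresh = norm.ppf(p_sub)  # carrier if latent below subpop quantile
    alleles = (Z < thresh[hap_pop]).astype(np.int8)
    dose = alleles[0::2] + alleles[1::2]

    freq = dose.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min

    ref = rng.choice(_BASES, size=n_snps)
    alt_offset = rng.integers(1, 4, size=n_snps)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_offset) % 4]

    snp_ids = np.array([f"s{c[3:]}_{p}" for c, p in zip(chroms, positions)])
    lines = _line_ids(n_lines, subpop)
    dosages = pd.DataFrame(dose[:, keep].astype(float), index=lines,
                           columns=snp_ids[keep])
    variants = pd.DataFrame(
        {"chrom": np.asarray(chroms)[keep], "pos": positions[keep],
         "ref": ref[keep], "alt": alt[keep], "maf": maf[keep],
         "block": block_ids[keep]},
        index=snp_ids[keep])
    return GenotypeMatrix(dosages, variants), variants


def generate_gene_models(
    genotypes: GenotypeMatrix,
    n_genes: int,
    seed: int = 0,
    gene_len_range: tuple[int, int] = (2_000, 6_000),
) -> GeneModelSet:
    """Non-overlapping gene spans laid out over the genotyped chromosomes.

    Genes are anchored near SNP positions so that cis windows are never
    empty by construction of the coordinate range.
    """
    rng = np.random.default_rng(seed)
    var = genotypes.variants
    rows = []
    anchor_idx = np.sort(rng.choice(len(var), size=min(n_genes, len(var)),
                                    replace=False))
    last_end: dict[str, int] = {}
    g = 0
    for i in anchor_idx:
        chrom = var["chrom"].iloc[i]
        length = int(rng.integers(*gene_len_range))
        start = max(1, int(var["pos"].iloc[i]) - length // 2)
        if start <= last_end.get(chrom, 0):
            start = last_end[chrom] + 1
        end = start + length - 1
        last_end[chrom] = end
        strand = rng.choice(["+", "-"])
        rows.append((f"gene{g + 1:05d}", chrom, start, end, strand))
        g += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand"]).set_index("gene_id")
    genes.index.name = None
    return GeneModelSet(genes=genes)


def generate_metabolome(
    genotypes: GenotypeMatrix,
    n_metabolites: int = 400,
    n_causal: int = 40,
    pve: float = 0.2,
    drought_frac: float = 0.25,
    fc_log2_mean: float = 2.0,
    missing_rate: float = 0.1,
    redundancy: float = 0.3,
    seed: int = 0,
    up_fraction: float = 0.8,
    noise_sd: float = 0.4,
) -> tuple[FeatureTable, FeatureTable, SyntheticTruth]:
    """Paired WW/DS LC-MS-like feature tables with known injected signal.

    Per metabolite ``m`` with causal SNP ``g``: log intensity =
    baseline + b(g - mean g) + shift*[DS & drought-responsive] + noise, with
    b scaled so the dosage term explains ``pve`` of within-condition
    variance. Drought shifts are log2 fold changes with mean magnitude
    ``fc_log2_mean``; ``up_fraction`` of responsive metabolites shift up,
    matching the predominance of drought-induced accumulation in real
    maize leaf data. ``redundancy`` is the Poisson mean number of redundant
    duplicate features per metabolite (shared retention time within the
    grouping tolerance, log-intensity correlation > 0.95, alternating
    ionization mode). Missingness is completely at random at
    ``missing_rate``.
    """
    if n_causal > n_metabolites:
        raise ValueError("n_causal cannot exceed n_metabolites")
    if not 0 < pve < 1:
        raise ValueError("pve must lie in (0, 1)")
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_lines = len(genotypes.line_ids)
    dose = genotypes.dosages.to_numpy(dtype=float)
    snp_ids = np.asarray(genotypes.snp_ids)

    met_ids = [f"M{i + 1:05d}" for i in range(n_metabolites)]
    baseline = rng.normal(12.0, 1.0, size=n_metabolites)
    log_ww = baseline + rng.normal(0.0, noise_sd, size=(n_lines, n_metabolites))
    log_ds = baseline + rng.normal(0.0, noise_sd, size=(n_lines, n_metabolites))

    truth = SyntheticTruth(seed=seed)
    causal_mets = rng.choice(n_metabolites, size=n_causal, replace=False)
    causal_snps = rng.choice(len(snp_ids), size=n_causal, replace=False)
    for m, s in zip(causal_mets, causal_snps):
        g = dose[:, s]
        var_g = g.var()
        if var_g < 1e-9:
            continue
        b = np.sqrt(pve / (1 - pve) * noise_sd**2 / var_g) * rng.choice([-1.0, 1.0])
        term = b * (g - g.mean())
        log_ww[:, m] += term
        log_ds[:, m] += term
        truth.trait_effects[met_ids[m]] = (str(snp_ids[s]), float(b), float(pve))
        truth.causal_snp_ids.append(str(snp_ids[s]))

    n_shift = int(round(drought_frac * n_metabolites))
    shifted = rng.choice(n_metabolites, size=n_shift, replace=False)
    for m in shifted:
        sign = 1.0 if rng.random() < up_fraction else -1.0
        lfc = sign * rng.normal(fc_log2_mean, 0.25 * abs(fc_log2_mean) or 0.25)
        log_ds[:, m] += lfc * np.log(2.0)
        truth.drought_shifts[met_ids[m]] = float(lfc)

    # redundant duplicates: same underlying metabolite, shifted m/z, nearby
    # retention time, near-unit log-scale correlation, alternating mode
    rt = rng.uniform(0.5, 30.0, size=n_metabolites)
    mz = rng.uniform(100.0, 1200.0, size=n_metabolites)
    mode0 = rng.choice(["positive", "negative"], size=n_metabolites)
    n_dup = rng.poisson(redundancy, size=n_metabolites)

    feat_ids, feat_mz, feat_rt, feat_mode = [], [], [], []
    cols_ww, cols_ds = [], []
    for m in range(n_metabolites):
        members = [f"F{m + 1:05d}_0"]
        feat_ids.append(members[0])
        feat_mz.append(mz[m])
        feat_rt.append(rt[m])
        feat_mode.append(mode0[m])
        cols_ww.append(log_ww[:, m])
        cols_ds.append(log_ds[:, m])
        for k in range(n_dup[m]):
            fid = f"F{m + 1:05d}_{k + 1}"
            members.append(fid)
            feat_ids.append(fid)
            feat_mz.append(mz[m] + rng.uniform(1.0, 60.0))
            feat_rt.append(rt[m] + rng.uniform(-0.08, 0.08))
            feat_mode.append("negative" if (k + (mode0[m] == "negative")) % 2 == 0
                             else "positive")
            gain = rng.normal(0.0, 0.3)
            jitter = 0.05
            cols_ww.append(log_ww[:, m] + gain + rng.normal(0, jitter, n_lines))
            cols_ds.append(log_ds[:, m] + gain + rng.normal(0, jitter, n_lines))
        truth.feature_groups[met_ids[m]] = members

    inten_ww = np.exp(np.column_stack(cols_ww))
    inten_ds = np.exp(np.column_stack(cols_ds))
    if missing_rate > 0:
        inten_ww[rng.random(inten_ww.shape) < missing_rate] = np.nan
        inten_ds[rng.random(inten_ds.shape) < missing_rate] = np.nan

    meta = pd.DataFrame({"mz": feat_mz, "rt": np.clip(feat_rt, 0.0, None),
                         "mode": feat_mode},
                        index=pd.Index(feat_ids))
    lines = genotypes.line_ids
    ww = FeatureTable(meta=meta, condition="WW",
                      intensities=pd.DataFrame(inten_ww.T, index=feat_ids,
                                               columns=lines))
    ds = FeatureTable(meta=meta.copy(), condition="DS",
                      intensities=pd.DataFrame(inten_ds.T, index=feat_ids,
                                               columns=lines))
    truth.validate_against(genotypes)
    return ww, ds, truth


def generate_expression(
    genotypes: GenotypeMatrix,
    gene_models: GeneModelSet,
    n_cis: int = 20,
    n_trans: int = 20,
    pve: float = 0.3,
    seed: int = 0,
    condition_specific_frac: float = 0.5,
    cis_window: int = 20_000,
    trans_min_dist: int = 1_000_000,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Expression for WW and DS with injected cis and trans eQTLs.

    Cis effects use a SNP within ``cis_window`` bp of the target gene span;
    trans effects a SNP farther than ``trans_min_dist`` or on another
    chromosome. A ``condition_specific_frac`` share of effects is active in
    one random condition only (recorded in ``truth.condition_specific`` as
    WW/DS; shared effects as "both"). Emitted values are on a raw positive
    scale (2**log2-expression).
    """
    rng = np.random.default_rng(seed)
    var = genotypes.variants
    dose = genotypes.dosages.to_numpy(dtype=float)
    genes = gene_models.genes
    n_genes = len(genes)
    n_lines = dose.shape[0]
    if n_cis + n_trans > n_genes:
        raise ValueError("n_cis + n_trans exceeds the number of genes")

    pos = var["pos"].to_numpy()
    chrom = var["chrom"].to_numpy()

    def snps_near(gene_row) -> np.ndarray:
        on = chrom == gene_row["chrom"]
        return np.flatnonzero(on & (pos >= gene_row["start"] - cis_window)
                              & (pos <= gene_row["end"] + cis_window))

    def snps_far(gene_row) -> np.ndarray:
        off = chrom != gene_row["chrom"]
        same_far = (chrom == gene_row["chrom"]) & (
            (pos < gene_row["start"] - trans_min_dist)
            | (pos > gene_row["end"] + trans_min_dist))
        return np.flatnonzero(off | same_far)

    cis_eligible = [g for g in range(n_genes) if len(snps_near(genes.iloc[g]))]
    if n_cis > 0 and not cis_eligible:
        raise ValueError(f"no SNP within {cis_window} bp of any gene")

    base = rng.normal(5.0, 1.0, size=n_genes)
    noise_sd = 1.0
    z_ww = base + rng.normal(0, noise_sd, size=(n_lines, n_genes))
    z_ds = base + rng.normal(0, noise_sd, size=(n_lines, n_genes))
    # a mild global drought response so conditions differ even without eQTLs
    z_ds += rng.normal(0.0, 0.3, size=n_genes)

    truth = SyntheticTruth(seed=seed)
    chosen_cis = rng.choice(cis_eligible, size=min(n_cis, len(cis_eligible)),
                            replace=False)
    remaining = np.setdiff1d(np.arange(n_genes), chosen_cis)
    chosen_trans = rng.choice(remaining, size=min(n_trans, len(remaining)),
                              replace=False)

    def inject(gene_idx: int, snp_idx: int) -> None:
        gid = genes.index[gene_idx]
        g = dose[:, snp_idx]
        var_g = g.var()
        if var_g < 1e-9:
            return
        b = np.sqrt(pve / (1 - pve) * noise_sd**2 / var_g) * rng.choice([-1.0, 1.0])
        term = b * (g - g.mean())
        u = rng.random()
        if u < condition_specific_frac:
            cond = "WW" if rng.random() < 0.5 else "DS"
        else:
            cond = "both"
        if cond in ("WW", "both"):
            z_ww[:, gene_idx] += term
        if cond in ("DS", "both"):
            z_ds[:, gene_idx] += term
        sid = str(var.index[snp_idx])
        truth.trait_effects[gid] = (sid, float(b), float(pve))
        truth.causal_snp_ids.append(sid)
        truth.condition_specific[gid] = cond

    for g in chosen_cis:
        inject(g, int(rng.choice(snps_near(genes.iloc[g]))))
    for g in chosen_trans:
        far = snps_far(genes.iloc[g])
        if len(far):
            inject(g, int(rng.choice(far)))

    lines = genotypes.line_ids
    gene_ids = list(genes.index)
    expr_ww = ExpressionMatrix(values=pd.DataFrame(2.0**z_ww, index=lines,
                                                   columns=gene_ids),
                               condition="WW")
    expr_ds = ExpressionMatrix(values=pd.DataFrame(2.0**z_ds, index=lines,
                                                   columns=gene_ids),
                               condition="DS")
    truth.validate_against(genotypes)
    return expr_ww, expr_ds, truth


def couple_hub_genes(
    expr_ww: ExpressionMatrix,
    expr_ds: ExpressionMatrix,
    ww: FeatureTable,
    ds: FeatureTable,
    truth: SyntheticTruth,
    n_hubs: int = 5,
    targets_per_hub: int = 12,
    strength: float = 0.45,
    seed: int = 0,
    ds_specific_frac: float = 0.6,
) -> None:
    """Make selected genes drive many metabolites (hub structure), in place.

    For each hub gene, ``targets_per_hub`` metabolites (all their redundant
    member features) gain a multiplicative contribution
    exp(strength * z-scored log2 expression) under the conditions where the
    hub is active. ``ds_specific_frac`` of hubs act only under drought,
    mirroring the strong condition specificity of stress hub genes; half
    the remainder act only under WW, the rest under both. Hub ids are
    appended to ``truth.hub_gene_ids`` and their activity condition to
    ``truth.condition_specific`` under the key ``hub:<gene_id>``.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(expr_ww.gene_ids)
    hubs = rng.choice(gene_ids, size=min(n_hubs, len(gene_ids)), replace=False)
    met_ids = list(truth.feature_groups)
    for hub in hubs:
        u = rng.random()
        cond = ("DS" if u < ds_specific_frac
                else "WW" if u < ds_specific_frac + (1 - ds_specific_frac) / 2
                else "both")
        targets = rng.choice(len(met_ids), size=min(targets_per_hub, len(met_ids)),
                             replace=False)
        for expr, table, active in ((expr_ww, ww, cond in ("WW", "both")),
                                    (expr_ds, ds, cond in ("DS", "both"))):
            if not active:
                continue
            z = np.log2(expr.values[hub].astype(float) + 1.0)
            z = (z - z.mean()) / (z.std() or 1.0)
            bump = np.exp(strength * z)  # line-indexed Series
            for t in targets:
                for fid in truth.feature_groups[met_ids[t]]:
                    table.intensities.loc[fid] = (
                        table.intensities.loc[fid] * bump)
        truth.hub_gene_ids.append(str(hub))
        truth.condition_specific[f"hub:{hub}"] = cond


def generate_phenotype(
    metabolome_ds: MetaboliteMatrix,
    n_drivers: int = 15,
    h2: float = 0.6,
    seed: int = 0,
    environments: tuple[str, ...] = ("E1", "E2"),
    replicates: int = 2,
    driver_pool: list[str] | None = None,
) -> tuple[PhenotypeTable, SyntheticTruth]:
    """Survival-rate-like phenotype driven by a sparse metabolite subset.

    A weighted sum of ``n_drivers`` standardized DS metabolite abundances
    plus Gaussian noise (variance ratio set by heritability ``h2``) is
    squashed through a logistic to produce a survival rate in [0, 1].
    Fresh weight and dry mass are emitted per environment x replicate with
    genotype effects proportional to the same latent score, for BLUP
    fitting. ``driver_pool`` restricts the candidate driver metabolites
    (e.g. to the drought-shifted subset, emulating stress-responsive
    compounds carrying the tolerance signal).
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    vals = metabolome_ds.values
    if n_drivers > vals.shape[1]:
        raise ValueError("n_drivers exceeds the metabolite count")
    rng = np.random.default_rng(seed)
    n_lines = vals.shape[0]
    X = vals.to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    if driver_pool is not None:
        pool = [vals.columns.get_loc(c) for c in driver_pool
                if c in vals.columns]
        if len(pool) < n_drivers:
            raise ValueError("driver_pool smaller than n_drivers")
        drivers = rng.choice(pool, size=n_drivers, replace=False)
    else:
        drivers = rng.choice(vals.shape[1], size=n_drivers, replace=False)
    w = rng.normal(0.0, 1.0, size=n_drivers)
    score = Z[:, drivers] @ w
    sd = score.std()
    score = score / sd if sd > 0 else score
    latent = np.sqrt(h2) * score + np.sqrt(1 - h2) * rng.standard_normal(n_lines)
    survival = 1.0 / (1.0 + np.exp(-latent))

    truth = SyntheticTruth(seed=seed)
    for d, wt in zip(drivers, w):
        truth.metabolite_weights_on_phenotype[vals.columns[d]] = float(wt)

    rows = []
    lines = list(vals.index)
    for line, s in zip(lines, survival):
        rows.append((line, "DS", "R1", "survival_rate", float(s)))
    geno_fw = 2.0 * latent
    geno_dm = 1.0 * latent
    for trait, geno_eff, base in (("fresh_weight", geno_fw, 20.0),
                                  ("dry_mass", geno_dm, 5.0)):
        for e, env in enumerate(environments):
            env_eff = rng.normal(0.0, 1.0)
            for r in range(replicates):
                rep_eff = rng.normal(0.0, 0.5)
                noise = rng.normal(0.0, 0.8, size=n_lines)
                vals_tr = base + env_eff + rep_eff + geno_eff + noise
                for line, v in zip(lines, vals_tr):
                    rows.append((line, env, f"R{r + 1}", trait, float(v)))
    table = pd.DataFrame(rows, columns=["line", "environment", "replicate",
                                        "trait", "value"])
    return PhenotypeTable(table=table), truth
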