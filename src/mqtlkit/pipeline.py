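"""End-to-end orchestration: config, stage execution, summary report.

``run_pipeline`` executes feature processing -> drought-response calling ->
mQTL mapping -> eQTL mapping -> network/hub analysis -> metabolome
prediction on either user-supplied files or a self-generated synthetic
dataset, writing per-stage TSVs plus a JSON summary whose every count and
ratio is recomputable from the emitted stage files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eqtl as eqtl_mod
from . import features as feat_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import network as net_mod
from . import predict as pred_mod
from . import simulate as sim_mod
from . import stress as stress_mod
from .containers import GeneModelSet

log = logging.getLogger("mqtlkit")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one auditable place.

    Threshold defaults are the published analysis values; synthetic-data
    fields control the bundled generator used when no input paths are
    given.
    """

    # input paths (None -> generate synthetically)
    genotypes: str | None = None          # HapMap-dialect TSV
    features_ww: str | None = None
    features_ds: str | None = None
    expression_ww: str | None = None
    expression_ds: str | None = None
    gene_models: str | None = None        # GFF3
    known_qtl: str | None = None          # BED
    pathways: str | None = None           # GMT
    phenotypes: str | None = None         # long TSV

    # feature processing
    max_missing: float = 0.2
    rt_tol: float = 0.2
    corr_min: float = 0.95

    # drought-response calling
    vip_min: float = 1.0
    fdr_max: float = 0.05
    fc_min: float = 2.0
    n_ortho: int = 1

    # association scans
    maf_min: float = 0.05
    n_pc: int = 5
    meff: int | None = None               # inject external Meff; else simpleM
    p_threshold: float | None = None      # else 1/Meff
    mqtl_gap: int = 10_000
    eqtl_threshold: float = 4.2e-8
    cis_window: int = 20_000

    # networks
    edge_threshold: float = 1e-5
    coexp_threshold: float = 4.67e-9
    n_perm: int = 1000
    hub_alpha: float = 0.01

    # prediction
    folds: int = 10
    repeats: int = 100
    n_boot: int = 100
    stepwise: bool = True

    # synthetic-data scale (used when input paths are None)
    n_lines: int = 120
    n_snps: int = 2000
    n_metabolites: int = 400
    n_causal: int = 40
    met_pve: float = 0.2
    drought_frac: float = 0.25
    fc_log2_mean: float = 2.0
    missing_rate: float = 0.1
    redundancy: float = 0.3
    n_genes: int = 80
    n_cis: int = 12
    n_trans: int = 12
    expr_pve: float = 0.35
    n_hubs: int = 5
    targets_per_hub: int = 12
    hub_strength: float = 0.45
    n_drivers: int = 15
    h2: float = 0.6
    n_subpops: int = 3
    n_pathways: int = 10

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_missing", "fdr_max", "hub_alpha", "eqtl_threshold",
                     "edge_threshold", "coexp_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("n_perm", "folds", "repeats", "n_boot", "n_pc",
                     "mqtl_gap", "cis_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


class StageError(RuntimeError):
    """Failure in a named pipeline stage; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _synthesize_inputs(cfg: PipelineConfig, out: Path) -> dict:
    """Generate the full synthetic dataset and write it to ``out``/inputs."""
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(s) for k, s in zip(
        ("geno", "met", "genes", "expr", "pheno", "bed", "gmt"),
        rng.integers(0, 2**31 - 1, size=7))}
    inp = out / "inputs"
    inp.mkdir(parents=True, exist_ok=True)
    geno, _ = sim_mod.generate_genotypes(
        cfg.n_lines, cfg.n_snps, n_subpops=cfg.n_subpops,
        maf_min=cfg.maf_min, seed=seeds["geno"])
    ww, ds, met_truth = sim_mod.generate_metabolome(
        geno, n_metabolites=cfg.n_metabolites, n_causal=cfg.n_causal,
        pve=cfg.met_pve, drought_frac=cfg.drought_frac,
        fc_log2_mean=cfg.fc_log2_mean, missing_rate=cfg.missing_rate,
        redundancy=cfg.redundancy, seed=seeds["met"])
    genes = sim_mod.generate_gene_models(geno, cfg.n_genes, seed=seeds["genes"])
    expr_ww, expr_ds, expr_truth = sim_mod.generate_expression(
        geno, genes, n_cis=cfg.n_cis, n_trans=cfg.n_trans, pve=cfg.expr_pve,
        seed=seeds["expr"])
    if cfg.n_hubs > 0:
        sim_mod.couple_hub_genes(expr_ww, expr_ds, ww, ds, met_truth,
                                 n_hubs=cfg.n_hubs,
                                 targets_per_hub=cfg.targets_per_hub,
                                 strength=cfg.hub_strength,
                                 seed=seeds["expr"] // 2 + 1)

    # known-QTL BED: windows around a subset of causal SNPs plus decoys,
    # written 0-based half-open
    bed_rng = np.random.default_rng(seeds["bed"])
    var = geno.variants
    causal = [s for s in met_truth.causal_snp_ids if s in var.index]
    chosen = bed_rng.choice(causal, size=max(1, len(causal) // 3),
                            replace=False) if causal else []
    bed_rows = []
    for s in chosen:
        pos = int(var.loc[s, "pos"])
        bed_rows.append((var.loc[s, "chrom"], max(0, pos - 5000), pos + 5000,
                         f"known_{s}"))
    for _ in range(10):
        i = int(bed_rng.integers(0, len(var)))
        pos = int(var["pos"].iloc[i])
        bed_rows.append((var["chrom"].iloc[i], max(0, pos - 5000), pos + 5000,
                         "decoy"))
    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"])
    bed.to_csv(inp / "known_qtl.bed", sep="\t", header=False, index=False)

    gmt_rng = np.random.default_rng(seeds["gmt"])
    gene_ids = list(genes.genes.index)
    pathways = {
        f"pathway_{i + 1}": set(gmt_rng.choice(
            gene_ids, size=int(gmt_rng.integers(5, max(6, len(gene_ids) // 4))),
            replace=False))
        for i in range(cfg.n_pathways)}
    io_mod.write_gmt(pathways, inp / "pathways.gmt")

    io_mod.write_hapmap(geno, inp / "genotypes.hmp.tsv", seed=seeds["geno"])
    io_mod.write_feature_table(ww, inp / "features_WW.tsv", seed=seeds["met"])
    io_mod.write_feature_table(ds, inp / "features_DS.tsv", seed=seeds["met"])
    io_mod.write_gff3(genes, inp / "genes.gff3")
    io_mod.write_expression(expr_ww, inp / "expression_WW.tsv", seed=seeds["expr"])
    io_mod.write_expression(expr_ds, inp / "expression_DS.tsv", seed=seeds["expr"])
    return {"geno": geno, "ww": ww, "ds": ds, "genes": genes,
            "expr_ww": expr_ww, "expr_ds": expr_ds, "bed": bed,
            "pathways": pathways, "met_truth": met_truth,
            "expr_truth": expr_truth, "seeds": seeds}


def _load_inputs(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.genotypes is None:
        return _synthesize_inputs(cfg, out)
    geno = io_mod.read_hapmap(cfg.genotypes)
    data = {
        "geno": geno.filter_maf(cfg.maf_min),
        "ww": io_mod.read_feature_table(cfg.features_ww, "WW"),
        "ds": io_mod.read_feature_table(cfg.features_ds, "DS"),
        "genes": io_mod.read_gff3(cfg.gene_models) if cfg.gene_models else None,
        "expr_ww": (io_mod.read_expression(cfg.expression_ww, "WW")
                    if cfg.expression_ww else None),
        "expr_ds": (io_mod.read_expression(cfg.expression_ds, "DS")
                    if cfg.expression_ds else None),
        "bed": io_mod.read_bed(cfg.known_qtl) if cfg.known_qtl else None,
        "pathways": io_mod.read_gmt(cfg.pathways) if cfg.pathways else None,
        "met_truth": None, "expr_truth": None, "seeds": {"root": cfg.seed},
    }
    return data


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    t_start = time.time()
    summary: dict = {"config_seed": cfg.seed, "stages": {}}

    data = _run_stage("inputs", _load_inputs, cfg, out)
    geno = data["geno"]

    # --- feature processing -------------------------------------------------
    def stage_featproc():
        mm_ww, mm_ds = feat_mod.process_feature_tables(
            data["ww"], data["ds"], max_missing=cfg.max_missing,
            rt_tol=cfg.rt_tol, corr_min=cfg.corr_min)
        io_mod.write_metabolite_matrix(mm_ww, out / "metabolites_WW.tsv",
                                       seed=cfg.seed)
        io_mod.write_metabolite_matrix(mm_ds, out / "metabolites_DS.tsv",
                                       seed=cfg.seed)
        return mm_ww, mm_ds

    mm_ww, mm_ds = _run_stage("featproc", stage_featproc)
    n_input_features = len(data["ww"].feature_ids)
    summary["stages"]["featproc"] = {
        "input_features": n_input_features,
        "nonredundant_metabolites": len(mm_ww.metabolite_ids),
    }

    # --- drought response ----------------------------------------------------
    def stage_stress():
        tab = stress_mod.drought_response_table(
            mm_ww, mm_ds, vip_min=cfg.vip_min, fdr_max=cfg.fdr_max,
            fc_min=cfg.fc_min, n_ortho=cfg.n_ortho)
        tab.to_csv(out / "drought_response.tsv", sep="\t")
        return tab

    resp = _run_stage("stressresp", stage_stress)
    n_up = int((resp["direction"] == "up").sum())
    n_down = int((resp["direction"] == "down").sum())
    n_resp = int(resp["responsive"].sum())
    summary["stages"]["stressresp"] = {
        "tested": len(resp), "responsive": n_resp, "up": n_up, "down": n_down,
        "pct_up_of_responsive": net_mod.summarize_ratios(
            {"x": (n_up, max(n_resp, 1))})["x"],
    }

    # --- mQTL mapping --------------------------------------------------------
    def stage_mgwas():
        K = gwas_mod.kinship(geno)
        meff = cfg.meff or gwas_mod.effective_marker_count(geno)
        p_thr = cfg.p_threshold or gwas_mod.suggestive_threshold(meff)
        resp_ids = list(resp.index[resp["responsive"]])
        scans = {}
        for cond, mm in (("WW", mm_ww), ("DS", mm_ds)):
            traits = mm.values[resp_ids] if resp_ids else mm.values.iloc[:, :0]
            scans[cond] = gwas_mod.scan_traits(geno, traits, K, n_pc=cfg.n_pc,
                                               condition=cond, p_keep=p_thr)
        sig = pd.concat(scans.values(), ignore_index=True)
        sig.to_csv(out / "gwas_significant.tsv", sep="\t", index=False)
        mqtls = gwas_mod.cluster_mqtl(sig, gap=cfg.mqtl_gap)
        if data["genes"] is not None:
            gwas_mod.assign_candidate_genes(mqtls, data["genes"], sig)
        frac = None
        if data["bed"] is not None and mqtls:
            _, frac = gwas_mod.qtl_overlap(mqtls, data["bed"])
        gwas_mod.mqtls_to_frame(mqtls).to_csv(out / "mqtls.tsv", sep="\t",
                                              index=False)
        return K, meff, p_thr, scans, sig, mqtls, frac

    K, meff, p_thr, scans, sig, mqtls, overlap_frac = _run_stage(
        "mlmgwas", stage_mgwas)
    snps_ww = set(scans["WW"]["snp"]) if len(scans["WW"]) else set()
    snps_ds = set(scans["DS"]["snp"]) if len(scans["DS"]) else set()
    union = snps_ww | snps_ds
    n_candidates = len({g for q in mqtls for g in q.candidate_genes})
    summary["stages"]["mlmgwas"] = {
        "meff": int(meff), "p_threshold": float(p_thr),
        "significant_snps_ww": len(snps_ww), "significant_snps_ds": len(snps_ds),
        "significant_snps_total": len(union),
        "pct_shared_snps": net_mod.summarize_ratios(
            {"x": (len(snps_ww & snps_ds), max(len(union), 1))})["x"],
        "mqtls": len(mqtls), "candidate_genes": n_candidates,
        "pct_novel_mqtl": (None if overlap_frac is None else
                           net_mod.summarize_ratios(
                               {"x": (sum(1 for q in mqtls if not q.known_overlap),
                                      max(len(mqtls), 1))})["x"]),
    }

    # --- eQTL mapping --------------------------------------------------------
    if data["expr_ww"] is not None and data["genes"] is not None:
        def stage_eqtl():
            recs_ww = eqtl_mod.eqtl_scan(
                geno, data["expr_ww"], K, threshold=cfg.eqtl_threshold,
                n_pc=cfg.n_pc, gap=cfg.mqtl_gap, gene_models=data["genes"],
                cis_window=cfg.cis_window)
            recs_ds = eqtl_mod.eqtl_scan(
                geno, data["expr_ds"], K, threshold=cfg.eqtl_threshold,
                n_pc=cfg.n_pc, gap=cfg.mqtl_gap, gene_models=data["genes"],
                cis_window=cfg.cis_window)
            eqtl_mod.classify_sharing(recs_ww, recs_ds)
            df = eqtl_mod.records_to_frame(recs_ww + recs_ds)
            df.to_csv(out / "eqtls.tsv", sep="\t", index=False)
            return df

        edf = _run_stage("eqtlmap", stage_eqtl)
        n_eqtl = len(edf)
        summary["stages"]["eqtlmap"] = {
            "eqtls": n_eqtl,
            "cis": int((edf["kind"] == "cis").sum()) if n_eqtl else 0,
            "trans": int((edf["kind"] == "trans").sum()) if n_eqtl else 0,
            "shared": int((edf["sharing"] == "shared").sum()) if n_eqtl else 0,
            "dynamic": int((edf["sharing"] == "dynamic").sum()) if n_eqtl else 0,
            "pct_trans": (net_mod.summarize_ratios(
                {"x": (int((edf["kind"] == "trans").sum()), n_eqtl)})["x"]
                if n_eqtl else None),
        }

    # --- networks and hubs ---------------------------------------------------
    if data["expr_ww"] is not None:
        def stage_netlink():
            rng = np.random.default_rng(cfg.seed + 101)
            nets, hubs = {}, {}
            for cond, expr, mm in (("WW", data["expr_ww"], mm_ww),
                                   ("DS", data["expr_ds"], mm_ds)):
                net = net_mod.gene_metabolite_edges(expr, mm,
                                                    threshold=cfg.edge_threshold)
                nets[cond] = net
                hubs[cond] = net_mod.call_hubs(
                    net, n_perm=cfg.n_perm, alpha=cfg.hub_alpha,
                    seed=int(rng.integers(0, 2**31 - 1)))
            edges = pd.concat([n.edges for n in nets.values()], ignore_index=True)
            edges.to_csv(out / "gene_metabolite_edges.tsv", sep="\t", index=False)
            coexp = pd.concat(
                [net_mod.coexpression_edges(data[f"expr_{c.lower()}"],
                                            threshold=cfg.coexp_threshold)
                 for c in ("WW", "DS")], ignore_index=True)
            coexp.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
            calls = pd.concat([h.calls.assign(condition=c)
                               for c, h in hubs.items()], ignore_index=True)
            calls.to_csv(out / "hub_calls.tsv", sep="\t", index=False)
            enrich = None
            hub_genes = set(calls[calls["is_hub"]]["gene_id"])
            if data["pathways"] is not None and hub_genes:
                universe = set(nets["WW"].genes)
                enrich = net_mod.fisher_enrichment(hub_genes & universe,
                                                   universe, data["pathways"])
                enrich.to_csv(out / "hub_enrichment.tsv", sep="\t", index=False)
            return nets, hubs, enrich

        nets, hubs, enrich = _run_stage("netlink", stage_netlink)
        hub_sets = {c: set(h.calls[h.calls["is_hub"]]["gene_id"])
                    for c, h in hubs.items()}
        all_hubs = hub_sets["WW"] | hub_sets["DS"]
        summary["stages"]["netlink"] = {
            "edges_ww": len(nets["WW"].edges), "edges_ds": len(nets["DS"].edges),
            "hub_threshold_ww": hubs["WW"].threshold,
            "hub_threshold_ds": hubs["DS"].threshold,
            "hubs_ww": len(hub_sets["WW"]), "hubs_ds": len(hub_sets["DS"]),
            "hubs_total": len(all_hubs),
            "pct_ds_specific_hubs": (net_mod.summarize_ratios(
                {"x": (len(hub_sets["DS"] - hub_sets["WW"]), len(all_hubs), 0)})["x"]
                if all_hubs else None),
        }

    # --- prediction ----------------------------------------------------------
    def stage_mpredict():
        rng = np.random.default_rng(cfg.seed + 202)
        if data.get("met_truth") is not None:
            # drivers come from the drought-shifted metabolites: the stress
            # response carries the tolerance signal in this emulation
            truth = data["met_truth"]
            member_of = {f: m for m, fs in truth.feature_groups.items()
                         for f in fs}
            shifted = set(truth.drought_shifts)
            pool = [c for c in mm_ds.metabolite_ids
                    if any(member_of.get(f) in shifted
                           for f in mm_ds.group_map.get(c, [c]))] or None
            n_drv = min(cfg.n_drivers, len(pool or mm_ds.metabolite_ids))
            pheno, _ = sim_mod.generate_phenotype(
                mm_ds, n_drivers=n_drv, h2=cfg.h2, driver_pool=pool,
                seed=int(rng.integers(0, 2**31 - 1)))
            io_mod.write_phenotypes(pheno, out / "inputs" / "phenotypes.tsv",
                                    seed=cfg.seed)
        else:
            pheno = io_mod.read_phenotypes(cfg.phenotypes)
        y = pheno.trait("survival_rate")
        y = y[y > 0]  # survival-rate > 0 pre-filter
        lines = [l for l in mm_ds.line_ids if l in y.index]
        y = y.loc[lines]
        resp_ids = list(resp.index[resp["responsive"]])
        sets = {"responsive": resp_ids,
                "all": list(mm_ds.metabolite_ids)}
        if resp_ids:
            sets["random"] = list(rng.choice(mm_ds.metabolite_ids,
                                             size=len(resp_ids), replace=False))
        reports, rows = {}, []
        for name, ids in sets.items():
            if not ids:
                continue
            rep = pred_mod.cross_validate(mm_ds.values.loc[lines, ids], y,
                                          k=cfg.folds, repeats=cfg.repeats,
                                          seed=int(rng.integers(0, 2**31 - 1)))
            reports[name] = rep
            for i, r in enumerate(rep.accuracies):
                rows.append({"predictor_set": name, "repeat": i, "r": r})
        pd.DataFrame(rows).to_csv(out / "prediction_accuracy.tsv", sep="\t",
                                  index=False)
        ratio_p = None
        if ("responsive" in reports and "random" in reports
                and reports["random"].accuracies.mean() > 0):
            ratio_p = pred_mod.bootstrap_ratio_test(
                reports["responsive"].accuracies, reports["random"].accuracies,
                n_boot=cfg.n_boot, seed=int(rng.integers(0, 2**31 - 1)))
        selected, cv_r2 = [], None
        if cfg.stepwise and resp_ids and len(lines) >= 30:
            selected, cv_r2 = pred_mod.stepwise_select(
                mm_ds.values.loc[lines, resp_ids], y,
                seed=int(rng.integers(0, 2**31 - 1)))
            (out / "stepwise_selected.txt").write_text("\n".join(selected) + "\n")
        blups = {}
        for trait in ("fresh_weight", "dry_mass"):
            sub = pheno.table[pheno.table["trait"] == trait]
            if len(sub):
                blups[trait] = pred_mod.phenotype_blup(sub)
        return reports, ratio_p, selected, cv_r2, blups

    reports, ratio_p, selected, cv_r2, blups = _run_stage(
        "mpredict", stage_mpredict)
    summary["stages"]["mpredict"] = {
        "cv_accuracy_mean": {name: float(rep.accuracies.mean())
                             for name, rep in reports.items()},
        "bootstrap_ratio_p": ratio_p,
        "stepwise_selected": len(selected),
        "stepwise_cv_r2": cv_r2,
        "blup_traits": sorted(blups),
    }

    # summary.json is byte-deterministic for a given config + seed; wall time
    # goes to a separate run-info file
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=_json_default) + "\n")
    (out / "run_info.json").write_text(json.dumps(
        {"runtime_s": round(time.time() - t_start, 2)}) + "\n")
    return summary


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _run_stage(name, fn, *args):
    log.info("stage %s ...", name)
    t0 = time.time()
    try:
        result = fn(*args)
    except Exception as exc:
        raise StageError(name, exc) from exc
    log.info("stage %s done in %.1fs", name, time.time() - t0)
    return result
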