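"""eQTL mapping and the gene-metabolite hub network.

Scans expression traits for cis (lead SNP within 20 kb of the gene) and
trans loci, then builds the gene-metabolite network per condition and
calls hub genes against the permutation null.
"""

from mqtlkit import eqtl, features, gwas, network, simulate

geno, _ = simulate.generate_genotypes(150, 1000, seed=21)
genes = simulate.generate_gene_models(geno, 60, seed=22)
expr_ww, expr_ds, etruth = simulate.generate_expression(
    geno, genes, n_cis=8, n_trans=8, pve=0.4, seed=23)
ww, ds, mtruth = simulate.generate_metabolome(
    geno, n_metabolites=120, n_causal=0, drought_frac=0.25,
    missing_rate=0, redundancy=0, seed=24)
simulate.couple_hub_genes(expr_ww, expr_ds, ww, ds, mtruth,
                          n_hubs=4, targets_per_hub=12, seed=25)
mm_ww, mm_ds = features.process_feature_tables(ww, ds)

K = gwas.kinship(geno)
recs_ww = eqtl.eqtl_scan(geno, expr_ww, K, threshold=1e-6, gene_models=genes)
recs_ds = eqtl.eqtl_scan(geno, expr_ds, K, threshold=1e-6, gene_models=genes)
eqtl.classify_sharing(recs_ww, recs_ds)
df = eqtl.records_to_frame(recs_ww + recs_ds)
print(f"eQTLs at p <= 1e-6: {len(df)} "
      f"({(df.kind == 'cis').sum()} cis / {(df.kind == 'trans').sum()} trans; "
      f"{(df.sharing == 'shared').sum()} shared / "
      f"{(df.sharing == 'dynamic').sum()} dynamic)")

net_ds = network.gene_metabolite_edges(expr_ds, mm_ds, threshold=1e-5)
hubs = network.call_hubs(net_ds, n_perm=1000, alpha=0.01, seed=26)
called = hubs.calls[hubs.calls.is_hub]
print(f"\nDS network: {len(net_ds.edges)} gene-metabolite edges; "
      f"permutation degree threshold = {hubs.threshold}")
print(f"hub genes called: {list(called.gene_id)}")
print(f"true injected hubs: {mtruth.hub_gene_ids} "
      f"(active: { {g.split(':')[1]: c for g, c in mtruth.condition_specific.items() if g.startswith('hub:')} })")

pct = network.summarize_ratios({"trans_share": (int((df.kind == 'trans').sum()),
                                                max(len(df), 1))})
print(f"\ntrans share of eQTLs: {pct['trans_share']}%")
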