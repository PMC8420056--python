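"""Call drought-responsive metabolites by the three-criterion intersection.

VIP >= 1 from OPLS-DA, paired-t FDR <= 0.05, and fold change DS/WW >= 2 or
<= 0.5 must all hold. Compares the calls with the generator's injected
drought shifts.
"""

from mqtlkit import features, simulate, stress

geno, _ = simulate.generate_genotypes(150, 300, seed=3)
ww, ds, truth = simulate.generate_metabolome(
    geno, n_metabolites=200, n_causal=0, drought_frac=0.25,
    fc_log2_mean=2.0, missing_rate=0.05, redundancy=0, seed=4)
mm_ww, mm_ds = features.process_feature_tables(ww, ds)

scores, frac = stress.pca_conditions(mm_ww, mm_ds, n_pc=2)
print(f"PCA over stacked WW/DS samples: PC1 explains {frac[0]:.1%}, "
      f"PC2 {frac[1]:.1%}")

tab = stress.drought_response_table(mm_ww, mm_ds)
n = int(tab.responsive.sum())
up = int((tab.direction == "up").sum())
print(f"\nresponsive metabolites: {n}/{len(tab)} "
      f"({up} up, {n - up} down under drought)")

member_of = {f: m for m, fs in truth.feature_groups.items() for f in fs}
called = {member_of[c] for c in tab.index[tab.responsive]}
shifted = set(truth.drought_shifts)
tp = len(called & shifted)
print(f"against ground truth: recall {tp / len(shifted):.2f}, "
      f"false positives {len(called - shifted)}")
print("\ntop calls by |log2 FC|:")
print(tab[tab.responsive].reindex(
    tab[tab.responsive].log2fc.abs().sort_values(ascending=False).index)
    [["vip", "fc", "fdr", "direction"]].head(5).round(3))
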