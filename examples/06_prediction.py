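"""Predict a survival-rate-like drought index from the metabolome.

Compares repeated 10-fold CV accuracy of the ridge-BLUP predictor using
the drought-responsive metabolites versus an equal-size random set, tests
the accuracy ratio by bootstrap, and selects a small marker panel by
stepwise regression.
"""

import numpy as np

from mqtlkit import features, predict, simulate, stress

geno, _ = simulate.generate_genotypes(200, 300, seed=31)
ww, ds, truth = simulate.generate_metabolome(
    geno, n_metabolites=150, n_causal=0, drought_frac=0.25,
    missing_rate=0, redundancy=0, seed=32)
mm_ww, mm_ds = features.process_feature_tables(ww, ds)

# drivers drawn from the drought-shifted metabolites
member_of = {f: m for m, fs in truth.feature_groups.items() for f in fs}
pool = [c for c in mm_ds.metabolite_ids if member_of[c] in truth.drought_shifts]
pheno, ptruth = simulate.generate_phenotype(mm_ds, n_drivers=12, h2=0.6,
                                            driver_pool=pool, seed=33)
y = pheno.trait("survival_rate")

resp = stress.drought_response_table(mm_ww, mm_ds)
resp_ids = list(resp.index[resp.responsive])
rng = np.random.default_rng(34)
rand_ids = list(rng.choice(mm_ds.metabolite_ids, size=len(resp_ids),
                           replace=False))

rep_resp = predict.cross_validate(mm_ds.values[resp_ids], y, k=10,
                                  repeats=20, seed=35)
rep_rand = predict.cross_validate(mm_ds.values[rand_ids], y, k=10,
                                  repeats=20, seed=35)
print(f"CV accuracy (Pearson r, 20 repeats of 10-fold):")
print(f"  responsive set ({len(resp_ids)} metabolites): "
      f"{rep_resp.accuracies.mean():.3f}")
print(f"  random set     ({len(rand_ids)} metabolites): "
      f"{rep_rand.accuracies.mean():.3f}")
if rep_rand.accuracies.mean() > 0:
    p = predict.bootstrap_ratio_test(rep_resp.accuracies,
                                     rep_rand.accuracies,
                                     n_boot=1000, seed=36)
    print(f"  bootstrap test of accuracy ratio = 1: p = {p:.4f}")

sel, r2 = predict.stepwise_select(mm_ds.values[resp_ids], y, seed=37)
hits = len(set(sel) & set(ptruth.metabolite_weights_on_phenotype))
print(f"\nstepwise panel: {len(sel)} metabolites, CV R^2 = {r2:.2f} "
      f"({hits} of {len(ptruth.metabolite_weights_on_phenotype)} true drivers)")

blup = predict.phenotype_blup(
    pheno.table[pheno.table.trait == "fresh_weight"])
print(f"\nfresh-weight BLUPs: {len(blup.genotype_blups)} lines, "
      f"variance components {({k: round(v, 2) for k, v in blup.variance_components.items()})}")
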