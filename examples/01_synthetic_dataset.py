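"""Generate a small synthetic population dataset and inspect its structure.

Creates structured genotypes (three subpopulations, LD blocks), a paired
WW/DS metabolome with injected drought shifts and SNP effects, and prints
what the ground truth contains.
"""

import numpy as np

from mqtlkit import simulate

geno, variants = simulate.generate_genotypes(
    n_lines=120, n_snps=1000, n_subpops=3, seed=7)
print(f"genotypes: {geno.dosages.shape[0]} lines x "
      f"{geno.dosages.shape[1]} SNPs (MAF >= 0.05 after filtering)")
print(f"MAF range: {variants['maf'].min():.3f} - {variants['maf'].max():.3f}")

ww, ds, truth = simulate.generate_metabolome(
    geno, n_metabolites=200, n_causal=20, pve=0.2, drought_frac=0.25,
    fc_log2_mean=2.0, missing_rate=0.1, redundancy=0.3, seed=8)
print(f"\nfeature tables: {len(ww.feature_ids)} LC-MS-like features "
      f"({len(truth.feature_groups)} underlying metabolites) x "
      f"{len(ww.line_ids)} lines, per condition")
print(f"injected drought shifts: {len(truth.drought_shifts)} metabolites, "
      f"median |log2 FC| = "
      f"{np.median(np.abs(list(truth.drought_shifts.values()))):.2f}")
print(f"injected SNP effects: {len(truth.trait_effects)} metabolites at "
      f"PVE 0.2 each")
print(f"missing cells (WW): {ww.intensities.isna().mean().mean():.1%}")

# the PVE of an injected effect is recoverable by plain regression
met, (snp, beta, pve) = next(iter(truth.trait_effects.items()))
feat = truth.feature_groups[met][0]
x = geno.dosages[snp].to_numpy()
y = np.log(ww.intensities.loc[feat].to_numpy(dtype=float))
ok = ~np.isnan(y)
r = np.corrcoef(x[ok], y[ok])[0, 1]
print(f"\nexample: metabolite {met} <- SNP {snp}: target PVE {pve}, "
      f"single-SNP R^2 on emitted data = {r**2:.3f}")
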