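"""Run the whole pipeline on a self-generated synthetic dataset.

Equivalent to ``mqtlkit run --out-dir out --seed 1`` from the shell; every
stage writes its TSV outputs plus a summary JSON whose numbers are all
recomputable from the stage files.
"""

import json

from mqtlkit.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_lines=100, n_snps=1000, n_metabolites=200,
                     repeats=20, n_perm=500)
summary = run_pipeline(cfg, "pipeline_out")
print(json.dumps(summary, indent=2))
print("\nstage outputs in pipeline_out/: metabolites_{WW,DS}.tsv, "
      "drought_response.tsv, gwas_significant.tsv, mqtls.tsv, eqtls.tsv, "
      "gene_metabolite_edges.tsv, hub_calls.tsv, prediction_accuracy.tsv, "
      "summary.json")
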