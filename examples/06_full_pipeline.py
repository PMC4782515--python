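"""Run the whole pipeline from files, exactly as the CLI would.

Writes the default synthetic dataset to disk, builds a pipeline configuration
pointing at those files, runs promoters -> scan -> GRN -> recruitment -> TE
evidence, and prints the report, including the evaluation against the planted
truth table.
"""

import json

import motifrecruit as mr

paths = mr.write_dataset(mr.generate_dataset(mr.SimConfig(seed=42)),
                         "scratch/pipeline_inputs")

config = mr.PipelineConfig(
    genome_c3=str(paths["genome_c3"]),
    genome_c4=str(paths["genome_c4"]),
    genes_c3=str(paths["genes_c3"]),
    genes_c4=str(paths["genes_c4"]),
    orthologs=str(paths["orthologs"]),
    motifs=str(paths["motifs"]),
    te_library=str(paths["te_library"]),
    chromosomes=str(paths["chromosomes"]),
    grn_edges=str(paths["grn_truth"]),
    truth_table=str(paths["truth_table"]),
    outdir="scratch/pipeline_run",
)
report = mr.run_pipeline(config)
print(json.dumps(report, indent=2))
print("\nArtifacts (presence.tsv, events.tsv, te_evidence.tsv, report.json, "
      "manifest.json) are under scratch/pipeline_run/. With the planted GRN "
      "and no mutation noise, precision = recall = 1.0.")
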