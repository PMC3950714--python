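"""End-to-end run: synthetic collection -> report tables.

Generates a small synthetic genome collection with planted adaptation
signals, runs every pipeline stage, and prints the aerobicity result the
report recovers.
"""

from pathlib import Path

import pandas as pd

from nucadapt import RunConfig, run_pipeline
from nucadapt.synth import SyntheticSpec, synth_collection

spec = SyntheticSpec(
    n_genomes=12, genes_per_genome=20, gene_length_codons_mean=120.0,
    ncdna_segments=3, ncdna_length=300, trna_count=4, rrna_count=1,
    rrna_length=500,
)
genomes = synth_collection(spec, seed=5)

out = Path("scratch/example_run")
bundle = run_pipeline(RunConfig(out_dir=out, seed=5, max_fold_genes=1), genomes=genomes)
print("tables written:", ", ".join(sorted(bundle)))

gc3 = bundle["gc3_aerobicity"]
pd.set_option("display.width", 120)
print("\n(G+C)3 by oxygen class (natural vs codon-bias-free):")
print(gc3[["statistic", "aerobe_mean", "anaerobe_mean", "gap", "p", "tier"]].to_string(index=False))
# The natural sequences show the planted ~0.20 aerobe excess; the NCB row
# shows the gap vanishing once the codon bias is removed - the signal
# lives entirely in synonymous codon choice.
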