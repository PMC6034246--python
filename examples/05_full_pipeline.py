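"""Run every stage end to end on synthetic inputs and inspect the reports.

Writes the simulated input files, runs grouping/enrichment, SKAT,
annotation and phenotype comparison, and prints where each report landed
plus the recovered pathogenic tRNA alleles.
"""

import tempfile
from pathlib import Path

import pandas as pd

from mitoburden.pipeline import PipelineConfig, run_pipeline
from mitoburden.synthetic import SimulationConfig, generate_cohort, write_all_inputs

workdir = Path(tempfile.mkdtemp(prefix="mitoburden_"))
cfg = SimulationConfig(seed=1)
dataset, truth = generate_cohort(cfg)
paths = write_all_inputs(dataset, truth, workdir / "inputs", cfg)

out = run_pipeline(PipelineConfig(
    variants=str(paths["variants_tsv"]), samples=str(paths["samples"]),
    phenotypes=str(paths["phenotypes"]), reference=str(paths["reference"]),
    gene_map=str(paths["gene_map"]), ratings=str(paths["ratings"]),
    panel_counts=str(paths["panel_counts"]),
    conservation=str(paths["conservation"]), structures=str(paths["structures"]),
    output_dir=str(workdir / "reports"), seed=1,
))

for name, path in out.items():
    print(f"{name:30s} {path}")

trna = pd.read_csv(out["step3_trna"], sep="\t")
recovered = [
    f"m.{int(r.pos)}{r.ref}>{r.alt}"
    for r in trna[trna["pathogenic"]].itertuples(index=False)
]
print("\nplanted pathogenic tRNA alleles:", ", ".join(truth["trna_pathogenic"]))
print("recovered by the pipeline:      ", ", ".join(recovered))

# The recovered list contains every planted stem-disrupting allele; extra
# entries are synthetic alleles that satisfy all three criteria by chance.
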