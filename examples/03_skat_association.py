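"""Burden-ratio stratified kernel association (SKAT) on a synthetic cohort.

Per gene, alleles are split by the burden ratio (case frequency over
control frequency); SKAT then scores each allele set against the phenotype
with a variance-component test that tolerates mixed effect directions.
"""

from mitoburden import build_genotype_matrix, gene_burden_partition, skat_test
from mitoburden.synthetic import SimulationConfig, generate_cohort

dataset, truth = generate_cohort(SimulationConfig(seed=1))

for gene in ("MT-CO3", "MT-TA", "MT-CYB"):
    alleles = sorted(
        a for a in dataset.distinct_alleles()
        if gene in dataset.gene_map.assign_gene(a.position)
        and a.functional_class != "synonymous"
    )
    part = gene_burden_partition(dataset, gene, alleles)
    for label, subset in (("positive", part.positive_alleles),
                          ("negative", part.negative_alleles)):
        if not subset:
            continue
        G, y = build_genotype_matrix(dataset, subset)
        res = skat_test(G, y, genes=(gene,), allele_set=label)
        print(f"{gene:8s} {label:8s} alleles={res.n_alleles:3d} "
              f"Q={res.Q:10.2f} p={res.p_value:.4g}")

# Genes carrying the planted case-only alleles (MT-CO3, MT-TA) show small
# p-values on their positively associated set; the negative sets do not.
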