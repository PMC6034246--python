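"""The synthetic-cohort generator and its fixtures."""

import numpy as np
import pytest
from scipy import stats

from mitoburden import annotation as ann
from mitoburden import synthetic as syn
from mitoburden.enrichment import (
    G2_CASE_ONLY,
    G3_CONTROL_ONLY,
    assign_groups,
    group_sizes,
)
from mitoburden.heteroplasmy import compute_hf
from mitoburden.model import MitoburdenError, TRNA
from mitoburden.skat import MOMENT_MATCHING, build_genotype_matrix, skat_test


class TestDeterminism:
    def test_identical_seeds_identical_datasets(self):
        cfg = syn.SimulationConfig(seed=11)
        a, ta = syn.generate_cohort(cfg)
        b, tb = syn.generate_cohort(syn.SimulationConfig(seed=11))
        key = lambda ds: [
            (o.sample_id, o.allele.key, o.mutant_reads, o.total_reads)
            for o in ds.observations
        ]
        assert key(a) == key(b)
        assert ta == tb
        assert a.phenotypes.equals(b.phenotypes)

    def test_different_seeds_differ(self):
        a, _ = syn.generate_cohort(syn.SimulationConfig(seed=1))
        b, _ = syn.generate_cohort(syn.SimulationConfig(seed=2))
        assert {o.allele.key for o in a.observations} != {
            o.allele.key for o in b.observations
        }

    def test_seed_recorded_in_truth(self):
        _, truth = syn.generate_cohort(syn.SimulationConfig(seed=5))
        assert truth["seed"] == 5


class TestCohortShape:
    def test_cohort_sizes_and_membership(self, default_cohort):
        dataset, _ = default_cohort
        assert dataset.n_cases == 52
        assert dataset.n_controls == 104
        samples_with_alleles = {o.sample_id for o in dataset.observations}
        assert samples_with_alleles == dataset.cases | dataset.controls

    def test_read_counts_valid(self, default_cohort):
        dataset, _ = default_cohort
        lo, hi = 2027, 5613
        for o in dataset.observations:
            assert 1 <= o.mutant_reads <= o.total_reads
            assert lo <= o.total_reads <= hi

    def test_depth_moments_match_truncated_normal(self):
        cfg = syn.SimulationConfig(seed=3)
        lo, hi = cfg.depth_range
        a = (lo - cfg.depth_mean) / cfg.depth_sd
        b = (hi - cfg.depth_mean) / cfg.depth_sd
        expected_mean = stats.truncnorm.mean(a, b, loc=cfg.depth_mean, scale=cfg.depth_sd)
        expected_sd = stats.truncnorm.std(a, b, loc=cfg.depth_mean, scale=cfg.depth_sd)
        ds, _ = syn.generate_cohort(cfg)
        depths = np.array([o.total_reads for o in ds.observations], float)
        assert depths.mean() == pytest.approx(expected_mean, rel=0.02)
        assert depths.std() == pytest.approx(expected_sd, rel=0.06)

    def test_excess_of_low_frequency_alleles(self, default_cohort):
        dataset, _ = default_cohort
        grouped = assign_groups(dataset)
        low = sum(
            1 for ga in grouped
            if 100 * max(ga.case_carriers / 52, ga.control_carriers / 104) < 5
        )
        assert low / len(grouped) > 0.5

    def test_hf_mixture_is_bimodal(self, default_cohort):
        dataset, _ = default_cohort
        hfs = np.array([compute_hf(o) for o in dataset.observations])
        frac_hi = ((hfs >= 95) & (hfs <= 100)).mean()
        frac_mid = ((hfs >= 40) & (hfs <= 80)).mean()
        assert frac_hi + frac_mid > 0.97
        assert 0.6 <= frac_hi <= 0.8  # configured weight 0.7

    def test_shared_only_pool_empties_private_groups(self, gene_map):
        # a high-frequency shared pool is seen in both cohorts with
        # probability ~1, so case-only and control-only groups are empty
        cfg = syn.SimulationConfig(
            n_pool_alleles=60, n_private_case=0, n_private_control=0,
            freq_min=0.3, freq_max=0.5,
            plant_protein_pathogenic=False, plant_trna_pathogenic=False,
            seed=23,
        )
        ds, _ = syn.generate_cohort(cfg)
        sizes = group_sizes(assign_groups(ds))
        assert sizes[G2_CASE_ONLY] == 0
        assert sizes[G3_CONTROL_ONLY] == 0

    def test_infeasible_rate_rejected(self):
        with pytest.raises(MitoburdenError):
            syn.SimulationConfig(n_pool_alleles=17000)

    def test_causal_gene_shifts_skat_p_below_null(self):
        """Cohorts with a strong causal gene yield smaller SKAT p-values than
        matched null cohorts (reduced scale: 40 replicate pairs)."""
        gene = "MT-CYB"
        ps = {True: [], False: []}
        for rep in range(40):
            for causal in (False, True):
                cfg = syn.SimulationConfig(
                    n_pool_alleles=80, n_private_case=10, n_private_control=20,
                    causal_genes={gene: 4.0} if causal else {},
                    plant_protein_pathogenic=False, plant_trna_pathogenic=False,
                    seed=1000 + rep,
                )
                ds, _ = syn.generate_cohort(cfg)
                alleles = sorted(
                    a for a in ds.distinct_alleles()
                    if gene in ds.gene_map.assign_gene(a.position)
                )
                if not alleles:
                    continue
                G, y = build_genotype_matrix(ds, alleles)
                ps[causal].append(skat_test(G, y, method=MOMENT_MATCHING).p_value)
        assert np.median(ps[True]) < np.median(ps[False])


class TestConservationPanelGenerator:
    def test_rejects_k_zero(self):
        with pytest.raises(MitoburdenError):
            syn.generate_conservation_panel({100: 0})

    def test_panel_has_17_rows_human_first(self):
        panel = syn.generate_conservation_panel({5628: 16})
        assert panel.n_species == 17
        assert panel.names[0] == "human"
        ref = syn.reference_genome()
        col = panel.column_for(5628)
        assert panel.sequences[0][col] == ref[5627]


class TestTrnaFixtures:
    def test_ta_anticodon_stem_pairing(self):
        s = syn.generate_trna_fixture("MT-TA")
        p31 = next(p for p in s.positions.values() if p.number == 31)
        assert p31.region == ann.ANTICODON_STEM
        partner = s[p31.partner_pos]
        assert 39 <= partner.number <= 43

    def test_all_fixtures_validate(self, gene_map):
        for region in gene_map.genes_of_class(TRNA):
            s = syn.generate_trna_fixture(region.symbol)
            s.validate()  # mutual partners, stems only
            numbers = [p.number for p in s.positions.values()]
            assert len(numbers) == len(set(numbers)) == len(region)

    def test_numbering_monotone_along_gene_strand(self, gene_map):
        for gene in ("MT-TA", "MT-TS2", "MT-TT", "MT-TQ"):
            region = gene_map[gene]
            s = syn.generate_trna_fixture(gene)
            ordered = sorted(
                s.positions.values(), key=lambda p: region.gene_index(p.genomic_pos)
            )
            nums = [p.number for p in ordered]
            assert nums == sorted(nums)

    def test_corrupted_partner_fails_validation(self):
        s = syn.generate_trna_fixture("MT-TA")
        p31 = next(p for p in s.positions.values() if p.number == 31)
        broken = dict(s.positions)
        broken[p31.genomic_pos] = ann.TrnaPosition(
            p31.genomic_pos, p31.number, p31.region, p31.genomic_pos + 1, p31.base
        )
        with pytest.raises(MitoburdenError):
            ann.TrnaStructure("MT-TA", "L", broken.values())

    def test_structures_tsv_round_trip(self, tmp_path):
        structures = [syn.generate_trna_fixture(g) for g in ("MT-TA", "MT-TS2")]
        p = tmp_path / "structures.tsv"
        ann.write_structures_tsv(structures, p)
        back = ann.read_structures_tsv(p)
        for s in structures:
            assert back[s.gene].positions == s.positions


def test_reference_genome_is_deterministic_and_orf_clean(gene_map):
    ref = syn.reference_genome()
    assert len(ref) == 16569
    assert ref == syn.reference_genome()
    # protein genes begin with ATG on the gene strand and contain no
    # in-frame stop codon before the terminal one
    from mitoburden.model import MT_CODON_TABLE, reverse_complement

    for region in gene_map.genes_of_class("protein"):
        seq = ref[region.start - 1 : region.end]
        if region.strand == "L":
            seq = reverse_complement(seq)
        assert seq.startswith("ATG")
        n_codons = len(seq) // 3
        internal = [seq[3 * i : 3 * i + 3] for i in range(1, n_codons - 1)]
        assert not set(internal) & set(MT_CODON_TABLE.stop_codons)
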