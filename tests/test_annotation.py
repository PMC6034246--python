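"""Rating combination, conservation index, tRNA structure and verdicts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitoburden import annotation as ann
from mitoburden.model import Allele, MitoburdenError, complement
from mitoburden import synthetic as syn


class TestCombineRatings:
    @pytest.mark.parametrize(
        "triple,expected", [((2, 2, 3), 2), ((3, 3, 3), 3), ((1, 2, 3), 2), ((1, 1, 2), 1)]
    )
    def test_examples(self, triple, expected):
        assert ann.combine_ratings(triple) == expected

    def test_permutation_invariant_and_monotone(self):
        for triple in itertools.product((1, 2, 3), repeat=3):
            base = ann.combine_ratings(triple)
            for perm in itertools.permutations(triple):
                assert ann.combine_ratings(perm) == base
            bumped = tuple(min(3, t + 1) for t in triple)
            assert ann.combine_ratings(bumped) >= base

    def test_half_rule_never_triggers_for_integer_triples(self):
        # 3*mean is an integer, so an exact .5 mean is impossible: the
        # configurable rounding direction cannot change any verdict
        for triple in itertools.product((1, 2, 3), repeat=3):
            assert ann.combine_ratings(triple) == ann.combine_ratings(
                triple, rounding="half_down"
            )

    def test_invalid_rating_rejected(self):
        with pytest.raises(MitoburdenError):
            ann.combine_ratings((0, 2, 3))


class TestConservationIndex:
    def test_constructed_panel_examples(self):
        panel = syn.generate_conservation_panel({1000: 16, 1005: 17}, seed=0)
        ref = syn.reference_genome()
        assert ann.conservation_index(panel, 1000, ref[999]) == pytest.approx(94.12)
        assert ann.conservation_index(panel, 1005, ref[1004]) == pytest.approx(100.00)

    def test_random_targets_recovered_exactly(self):
        rng = np.random.default_rng(6)
        targets = {int(p): int(rng.integers(1, 18)) for p in rng.choice(2000, 30, replace=False) + 100}
        panel = syn.generate_conservation_panel(targets, seed=1)
        ref = syn.reference_genome()
        for pos, k in targets.items():
            ci = ann.conservation_index(panel, pos, ref[pos - 1])
            assert ci == pytest.approx(round(100 * k / 17, 2))

    def test_ci_values_are_multiples_of_one_seventeenth(self):
        rng = np.random.default_rng(13)
        targets = {int(p): int(rng.integers(1, 18)) for p in rng.choice(500, 20, replace=False) + 3000}
        panel = syn.generate_conservation_panel(targets, seed=2)
        ref = syn.reference_genome()
        for pos in targets:
            ci = ann.conservation_index(panel, pos, ref[pos - 1])
            assert round(ci / round(100 / 17, 10)) * 100 / 17 == pytest.approx(ci, abs=0.01)

    def test_gapped_alignment_position_mapping(self):
        # human row with a gap: genomic positions skip the gapped column
        panel = ann.ConservationPanel(
            ["AC-GT", "ACTGT", "ACAGT"], ["human", "sp1", "sp2"], human_start=10
        )
        assert panel.column_for(12) == 3  # the G after the gap
        assert ann.conservation_index(panel, 12, "G") == pytest.approx(100.0)

    def test_uncovered_position_rejected(self):
        panel = ann.ConservationPanel(["ACGT"], ["human"], human_start=10)
        with pytest.raises(MitoburdenError):
            panel.column_for(99)


class TestPanelFrequency:
    @pytest.mark.parametrize(
        "count,size,passes",
        [
            (31, 2704, False),  # 1.15% fails the < 1% criterion
            (4, 2704, True),    # 0.15% passes
            (1, 100, False),    # exactly 1.00% fails (strict)
            (0, 2704, True),
        ],
    )
    def test_threshold_is_strict(self, count, size, passes):
        assert ann.panel_frequency_check(count, size) is passes

    def test_invalid_counts_rejected(self):
        with pytest.raises(MitoburdenError):
            ann.panel_frequency_check(5, 0)


class TestStructuralAssessment:
    @pytest.mark.parametrize(
        "gene,pos,ref,alt,region,number,alteration",
        [
            ("MT-TA", 5628, "T", "C", ann.ANTICODON_STEM, 31, True),
            ("MT-TC", 5783, "G", "A", ann.T_STEM, 50, True),
            ("MT-TC", 5814, "T", "C", ann.D_STEM, 13, True),
            ("MT-TT", 15894, "G", "A", ann.ACCEPTOR_STEM, 7, True),
            ("MT-TT", 15940, "T", "C", ann.T_LOOP, 59, False),
            ("MT-TS2", 12234, "A", "G", ann.ANTICODON_STEM, 42, False),
            ("MT-TQ", 4386, "T", "C", ann.D_LOOP, 15, False),
        ],
    )
    def test_curated_positions(self, gene, pos, ref, alt, region, number, alteration):
        structure = syn.generate_trna_fixture(gene)
        call = ann.structural_assessment(Allele(pos, ref, alt), structure)
        assert call.region == region
        assert call.trna_number == number
        assert call.alteration is alteration

    def test_anticodon_loop_flagged_separately(self):
        structure = syn.generate_trna_fixture("MT-TH")
        call = ann.structural_assessment(Allele(12172, "A", "G"), structure)
        assert call.anticodon_loop is True
        assert call.alteration is False

    def test_loop_positions_never_altered(self):
        stems = ann.STEM_REGIONS
        for gene in ("MT-TA", "MT-TW", "MT-TH", "MT-TS2", "MT-TF", "MT-TP"):
            structure = syn.generate_trna_fixture(gene)
            for p in structure.positions.values():
                ref = p.base if structure.strand == "H" else complement(p.base)
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    call = ann.structural_assessment(
                        Allele(p.genomic_pos, ref, alt), structure
                    )
                    if p.region not in stems:
                        assert not call.alteration

    def test_position_absent_from_table_rejected(self):
        structure = syn.generate_trna_fixture("MT-TA")
        with pytest.raises(MitoburdenError, match="absent"):
            ann.structural_assessment(Allele(9957, "T", "C"), structure)


class TestClassifyTrna:
    def test_pathogenic_worked_example(self):
        # absent in controls, panel 0.15%, CI 94.12, stem disruption
        v = ann.classify_trna(Allele(5628, "T", "C"), True, 4, 2704, 94.12, True)
        assert v.pathogenic

    def test_low_ci_excludes(self):
        v = ann.classify_trna(Allele(12178, "C", "T"), True, 0, 2704, 64.71, True)
        assert not v.pathogenic and not v.ci_ok

    def test_panel_frequency_excludes(self):
        v = ann.classify_trna(Allele(12172, "A", "G"), True, 31, 2704, 88.24, False, True)
        assert not v.pathogenic and not v.panel_ok

    def test_equals_conjunction_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            absent = bool(rng.integers(2))
            count = int(rng.integers(0, 60))
            ci = float(rng.uniform(0, 100))
            alt = bool(rng.integers(2))
            v = ann.classify_trna(Allele(100, "A", "G"), absent, count, 2704, ci, alt)
            expected = absent and (100 * count / 2704 < 1) and (ci > 75) and alt
            assert v.pathogenic == expected

    def test_missing_inputs_name_criterion(self):
        with pytest.raises(MitoburdenError, match="criterion 1"):
            ann.classify_trna(Allele(100, "A", "G"), True, None, 2704, 90.0, True)
        with pytest.raises(MitoburdenError, match="criterion 2"):
            ann.classify_trna(Allele(100, "A", "G"), True, 3, 2704, None, True)


class TestProteinShortlist:
    def test_published_star_and_hf_inputs(self):
        # star triples chosen to combine to the printed impact levels
        records = pd.DataFrame(
            [
                {"pos": 9438, "ref": "G", "alt": "A", "polyphen": 2, "sift": 2, "pmut": 3, "hf": 42.05},
                {"pos": 9490, "ref": "C", "alt": "T", "polyphen": 2, "sift": 2, "pmut": 2, "hf": 99.23},
                {"pos": 9755, "ref": "G", "alt": "C", "polyphen": 1, "sift": 1, "pmut": 2, "hf": 99.59},
                {"pos": 9856, "ref": "T", "alt": "C", "polyphen": 2, "sift": 3, "pmut": 2, "hf": 99.71},
                {"pos": 9957, "ref": "T", "alt": "C", "polyphen": 3, "sift": 2, "pmut": 2, "hf": 99.35},
            ]
        )
        kept = ann.protein_shortlist(records)
        assert set(kept["pos"]) == {9438, 9490, 9856, 9957}

    def test_all_neutral_empty(self):
        records = pd.DataFrame(
            [{"pos": 100, "ref": "A", "alt": "G", "polyphen": 1, "sift": 1, "pmut": 1, "hf": 99.0}]
        )
        assert len(ann.protein_shortlist(records)) == 0

    def test_hf_at_threshold_excluded(self):
        records = pd.DataFrame(
            [{"pos": 100, "ref": "A", "alt": "G", "polyphen": 3, "sift": 3, "pmut": 3, "hf": 39.0}]
        )
        assert len(ann.protein_shortlist(records)) == 0
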