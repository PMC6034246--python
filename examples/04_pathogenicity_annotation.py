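"""Pathogenicity annotation: protein rating combination and the
three-criterion tRNA classifier.

Protein alleles combine three external 1-3 star verdicts by averaging and
rounding. tRNA alleles are pathogenic iff absent from controls and rare in
a 2704-genome panel, conserved (CI > 75% across 17 vertebrates), and
structurally disruptive (a broken Watson-Crick stem pair).
"""

from mitoburden import combine_ratings, conservation_index, structural_assessment
from mitoburden.annotation import classify_trna
from mitoburden.model import Allele
from mitoburden.synthetic import generate_conservation_panel, generate_trna_fixture

# -- protein: averaging-and-rounding of three tool verdicts
print("ratings (2,2,3) ->", combine_ratings((2, 2, 3)), "stars  (mean 2.33 -> 2)")
print("ratings (3,3,3) ->", combine_ratings((3, 3, 3)), "stars")

# -- tRNA: the anticodon-stem substitution m.5628 T>C in MT-TA
allele = Allele(5628, "T", "C")
structure = generate_trna_fixture("MT-TA")
call = structural_assessment(allele, structure)
print(f"\n{allele.label} sits at tRNA position {call.trna_number} "
      f"({call.region}); Watson-Crick disruption: {call.alteration}")

panel = generate_conservation_panel({5628: 16})  # 16 of 17 species wild-type
ci = conservation_index(panel, 5628, "T")
print(f"conservation index: {ci}%  (16/17 species carry the wild-type base)")

verdict = classify_trna(allele, absent_in_controls=True, panel_count=4,
                        panel_size=2704, ci=ci, alteration=call.alteration)
print(f"panel frequency 4/2704 = 0.15% (<1%): {verdict.panel_ok}")
print(f"potentially pathogenic: {verdict.pathogenic}")

# All three criteria hold, so the allele is flagged; dropping any one of
# them (common in the panel, CI <= 75%, or a loop location) clears the flag.
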