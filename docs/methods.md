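# Methods

This note documents the models, the numerical choices, what the synthetic
data emulate (and what they do not), and the design decisions taken where
the problem was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, domain model and consequence calling

All positions are 1-based inclusive on the 16,569-bp human mitochondrial
reference frame (rCRS, identical to GRCh38 chrM) and written `m.POS`. The
packaged gene map (`data/gene_map.tsv`) carries the standard 37-gene
annotation: 13 protein, 22 tRNA and 2 rRNA genes, including the real
overlaps (MT-ATP8/MT-ATP6 at 8527–8572, MT-ND4L/MT-ND4 at 10760–10766,
MT-TC/MT-TY at 5826, MT-TI/MT-TQ at 4329–4331). `assign_gene` returns every
overlapping symbol; unannotated positions are `noncoding`.

Only single-nucleotide substitutions are modelled; indel records in a VCF
are skipped with a warning. Multi-allelic sites split into independent
alleles keyed by `(pos, ref, alt)`. Light-strand genes (MT-ND6 and the
tRNAs Q, A, N, C, Y, S1, E, P) are handled on the gene strand: the
consequence caller complements the allele and reads the frame from the
genomic end of the gene, and tRNA structure logic compares gene-strand
bases. Alleles are reported in genomic orientation with the gene-strand
complement available (`m.5814T>C` ↔ gene-strand `m.5814A>G`).

Protein consequences use the vertebrate mitochondrial code (NCBI
translation table 2, via Biopython): AGA/AGG are stops, TGA is tryptophan.
Several mitochondrial ORFs end in a 3′-incomplete codon completed by
polyadenylation in vivo; a substitution in that tail raises an error rather
than guessing a codon.

## Heteroplasmy and frequency bands

HF = 100 · mutant_reads / total_reads per observation. When an allele
recurs in several samples, downstream tables report the per-observation
maximum. The metabolic threshold is strict (`HF > 40`), and the
common/low-frequency band boundary is strict in the other direction
(common iff cohort carrier frequency > 5%; exactly 5% is low-frequency).
Both thresholds are parameters. No sequencing-error model is applied to
HF estimates.

## Carrier enrichment

The counting unit is the carrier: an individual with ≥ 1 allele of a given
gene/group. Group-1 (shared) alleles are tested case vs control; group-2
(case-only) and group-3 (control-only) alleles are tested against the
structurally allele-free other cohort, which mirrors how such tables are
conventionally presented. Test selection: Pearson chi-square without
continuity correction (df = 1) when all four expected cell counts are ≥ 5,
otherwise the two-sided Fisher exact test (sum of hypergeometric point
probabilities ≤ the observed table's). This switching rule reproduces every
recomputable published enrichment p-value we checked (see
`tests/test_acceptance.py`); the expected-count cutoff is configurable. A
table with a zero-variation margin (e.g. all individuals in both cohorts
are carriers) returns p = 1. The 22 tRNA genes are pooled into one
`MT-TRNA` row in per-gene tables, since individually they carry too few
alleles to tabulate. No multiple-testing correction is applied: the
workflow is exploratory and reports raw p-values at α = 0.05.

Per-individual burden: for each region, each sample's count of distinct
alleles (0 for non-carriers) is compared between cohorts with the
Mann-Whitney U test.

## Burden-ratio partition and SKAT

The burden ratio of an allele is (case allele frequency) / (control allele
frequency), with carrier count / cohort size as the default frequency (the
unit of the enrichment tables); an HF-weighted dosage frequency is
available because heteroplasmy makes 0/1 genotypes lossy. A control
frequency of zero with nonzero case frequency gives ratio +∞ (positive);
ratio exactly 1 is negative. The test runs per gene separately on the
positive and negative sets — the stratification the supplementary tables
of the emulated study imply — and the joint-set alternative is one flag
away.

The score statistic is Q = (y − μ̂)ᵀ G W² Gᵀ (y − μ̂) with a from-scratch
IRLS logistic null fit (intercept plus optional covariates; covariates
default to none because the cohorts are age-matched). Weights are the
Beta(1, 25) density on pooled carrier frequency (flat weights optional) —
the conventional rare-variant upweighting. Null distribution: a weighted
sum of 1-df chi-squares with weights the positive eigenvalues of
(GW)ᵀ P₀ (GW), P₀ = V − VX(XᵀVX)⁻¹XᵀV, V = diag(μ̂(1−μ̂)).

Three p-value routes:

- `moment_matching` (default): moment matching onto a scaled, possibly
  non-central chi-square (mean and variance exact, skewness as close as the
  family allows). For a single eigenvalue it reduces to the exact χ²₁ tail,
  which the tests exploit as a closed-form oracle.
- `eigen`: Imhof-type numerical inversion of the characteristic function
  (`scipy.integrate.quad`, 500-interval limit).
- `permutation`: phenotype permutation against the intercept-only null
  mean, vectorised; p = (#{Q* ≥ Q} + 1)/(B + 1), B defaulting to 2000 with
  an explicit seed. With covariates the reshuffle ignores them (warned).

Zero-variance allele columns are dropped with a warning; an empty matrix
returns Q = 0, p = 1. Quasi-complete separation in the null fit (|η| > 30)
raises with guidance rather than returning an unstable fit.

Interaction: the published analysis reports gene-gene interactions without
stating a method; our interpretation — documented as such — is a score test
for the centred product of the two genes' weighted burden scores added to a
null model containing both main-effect burdens. With one tested direction
the statistic is U²/Var(U) ~ χ²₁. Genes whose burden is constant, or whose
positive alleles are entirely case-only (separation of the null fit), raise
an error; the pipeline logs and skips such pairs.

## Annotation

Protein: three external tool verdicts on a 1–3 star scale are combined by
arithmetic mean, rounded half-up (configurable to half-down; with three
integer ratings an exact half is arithmetically impossible, so the choice
never changes a verdict — property-tested). The shortlist keeps combined
rating ≥ 2 with HF > 40%. The mapping from raw external-tool output to
stars is upstream of this package: the ratings table is an input.

tRNA: the three-criterion conjunction (control-absent ∧ panel-rare ∧
conserved ∧ stem-disrupting) with thresholds 1% (strict <), CI 75%
(strict >). CI = 100 · (#rows with the human wild-type base) / 17, to two
decimals; the human alignment row must be ungapped at the assessed column.
A G·U wobble created in a stem counts as a disruption (the criterion is
*classic* Watson-Crick pairs only). An anticodon-loop location is surfaced
as a separate `anticodon_loop` flag but is not by itself an alteration: in
the emulated study the one candidate in that situation was already excluded
on panel frequency, so the question was never adjudicated, and we do not
guess. Unpaired stem positions (possible in short tRNAs that lack arms)
can never be called disruptions.

## Synthetic data: what it emulates, what it does not

`SimulationConfig` defaults are the emulated study's conditions: 52 cases
vs 104 age-matched controls; read depth ~ truncated normal(3251.22,
964.63²) on [2027, 5613] (note the observed mean of that truncated law is
≈ 3400 — the truncation is asymmetric); HF a 0.7/0.3 mixture of
uniform(95, 100) and uniform(40, 80); a population allele pool with 1/f
frequency spectrum on [1/104, 0.15] plus cohort-private injections
(pool 400, case-private 170, control-private 350), sized once to land in
the study's reported allele-count regime (hundreds of alleles per cohort,
~300 shared, a strong excess of low-frequency alleles) and then frozen.
Causal genes multiply case carriage probability by a configurable risk
ratio. Phenotype tables carry the standard clinical fields (age, uric
acid, BMI, diabetes, fasting glucose, total cholesterol, HDL, LDL,
triglycerides) with an HDL shift (default +13.8 mg/dl) for carriers of the
planted protein set.

Planted truth: four nonsynonymous MT-CO3 alleles (2 case carriers each)
and four stem-disrupting tRNA alleles in MT-TA/MT-TC/MT-TT (3 case
carriers each), absent from controls, HF in the near-homoplasmic
component. Carrier multiplicities were chosen so the planted genes carry
enough signal for the kernel test to flag them at the 52-vs-104 sample
size; with single carriers the planted genes fall below α on some seeds
and the end-to-end recovery check would measure seed luck rather than
pipeline correctness.

What the generator does **not** emulate: linkage/haplogroup structure
(alleles are carried independently), platform-specific error profiles,
read-level data, strand bias, contamination, or a genuine site-frequency
spectrum conditioned on phylogeny. Tests passing on this generator
therefore validate the statistical machinery and the plumbing, not
robustness to those real-data features.

Two bundled objects are synthetic stand-ins, labelled as such in names and
docstrings, because the genuine artefacts cannot be bundled here:

- **Reference genome** (`synthetic.reference_genome()`): deterministic
  16,569-bp sequence in which the 37-gene coordinates are the standard
  annotation, every protein gene is a stop-free ORF under translation
  table 2 (ATG start; TAA stop where the length is a codon multiple, the
  real 3′-incomplete tails otherwise), tRNA stems are Watson-Crick paired
  on the gene strand, and a curated set of clinically described positions
  carries its published reference base with the surrounding codon pinned
  to reproduce the published amino-acid change. All other bases are
  random. Real analyses should pass a real rCRS FASTA.
- **tRNA cloverleaf tables** (`synthetic.generate_trna_fixture`):
  conventional-numbering spans (acceptor stem 1–7/66–72, D-arm 10–25,
  anticodon arm 27–43 with loop 32–38, variable region 44–48, T-arm
  49–65 with loop 54–60) anchored at curated published position numbers
  for the analysed mt-tRNA positions; between anchors the index→number
  mapping is a monotone interpolation that drops loop positions first
  (where real mt-tRNAs actually vary). One curated stem pair (MT-TS2
  28:42) is deliberately non-Watson-Crick in the wild type. Pairing is
  mutual by construction; a dropped pair side leaves its partner unpaired
  rather than mispaired.

The conservation-panel generator builds an ungapped 17-row alignment
(human first) with an exact number k of wild-type rows at each requested
column (k ≥ 1 since the human row is wild-type by definition) and a 90%
per-site conservation rate elsewhere.

## Numerical and procedural choices

- Fisher two-sidedness: sum of point probabilities ≤ observed (scipy's
  convention), validated exhaustively against a log-gamma enumeration
  oracle over all tables with row margins ≤ 30.
- Mann-Whitney: exact distribution when min(n) ≤ 8 and the pooled sample
  is tie-free, otherwise the normal approximation with tie and continuity
  correction. Validated against full label-enumeration on small samples.
- Summary t-test: pooled by default; pooled and Welch agree to printed
  precision on the age-comparison check, and both are exposed.
- IRLS: tolerance 1e-10 on coefficients, max 100 iterations, divergence
  guard at |η| > 30.
- Determinism: every stochastic component takes a seed; identical seeds
  give byte-identical datasets and reports (tested). The pipeline manifest
  records seed, thresholds, package/library versions, input SHA-256
  checksums and stage timings; any stage failure removes partial outputs.
- Problem sizes in the statistical tests (e.g. 1000 null replicates for
  SKAT calibration at n = 156, 400-permutation inner loops, 40-replicate
  power comparisons, reduced-scale cohorts for the causal-gene check) are
  the package's own choice of scale: large enough for the binomial
  intervals asserted, small enough to keep the suite fast.

## Known limitations

- The interaction test is an interpretation (see above), not a published
  algorithm; treat cross-study comparisons of interaction p-values with
  care.
- Carrier-frequency burden ratios ignore HF magnitude unless the HF dosage
  option is chosen; with very deep heteroplasmy structure the two choices
  can partition alleles differently.
- The synthetic reference supports consequence calling only up to codon
  identity at pinned positions; amino-acid changes at non-curated positions
  are internally consistent but not those of the real genome.
- SKAT small-sample moment adjustments and SKAT-O are out of scope.
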