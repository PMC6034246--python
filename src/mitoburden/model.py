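"""Domain model for mitochondrial case-control variant analysis.

Coordinates are 1-based inclusive on the 16,569-bp human mitochondrial
reference (rCRS, identical to GRCh38 chrM); positions are written in the
clinical ``m.POS`` convention.  The module holds the core record types
(alleles, per-sample observations, gene regions, cohorts), readers and
writers for the tabular input formats, and the consequence caller built on
the vertebrate mitochondrial genetic code.

Light-strand (L) genes store their sequence on the gene strand: an allele is
reported both in genomic orientation (e.g. ``m.5814 T>C``) and, for L-strand
genes, as its gene-strand complement (``m.5814 A>G``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

MT_GENOME_LENGTH = 16569

NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
MT_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]

PROTEIN = "protein"
TRNA = "tRNA"
RRNA = "rRNA"
NONCODING = "noncoding"

FUNCTIONAL_CLASSES = ("synonymous", "nonsynonymous", "tRNA", "rRNA", "noncoding")


class MitoburdenError(Exception):
    """Base error for this package."""


class ValidationError(MitoburdenError):
    """A record violates a domain invariant."""


class ParseError(MitoburdenError):
    """A file could not be parsed; the message names the offending line."""


def check_position(pos: int) -> int:
    """Validate a 1-based mitochondrial genome position."""
    if not 1 <= int(pos) <= MT_GENOME_LENGTH:
        raise ValidationError(
            f"position {pos} outside the mitochondrial genome (1..{MT_GENOME_LENGTH})"
        )
    return int(pos)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Allele:
    """A single-nucleotide substitution keyed by (position, ref, alt).

    ``gene`` and ``functional_class`` are annotations filled in once a gene
    map (and, for protein genes, a reference sequence) is available; they do
    not participate in identity.
    """

    position: int
    ref: str
    alt: str
    gene: str = field(default="", compare=False)
    functional_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        check_position(self.position)
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"m.{self.position}: ref/alt must be single bases A/C/G/T, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"m.{self.position}: ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)

    @property
    def label(self) -> str:
        """Genomic-orientation label, e.g. ``m.5814T>C``."""
        return f"m.{self.position}{self.ref}>{self.alt}"

    def gene_strand_label(self, strand: str) -> str:
        """Label on the gene strand; the complement for L-strand genes."""
        if strand == "L":
            return f"m.{self.position}{complement(self.ref)}>{complement(self.alt)}"
        return self.label


@dataclass(frozen=True)
class AlleleObservation:
    """One sample's read-count evidence for one substitution."""

    sample_id: str
    allele: Allele
    mutant_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValidationError(
                f"{self.sample_id} {self.allele.label}: total_reads must be positive"
            )
        if not 0 <= self.mutant_reads <= self.total_reads:
            raise ValidationError(
                f"{self.sample_id} {self.allele.label}: mutant_reads "
                f"{self.mutant_reads} outside [0, {self.total_reads}]"
            )


@dataclass(frozen=True)
class GeneRegion:
    """One of the 37 mitochondrial genes (1-based inclusive coordinates)."""

    symbol: str
    start: int
    end: int
    strand: str  # H (heavy) or L (light)
    cls: str  # protein / tRNA / rRNA
    codon_start_offset: int = 0

    def __post_init__(self) -> None:
        check_position(self.start)
        check_position(self.end)
        if self.start > self.end:
            raise ValidationError(f"{self.symbol}: start {self.start} > end {self.end}")
        if self.strand not in ("H", "L"):
            raise ValidationError(f"{self.symbol}: strand must be H or L")
        if self.cls not in (PROTEIN, TRNA, RRNA):
            raise ValidationError(f"{self.symbol}: unknown gene class {self.cls!r}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    def gene_index(self, pos: int) -> int:
        """1-based index along the gene strand (5'->3' on the coding strand)."""
        if pos not in self:
            raise ValidationError(f"m.{pos} outside {self.symbol}")
        if self.strand == "L":
            return self.end - pos + 1
        return pos - self.start + 1


class GeneMap:
    """The 37-gene mitochondrial annotation with interval lookup."""

    def __init__(self, regions: Iterable[GeneRegion]):
        self.regions: list[GeneRegion] = sorted(regions, key=lambda r: (r.start, r.end))
        self._by_symbol = {r.symbol: r for r in self.regions}
        if len(self._by_symbol) != len(self.regions):
            raise ValidationError("duplicate gene symbols in gene map")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, symbol: str) -> GeneRegion:
        return self._by_symbol[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def genes_of_class(self, cls: str) -> list[GeneRegion]:
        return [r for r in self.regions if r.cls == cls]

    def assign_gene(self, pos: int) -> list[str]:
        """Gene symbols covering ``pos``, or ``["noncoding"]``.

        Overlapping genes (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, ...) both appear,
        ordered by start coordinate.
        """
        check_position(pos)
        hits = [r.symbol for r in self.regions if pos in r]
        return hits if hits else [NONCODING]

    def functional_class(self, pos: int) -> str:
        """Coarse class of a position: protein genes dominate overlaps."""
        hits = [r for r in self.regions if pos in r]
        if not hits:
            return NONCODING
        for cls in (PROTEIN, TRNA, RRNA):
            if any(r.cls == cls for r in hits):
                return cls
        return NONCODING

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneMap":
        df = pd.read_csv(path, sep="\t")
        required = {"symbol", "start", "end", "strand", "class"}
        if missing := required - set(df.columns):
            raise ParseError(f"{path}: gene map missing columns {sorted(missing)}")
        df = df.rename(columns={"class": "cls"})
        return cls(
            GeneRegion(row.symbol, int(row.start), int(row.end), row.strand, row.cls)
            for row in df.itertuples(index=False)
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "symbol": r.symbol,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "class": r.cls,
                }
                for r in self.regions
            ]
        ).to_csv(path, sep="\t", index=False)


def default_gene_map() -> GeneMap:
    """The packaged rCRS/GRCh38-chrM gene annotation (standard coordinates)."""
    with resources.as_file(
        resources.files("mitoburden").joinpath("data/gene_map.tsv")
    ) as p:
        return GeneMap.from_tsv(p)


@dataclass
class CohortDataset:
    """Case/control sample sets with observations, gene map and phenotypes."""

    cases: set[str]
    controls: set[str]
    observations: list[AlleleObservation]
    gene_map: GeneMap
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        overlap = self.cases & self.controls
        if overlap:
            raise ValidationError(f"samples in both cohorts: {sorted(overlap)[:5]}")
        members = self.cases | self.controls
        stray = {o.sample_id for o in self.observations} - members
        if stray:
            raise ValidationError(
                f"observations from samples outside both cohorts: {sorted(stray)[:5]}"
            )

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def cohort_of(self, sample_id: str) -> str:
        if sample_id in self.cases:
            return "case"
        if sample_id in self.controls:
            return "control"
        raise KeyError(sample_id)

    def observations_in(self, cohort: str) -> list[AlleleObservation]:
        members = self.cases if cohort == "case" else self.controls
        return [o for o in self.observations if o.sample_id in members]

    def distinct_alleles(self, cohort: str | None = None) -> set[Allele]:
        obs = self.observations if cohort is None else self.observations_in(cohort)
        return {o.allele for o in obs}

    def carriers(self, alleles: Iterable[Allele], cohort: str) -> set[str]:
        """Samples in ``cohort`` carrying >= 1 of ``alleles``."""
        keys = {a.key for a in alleles}
        members = self.cases if cohort == "case" else self.controls
        return {
            o.sample_id
            for o in self.observations
            if o.allele.key in keys and o.sample_id in members
        }

    def annotate_alleles(self, reference: str | None = None) -> None:
        """Fill gene symbol and functional class on every observation's allele.

        Protein-gene substitutions get synonymous/nonsynonymous from the
        consequence caller when a reference sequence is supplied; otherwise
        the coarse class ``protein`` is left in place.
        """
        cache: dict[tuple[int, str, str], Allele] = {}
        annotated = []
        for obs in self.observations:
            a = obs.allele
            if a.key not in cache:
                genes = self.gene_map.assign_gene(a.position)
                cls = self.gene_map.functional_class(a.position)
                if cls == PROTEIN and reference is not None:
                    region = next(
                        self.gene_map[g]
                        for g in genes
                        if self.gene_map[g].cls == PROTEIN
                    )
                    try:
                        cls = call_consequence(a, region, reference).effect
                    except ValidationError:
                        pass  # trailing partial codon: leave coarse class
                cache[a.key] = replace(
                    a, gene="/".join(genes), functional_class=cls
                )
            annotated.append(replace(obs, allele=cache[obs.allele.key]))
        self.observations = annotated


# ---------------------------------------------------------------------------
# Variant table IO

TSV_COLUMNS = ["sample", "pos", "ref", "alt", "mutant_reads", "total_reads"]


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[AlleleObservation]:
    """Read per-sample substitution observations from TSV or VCF.

    TSV dialect: header ``sample,pos,ref,alt,mutant_reads,total_reads``
    (tab- or comma-separated).  VCF dialect: any text VCF 4.x; per-sample
    mutant/total reads come from the AD field (summed over alleles for the
    depth) or, failing that, DP together with AF.  Multi-allelic records are
    split into one observation per alternate allele.  Indels and other
    non-SNV alleles are skipped with a warning (substitutions only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> list[AlleleObservation]:
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        if path.stat().st_size > 0 and path.read_text().strip():
            raise ParseError(f"{path}: could not determine the table delimiter")
        logger.warning("%s: empty variant table", path)
        return []
    if missing := set(TSV_COLUMNS) - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            allele = Allele(int(row.pos), str(row.ref), str(row.alt))
            out.append(
                AlleleObservation(
                    str(row.sample), allele, int(row.mutant_reads), int(row.total_reads)
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    if not out:
        logger.warning("%s: no observations parsed", path)
    return out


def _read_vcf(path: Path) -> list[AlleleObservation]:
    import pysam

    out: list[AlleleObservation] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
    for rec in vf:
        for sample, call in rec.samples.items():
            ad = call.get("AD")
            gt = call.get("GT")
            alts = rec.alts or ()
            for j, alt in enumerate(alts):
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in NUCLEOTIDES:
                    logger.warning(
                        "%s: skipping non-SNV record %s>%s at %s (substitutions only)",
                        path, rec.ref, alt, rec.pos,
                    )
                    continue
                if ad is not None and ad[0] is not None:
                    mutant = int(ad[j + 1])
                    total = int(sum(x for x in ad if x is not None))
                else:
                    dp = call.get("DP")
                    af = call.get("AF")
                    if dp is None or af is None:
                        if gt is None or all(g in (0, None) for g in gt):
                            continue  # non-carrier sample without depth fields
                        raise ParseError(
                            f"{path}: record at pos {rec.pos} sample {sample} "
                            "carries neither AD nor DP+AF"
                        )
                    afj = af[j] if isinstance(af, (tuple, list)) else af
                    mutant = round(int(dp) * float(afj))
                    total = int(dp)
                if mutant == 0:
                    continue  # sample does not carry this alt
                try:
                    allele = Allele(int(rec.pos), rec.ref, alt)
                    out.append(AlleleObservation(sample, allele, mutant, total))
                except ValidationError as exc:
                    raise ParseError(f"{path}: record at pos {rec.pos}: {exc}") from exc
    if not out:
        logger.warning("%s: no observations parsed", path)
    return out


def write_variant_table(
    observations: Sequence[AlleleObservation], path: str | Path
) -> None:
    """Write the TSV dialect (lossless round trip with ``read_variant_table``)."""
    pd.DataFrame(
        [
            {
                "sample": o.sample_id,
                "pos": o.allele.position,
                "ref": o.allele.ref,
                "alt": o.allele.alt,
                "mutant_reads": o.mutant_reads,
                "total_reads": o.total_reads,
            }
            for o in observations
        ],
        columns=TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: one row per sample, indexed by the ``sample`` column."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ParseError(f"{path}: phenotype table needs a 'sample' column")
    bad = [
        c
        for c in df.columns
        if c != "sample"
        and pd.api.types.is_numeric_dtype(df[c])
        and (df[c].dropna() < 0).any()
    ]
    if bad:
        raise ValidationError(f"{path}: negative values in columns {bad}")
    return df.set_index("sample")


def read_fasta_reference(path: str | Path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Consequence calling

@dataclass(frozen=True)
class Consequence:
    """Protein-level effect of a substitution in a protein-coding gene."""

    effect: str  # synonymous | nonsynonymous
    codon_number: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def amino_acid_change(self) -> str:
        """Compact p. notation, e.g. ``F251L``; ``F251`` when synonymous."""
        if self.effect == "synonymous":
            return f"{self.ref_aa}{self.codon_number}"
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


def _translate_codon(codon: str) -> str:
    if codon in MT_CODON_TABLE.stop_codons:
        return "*"
    return MT_CODON_TABLE.forward_table[codon]


def call_consequence(allele: Allele, region: GeneRegion, reference: str) -> Consequence:
    """Classify a substitution in a protein gene under translation table 2.

    The codon is read on the gene strand: for L-strand genes the genomic
    allele is complemented and the frame runs from the genomic end of the
    gene.  Several mitochondrial ORFs end in a partial codon completed by
    polyadenylation; a substitution falling in that tail raises
    ``ValidationError``.
    """
    if region.cls != PROTEIN:
        raise ValidationError(f"{region.symbol} is not a protein-coding gene")
    if allele.position not in region:
        raise ValidationError(f"{allele.label} outside {region.symbol}")
    if len(reference) != MT_GENOME_LENGTH:
        raise ValidationError(
            f"reference length {len(reference)} != {MT_GENOME_LENGTH}"
        )
    ref_base = reference[allele.position - 1]
    if ref_base != allele.ref:
        raise ValidationError(
            f"{allele.label}: reference has {ref_base} at m.{allele.position}"
        )

    idx = region.gene_index(allele.position) - 1 - region.codon_start_offset
    if idx < 0:
        raise ValidationError(f"{allele.label} upstream of the coding frame")
    codon_number = idx // 3 + 1
    offset_in_codon = idx % 3
    codon_start_idx = idx - offset_in_codon  # 0-based gene index of codon start

    n_full_codons = (len(region) - region.codon_start_offset) // 3
    if codon_number > n_full_codons:
        raise ValidationError(
            f"{allele.label} falls in the incomplete terminal codon of {region.symbol}"
        )

    gene_seq = reference[region.start - 1 : region.end]
    if region.strand == "L":
        gene_seq = reverse_complement(gene_seq)
    ref_codon = gene_seq[
        region.codon_start_offset + codon_start_idx : region.codon_start_offset
        + codon_start_idx
        + 3
    ]
    alt_on_gene = allele.alt if region.strand == "H" else complement(allele.alt)
    alt_codon = (
        ref_codon[:offset_in_codon] + alt_on_gene + ref_codon[offset_in_codon + 1 :]
    )
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return Consequence(effect, codon_number, ref_codon, alt_codon, ref_aa, alt_aa)
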