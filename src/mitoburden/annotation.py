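"""Pathogenicity annotation of candidate alleles (workflow steps 3a/3b).

Protein alleles: three external impact-prediction verdicts (each already on
a 1-3 star scale: 1 neutral, 2 moderate, 3 strong evidence of pathogenicity)
are combined by averaging and rounding; the shortlist keeps alleles with a
combined rating of at least 2 stars and a heteroplasmic fraction above the
metabolic threshold.

tRNA alleles are classified as potentially pathogenic iff all three criteria
hold: (1) absent from the control cohort and below 1% in a large reference
panel of mitochondrial genomes; (2) evolutionarily conserved - the
conservation index (CI), the percentage of a 17-species vertebrate orthologue
alignment carrying the human wild-type base, exceeds 75%; (3) structurally
altering - the substitution falls in a cloverleaf stem and breaks a classic
Watson-Crick pair (A-U or G-C on the gene strand).  A G.U wobble created in
a stem counts as non-Watson-Crick.  An anticodon-loop location is flagged
separately as functionally sensitive but is not by itself counted as a
structural alteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .heteroplasmy import METABOLIC_THRESHOLD_PCT
from .model import Allele, GeneRegion, MitoburdenError, complement

# Cloverleaf region vocabulary (conventional tRNA numbering).
ACCEPTOR_STEM = "acceptor stem"
D_STEM = "D-stem"
D_LOOP = "D-loop"
ANTICODON_STEM = "anticodon stem"
ANTICODON_LOOP = "anticodon loop"
VARIABLE_REGION = "variable region"
T_STEM = "T-stem"
T_LOOP = "T-loop"
CONNECTOR = "connector"
ACCEPTOR_END = "acceptor end"

STEM_REGIONS = frozenset({ACCEPTOR_STEM, D_STEM, ANTICODON_STEM, T_STEM})

#: Default thresholds of the three tRNA criteria.
PANEL_FREQUENCY_THRESHOLD_PCT = 1.0
CI_THRESHOLD_PCT = 75.0

_WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})


def is_watson_crick(base1: str, base2: str) -> bool:
    """Classic Watson-Crick pair on the gene strand (DNA alphabet, T == U)."""
    return (base1, base2) in _WC_PAIRS


# ---------------------------------------------------------------------------
# Step 3a: protein alleles

def combine_ratings(ratings: Sequence[int], rounding: str = "half_up") -> int:
    """Combine the three tool star ratings by averaging and rounding.

    The mean of the three integers is rounded to the nearest star;
    halves round up by default (``rounding='half_down'`` flips that).
    The published worked example (2, 2, 3) -> mean 2.333 -> 2 stars does not
    disambiguate halves, so the rule is configurable.
    """
    ratings = list(ratings)
    if len(ratings) != 3 or any(r not in (1, 2, 3) for r in ratings):
        raise MitoburdenError(f"ratings must be three integers in {{1,2,3}}, got {ratings}")
    mean = sum(ratings) / 3.0
    if rounding == "half_up":
        return int(np.floor(mean + 0.5))
    return int(np.ceil(mean - 0.5))


def read_ratings_table(path: str | Path) -> pd.DataFrame:
    """Starred-ratings TSV: pos, ref, alt, polyphen, sift, pmut (1-3 each)."""
    df = pd.read_csv(path, sep="\t")
    required = {"pos", "ref", "alt", "polyphen", "sift", "pmut"}
    if missing := required - set(df.columns):
        raise MitoburdenError(f"{path}: ratings table missing columns {sorted(missing)}")
    return df


def protein_shortlist(
    records: pd.DataFrame,
    min_stars: int = 2,
    hf_threshold_pct: float = METABOLIC_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Flag protein alleles with combined rating >= ``min_stars`` and HF above
    the metabolic threshold.

    ``records`` needs columns pos/ref/alt, the three tool ratings and ``hf``
    (the carrier HF in percent; for multi-carrier alleles the maximum HF).
    Returns the retained rows with a ``stars`` column added.
    """
    out = records.copy()
    out["stars"] = [
        combine_ratings((int(r.polyphen), int(r.sift), int(r.pmut)))
        for r in out.itertuples(index=False)
    ]
    keep = (out["stars"] >= min_stars) & (out["hf"] > hf_threshold_pct)
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Step 3b: conservation

class ConservationPanel:
    """A 17-row orthologue alignment (human first) with a genomic-position map.

    ``sequences`` are equal-length aligned rows; ``position_of_column`` is
    derived from the human row: alignment columns where the human row is
    ungapped are numbered by consecutive genomic positions starting at
    ``human_start``.
    """

    def __init__(self, sequences: Sequence[str], names: Sequence[str], human_start: int):
        if len({len(s) for s in sequences}) != 1:
            raise MitoburdenError("aligned sequences must have equal length")
        self.sequences = [s.upper() for s in sequences]
        self.names = list(names)
        self.human_start = human_start
        self._col_of_pos: dict[int, int] = {}
        pos = human_start
        for col, base in enumerate(self.sequences[0]):
            if base != "-":
                self._col_of_pos[pos] = col
                pos += 1

    @property
    def n_species(self) -> int:
        return len(self.sequences)

    def column_for(self, position: int) -> int:
        if position not in self._col_of_pos:
            raise MitoburdenError(f"m.{position} not covered by the alignment panel")
        return self._col_of_pos[position]

    @classmethod
    def from_fasta(cls, path: str | Path, human_start: int) -> "ConservationPanel":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([str(r.seq) for r in records], [r.id for r in records], human_start)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                fh.write(f">{name}\n{seq}\n")


def conservation_index(
    panel: ConservationPanel, position: int, wild_type_base: str
) -> float:
    """CI = 100 * (#species with the wild-type base at the column) / n_species,
    reported to two decimals."""
    col = panel.column_for(position)
    human = panel.sequences[0][col]
    if human == "-":
        raise MitoburdenError(f"human row gapped at m.{position}")
    count = sum(1 for s in panel.sequences if s[col] == wild_type_base.upper())
    return round(100.0 * count / panel.n_species, 2)


def panel_frequency_check(
    count: int, panel_size: int, threshold_pct: float = PANEL_FREQUENCY_THRESHOLD_PCT
) -> bool:
    """True iff the reference-panel allele frequency is strictly below 1%."""
    if panel_size <= 0:
        raise MitoburdenError("panel_size must be positive")
    if not 0 <= count <= panel_size:
        raise MitoburdenError(f"count {count} outside [0, {panel_size}]")
    return 100.0 * count / panel_size < threshold_pct


# ---------------------------------------------------------------------------
# Step 3b: tRNA structure

@dataclass(frozen=True)
class TrnaPosition:
    """One genomic position of a tRNA gene mapped onto the cloverleaf."""

    genomic_pos: int
    number: int  # conventional (Sprinzl-style) position number
    region: str
    partner_pos: int | None  # genomic position of the pairing partner
    base: str  # gene-strand base (DNA alphabet)


class TrnaStructure:
    """Cloverleaf mapping for one mitochondrial tRNA gene."""

    def __init__(self, gene: str, strand: str, positions: Iterable[TrnaPosition]):
        self.gene = gene
        self.strand = strand
        self.positions = {p.genomic_pos: p for p in positions}
        self.validate()

    def __getitem__(self, genomic_pos: int) -> TrnaPosition:
        if genomic_pos not in self.positions:
            raise MitoburdenError(
                f"m.{genomic_pos} absent from the {self.gene} structure table"
            )
        return self.positions[genomic_pos]

    def __contains__(self, genomic_pos: int) -> bool:
        return genomic_pos in self.positions

    def validate(self) -> None:
        """Partners, when present, must be mutual; loop partners are absent."""
        for p in self.positions.values():
            if p.partner_pos is not None:
                if p.partner_pos not in self.positions:
                    raise MitoburdenError(
                        f"{self.gene} m.{p.genomic_pos}: partner m.{p.partner_pos} "
                        "missing from the table"
                    )
                q = self.positions[p.partner_pos]
                if q.partner_pos != p.genomic_pos:
                    raise MitoburdenError(
                        f"{self.gene}: pairing m.{p.genomic_pos}<->m.{p.partner_pos} "
                        "is not mutual"
                    )
                if p.region not in STEM_REGIONS:
                    raise MitoburdenError(
                        f"{self.gene} m.{p.genomic_pos}: paired position outside a stem"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": self.gene,
                    "strand": self.strand,
                    "pos": p.genomic_pos,
                    "number": p.number,
                    "region": p.region,
                    "partner_pos": p.partner_pos if p.partner_pos is not None else 0,
                    "base": p.base,
                }
                for p in sorted(self.positions.values(), key=lambda q: q.number)
            ]
        )


def write_structures_tsv(structures: Iterable[TrnaStructure], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in structures]).to_csv(path, sep="\t", index=False)


def read_structures_tsv(path: str | Path) -> dict[str, TrnaStructure]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "strand", "pos", "number", "region", "partner_pos", "base"}
    if missing := required - set(df.columns):
        raise MitoburdenError(f"{path}: structure table missing columns {sorted(missing)}")
    out = {}
    for gene, sub in df.groupby("gene", sort=False):
        out[gene] = TrnaStructure(
            gene,
            sub["strand"].iloc[0],
            [
                TrnaPosition(
                    int(r.pos),
                    int(r.number),
                    r.region,
                    int(r.partner_pos) or None,
                    r.base,
                )
                for r in sub.itertuples(index=False)
            ],
        )
    return out


@dataclass(frozen=True)
class StructuralCall:
    """Structural placement and alteration verdict for one tRNA allele."""

    region: str
    trna_number: int
    alteration: bool
    anticodon_loop: bool


def structural_assessment(allele: Allele, structure: TrnaStructure) -> StructuralCall:
    """Does the substitution break a Watson-Crick stem pair?

    Bases are compared on the gene strand: for L-strand tRNA genes the
    genomic allele is complemented first.  ``alteration`` is True iff the
    position is stem-paired, the wild-type pair is Watson-Crick and the
    mutant pair is not.  An anticodon-loop position raises the separate
    ``anticodon_loop`` flag (functionally sensitive, but the published
    criterion counts only stem disruption as alteration).
    """
    p = structure[allele.position]
    ref_gene = allele.ref if structure.strand == "H" else complement(allele.ref)
    alt_gene = allele.alt if structure.strand == "H" else complement(allele.alt)
    if p.base != ref_gene:
        raise MitoburdenError(
            f"{structure.gene} m.{allele.position}: structure table has gene-strand "
            f"base {p.base}, allele ref implies {ref_gene}"
        )
    alteration = False
    if p.region in STEM_REGIONS and p.partner_pos is not None:
        partner = structure[p.partner_pos]
        wild_wc = is_watson_crick(p.base, partner.base)
        mut_wc = is_watson_crick(alt_gene, partner.base)
        alteration = wild_wc and not mut_wc
    return StructuralCall(p.region, p.number, alteration, p.region == ANTICODON_LOOP)


# ---------------------------------------------------------------------------
# Step 3b: combined verdict

@dataclass(frozen=True)
class TrnaVerdict:
    """The three-criterion pathogenicity call for one tRNA allele."""

    allele: Allele
    absent_in_controls: bool
    panel_ok: bool
    ci: float
    ci_ok: bool
    alteration: bool
    anticodon_loop: bool
    pathogenic: bool


def classify_trna(
    allele: Allele,
    absent_in_controls: bool,
    panel_count: int | None,
    panel_size: int,
    ci: float | None,
    alteration: bool,
    anticodon_loop: bool = False,
    ci_threshold_pct: float = CI_THRESHOLD_PCT,
    panel_threshold_pct: float = PANEL_FREQUENCY_THRESHOLD_PCT,
) -> TrnaVerdict:
    """Conjunction of the three criteria (population, conservation, structure)."""
    if panel_count is None:
        raise MitoburdenError(f"{allele.label}: missing reference-panel count (criterion 1)")
    if ci is None:
        raise MitoburdenError(f"{allele.label}: missing conservation index (criterion 2)")
    panel_ok = panel_frequency_check(panel_count, panel_size, panel_threshold_pct)
    ci_ok = ci > ci_threshold_pct
    pathogenic = bool(absent_in_controls and panel_ok and ci_ok and alteration)
    return TrnaVerdict(
        allele, absent_in_controls, panel_ok, float(ci), ci_ok, alteration,
        anticodon_loop, pathogenic,
    )
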