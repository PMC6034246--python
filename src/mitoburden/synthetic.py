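"""Synthetic cohorts and fixtures with the statistical shape the analysis assumes.

The generator emulates a two-cohort mitochondrial resequencing study: 52
cases and 104 controls by default, a population allele pool with a 1/f
frequency spectrum (hence an excess of alleles carried by < 5% of a
cohort), cohort-private alleles, bimodal heteroplasmic fractions (a
near-homoplasmic component on 95-100% and an intermediate component on
40-80%), and read depths drawn from a truncated normal with mean 3251.22,
SD 964.63 on [2027, 5613].  Planted "truth" alleles - a flagged
protein-gene set and Watson-Crick-disrupting tRNA alleles absent from
controls - let every downstream stage be exercised and verified end to end.

The reference genome produced here is SYNTHETIC: the 37-gene annotation is
the standard one, protein genes are well-formed open reading frames under
the vertebrate mitochondrial code, tRNA stems are Watson-Crick paired, and
the bases at a curated set of clinically described positions match their
published reference alleles, but the remaining sequence is random.  It is a
stand-in for the real rCRS sequence, which is deliberately not bundled.

Likewise the cloverleaf tables: region spans and pairing follow the
conventional tRNA numbering (acceptor stem 1-7/66-72, D-stem 10-13/22-25,
anticodon stem 27-31/39-43, anticodon loop 32-38, variable region 44-48,
T-stem 49-53/61-65, T-loop 54-60), anchored at curated published position
numbers for the mt-tRNA positions analysed in the worked examples; between
anchors the mapping is a synthetic monotone interpolation that preferentially
drops loop positions (where real tRNAs vary in length).
"""

from __future__ import annotations

import functools
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import annotation as ann
from .model import (
    Allele,
    AlleleObservation,
    CohortDataset,
    GeneMap,
    GeneRegion,
    MitoburdenError,
    MT_GENOME_LENGTH,
    MT_CODON_TABLE,
    PROTEIN,
    TRNA,
    complement,
    default_gene_map,
    reverse_complement,
    write_variant_table,
)

_BASES = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# Conventional cloverleaf layout

CANONICAL_PAIRS: dict[int, int] = {}
for _a, _b in (
    [(i, 73 - i) for i in range(1, 8)]  # acceptor stem 1-7 : 66-72
    + [(10 + i, 25 - i) for i in range(4)]  # D-stem 10-13 : 22-25
    + [(27 + i, 43 - i) for i in range(5)]  # anticodon stem 27-31 : 39-43
    + [(49 + i, 65 - i) for i in range(5)]  # T-stem 49-53 : 61-65
):
    CANONICAL_PAIRS[_a] = _b
    CANONICAL_PAIRS[_b] = _a


def region_of_number(n: int) -> str:
    """Cloverleaf region of a conventional tRNA position number."""
    if 1 <= n <= 7 or 66 <= n <= 72:
        return ann.ACCEPTOR_STEM
    if n in (8, 9, 26):
        return ann.CONNECTOR
    if 10 <= n <= 13 or 22 <= n <= 25:
        return ann.D_STEM
    if 14 <= n <= 21:
        return ann.D_LOOP
    if 27 <= n <= 31 or 39 <= n <= 43:
        return ann.ANTICODON_STEM
    if 32 <= n <= 38:
        return ann.ANTICODON_LOOP
    if 44 <= n <= 48:
        return ann.VARIABLE_REGION
    if 49 <= n <= 53 or 61 <= n <= 65:
        return ann.T_STEM
    if 54 <= n <= 60:
        return ann.T_LOOP
    return ann.ACCEPTOR_END  # discriminator and any 3' tail


#: Drop preference when a gene is shorter than the canonical numbering:
#: loop and linker numbers go first (real mt-tRNAs vary there), stems last.
_DROP_RANK = {
    ann.D_LOOP: 0,
    ann.VARIABLE_REGION: 1,
    ann.T_LOOP: 2,
    ann.CONNECTOR: 3,
    ann.ANTICODON_LOOP: 4,
    ann.D_STEM: 5,
}

#: Curated conventional-numbering anchors (genomic position -> number) for
#: the mt-tRNA positions used in the worked examples; from published
#: structural annotations of the human mitochondrial tRNAs.
TRNA_NUMBER_ANCHORS: dict[str, dict[int, int]] = {
    "MT-TQ": {4386: 15},
    "MT-TW": {5528: 18, 5557: 48, 5563: 55},
    "MT-TA": {5601: 59, 5628: 31},
    "MT-TC": {5783: 50, 5814: 13},
    "MT-TH": {12172: 38, 12178: 44},
    "MT-TS2": {12234: 42, 12239: 48, 12248: 57},
    "MT-TT": {15894: 7, 15940: 59},
}

#: Reference (genomic-strand) bases at curated clinically described
#: positions; the synthetic genome is pinned to these.
ANCHOR_REF_BASES: dict[int, str] = {
    4386: "T", 5528: "T", 5557: "T", 5563: "G", 5601: "C", 5628: "T",
    5783: "G", 5814: "T", 9438: "G", 9490: "C", 9755: "G", 9856: "T",
    9957: "T", 12172: "A", 12178: "C", 12234: "A", 12239: "C", 12248: "A",
    15894: "G", 15940: "T",
}

#: Protein-gene codon pins (gene, codon number) -> codon, chosen so the
#: curated substitutions above produce their described amino-acid changes.
_CODON_PINS: dict[tuple[str, int], str] = {
    ("MT-CO3", 78): "GGC",   # m.9438 G>A -> G78S
    ("MT-CO3", 95): "GCT",   # m.9490 C>T -> A95V
    ("MT-CO3", 183): "GAG",  # m.9755 G>C -> E183D
    ("MT-CO3", 217): "ATC",  # m.9856 T>C -> I217T
    ("MT-CO3", 251): "TTC",  # m.9957 T>C -> F251L
}

#: Stem pairs deliberately left non-Watson-Crick in the synthetic genome
#: (gene, lower number): mirrors stems that are mismatched in the real
#: molecule, so a substitution there does not count as an alteration.
_NON_WC_STEM_PAIRS = {("MT-TS2", 28)}


def _assign_numbers(n: int, anchors: Mapping[int, int]) -> dict[int, int]:
    """Monotone gene-index -> conventional-number assignment through anchors.

    ``anchors`` maps gene-strand indices (1-based) to conventional numbers.
    Between anchors, surplus numbers are dropped by region preference
    (loops first); the gene end extends past 72 when the 3' tail needs it.
    """
    pts = dict(anchors)
    pts.setdefault(1, 1)
    last_idx = max(pts)
    last_num = pts[last_idx]
    if n not in pts:
        pts[n] = max(72, last_num + (n - last_idx))
    items = sorted(pts.items())
    for (i0, n0), (i1, n1) in zip(items, items[1:]):
        if n1 - n0 < i1 - i0:
            raise MitoburdenError(
                f"infeasible numbering: indices {i0}..{i1} need more numbers "
                f"than {n0}..{n1} provides"
            )
    out: dict[int, int] = {}
    for (i0, n0), (i1, n1) in zip(items, items[1:]):
        out[i0] = n0
        avail = list(range(n0 + 1, n1))
        need = i1 - i0 - 1
        drop = len(avail) - need
        if drop > 0:
            by_pref = sorted(avail, key=lambda x: (_DROP_RANK.get(region_of_number(x), 9), x))
            dropped = set(by_pref[:drop])
            avail = [x for x in avail if x not in dropped]
        for k, num in enumerate(avail, start=1):
            out[i0 + k] = num
    out[items[-1][0]] = items[-1][1]
    return out


def generate_trna_fixture(
    gene: str,
    gene_map: GeneMap | None = None,
    reference: str | None = None,
) -> ann.TrnaStructure:
    """Cloverleaf structure table for one mitochondrial tRNA gene.

    Bases are taken from the (synthetic by default) reference on the gene
    strand; the index-to-number mapping is anchored at the curated positions
    and interpolated elsewhere (see the module docstring).
    """
    gene_map = gene_map or default_gene_map()
    region = gene_map[gene]
    if region.cls != TRNA:
        raise MitoburdenError(f"{gene} is not a tRNA gene")
    if reference is None:
        reference = reference_genome()
    n = len(region)
    anchors_genomic = TRNA_NUMBER_ANCHORS.get(gene, {})
    anchors = {region.gene_index(pos): num for pos, num in anchors_genomic.items()}
    numbering = _assign_numbers(n, anchors)
    pos_of_number = {}
    for idx, num in numbering.items():
        gpos = region.end - idx + 1 if region.strand == "L" else region.start + idx - 1
        pos_of_number[num] = gpos
    positions = []
    for idx, num in sorted(numbering.items()):
        gpos = region.end - idx + 1 if region.strand == "L" else region.start + idx - 1
        partner_num = CANONICAL_PAIRS.get(num)
        partner_pos = pos_of_number.get(partner_num) if partner_num else None
        base = reference[gpos - 1]
        if region.strand == "L":
            base = complement(base)
        positions.append(ann.TrnaPosition(gpos, num, region_of_number(num), partner_pos, base))
    return ann.TrnaStructure(gene, region.strand, positions)


def all_trna_fixtures(
    gene_map: GeneMap | None = None, reference: str | None = None
) -> dict[str, ann.TrnaStructure]:
    gene_map = gene_map or default_gene_map()
    reference = reference or reference_genome()
    return {
        r.symbol: generate_trna_fixture(r.symbol, gene_map, reference)
        for r in gene_map.genes_of_class(TRNA)
    }


# ---------------------------------------------------------------------------
# Synthetic reference genome

_STOP_CODONS = set(MT_CODON_TABLE.stop_codons)
_SAFE_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in _STOP_CODONS and c != "ATG"
)


@functools.lru_cache(maxsize=1)
def reference_genome() -> str:
    """Deterministic synthetic 16,569-bp mitochondrial reference (see module
    docstring for exactly which features are realistic and which are random)."""
    rng = np.random.default_rng(16569)
    seq = rng.choice(_BASES, size=MT_GENOME_LENGTH)
    gene_map = default_gene_map()

    # Protein genes: ATG start, stop-free body, TAA stop when in frame;
    # several real mitochondrial ORFs end in a 3'-incomplete codon, which the
    # length of the annotation reproduces.
    for region in gene_map.genes_of_class(PROTEIN):
        n = len(region)
        n_codons, tail = divmod(n, 3)
        body = rng.choice(_SAFE_CODONS, size=max(n_codons - 2, 0))
        parts = ["ATG", *body]
        if n_codons >= 2:
            parts.append("TAA" if tail == 0 else rng.choice(_SAFE_CODONS))
        gene_seq = "".join(parts) + "TA"[:tail]
        if region.strand == "L":
            gene_seq = reverse_complement(gene_seq)
        seq[region.start - 1 : region.end] = list(gene_seq)

    for (gene, codon_number), codon in _CODON_PINS.items():
        region = gene_map[gene]
        start = region.start + 3 * (codon_number - 1)
        seq[start - 1 : start + 2] = list(codon)

    for pos, base in ANCHOR_REF_BASES.items():
        seq[pos - 1] = base

    # tRNA stems: make canonical pairs Watson-Crick on the gene strand,
    # holding anchored bases fixed and honouring deliberate mismatches.
    anchored = set(ANCHOR_REF_BASES)
    ref_str = "".join(seq)
    for region in gene_map.genes_of_class(TRNA):
        structure = generate_trna_fixture(region.symbol, gene_map, ref_str)
        for p in structure.positions.values():
            if p.partner_pos is None or p.partner_pos < p.genomic_pos:
                continue
            low, high = p.genomic_pos, p.partner_pos
            if (region.symbol, min(p.number, structure[high].number)) in _NON_WC_STEM_PAIRS:
                # force a wild-type mismatch: identical genomic bases give
                # identical gene-strand bases on either strand orientation
                src, tgt = (high, low) if high in anchored else (low, high)
                if tgt not in anchored:
                    seq[tgt - 1] = seq[src - 1]
                continue
            # choose which side to adjust: never overwrite an anchored base
            if low in anchored and high in anchored:
                continue
            src, tgt = (high, low) if (high in anchored and low not in anchored) else (low, high)
            if tgt in anchored:
                continue
            # gene-strand WC complement maps to plain complement in genomic
            # coordinates for both strand orientations
            seq[tgt - 1] = complement(seq[src - 1])
    return "".join(seq)


def write_reference_fasta(path: str | Path, name: str = "chrM_synthetic") -> None:
    ref = reference_genome()
    with open(path, "w") as fh:
        fh.write(f">{name} synthetic mitochondrial reference\n")
        for i in range(0, len(ref), 70):
            fh.write(ref[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Conservation panel

_SPECIES = [
    "human", "chimpanzee", "gorilla", "orangutan", "macaque", "marmoset",
    "mouse", "rat", "rabbit", "dog", "cat", "cow", "pig", "horse",
    "opossum", "chicken", "zebrafish",
]


def generate_conservation_panel(
    ci_targets: Mapping[int, int],
    reference: str | None = None,
    flank: int = 5,
    conserved_rate: float = 0.9,
    seed: int = 0,
) -> ann.ConservationPanel:
    """17-row orthologue alignment with exact conservation at target columns.

    ``ci_targets`` maps genomic positions to k, the number of species (out
    of 17, human included) carrying the human wild-type base there; the
    conservation index recovers 100*k/17 exactly.  k must be >= 1 since the
    human row always carries the wild type.  Off-target columns are
    conserved at ``conserved_rate`` per species.  The panel is ungapped.
    """
    if not ci_targets:
        raise MitoburdenError("ci_targets must be non-empty")
    if any(not 1 <= k <= 17 for k in ci_targets.values()):
        raise MitoburdenError("each CI target k must lie in 1..17 (human is always wild-type)")
    reference = reference or reference_genome()
    rng = np.random.default_rng(seed)
    start = max(1, min(ci_targets) - flank)
    end = min(MT_GENOME_LENGTH, max(ci_targets) + flank)
    human = reference[start - 1 : end]
    rows = [human]
    n_cols = len(human)
    for _ in _SPECIES[1:]:
        row = np.array(list(human))
        mutate = rng.random(n_cols) > conserved_rate
        other = rng.choice(_BASES, size=n_cols)
        clash = other == row
        other[clash] = np.array([_BASES[(list(_BASES).index(b) + 1) % 4] for b in other[clash]])
        row[mutate] = other[mutate]
        rows.append("".join(row))
    # pin exact counts at target columns
    rows = [list(r) for r in rows]
    for pos, k in ci_targets.items():
        col = pos - start
        wt = human[col]
        order = rng.permutation(16) + 1  # non-human rows
        for rank, i in enumerate(order):
            if rank < k - 1:
                rows[i][col] = wt
            else:
                alt = _BASES[(list(_BASES).index(wt) + 1 + rank % 3) % 4]
                rows[i][col] = alt if alt != wt else complement(wt)
    return ann.ConservationPanel(["".join(r) for r in rows], _SPECIES, human_start=start)


# ---------------------------------------------------------------------------
# Cohort simulation

@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the emulated study: 52 cases vs 104 controls, a 1/f
    population frequency spectrum dominated by low-frequency alleles,
    bimodal heteroplasmic fractions, truncated-normal read depth
    (mean 3251.22, SD 964.63, range 2027-5613), and planted pathogenic
    protein and tRNA allele sets carried only by cases.
    """

    n_cases: int = 52
    n_controls: int = 104
    n_pool_alleles: int = 400
    n_private_case: int = 170
    n_private_control: int = 350
    freq_min: float | None = None  # default 1/n_controls
    freq_max: float = 0.15
    private_rate_range: tuple[float, float] = (0.01, 0.05)
    hf_weights: tuple[float, float] = (0.7, 0.3)
    hf_homoplasmic: tuple[float, float] = (95.0, 100.0)
    hf_intermediate: tuple[float, float] = (40.0, 80.0)
    depth_mean: float = 3251.22
    depth_sd: float = 964.63
    depth_range: tuple[float, float] = (2027.0, 5613.0)
    causal_genes: dict = field(default_factory=dict)  # gene -> case risk ratio
    plant_protein_pathogenic: bool = True
    plant_trna_pathogenic: bool = True
    # case carriers per planted allele: enough signal for the kernel test to
    # flag the planted genes at the 52-vs-104 sample size
    planted_protein_carriers: int = 2
    planted_trna_carriers: int = 3
    hdl_carrier_shift: float = 13.8
    panel_size: int = 2704
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.hf_weights) - 1.0) > 1e-9:
            raise MitoburdenError("HF mixture weights must sum to 1")
        total = self.n_pool_alleles + self.n_private_case + self.n_private_control + 8
        if total > MT_GENOME_LENGTH:
            raise MitoburdenError("allele rates imply more sites than the genome holds")


#: Planted flagged protein alleles (case-only, nonsynonymous in the
#: synthetic reference by construction).
PLANTED_PROTEIN_ALLELES = (
    Allele(9438, "G", "A"),
    Allele(9490, "C", "T"),
    Allele(9856, "T", "C"),
    Allele(9957, "T", "C"),
)

#: Planted pathogenic tRNA alleles (stem Watson-Crick disruptions).
PLANTED_TRNA_ALLELES = (
    Allele(5628, "T", "C"),
    Allele(5783, "G", "A"),
    Allele(5814, "T", "C"),
    Allele(15894, "G", "A"),
)


def _draw_depths(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    lo, hi = cfg.depth_range
    a = (lo - cfg.depth_mean) / cfg.depth_sd
    b = (hi - cfg.depth_mean) / cfg.depth_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.depth_mean, scale=cfg.depth_sd, size=size, random_state=rng
    )


def _draw_hf(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    comp = rng.random(size) < cfg.hf_weights[0]
    lo_h, hi_h = cfg.hf_homoplasmic
    lo_i, hi_i = cfg.hf_intermediate
    return np.where(
        comp,
        rng.uniform(lo_h, hi_h, size),
        rng.uniform(lo_i, hi_i, size),
    )


def generate_cohort(cfg: SimulationConfig) -> tuple[CohortDataset, dict]:
    """Simulate a complete case-control cohort plus a truth record.

    Identical seeds give identical datasets.  The truth record names the
    planted allele sets, the causal genes and the seed; it is meant to be
    stored alongside outputs, never consumed by the analysis itself.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_map = default_gene_map()
    reference = reference_genome()
    cases = [f"case{j:03d}" for j in range(1, cfg.n_cases + 1)]
    controls = [f"ctrl{j:03d}" for j in range(1, cfg.n_controls + 1)]

    planted_positions = {a.position for a in PLANTED_PROTEIN_ALLELES + PLANTED_TRNA_ALLELES}
    available = np.setdiff1d(
        np.arange(1, MT_GENOME_LENGTH + 1), np.fromiter(planted_positions, int)
    )
    n_sites = cfg.n_pool_alleles + cfg.n_private_case + cfg.n_private_control
    sites = rng.choice(available, size=n_sites, replace=False)

    def make_allele(pos: int) -> Allele:
        ref = reference[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return Allele(int(pos), ref, str(alt))

    alleles = [make_allele(p) for p in sites]
    pool = alleles[: cfg.n_pool_alleles]
    private_case = alleles[cfg.n_pool_alleles : cfg.n_pool_alleles + cfg.n_private_case]
    private_ctrl = alleles[cfg.n_pool_alleles + cfg.n_private_case :]

    fmin = cfg.freq_min if cfg.freq_min is not None else 1.0 / cfg.n_controls
    # 1/f spectrum: inverse-CDF sampling of density proportional to 1/f
    u = rng.random(len(pool))
    pool_freq = fmin * (cfg.freq_max / fmin) ** u
    lo, hi = cfg.private_rate_range
    case_rate = rng.uniform(lo, hi, len(private_case))
    ctrl_rate = rng.uniform(lo, hi, len(private_ctrl))

    def risk_multiplier(allele: Allele) -> float:
        for gene, rr in cfg.causal_genes.items():
            if gene in gene_map.assign_gene(allele.position):
                return float(rr)
        return 1.0

    carried: dict[str, set[tuple]] = {s: set() for s in cases + controls}

    def scatter(allele: Allele, p_case: float, p_ctrl: float) -> None:
        for s in cases:
            if rng.random() < min(p_case, 0.95):
                carried[s].add(allele.key)
        for s in controls:
            if rng.random() < min(p_ctrl, 0.95):
                carried[s].add(allele.key)

    for allele, f in zip(pool, pool_freq):
        scatter(allele, f * risk_multiplier(allele), f)
    for allele, r in zip(private_case, case_rate):
        scatter(allele, r * risk_multiplier(allele), 0.0)
    for allele, r in zip(private_ctrl, ctrl_rate):
        scatter(allele, 0.0, r)

    allele_by_key = {a.key: a for a in alleles}

    truth: dict = {"seed": cfg.seed, "causal_genes": dict(cfg.causal_genes)}

    def plant(alleles: tuple[Allele, ...], carriers_per_allele: int) -> set[str]:
        carriers: set[str] = set()
        for allele in alleles:
            chosen = rng.choice(cfg.n_cases, size=carriers_per_allele, replace=False)
            for ci in chosen:
                carried[cases[ci]].add(allele.key)
                carriers.add(cases[ci])
            allele_by_key[allele.key] = allele
        return carriers

    if cfg.plant_protein_pathogenic:
        who = plant(PLANTED_PROTEIN_ALLELES, cfg.planted_protein_carriers)
        truth["protein_pathogenic"] = [a.label for a in PLANTED_PROTEIN_ALLELES]
        truth["protein_carriers"] = sorted(who)
    if cfg.plant_trna_pathogenic:
        who = plant(PLANTED_TRNA_ALLELES, cfg.planted_trna_carriers)
        truth["trna_pathogenic"] = [a.label for a in PLANTED_TRNA_ALLELES]
        truth["trna_carriers"] = sorted(who)

    # every sample carries at least one allele (take the commonest pool allele)
    fallback = pool[int(np.argmax(pool_freq))]
    for s, keys in carried.items():
        if not keys:
            keys.add(fallback.key)

    planted_keys = {a.key for a in PLANTED_PROTEIN_ALLELES + PLANTED_TRNA_ALLELES}
    pairs = [(s, key) for s in cases + controls for key in sorted(carried[s])]
    depths = np.round(_draw_depths(cfg, rng, len(pairs))).astype(int)
    hfs = _draw_hf(cfg, rng, len(pairs))
    planted_mask = np.array([key in planted_keys for _, key in pairs])
    # planted alleles sit in the near-homoplasmic component, above the 40% threshold
    hfs[planted_mask] = rng.uniform(*cfg.hf_homoplasmic, size=int(planted_mask.sum()))
    observations = []
    for (s, key), depth, hf in zip(pairs, depths, hfs):
        mutant = int(np.clip(round(int(depth) * float(hf) / 100.0), 1, int(depth)))
        observations.append(AlleleObservation(s, allele_by_key[key], mutant, int(depth)))

    phen = _generate_phenotypes(cfg, rng, cases, controls, carried, truth)
    dataset = CohortDataset(set(cases), set(controls), observations, gene_map, phen)
    dataset.annotate_alleles(reference)
    return dataset, truth


def _generate_phenotypes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    cases: Sequence[str],
    controls: Sequence[str],
    carried: Mapping[str, set],
    truth: Mapping,
) -> pd.DataFrame:
    """Clinical variables with a configurable HDL shift for flagged carriers."""
    flagged = {a.key for a in PLANTED_PROTEIN_ALLELES} if cfg.plant_protein_pathogenic else set()
    rows = []
    for s in list(cases) + list(controls):
        is_case = s in set(cases)
        carrier = bool(carried[s] & flagged)
        rows.append(
            {
                "sample": s,
                "age": max(20.0, rng.normal(51.6, 10.8)),
                "uric_acid": max(1.0, rng.normal(7.7 if is_case else 6.2, 1.6)),
                "bmi": max(15.0, rng.normal(26.7, 3.7)),
                "diabetes": int(rng.random() < 0.07),
                "fasting_glucose": max(50.0, rng.normal(99.9, 19.3)),
                "total_cholesterol": max(80.0, rng.normal(191.0, 40.0)),
                "hdl": max(
                    10.0,
                    rng.normal(47.2, 12.6) + (cfg.hdl_carrier_shift if carrier else 0.0),
                ),
                "ldl": max(30.0, rng.normal(119.5, 38.8)),
                "triglycerides": max(30.0, rng.normal(159.0, 100.0)),
            }
        )
    return pd.DataFrame(rows).set_index("sample").round(2)


# ---------------------------------------------------------------------------
# Auxiliary input tables

def generate_ratings_table(
    dataset: CohortDataset, rng_seed: int = 0
) -> pd.DataFrame:
    """Starred tool-verdict table for every nonsynonymous allele.

    Planted flagged alleles get ratings that combine to >= 2 stars; the
    rest draw mostly neutral triples, mimicking external predictor output.
    """
    rng = np.random.default_rng(rng_seed)
    planted = {a.key for a in PLANTED_PROTEIN_ALLELES}
    rows = []
    for allele in sorted(dataset.distinct_alleles()):
        if allele.functional_class != "nonsynonymous":
            continue
        if allele.key in planted:
            options = [(2, 2, 3), (2, 3, 2), (3, 2, 2), (3, 3, 3)]
            trio = options[int(rng.integers(len(options)))]
        else:
            trio = rng.choice([1, 2], size=3, p=[0.9, 0.1])
        rows.append(
            {
                "pos": allele.position, "ref": allele.ref, "alt": allele.alt,
                "polyphen": int(trio[0]), "sift": int(trio[1]), "pmut": int(trio[2]),
            }
        )
    return pd.DataFrame(rows)


def generate_panel_counts(
    dataset: CohortDataset, panel_size: int = 2704, rng_seed: int = 0
) -> pd.DataFrame:
    """Reference-panel allele counts (emulating a 2704-genome lookup).

    Planted pathogenic tRNA alleles are rare in the panel (< 1%); other
    alleles draw counts from a geometric-tailed distribution so a minority
    exceed the 1% criterion.
    """
    rng = np.random.default_rng(rng_seed)
    planted = {a.key for a in PLANTED_TRNA_ALLELES}
    rows = []
    for allele in sorted(dataset.distinct_alleles()):
        if allele.functional_class != TRNA:
            continue
        if allele.key in planted:
            count = int(rng.integers(0, 12))  # <= 0.44% of 2704
        else:
            count = int(min(rng.geometric(0.08) - 1, panel_size))
        rows.append(
            {
                "pos": allele.position, "ref": allele.ref, "alt": allele.alt,
                "count": count, "panel_size": panel_size,
            }
        )
    return pd.DataFrame(rows)


def generate_panel_for_dataset(
    dataset: CohortDataset, rng_seed: int = 0
) -> ann.ConservationPanel:
    """Conservation panel covering every tRNA allele in the dataset.

    Planted pathogenic alleles are highly conserved (16-17 of 17 species
    wild-type); other positions draw k uniformly from 7..17.
    """
    rng = np.random.default_rng(rng_seed)
    planted = {a.key for a in PLANTED_TRNA_ALLELES}
    targets = {}
    for allele in sorted(dataset.distinct_alleles()):
        if allele.functional_class != TRNA:
            continue
        if allele.key in planted:
            targets[allele.position] = int(rng.choice([16, 17]))
        else:
            targets[allele.position] = int(rng.integers(7, 18))
    return generate_conservation_panel(targets, seed=rng_seed)


def write_vcf(
    dataset: CohortDataset, path: str | Path, reference_name: str = "chrM"
) -> None:
    """Minimal multi-sample VCF 4.2 with GT:AD:DP per sample."""
    samples = sorted(dataset.cases) + sorted(dataset.controls)
    by_site: dict[tuple, dict[str, AlleleObservation]] = {}
    for o in dataset.observations:
        by_site.setdefault(o.allele.key, {})[o.sample_id] = o
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference_name},length={MT_GENOME_LENGTH}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (pos, ref, alt), obs_map in sorted(by_site.items()):
            cells = []
            for s in samples:
                o = obs_map.get(s)
                if o is None:
                    cells.append("0:.:.")
                else:
                    ref_reads = o.total_reads - o.mutant_reads
                    cells.append(f"1:{ref_reads},{o.mutant_reads}:{o.total_reads}")
            fh.write(
                f"{reference_name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP\t"
                + "\t".join(cells) + "\n"
            )


def write_all_inputs(
    dataset: CohortDataset, truth: Mapping, outdir: str | Path, cfg: SimulationConfig | None = None
) -> dict[str, Path]:
    """Write every pipeline input format plus the truth record; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants_tsv": outdir / "variants.tsv",
        "variants_vcf": outdir / "variants.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "samples": outdir / "samples.tsv",
        "reference": outdir / "reference_synthetic.fasta",
        "gene_map": outdir / "gene_map.tsv",
        "ratings": outdir / "ratings.tsv",
        "panel_counts": outdir / "panel_counts.tsv",
        "conservation": outdir / "conservation_panel.fasta",
        "structures": outdir / "trna_structures_synthetic.tsv",
        "truth": outdir / "truth.json",
    }
    write_variant_table(dataset.observations, paths["variants_tsv"])
    write_vcf(dataset, paths["variants_vcf"])
    dataset.phenotypes.reset_index().to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        {"sample": sorted(dataset.cases) + sorted(dataset.controls)}
    ).assign(cohort=lambda d: ["case" if s in dataset.cases else "control" for s in d["sample"]]).to_csv(
        paths["samples"], sep="\t", index=False
    )
    write_reference_fasta(paths["reference"])
    dataset.gene_map.to_tsv(paths["gene_map"])
    seed = truth.get("seed", 0)
    generate_ratings_table(dataset, rng_seed=seed).to_csv(paths["ratings"], sep="\t", index=False)
    generate_panel_counts(dataset, rng_seed=seed).to_csv(paths["panel_counts"], sep="\t", index=False)
    panel = generate_panel_for_dataset(dataset, rng_seed=seed)
    panel.to_fasta(paths["conservation"])
    (outdir / "conservation_panel.start").write_text(str(panel.human_start) + "\n")
    ann.write_structures_tsv(all_trna_fixtures(dataset.gene_map).values(), paths["structures"])
    paths["truth"].write_text(json.dumps(dict(truth), indent=2) + "\n")
    return paths
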