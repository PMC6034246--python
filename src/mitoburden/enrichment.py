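"""Allele grouping and carrier-enrichment testing (workflow step 1).

Every distinct substitution (keyed by position/ref/alt) is placed in one of
three groups by where it is seen: shared by both cohorts (group 1), cases
only (group 2), controls only (group 3).  Per gene and group, the unit of
counting is the *carrier* - an individual with at least one allele of that
gene/group - and enrichment is tested on the 2x2 carrier table with Pearson
chi-square (no continuity correction) when all expected cell counts reach 5,
and the two-sided Fisher exact test otherwise.  This switching rule
reproduces every recomputable published enrichment P-value we checked, and
is configurable.

The 22 tRNA genes are pooled into a single ``MT-TRNA`` row, matching the
aggregation used in the published per-gene tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Allele, CohortDataset, MitoburdenError, TRNA
from .phenotype import compare_phenotype

G1_SHARED = "G1_shared"
G2_CASE_ONLY = "G2_case_only"
G3_CONTROL_ONLY = "G3_control_only"
GROUPS = (G1_SHARED, G2_CASE_ONLY, G3_CONTROL_ONLY)

CHI_SQUARE = "chi_square"
FISHER_EXACT = "fisher_exact"

#: Pooled label for the 22 tRNA genes in per-gene tables.
TRNA_POOL = "MT-TRNA"


@dataclass(frozen=True)
class GroupedAllele:
    """A distinct allele with its sharing group and cohort carrier counts."""

    allele: Allele
    group: str
    case_carriers: int
    control_carriers: int

    def __post_init__(self) -> None:
        if self.group == G2_CASE_ONLY and self.control_carriers != 0:
            raise MitoburdenError(f"{self.allele.label}: case-only allele with control carriers")
        if self.group == G3_CONTROL_ONLY and self.case_carriers != 0:
            raise MitoburdenError(f"{self.allele.label}: control-only allele with case carriers")
        if self.group == G1_SHARED and (self.case_carriers == 0 or self.control_carriers == 0):
            raise MitoburdenError(f"{self.allele.label}: shared allele missing a cohort")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 carrier-table test for one gene/group."""

    gene: str
    group: str
    k_case: int
    n_case: int
    k_ctrl: int
    n_ctrl: int
    statistic: float | None
    p_value: float
    method: str


def assign_groups(dataset: CohortDataset) -> list[GroupedAllele]:
    """Partition distinct alleles into shared / case-only / control-only."""
    case_carr: dict[tuple, set[str]] = {}
    ctrl_carr: dict[tuple, set[str]] = {}
    alleles: dict[tuple, Allele] = {}
    for obs in dataset.observations:
        k = obs.allele.key
        alleles.setdefault(k, obs.allele)
        if obs.sample_id in dataset.cases:
            case_carr.setdefault(k, set()).add(obs.sample_id)
        else:
            ctrl_carr.setdefault(k, set()).add(obs.sample_id)
    out = []
    for k, allele in sorted(alleles.items()):
        nc = len(case_carr.get(k, ()))
        nn = len(ctrl_carr.get(k, ()))
        if nc and nn:
            group = G1_SHARED
        elif nc:
            group = G2_CASE_ONLY
        else:
            group = G3_CONTROL_ONLY
        out.append(GroupedAllele(allele, group, nc, nn))
    return out


def group_sizes(grouped: Iterable[GroupedAllele]) -> dict[str, int]:
    sizes = {g: 0 for g in GROUPS}
    for ga in grouped:
        sizes[ga.group] += 1
    return sizes


def carrier_enrichment_test(
    k_case: int,
    n_case: int,
    k_ctrl: int,
    n_ctrl: int,
    gene: str = "",
    group: str = "",
    min_expected: float = 5.0,
) -> EnrichmentResult:
    """Test a 2x2 carrier table [[k_case, n_case-k_case], [k_ctrl, n_ctrl-k_ctrl]].

    Pearson chi-square (df=1, no Yates correction) when every expected cell
    count is at least ``min_expected``; otherwise the two-sided Fisher exact
    test (sum of hypergeometric point probabilities not exceeding the
    observed table's).
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise MitoburdenError("both cohorts must be non-empty")
    if not (0 <= k_case <= n_case and 0 <= k_ctrl <= n_ctrl):
        raise MitoburdenError("carrier counts outside cohort sizes")
    table = np.array([[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected >= min_expected).all():
        if expected.min() == 0:  # a margin is zero: no variation to test
            stat, p = 0.0, 1.0
        else:
            stat = float((np.square(table - expected) / expected).sum())
            p = float(stats.chi2.sf(stat, df=1))
        method = CHI_SQUARE
    else:
        stat_, p = stats.fisher_exact(table, alternative="two-sided")
        stat, p = None, float(p)
        method = FISHER_EXACT
    return EnrichmentResult(gene, group, k_case, n_case, k_ctrl, n_ctrl, stat, min(p, 1.0), method)


def _gene_label(allele: Allele, dataset: CohortDataset, pool_trna: bool) -> list[str]:
    """Per-gene table labels for an allele (tRNA genes pooled)."""
    genes = dataset.gene_map.assign_gene(allele.position)
    labels = []
    for g in genes:
        if g != "noncoding" and pool_trna and dataset.gene_map[g].cls == TRNA:
            labels.append(TRNA_POOL)
        else:
            labels.append(g)
    return sorted(set(labels))


def enrichment_table(
    dataset: CohortDataset,
    grouped: Sequence[GroupedAllele] | None = None,
    pool_trna: bool = True,
    include_noncoding: bool = False,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Per-gene, per-group carrier counts and enrichment tests.

    Group-1 alleles are tested case-vs-control; group-2 (case-only) and
    group-3 (control-only) alleles are tested against the structurally
    allele-free other cohort, mirroring the published table layout.
    """
    if grouped is None:
        grouped = assign_groups(dataset)
    by_key = {ga.allele.key: ga for ga in grouped}
    gene_group_alleles: dict[tuple[str, str], list[Allele]] = {}
    for ga in grouped:
        for label in _gene_label(ga.allele, dataset, pool_trna):
            if label == "noncoding" and not include_noncoding:
                continue
            gene_group_alleles.setdefault((label, ga.group), []).append(ga.allele)

    rows = []
    genes = sorted({g for g, _ in gene_group_alleles})
    for gene in genes:
        row: dict[str, object] = {"gene": gene}
        for group in GROUPS:
            alleles = gene_group_alleles.get((gene, group), [])
            k_case = len(dataset.carriers(alleles, "case"))
            k_ctrl = len(dataset.carriers(alleles, "control"))
            res = carrier_enrichment_test(
                k_case, dataset.n_cases, k_ctrl, dataset.n_controls,
                gene=gene, group=group, min_expected=min_expected,
            )
            tag = {G1_SHARED: "g1", G2_CASE_ONLY: "g2", G3_CONTROL_ONLY: "g3"}[group]
            row[f"{tag}_case_carriers"] = k_case
            row[f"{tag}_case_pct"] = round(100 * k_case / dataset.n_cases, 2)
            row[f"{tag}_ctrl_carriers"] = k_ctrl
            row[f"{tag}_ctrl_pct"] = round(100 * k_ctrl / dataset.n_controls, 2)
            row[f"{tag}_p"] = res.p_value
            row[f"{tag}_method"] = res.method
        rows.append(row)
    return pd.DataFrame(rows)


def burden_per_individual(
    dataset: CohortDataset,
    grouped: Sequence[GroupedAllele] | None = None,
    pool_trna: bool = True,
) -> pd.DataFrame:
    """Per-region allele counts per individual, compared between cohorts.

    For every gene region, each sample's count of distinct alleles is
    tallied (zero for non-carriers) and the case and control count vectors
    are compared with the Mann-Whitney U test.  Regions where neither cohort
    carries any allele are reported with the comparison skipped (p = NaN).
    """
    per_sample: dict[str, dict[str, int]] = {}
    seen: dict[str, set[tuple[str, tuple]]] = {}
    for obs in dataset.observations:
        for label in _gene_label(obs.allele, dataset, pool_trna):
            key = (label, obs.allele.key)
            if key in seen.setdefault(obs.sample_id, set()):
                continue
            seen[obs.sample_id].add(key)
            per_sample.setdefault(label, {}).setdefault(obs.sample_id, 0)
            per_sample[label][obs.sample_id] += 1

    rows = []
    for region in sorted(per_sample):
        counts = per_sample[region]
        case_counts = np.array([counts.get(s, 0) for s in sorted(dataset.cases)], float)
        ctrl_counts = np.array([counts.get(s, 0) for s in sorted(dataset.controls)], float)
        if case_counts.sum() == 0 and ctrl_counts.sum() == 0:
            p = np.nan
        else:
            p = compare_phenotype(case_counts, ctrl_counts, kind="continuous").p_value
        sd = lambda v: float(v.std(ddof=1)) if len(v) > 1 else np.nan
        rows.append(
            {
                "region": region,
                "case_mean": case_counts.mean(),
                "case_sd": sd(case_counts),
                "ctrl_mean": ctrl_counts.mean(),
                "ctrl_sd": sd(ctrl_counts),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
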