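"""End-to-end orchestration of the five-stage analysis.

Stages: (1) allele grouping and per-gene carrier enrichment, (2) burden-ratio
partition and SKAT per gene plus interaction tests among positively
associated genes, (3a/3b) protein-rating and tRNA-criteria annotation with
the heteroplasmy threshold, (5) carrier phenotype comparison.  Outputs are
plain TSV tables shaped like the published ones, plus a JSON run manifest
(seed, thresholds, input checksums, stage timings).  Any stage failure
aborts with a stage-named error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import annotation as ann
from . import enrichment, skat
from .heteroplasmy import (
    COMMON_FREQUENCY_PCT,
    METABOLIC_THRESHOLD_PCT,
    compute_hf,
    frequency_band,
)
from .model import (
    CohortDataset,
    GeneMap,
    MitoburdenError,
    PROTEIN,
    RRNA,
    TRNA,
    default_gene_map,
    read_fasta_reference,
    read_phenotype_table,
    read_variant_table,
)
from .phenotype import phenotype_comparison_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and test settings for a pipeline run."""

    variants: str
    samples: str  # TSV: sample, cohort (case/control)
    phenotypes: str | None = None
    reference: str | None = None
    gene_map: str | None = None
    ratings: str | None = None
    panel_counts: str | None = None
    conservation: str | None = None
    conservation_start: int | None = None
    structures: str | None = None
    dialect: str = "tsv"
    output_dir: str = "mitoburden_out"
    common_threshold_pct: float = COMMON_FREQUENCY_PCT
    panel_threshold_pct: float = ann.PANEL_FREQUENCY_THRESHOLD_PCT
    ci_threshold_pct: float = ann.CI_THRESHOLD_PCT
    hf_threshold_pct: float = METABOLIC_THRESHOLD_PCT
    alpha: float = 0.05
    min_expected: float = 5.0
    skat_weighting: str = "beta"
    skat_dosage: str = "carrier"
    skat_method: str = skat.MOMENT_MATCHING
    n_permutations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("common_threshold_pct", "panel_threshold_pct",
                     "ci_threshold_pct", "hf_threshold_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise MitoburdenError(f"{name} must lie in (0, 100), got {v}")
        if not 0 < self.alpha < 1:
            raise MitoburdenError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_dataset(cfg: PipelineConfig) -> CohortDataset:
    gene_map = GeneMap.from_tsv(cfg.gene_map) if cfg.gene_map else default_gene_map()
    samples = pd.read_csv(cfg.samples, sep="\t")
    cases = set(samples.loc[samples["cohort"] == "case", "sample"].astype(str))
    controls = set(samples.loc[samples["cohort"] == "control", "sample"].astype(str))
    observations = read_variant_table(cfg.variants, dialect=cfg.dialect)
    phen = read_phenotype_table(cfg.phenotypes) if cfg.phenotypes else None
    dataset = CohortDataset(cases, controls, observations, gene_map, phen)
    reference = read_fasta_reference(cfg.reference) if cfg.reference else None
    dataset.annotate_alleles(reference)
    return dataset


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _max_hf(dataset: CohortDataset, allele_key) -> float:
    return max(
        compute_hf(o) for o in dataset.observations if o.allele.key == allele_key
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns the written report paths."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "thresholds": {
            "common_pct": cfg.common_threshold_pct,
            "panel_pct": cfg.panel_threshold_pct,
            "ci_pct": cfg.ci_threshold_pct,
            "hf_pct": cfg.hf_threshold_pct,
            "alpha": cfg.alpha,
            "min_expected": cfg.min_expected,
        },
        "inputs": {},
        "stage_seconds": {},
    }
    for name in ("variants", "samples", "phenotypes", "reference", "gene_map",
                 "ratings", "panel_counts", "conservation", "structures"):
        p = getattr(cfg, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    stage = "load"
    try:
        t0 = time.perf_counter()
        dataset = load_dataset(cfg)
        manifest["n_cases"] = dataset.n_cases
        manifest["n_controls"] = dataset.n_controls
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)

        # Stage 1: grouping + enrichment ---------------------------------
        stage = "step1_enrichment"
        t0 = time.perf_counter()
        grouped = enrichment.assign_groups(dataset)
        sizes = enrichment.group_sizes(grouped)
        manifest["allele_groups"] = sizes
        table1 = enrichment.enrichment_table(
            dataset, grouped, min_expected=cfg.min_expected
        )
        p = outdir / "step1_enrichment.tsv"
        table1.to_csv(p, sep="\t", index=False)
        written.append(p)
        burden = enrichment.burden_per_individual(dataset, grouped)
        p = outdir / "step1_burden_per_individual.tsv"
        burden.to_csv(p, sep="\t", index=False)
        written.append(p)
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)

        # Stage 2: burden partition + SKAT --------------------------------
        stage = "step2_association"
        t0 = time.perf_counter()
        # nonsynonymous alleles for protein genes; all alleles for RNA genes
        alleles_by_gene: dict[str, list] = {}
        for allele in sorted(dataset.distinct_alleles()):
            for gene in dataset.gene_map.assign_gene(allele.position):
                if gene == "noncoding":
                    continue
                cls = dataset.gene_map[gene].cls
                if cls == PROTEIN and allele.functional_class == "synonymous":
                    continue
                alleles_by_gene.setdefault(gene, []).append(allele)
        genes = sorted(alleles_by_gene)
        assoc, partitions = skat.association_table(
            dataset, genes, alleles_by_gene,
            dosage=cfg.skat_dosage, weighting=cfg.skat_weighting,
            method=cfg.skat_method, seed=cfg.seed,
        )
        p = outdir / "step2_associations.tsv"
        assoc.to_csv(p, sep="\t", index=False)
        written.append(p)

        sig_pos = (
            assoc[(assoc["allele_set"] == skat.POSITIVE) & (assoc["p_value"] < cfg.alpha)]
            ["gene"].tolist()
            if len(assoc)
            else []
        )
        manifest["positively_associated_genes"] = sig_pos
        inter_rows = []
        for i, g1 in enumerate(sig_pos):
            for g2 in sig_pos[i + 1 :]:
                G1, y = skat.build_genotype_matrix(
                    dataset, partitions[g1].positive_alleles,
                    dosage=cfg.skat_dosage, weighting=cfg.skat_weighting,
                )
                G2, _ = skat.build_genotype_matrix(
                    dataset, partitions[g2].positive_alleles,
                    dosage=cfg.skat_dosage, weighting=cfg.skat_weighting,
                )
                try:
                    res = skat.interaction_test(G1, G2, y, genes=(g1, g2))
                except MitoburdenError as exc:
                    logger.info("interaction %s x %s skipped: %s", g1, g2, exc)
                    continue
                inter_rows.append(
                    {"gene1": g1, "gene2": g2, "Q": res.Q, "p_value": res.p_value,
                     "method": res.method}
                )
        p = outdir / "step2_interactions.tsv"
        pd.DataFrame(inter_rows, columns=["gene1", "gene2", "Q", "p_value", "method"]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)

        # Stage 3a: protein annotation ------------------------------------
        stage = "step3_protein"
        t0 = time.perf_counter()
        protein_flagged: list = []
        if cfg.ratings:
            ratings = ann.read_ratings_table(cfg.ratings)
            candidate_genes = [
                g for g in sig_pos
                if g in dataset.gene_map and dataset.gene_map[g].cls == PROTEIN
            ]
            cand = {
                a.key: a
                for g in candidate_genes
                for a in partitions[g].positive_alleles
            }
            rows = []
            for r in ratings.itertuples(index=False):
                key = (int(r.pos), r.ref, r.alt)
                if key not in cand:
                    continue
                allele = cand[key]
                rows.append(
                    {
                        "gene": allele.gene, "pos": allele.position,
                        "ref": allele.ref, "alt": allele.alt,
                        "polyphen": int(r.polyphen), "sift": int(r.sift),
                        "pmut": int(r.pmut), "hf": _max_hf(dataset, key),
                    }
                )
            cand_df = pd.DataFrame(
                rows, columns=["gene", "pos", "ref", "alt", "polyphen", "sift", "pmut", "hf"]
            )
            if len(cand_df):
                flagged = ann.protein_shortlist(
                    cand_df, hf_threshold_pct=cfg.hf_threshold_pct
                )
            else:
                flagged = cand_df.assign(stars=pd.Series(dtype=int))
            p = outdir / "step3_protein.tsv"
            flagged.to_csv(p, sep="\t", index=False)
            written.append(p)
            protein_flagged = [
                (int(r.pos), r.ref, r.alt) for r in flagged.itertuples(index=False)
            ]
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)

        # Stage 3b: tRNA annotation ---------------------------------------
        stage = "step3_trna"
        t0 = time.perf_counter()
        trna_flagged: list = []
        if cfg.panel_counts and cfg.conservation and cfg.structures:
            counts = pd.read_csv(cfg.panel_counts, sep="\t")
            count_map = {
                (int(r.pos), r.ref, r.alt): (int(r.count), int(r.panel_size))
                for r in counts.itertuples(index=False)
            }
            start = cfg.conservation_start
            if start is None:
                sidecar = Path(cfg.conservation).with_suffix(".start")
                start = int(sidecar.read_text().strip()) if sidecar.exists() else 1
            panel = ann.ConservationPanel.from_fasta(cfg.conservation, human_start=start)
            structures = ann.read_structures_tsv(cfg.structures)
            rows = []
            trna_genes = [
                g for g in sig_pos
                if g in dataset.gene_map and dataset.gene_map[g].cls == TRNA
            ]
            for gene in trna_genes:
                for allele in partitions[gene].positive_alleles:
                    if gene not in structures or allele.position not in structures[gene]:
                        logger.warning("%s: no structure row for %s", gene, allele.label)
                        continue
                    call = ann.structural_assessment(allele, structures[gene])
                    count, size = count_map.get(allele.key, (None, 0))
                    absent = len(dataset.carriers([allele], "control")) == 0
                    ci = ann.conservation_index(panel, allele.position, allele.ref)
                    verdict = ann.classify_trna(
                        allele, absent, count, size, ci, call.alteration,
                        call.anticodon_loop,
                        ci_threshold_pct=cfg.ci_threshold_pct,
                        panel_threshold_pct=cfg.panel_threshold_pct,
                    )
                    hf = _max_hf(dataset, allele.key)
                    rows.append(
                        {
                            "gene": gene, "pos": allele.position, "ref": allele.ref,
                            "alt": allele.alt,
                            "gene_strand": allele.gene_strand_label(
                                dataset.gene_map[gene].strand
                            ),
                            "region": call.region, "number": call.trna_number,
                            "hf": hf, "absent_in_controls": absent,
                            "panel_count": count,
                            "panel_freq_pct": round(100 * count / size, 2) if size else np.nan,
                            "ci": verdict.ci, "alteration": call.alteration,
                            "anticodon_loop": call.anticodon_loop,
                            "pathogenic": verdict.pathogenic,
                            "hf_above_threshold": hf > cfg.hf_threshold_pct,
                        }
                    )
            trna_df = pd.DataFrame(
                rows,
                columns=["gene", "pos", "ref", "alt", "gene_strand", "region",
                         "number", "hf", "absent_in_controls", "panel_count",
                         "panel_freq_pct", "ci", "alteration", "anticodon_loop",
                         "pathogenic", "hf_above_threshold"],
            )
            p = outdir / "step3_trna.tsv"
            trna_df.to_csv(p, sep="\t", index=False)
            written.append(p)
            trna_flagged = [
                (int(r.pos), r.ref, r.alt)
                for r in trna_df[trna_df["pathogenic"]].itertuples(index=False)
            ]
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)

        # Stage 5: phenotype comparison -----------------------------------
        stage = "step5_phenotype"
        t0 = time.perf_counter()
        if dataset.phenotypes is not None:
            key_sets = {"protein": protein_flagged, "trna": trna_flagged}
            frames = []
            for label, keys in key_sets.items():
                if not keys:
                    continue
                alleles = [
                    a for a in dataset.distinct_alleles() if a.key in set(keys)
                ]
                carriers = dataset.carriers(alleles, "case")
                tbl = phenotype_comparison_table(
                    dataset.phenotypes, carriers, samples=sorted(dataset.cases)
                )
                tbl.insert(0, "allele_set", label)
                frames.append(tbl)
            p = outdir / "step5_phenotypes.tsv"
            (pd.concat(frames) if frames else pd.DataFrame(
                columns=["allele_set", "variable", "n_plus", "n_minus",
                         "carriers", "non_carriers", "p_value", "method"]
            )).to_csv(p, sep="\t", index=False)
            written.append(p)
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)

        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise MitoburdenError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return {p.stem: p for p in written}
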