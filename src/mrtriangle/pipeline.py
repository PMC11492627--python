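"""End-to-end orchestration of the triangulation study.

Step 1 runs genome-wide MR of every metabolite on every outcome; step 2 runs
cis MR of every protein (largest-sample study first) on the metabolites that
passed step 1; step 3 runs cis MR of the step-2 proteins on the outcomes.
Triangulation, annotation, enrichment and replication follow, and all tidy
outputs plus a run manifest are written to the output directory.  The run is
fully deterministic given the config and input files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, io
from .enrichment import (
    annotate_druggability,
    assess_replication,
    cardiac_expression_flags,
    cardiac_fraction,
    wald_proportion_enrichment,
)
from .estimators import DISCARDED, MRResult, results_to_frame, run_mr
from .instruments import GeneAnnotation
from .triangulation import (
    bonferroni_threshold,
    build_triangles,
    pleiotropic_summary,
    select_primary_study,
    triangles_to_network,
)

__all__ = ["ProteinStudy", "PipelineConfig", "load_config", "run_pipeline"]


class ProteinStudy(BaseModel):
    protein_id: str
    study_id: str
    path: Path
    sample_size: int = Field(ge=1)


class PipelineConfig(BaseModel):
    """Paths and numeric knobs of one pipeline run."""

    metabolite_gwas: dict[str, Path]
    outcome_gwas: dict[str, Path]
    protein_gwas: list[ProteinStudy]
    ld_path: Path
    gene_annotation_path: Path
    expression_path: Path
    druggability_path: Path
    pathway_path: Path
    cardiac_tissue: str = "heart"
    f_min: float = 24.0
    maf_min: float = 0.01
    r2_max: float = 0.3
    flank: int = 200_000
    min_variants: int = 6
    leverage_factor: float = 3.0
    outlier_cut: float = 10.83
    selection_alpha: float = 0.05
    alpha: float = 0.05
    overexpression_alpha: float = 0.05
    min_abundance: float = 0.0
    seed: int = 0
    output_dir: Path = Path("results")

    @field_validator("metabolite_gwas", "outcome_gwas")
    @classmethod
    def _paths_exist(cls, value):
        for name, path in value.items():
            if not Path(path).exists():
                raise ValueError(f"missing summary-statistic file for {name}: {path}")
        return value

    @field_validator(
        "ld_path",
        "gene_annotation_path",
        "expression_path",
        "druggability_path",
        "pathway_path",
    )
    @classmethod
    def _path_exists(cls, value):
        if not Path(value).exists():
            raise ValueError(f"missing input file: {value}")
        return value


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _mr_kwargs(config: PipelineConfig) -> dict:
    return dict(
        f_min=config.f_min,
        maf_min=config.maf_min,
        flank=config.flank,
        r2_max=config.r2_max,
        min_variants=config.min_variants,
        leverage_factor=config.leverage_factor,
        outlier_cut=config.outlier_cut,
        selection_alpha=config.selection_alpha,
    )


def _edge_frame(results: list[MRResult]) -> pd.DataFrame:
    rows = [
        {
            "exposure_id": r.exposure_id,
            "outcome_id": r.outcome_id,
            "beta": r.slope,
            "p_value": r.p_value,
        }
        for r in results
        if r.chosen_estimator != DISCARDED
    ]
    return pd.DataFrame(rows, columns=["exposure_id", "outcome_id", "beta", "p_value"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study flow and write the result bundle.

    Returns a dict with the manifest and every result frame.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    ld = io.read_ld(config.ld_path)
    gene_table = io.read_gene_annotation(config.gene_annotation_path)
    genes_by_protein = {
        row.encoded_protein: GeneAnnotation(
            gene_id=row.gene_id,
            chromosome=str(row.chromosome),
            start=int(row.start),
            end=int(row.end),
            encoded_protein=row.encoded_protein,
        )
        for row in gene_table.itertuples(index=False)
    }
    metabolites = {m: io.read_gwas(p) for m, p in sorted(config.metabolite_gwas.items())}
    outcomes = {o: io.read_gwas(p) for o, p in sorted(config.outcome_gwas.items())}

    studies_by_protein: dict[str, list[ProteinStudy]] = {}
    for study in config.protein_gwas:
        studies_by_protein.setdefault(study.protein_id, []).append(study)
    primary: dict[str, ProteinStudy] = {}
    for protein, studies in sorted(studies_by_protein.items()):
        chosen = select_primary_study([(s.study_id, s.sample_size) for s in studies])
        primary[protein] = next(s for s in studies if s.study_id == chosen)
    mr_kwargs = _mr_kwargs(config)

    # ---- step 1: genome-wide metabolite -> outcome MR -------------------
    step1: list[MRResult] = []
    for met, met_table in metabolites.items():
        for out, out_table in outcomes.items():
            step1.append(
                run_mr(
                    met_table,
                    out_table,
                    ld,
                    exposure_id=met,
                    outcome_id=out,
                    outcome_type="binary",
                    **mr_kwargs,
                )
            )
    threshold1 = bonferroni_threshold(config.alpha, len(metabolites), len(outcomes))
    sig_metabolites = sorted(
        {
            r.exposure_id
            for r in step1
            if r.chosen_estimator != DISCARDED and r.p_value < threshold1.threshold
        }
    )

    # ---- step 2: protein -> significant-metabolite cis MR ---------------
    step2: list[MRResult] = []
    if sig_metabolites:
        for protein, study in primary.items():
            prot_table = io.read_gwas(study.path)
            gene = genes_by_protein.get(protein)
            for met in sig_metabolites:
                step2.append(
                    run_mr(
                        prot_table,
                        metabolites[met],
                        ld,
                        gene=gene,
                        exposure_id=protein,
                        outcome_id=met,
                        outcome_type="continuous",
                        **mr_kwargs,
                    )
                )
    threshold2 = bonferroni_threshold(
        config.alpha, max(len(primary), 1), max(len(sig_metabolites), 1)
    )
    step2_proteins = sorted(
        {
            r.exposure_id
            for r in step2
            if r.chosen_estimator != DISCARDED and r.p_value < threshold2.threshold
        }
    )

    # ---- step 3: protein -> outcome cis MR ------------------------------
    step3: list[MRResult] = []
    for protein in step2_proteins:
        prot_table = io.read_gwas(primary[protein].path)
        gene = genes_by_protein.get(protein)
        for out, out_table in outcomes.items():
            step3.append(
                run_mr(
                    prot_table,
                    out_table,
                    ld,
                    gene=gene,
                    exposure_id=protein,
                    outcome_id=out,
                    outcome_type="binary",
                    **mr_kwargs,
                )
            )
    threshold3 = bonferroni_threshold(
        config.alpha, max(len(step2_proteins), 1), len(outcomes)
    )

    # ---- triangulation ---------------------------------------------------
    triangles = build_triangles(
        _edge_frame(step1),
        _edge_frame(step2),
        _edge_frame(step3),
        thresholds={
            "metabolite_outcome": threshold1.threshold,
            "protein_metabolite": threshold2.threshold,
            "protein_outcome": threshold3.threshold,
        },
    )
    prioritised = sorted(triangles["protein_id"].unique()) if not triangles.empty else []
    pleiotropic = pleiotropic_summary(triangles)
    nodes, edges = triangles_to_network(triangles)

    # ---- annotation ------------------------------------------------------
    expression = pd.read_table(config.expression_path)
    druggability = pd.read_table(config.druggability_path)
    pathways = pd.read_table(config.pathway_path)
    gene_of = {g.encoded_protein: g.gene_id for g in genes_by_protein.values()}
    tissue_cols = [c for c in expression.columns if c != "gene_id"]
    expr_by_gene = expression.set_index("gene_id")
    annotation_rows = []
    for protein in prioritised:
        gene_id = gene_of.get(protein)
        row = {"protein_id": protein, "gene_id": gene_id}
        if gene_id in expr_by_gene.index:
            profile = expr_by_gene.loc[gene_id, tissue_cols].astype(float)
            expressed, overexpressed = cardiac_expression_flags(
                profile,
                cardiac_tissue=config.cardiac_tissue,
                overexpression_alpha=config.overexpression_alpha,
                min_abundance=config.min_abundance,
            )
            row.update(
                cardiac_expressed=expressed,
                cardiac_overexpressed=overexpressed,
                cardiac_fraction=cardiac_fraction(profile, config.cardiac_tissue),
            )
        else:
            row.update(
                cardiac_expressed=False, cardiac_overexpressed=False, cardiac_fraction=0.0
            )
        annotation_rows.append(row)
    annotation = pd.DataFrame(
        annotation_rows,
        columns=[
            "protein_id",
            "gene_id",
            "cardiac_expressed",
            "cardiac_overexpressed",
            "cardiac_fraction",
        ],
    )
    if not annotation.empty:
        annotation = annotation.merge(
            annotate_druggability(annotation["protein_id"], druggability),
            on="protein_id",
        )

    # ---- enrichment ------------------------------------------------------
    background = sorted(primary)
    enrichment_rows = []
    if prioritised:
        for pathway_id, members in pathways.groupby("pathway_id")["protein_id"]:
            result = wald_proportion_enrichment(
                prioritised, background, set(members), group_label=str(pathway_id)
            )
            enrichment_rows.append(
                {
                    "group_label": result.group_label,
                    "k_prioritised_in_group": result.k_prioritised_in_group,
                    "n_prioritised": result.n_prioritised,
                    "k_background_in_group": result.k_background_in_group,
                    "n_background": result.n_background,
                    "z": result.z,
                    "p_value": result.p_value,
                    "degenerate": result.degenerate,
                }
            )
    enrichment = pd.DataFrame(
        enrichment_rows,
        columns=[
            "group_label",
            "k_prioritised_in_group",
            "n_prioritised",
            "k_background_in_group",
            "n_background",
            "z",
            "p_value",
            "degenerate",
        ],
    )

    # ---- replication -----------------------------------------------------
    rep_rows = []
    replicable = [
        p for p in prioritised if len(studies_by_protein.get(p, [])) > 1
    ]
    for protein in replicable:
        gene = genes_by_protein.get(protein)
        pairs = triangles.loc[
            triangles["protein_id"] == protein, "outcome_id"
        ].unique()
        for study in studies_by_protein[protein]:
            if study.study_id == primary[protein].study_id:
                continue
            prot_table = io.read_gwas(study.path)
            for out in pairs:
                res = run_mr(
                    prot_table,
                    outcomes[out],
                    ld,
                    gene=gene,
                    exposure_id=protein,
                    outcome_id=out,
                    outcome_type="binary",
                    **mr_kwargs,
                )
                if res.chosen_estimator != DISCARDED:
                    rep_rows.append(
                        {
                            "protein_id": protein,
                            "outcome_id": out,
                            "study_id": study.study_id,
                            "beta": res.slope,
                            "p_value": res.p_value,
                        }
                    )
    replication_table = pd.DataFrame(
        rep_rows, columns=["protein_id", "outcome_id", "study_id", "beta", "p_value"]
    )
    discovery_table = pd.DataFrame(
        [
            {"protein_id": r.exposure_id, "outcome_id": r.outcome_id, "beta": r.slope}
            for r in step3
            if r.chosen_estimator != DISCARDED and r.exposure_id in set(replicable)
        ],
        columns=["protein_id", "outcome_id", "beta"],
    )
    if replicable:
        verdicts, rep_summary = assess_replication(
            discovery_table, replication_table, n_tested=len(replicable), alpha=config.alpha
        )
        verdict_frame = pd.DataFrame(
            [
                {
                    "protein_id": v.protein_id,
                    "outcome_id": v.outcome_id,
                    "discovery_sign": v.discovery_sign,
                    "n_studies": len(v.entries),
                    "nominal": v.nominal,
                    "conservative": v.conservative,
                }
                for v in verdicts
            ],
            columns=[
                "protein_id",
                "outcome_id",
                "discovery_sign",
                "n_studies",
                "nominal",
                "conservative",
            ],
        )
    else:
        rep_summary = {"n_tested": 0}
        verdict_frame = pd.DataFrame(
            columns=[
                "protein_id",
                "outcome_id",
                "discovery_sign",
                "n_studies",
                "nominal",
                "conservative",
            ]
        )

    # ---- outputs and manifest -------------------------------------------
    frames = {
        "step1_results": results_to_frame(step1),
        "step2_results": results_to_frame(step2),
        "step3_results": results_to_frame(step3),
        "triangles": triangles,
        "network_nodes": nodes,
        "network_edges": edges,
        "protein_annotation": annotation,
        "enrichment": enrichment,
        "replication": verdict_frame,
    }
    for name, frame in frames.items():
        io.write_table(frame, outdir / f"{name}.tsv")

    def _stage(results: list[MRResult], threshold: float) -> dict:
        usable = [r for r in results if r.chosen_estimator != DISCARDED]
        return {
            "n_tests": len(results),
            "n_discarded": len(results) - len(usable),
            "n_significant_edges": sum(r.p_value < threshold for r in usable),
        }

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "thresholds": {
            "metabolite_outcome": {
                "exact": threshold1.threshold,
                "reported": threshold1.threshold_reported,
            },
            "protein_metabolite": {
                "exact": threshold2.threshold,
                "reported": threshold2.threshold_reported,
            },
            "protein_outcome": {
                "exact": threshold3.threshold,
                "reported": threshold3.threshold_reported,
            },
        },
        "counts": {
            "n_metabolites": len(metabolites),
            "n_outcomes": len(outcomes),
            "n_proteins": len(primary),
            "step1": {
                **_stage(step1, threshold1.threshold),
                "n_significant_metabolites": len(sig_metabolites),
            },
            "step2": {
                **_stage(step2, threshold2.threshold),
                "n_significant_proteins": len(step2_proteins),
            },
            "step3": _stage(step3, threshold3.threshold),
            "n_triangles": int(len(triangles)),
            "n_prioritised_proteins": len(prioritised),
            "n_pleiotropic_proteins": int(pleiotropic["pleiotropic"].sum())
            if not pleiotropic.empty
            else 0,
            "n_enriched_groups": int((enrichment["p_value"] < config.alpha).sum())
            if not enrichment.empty
            else 0,
        },
        "replication": rep_summary,
        "significant_metabolites": sig_metabolites,
        "prioritised_proteins": prioritised,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {"manifest": manifest, **frames}
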