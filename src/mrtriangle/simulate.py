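"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure a correlation-aware
two-sample MR analysis assumes: per-variant exposure effects are fixed truths
observed with sampling noise, outcome effects are ``causal_effect *
exposure_effect + pleiotropy`` observed with estimation noise whose
covariance is proportional to the signed LD matrix, and exposure and outcome
noise are drawn independently (two-sample independence).  Standard errors
scale as ``1/sqrt(n)`` of the respective GWAS sample size.  A fraction of
variants has its allele coding swapped between the two samples so that the
harmonisation step is exercised.

:func:`simulate_toy_study` plants a small, fully linked study -- proteins
with cis loci, metabolites inheriting protein effects, binary outcomes driven
by the metabolites plus optional direct protein effects -- so that the whole
pipeline, including triangulation, can be run end-to-end offline with a known
answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy import linalg, stats

from . import io

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ld_matrix",
    "simulate_mr_dataset",
    "simulate_annotation_fixtures",
    "simulate_toy_study",
    "write_toy_study",
]

NUCLEOTIDES = np.array(list("ACGT"))

#: default outcome labels for toy studies (cardiac endpoints)
OUTCOME_LABELS = ["AF", "HF", "DCM", "NICM"]


class SimConfig(BaseModel):
    """Parameters of one simulated two-sample MR dataset.

    Defaults mirror a large metabolite GWAS meta-analysis as the exposure
    sample (n = 86,507) and a binary cardiac outcome GWAS with an effective
    sample size of 20,000 on the log-odds scale; per-variant exposure effects
    span the moderate-to-strong range typical of metabolite and protein QTLs.
    """

    n_variants: int = Field(default=100, ge=1)
    causal_effect: float = 0.0
    exposure_effect_range: tuple[float, float] = (-0.5, 0.5)
    n_exposure: int = Field(default=86_507, ge=2)
    n_outcome: int = Field(default=20_000, ge=2)
    pleiotropy_mode: Literal["none", "balanced", "directional"] = "none"
    pleiotropy_sd: float = Field(default=0.0, ge=0.0)
    pleiotropy_mean: float = 0.0
    ld_block_size: int = Field(default=5, ge=1)
    ld_rho: float = Field(default=0.5, ge=0.0, lt=1.0)
    flip_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.exposure_effect_range
        if lo > hi:
            raise ValueError("exposure_effect_range must be a (low, high) interval")
        if self.pleiotropy_mode != "directional" and self.pleiotropy_mean != 0:
            raise ValueError("pleiotropy_mean must be 0 unless mode is directional")
        return self


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    causal_effect: float
    per_variant_pleiotropy: np.ndarray
    exposure_betas_true: np.ndarray


def simulate_ld_matrix(
    n_variants: int, block_size: int, rho: float, seed: int = 0
) -> pd.DataFrame:
    """Block-diagonal AR(1) signed LD matrix.

    Variants ``i`` and ``j`` in the same block of ``block_size`` have
    correlation ``rho ** |i - j|``; variants in different blocks are
    uncorrelated.  The result is symmetric, unit-diagonal and positive
    semi-definite.  ``seed`` is accepted for interface uniformity; the
    structure itself is deterministic.
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if block_size < 1 or n_variants < 1:
        raise ValueError("n_variants and block_size must be >= 1")
    idx = np.arange(n_variants)
    same_block = idx[:, None] // block_size == idx[None, :] // block_size
    lag = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(invalid="ignore"):
        matrix = np.where(same_block, float(rho) ** lag, 0.0)
    np.fill_diagonal(matrix, 1.0)
    ids = [f"rs{i + 1:06d}" for i in idx]
    return pd.DataFrame(matrix, index=ids, columns=ids)


def _draw_allele_pairs(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    first = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    second = (first + shift) % 4
    return NUCLEOTIDES[first], NUCLEOTIDES[second]


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _gwas_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p_value": _p_from_z(np.asarray(beta, float), np.asarray(se, float)),
            "n": n,
        }
    )


def simulate_mr_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one exposure GWAS, one outcome GWAS, their LD, and the truth.

    Returns ``(exposure, outcome, ld, truth)``.  Identical configs produce
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    ld = simulate_ld_matrix(m, config.ld_block_size, config.ld_rho, config.seed)
    R = ld.to_numpy()
    L = linalg.cholesky(R + 1e-12 * np.eye(m), lower=True)

    ids = list(ld.index)
    pos = 1_000_000 + 2_000 * np.arange(m)
    ea, oa = _draw_allele_pairs(rng, m)
    eaf = rng.uniform(0.05, 0.95, size=m)
    lo, hi = config.exposure_effect_range
    b_true = rng.uniform(lo, hi, size=m)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(m)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, config.pleiotropy_sd, size=m)

    se_x = np.full(m, 1.0 / np.sqrt(config.n_exposure))
    se_y = np.full(m, 1.0 / np.sqrt(config.n_outcome))
    beta_x = b_true + se_x * (L @ rng.standard_normal(m))
    beta_y = (
        config.causal_effect * b_true + alpha + se_y * (L @ rng.standard_normal(m))
    )

    exposure = _gwas_frame(ids, "1", pos, ea, oa, eaf, beta_x, se_x, config.n_exposure)
    outcome = _gwas_frame(ids, "1", pos, ea, oa, eaf, beta_y, se_y, config.n_outcome)

    n_flip = int(round(config.flip_fraction * m))
    if n_flip:
        flip = rng.choice(m, size=n_flip, replace=False)
        outcome.loc[flip, ["effect_allele", "other_allele"]] = outcome.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
        outcome.loc[flip, "beta"] = -outcome.loc[flip, "beta"]
        outcome.loc[flip, "eaf"] = 1.0 - outcome.loc[flip, "eaf"]

    truth = SimTruth(
        causal_effect=config.causal_effect,
        per_variant_pleiotropy=alpha,
        exposure_betas_true=b_true,
    )
    return exposure, outcome, ld, truth


def simulate_annotation_fixtures(
    n_proteins: int,
    n_pathways: int,
    n_tissues: int = 61,
    seed: int = 0,
    cardiac_tissue: str = "heart",
) -> dict[str, pd.DataFrame]:
    """Fixture tables standing in for tissue-expression, druggability,
    pathway-membership and gene-annotation resources.

    Every protein receives one expression row over ``n_tissues`` non-negative
    abundances (one tissue labelled cardiac), a druggability status in
    {drugged, druggable, none}, zero or more pathway memberships, and a gene
    locus.  Deterministic under ``seed``.
    """
    if min(n_proteins, n_pathways, n_tissues) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i + 1:03d}" for i in range(n_proteins)]
    genes = [f"GENE{i + 1:03d}" for i in range(n_proteins)]
    tissues = [cardiac_tissue] + [f"tissue_{i + 1:02d}" for i in range(n_tissues - 1)]

    abundance = rng.gamma(shape=2.0, scale=10.0, size=(n_proteins, n_tissues))
    expression = pd.DataFrame(abundance, columns=tissues)
    expression.insert(0, "gene_id", genes)

    status = rng.choice(
        ["drugged", "druggable", "none"], size=n_proteins, p=[0.3, 0.3, 0.4]
    )
    n_drugs = np.where(status == "none", 0, rng.integers(1, 7, size=n_proteins))
    druggability = pd.DataFrame(
        {
            "protein_id": proteins,
            "status": status,
            "n_drugs": n_drugs,
            "cardiac_indication": (status != "none") & (rng.random(n_proteins) < 0.3),
            "cardiac_side_effect": (status != "none") & (rng.random(n_proteins) < 0.3),
        }
    )

    membership = []
    for i, prot in enumerate(proteins):
        for j in range(n_pathways):
            if rng.random() < 0.3:
                membership.append({"pathway_id": f"PW{j + 1:02d}", "protein_id": prot})
    pathways = pd.DataFrame(membership, columns=["pathway_id", "protein_id"])

    gene_table = pd.DataFrame(
        {
            "gene_id": genes,
            "chromosome": "1",
            "start": 1_000_000 + 1_000_000 * np.arange(n_proteins),
            "end": 1_010_000 + 1_000_000 * np.arange(n_proteins),
            "encoded_protein": proteins,
        }
    )
    return {
        "expression": expression,
        "druggability": druggability,
        "pathways": pathways,
        "genes": gene_table,
    }


# ---------------------------------------------------------------------------
# Toy study: a fully linked protein -> metabolite -> outcome system
# ---------------------------------------------------------------------------


@dataclass
class ToyStudy:
    """In-memory bundle of a planted multi-trait study."""

    metabolite_gwas: dict[str, pd.DataFrame]
    outcome_gwas: dict[str, pd.DataFrame]
    protein_gwas: dict[str, dict[str, tuple[pd.DataFrame, int]]]  # protein -> study -> (table, n)
    ld: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    druggability: pd.DataFrame
    pathways: pd.DataFrame
    truth: dict


def _flip_coding(table: pd.DataFrame, rng: np.random.Generator, fraction: float) -> pd.DataFrame:
    table = table.copy()
    n_flip = int(round(fraction * len(table)))
    if n_flip:
        flip = rng.choice(len(table), size=n_flip, replace=False)
        table.loc[flip, ["effect_allele", "other_allele"]] = table.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
        table.loc[flip, "beta"] = -table.loc[flip, "beta"]
        table.loc[flip, "eaf"] = 1.0 - table.loc[flip, "eaf"]
    return table


def simulate_toy_study(
    n_metabolites: int = 6,
    n_proteins: int = 8,
    n_outcomes: int = 2,
    variants_per_locus: int = 20,
    protein_locus_sizes: Optional[list[int]] = None,
    n_pathways: int = 3,
    ld_rho: float = 0.6,
    n_protein_sample: int = 35_000,
    n_metabolite_sample: int = 86_507,
    n_outcome_sample: int = 100_000,
    n_replication_sample: int = 3_301,
    flip_fraction: float = 0.1,
    seed: int = 0,
) -> ToyStudy:
    """Plant a small protein/metabolite/outcome study with known structure.

    Each protein gets a cis locus of instruments; each metabolite gets its
    own genome-wide locus plus inherited effects at the cis loci of the
    proteins that regulate it (``B_pm``); each binary outcome is driven by a
    sparse subset of metabolites (``B_mo``) plus occasional direct protein
    effects (``D_po``) that break directional concordance for some triples.
    Half of the proteins carry a second, smaller-sample GWAS for replication.
    """
    rng = np.random.default_rng(seed)
    locus_sizes = list(protein_locus_sizes or [variants_per_locus] * n_proteins)
    if len(locus_sizes) != n_proteins:
        raise ValueError("protein_locus_sizes must have one entry per protein")
    met_sizes = [variants_per_locus] * n_metabolites
    sizes = locus_sizes + met_sizes
    m_total = sum(sizes)

    # genome layout: loci of AR(1)-correlated variants, 1 Mb apart on chr 1
    blocks, ids, pos, starts = [], [], [], []
    cursor = 1_000_000
    for k, size in enumerate(sizes):
        starts.append(cursor)
        block = simulate_ld_matrix(size, size, ld_rho).to_numpy()
        blocks.append(block)
        ids += [f"rs{k + 1:02d}_{j + 1:03d}" for j in range(size)]
        pos += [cursor + 2_000 * j for j in range(size)]
        cursor += 1_000_000
    R = linalg.block_diag(*blocks)
    ld = pd.DataFrame(R, index=ids, columns=ids)
    L = linalg.cholesky(R + 1e-12 * np.eye(m_total), lower=True)
    pos = np.array(pos)

    ea, oa = _draw_allele_pairs(rng, m_total)
    eaf = rng.uniform(0.05, 0.95, size=m_total)

    proteins = [f"PROT{i + 1:03d}" for i in range(n_proteins)]
    metabolites = [f"MET{i + 1:02d}" for i in range(n_metabolites)]
    outcomes = (OUTCOME_LABELS + [f"OUT{i}" for i in range(5, n_outcomes + 1)])[
        :n_outcomes
    ]

    offsets = np.cumsum([0] + sizes)
    prot_slice = {p: slice(offsets[i], offsets[i + 1]) for i, p in enumerate(proteins)}
    met_slice = {
        m: slice(offsets[n_proteins + i], offsets[n_proteins + i + 1])
        for i, m in enumerate(metabolites)
    }

    # per-variant true exposure effects at each trait's own locus
    b_protein = np.zeros((n_proteins, m_total))
    for i, p in enumerate(proteins):
        sl = prot_slice[p]
        sign = rng.choice([-1.0, 1.0])
        b_protein[i, sl] = sign * rng.uniform(0.1, 0.3, size=sl.stop - sl.start)
    b_met_own = np.zeros((n_metabolites, m_total))
    for i, m in enumerate(metabolites):
        sl = met_slice[m]
        sign = rng.choice([-1.0, 1.0])
        b_met_own[i, sl] = sign * rng.uniform(0.1, 0.3, size=sl.stop - sl.start)

    # structural coefficient matrices
    B_pm = np.zeros((n_proteins, n_metabolites))
    for i in range(n_proteins):
        targets = rng.choice(n_metabolites, size=rng.integers(1, 3), replace=False)
        for t in targets:
            B_pm[i, t] = rng.choice([-0.5, 0.5])
    B_mo = np.zeros((n_metabolites, n_outcomes))
    for j in range(n_outcomes):
        driving = rng.choice(
            n_metabolites, size=max(1, n_metabolites // 2), replace=False
        )
        for d in driving:
            B_mo[d, j] = rng.choice([-0.4, 0.4])
    D_po = np.zeros((n_proteins, n_outcomes))
    for i in range(n_proteins):
        for j in range(n_outcomes):
            if rng.random() < 0.25:
                D_po[i, j] = rng.choice([-0.6, 0.6])

    # propagate genetic effects through the linear system
    b_metab = b_met_own + B_pm.T @ b_protein
    b_out = B_mo.T @ b_metab + D_po.T @ b_protein

    def observe(b_true: np.ndarray, n_sample: int) -> pd.DataFrame:
        se = np.full(m_total, 1.0 / np.sqrt(n_sample))
        beta = b_true + se * (L @ rng.standard_normal(m_total))
        table = _gwas_frame(ids, "1", pos, ea, oa, eaf, beta, se, n_sample)
        return _flip_coding(table, rng, flip_fraction)

    metabolite_gwas = {
        m: observe(b_metab[i], n_metabolite_sample) for i, m in enumerate(metabolites)
    }
    outcome_gwas = {
        o: observe(b_out[j], n_outcome_sample) for j, o in enumerate(outcomes)
    }
    protein_gwas: dict[str, dict[str, tuple[pd.DataFrame, int]]] = {}
    for i, p in enumerate(proteins):
        studies = {"study_A": (observe(b_protein[i], n_protein_sample), n_protein_sample)}
        if i % 2 == 0:  # half the proteins carry a replication study
            studies["study_B"] = (
                observe(b_protein[i], n_replication_sample),
                n_replication_sample,
            )
        protein_gwas[p] = studies

    fixtures = simulate_annotation_fixtures(
        n_proteins, n_pathways, seed=rng.integers(2**31)
    )
    genes = fixtures["genes"].copy()
    genes["start"] = [starts[i] for i in range(n_proteins)]
    genes["end"] = [
        starts[i] + 2_000 * (locus_sizes[i] - 1) for i in range(n_proteins)
    ]

    truth = {
        "proteins": proteins,
        "metabolites": metabolites,
        "outcomes": outcomes,
        "B_pm": B_pm.tolist(),
        "B_mo": B_mo.tolist(),
        "D_po": D_po.tolist(),
        "seed": seed,
    }
    return ToyStudy(
        metabolite_gwas=metabolite_gwas,
        outcome_gwas=outcome_gwas,
        protein_gwas=protein_gwas,
        ld=ld,
        genes=genes,
        expression=fixtures["expression"],
        druggability=fixtures["druggability"],
        pathways=fixtures["pathways"],
        truth=truth,
    )


def write_toy_study(study: ToyStudy, outdir, seed: int = 0) -> Path:
    """Write a toy study to disk plus a ready-to-run pipeline config.

    Returns the path of the written ``config.yaml``.
    """
    outdir = Path(outdir)
    for sub in ("metabolites", "outcomes", "proteins"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    config: dict = {
        "metabolite_gwas": {},
        "outcome_gwas": {},
        "protein_gwas": [],
        "seed": seed,
        "output_dir": str(outdir / "results"),
    }
    for m, table in study.metabolite_gwas.items():
        path = outdir / "metabolites" / f"{m}.tsv"
        io.write_gwas(table, path)
        config["metabolite_gwas"][m] = str(path)
    for o, table in study.outcome_gwas.items():
        path = outdir / "outcomes" / f"{o}.tsv"
        io.write_gwas(table, path)
        config["outcome_gwas"][o] = str(path)
    for p, studies in study.protein_gwas.items():
        for s, (table, n) in studies.items():
            path = outdir / "proteins" / f"{p}_{s}.tsv"
            io.write_gwas(table, path)
            config["protein_gwas"].append(
                {"protein_id": p, "study_id": s, "path": str(path), "sample_size": n}
            )

    io.write_ld(study.ld, outdir / "ld.tsv")
    io.write_table(study.genes, outdir / "genes.tsv")
    io.write_table(study.expression, outdir / "expression.tsv")
    io.write_table(study.druggability, outdir / "druggability.tsv")
    io.write_table(study.pathways, outdir / "pathways.tsv")
    config.update(
        {
            "ld_path": str(outdir / "ld.tsv"),
            "gene_annotation_path": str(outdir / "genes.tsv"),
            "expression_path": str(outdir / "expression.tsv"),
            "druggability_path": str(outdir / "druggability.tsv"),
            "pathway_path": str(outdir / "pathways.tsv"),
        }
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2)
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
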