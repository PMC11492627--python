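"""Instrument selection, LD clumping, and two-sample harmonisation.

Genetic instruments for a two-sample Mendelian randomisation analysis are
selected from exposure summary statistics by instrument strength (per-variant
F-statistic) and minor allele frequency, optionally restricted to a *cis*
window around the gene encoding a protein exposure, greedily clumped so that
no retained pair exceeds an LD r-squared ceiling, and finally harmonised
against the outcome summary statistics so that both effect estimates refer to
the same effect allele.

Variant tables follow the column schema of :mod:`mrtriangle.io`.  The LD
matrix is a signed correlation matrix aligned to the **exposure** table's
effect-allele orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "InstrumentSet",
    "HarmonizationError",
    "f_statistic",
    "filter_instruments",
    "select_cis_window",
    "clump",
    "harmonize",
]

#: unordered allele pairs that are their own reverse complement
PALINDROMIC_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

#: columns of the harmonised per-variant table inside an InstrumentSet
INSTRUMENT_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "beta_exposure",
    "se_exposure",
    "p_value_exposure",
    "beta_outcome",
    "se_outcome",
]


class HarmonizationError(ValueError):
    """Raised when exposure and outcome statistics cannot be paired."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus (1-based, closed interval) and the protein it encodes."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    encoded_protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class InstrumentSet:
    """Harmonised exposure/outcome effect pairs plus their LD submatrix.

    ``variants`` holds one row per instrument (columns
    :data:`INSTRUMENT_COLUMNS`, order fixed); ``ld`` is the signed
    correlation submatrix aligned to that order.
    """

    variants: pd.DataFrame
    ld: np.ndarray
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.ld = np.asarray(self.ld, dtype=float)
        n = len(self.variants)
        if self.ld.shape != (n, n):
            raise ValueError(f"LD shape {self.ld.shape} does not match {n} variants")
        if n and not np.allclose(self.ld, self.ld.T, atol=1e-8):
            raise ValueError("LD submatrix must be symmetric")
        if n and not np.allclose(np.diag(self.ld), 1.0, atol=1e-6):
            raise ValueError("LD submatrix must have unit diagonal")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome type {self.outcome_type!r}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def subset(self, keep) -> "InstrumentSet":
        """Return a new set restricted to ``keep`` (boolean mask or variant ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep.tolist())
            idx = np.flatnonzero(self.variants["variant_id"].isin(wanted).to_numpy())
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            ld=self.ld[np.ix_(idx, idx)],
        )


def f_statistic(beta, se):
    """Per-variant instrument strength, (beta / se)^2.

    Accepts scalars or arrays; standard errors must be strictly positive.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard error must be strictly positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_instruments(
    variants: pd.DataFrame, f_min: float = 24.0, maf_min: float = 0.01
) -> pd.DataFrame:
    """Keep variants with F-statistic >= ``f_min`` and MAF >= ``maf_min``.

    The minor allele frequency is the folded effect-allele frequency
    ``min(eaf, 1 - eaf)``.  Both thresholds are inclusive and row order is
    preserved.  An empty input yields an empty output.
    """
    if variants.empty:
        return variants.copy()
    f = f_statistic(variants["beta"].to_numpy(), variants["se"].to_numpy())
    maf = np.minimum(variants["eaf"].to_numpy(), 1.0 - variants["eaf"].to_numpy())
    return variants.loc[(f >= f_min) & (maf >= maf_min)].copy()


def select_cis_window(
    gene: GeneAnnotation, variants: pd.DataFrame, flank: int = 200_000
) -> pd.DataFrame:
    """Restrict variants to the cis region ``[start - flank, end + flank]``.

    Coordinates are 1-based and the interval is closed on both sides; only
    variants on the gene's chromosome qualify.
    """
    lo, hi = gene.start - flank, gene.end + flank
    mask = (
        (variants["chromosome"].astype(str) == str(gene.chromosome))
        & (variants["position"] >= lo)
        & (variants["position"] <= hi)
    )
    return variants.loc[mask].copy()


def _aligned_ld(ld, ids: Sequence[str]) -> np.ndarray:
    if isinstance(ld, pd.DataFrame):
        missing = [v for v in ids if v not in ld.index]
        if missing:
            raise ValueError(f"LD matrix lacks variants: {missing[:5]}")
        return ld.loc[list(ids), list(ids)].to_numpy(dtype=float)
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (len(ids), len(ids)):
        raise ValueError(
            f"LD array of shape {ld.shape} is not aligned to {len(ids)} variants"
        )
    return ld


def clump(variants: pd.DataFrame, ld, r2_max: float = 0.3) -> pd.DataFrame:
    """Greedy LD clumping at an r-squared ceiling.

    Repeatedly retain the remaining variant with the smallest p-value (ties
    broken by lexicographically smallest variant id) and drop every remaining
    variant whose squared correlation with it exceeds ``r2_max``.  The result
    is sorted by genomic position and no retained pair has r^2 > ``r2_max``.
    """
    if variants.empty:
        return variants.copy()
    ids = list(variants["variant_id"])
    r2 = _aligned_ld(ld, ids) ** 2
    order = variants.reset_index(drop=True).sort_values(
        ["p_value", "variant_id"], kind="mergesort"
    )
    remaining = np.ones(len(ids), dtype=bool)
    kept: list[int] = []
    for pos in order.index:
        if not remaining[pos]:
            continue
        kept.append(pos)
        remaining &= r2[pos] <= r2_max
        remaining[pos] = False
    out = variants.iloc[sorted(kept)]
    return out.sort_values(["chromosome", "position", "variant_id"], kind="mergesort").copy()


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    return np.array(
        [frozenset({x, y}) in PALINDROMIC_PAIRS for x, y in zip(a1, a2)], dtype=bool
    )


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld=None,
    *,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    outcome_type: str = "binary",
    ambiguous_eaf: float = 0.42,
    ld_effect_alleles: dict[str, str] | None = None,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    For each shared variant: if the outcome's allele coding is the mirror of
    the exposure's, the outcome beta is sign-flipped and its frequency folded;
    variants whose allele sets do not match are dropped; palindromic variants
    (A/T or C/G) whose folded frequency exceeds ``ambiguous_eaf`` in either
    sample are dropped as strand-ambiguous.  ``ld`` (if given) is the signed
    LD matrix in the exposure's allele orientation, subset to the retained
    variants; ``ld_effect_alleles`` maps variant id to the LD panel's effect
    allele when the panel orientation differs from the exposure's, and
    triggers the corresponding row/column sign flips.

    Raises :class:`HarmonizationError` when no variant can be paired.
    """
    merged = exposure.merge(
        outcome, on="variant_id", how="inner", suffixes=("", "_out"), sort=False
    )
    if merged.empty:
        raise HarmonizationError("no overlapping instruments")

    same = (merged["effect_allele_out"] == merged["effect_allele"]) & (
        merged["other_allele_out"] == merged["other_allele"]
    )
    flipped = (merged["effect_allele_out"] == merged["other_allele"]) & (
        merged["other_allele_out"] == merged["effect_allele"]
    )
    palindromic = _is_palindromic(merged["effect_allele"], merged["other_allele"])
    folded_exp = np.minimum(merged["eaf"], 1 - merged["eaf"])
    folded_out = np.minimum(merged["eaf_out"], 1 - merged["eaf_out"])
    ambiguous = palindromic & (
        (folded_exp > ambiguous_eaf) | (folded_out > ambiguous_eaf)
    )
    keep = (same | flipped) & ~ambiguous
    merged = merged.loc[keep].copy()
    if merged.empty:
        raise HarmonizationError("no overlapping instruments after allele checks")
    flip = flipped.loc[keep].to_numpy()
    merged.loc[flip, "beta_out"] = -merged.loc[flip, "beta_out"]
    merged.loc[flip, "eaf_out"] = 1 - merged.loc[flip, "eaf_out"]

    variants = pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "chromosome": merged["chromosome"].astype(str),
            "position": merged["position"],
            "beta_exposure": merged["beta"],
            "se_exposure": merged["se"],
            "p_value_exposure": merged["p_value"],
            "beta_outcome": merged["beta_out"],
            "se_outcome": merged["se_out"],
        }
    )
    ids = list(variants["variant_id"])
    sub = np.eye(len(ids)) if ld is None else _aligned_ld(ld, ids)
    if ld_effect_alleles is not None:
        ea = merged["effect_allele"].to_numpy()
        sign = np.where(
            [ld_effect_alleles.get(v, a) == a for v, a in zip(ids, ea)], 1.0, -1.0
        )
        sub = sub * np.outer(sign, sign)
    return InstrumentSet(
        variants=variants,
        ld=sub,
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        outcome_type=outcome_type,
    )
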