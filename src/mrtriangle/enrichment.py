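"""Tissue expression, druggability, pathway enrichment, and replication.

Prioritised proteins are annotated with cardiac mRNA expression (expressed,
overexpressed relative to the other tissues, and the cardiac fraction of
total expression), joined against a druggability table, tested for pathway
or metabolite-class enrichment with a Wald two-proportion statistic, and
assessed for replication in independent proteomic studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "ReplicationVerdict",
    "cardiac_fraction",
    "cardiac_expression_flags",
    "wald_proportion_enrichment",
    "annotate_druggability",
    "assess_replication",
]

N_TISSUES = 61


@dataclass(frozen=True)
class EnrichmentResult:
    """Wald comparison of a group's share among prioritised vs background."""

    group_label: str
    k_prioritised_in_group: int
    n_prioritised: int
    k_background_in_group: int
    n_background: int
    z: float
    p_value: float
    degenerate: bool = False  # background proportion was 0 or 1


@dataclass
class ReplicationVerdict:
    """Replication status of one discovery association."""

    protein_id: str
    outcome_id: str
    discovery_sign: int
    entries: list[tuple[str, int, float]] = field(default_factory=list)
    nominal: bool = False
    conservative: bool = False


def cardiac_fraction(abundances: pd.Series, cardiac_tissue: str = "heart") -> float:
    """Cardiac abundance divided by total abundance (0 when total is 0)."""
    total = float(abundances.sum())
    if total == 0:
        return 0.0
    return float(abundances[cardiac_tissue]) / total


def cardiac_expression_flags(
    abundances: pd.Series,
    cardiac_tissue: str = "heart",
    overexpression_alpha: float = 0.05,
    min_abundance: float = 0.0,
) -> tuple[bool, bool]:
    """(expressed, overexpressed) flags for one gene's tissue profile.

    ``abundances`` maps the 61 tissue labels to non-negative abundances.
    A gene is expressed when its cardiac abundance exceeds ``min_abundance``,
    and overexpressed when, additionally, the cardiac abundance exceeds the
    mean of the other 60 tissues with a one-sided z-score (cardiac minus
    mean, divided by the across-tissue SD) significant at
    ``overexpression_alpha``.  This statistic is a provisional stand-in for
    a full differential-expression test.
    """
    if len(abundances) != N_TISSUES:
        raise ValueError(f"expected {N_TISSUES} tissues, got {len(abundances)}")
    if cardiac_tissue not in abundances.index:
        raise ValueError(f"no tissue labelled {cardiac_tissue!r}")
    cardiac = float(abundances[cardiac_tissue])
    expressed = cardiac > min_abundance
    if not expressed:
        return False, False
    others = abundances.drop(cardiac_tissue).to_numpy(dtype=float)
    sd = others.std(ddof=1)
    if sd == 0:
        return expressed, cardiac > others.mean()
    z = (cardiac - others.mean()) / sd
    return expressed, bool(z > stats.norm.ppf(1 - overexpression_alpha))


def wald_proportion_enrichment(
    prioritised: Iterable[str],
    background: Iterable[str],
    group: Iterable[str],
    group_label: str = "",
    pooled: bool = False,
    two_sided: bool = True,
) -> EnrichmentResult:
    """Wald test of the group's proportion among prioritised proteins.

    Compares p1 = |prioritised & group| / |prioritised| against
    p0 = |background & group| / |background| with standard error
    ``sqrt(p0 (1 - p0) / n_prioritised)`` (the background proportion under
    the null; ``pooled=True`` uses the pooled two-sample form instead) and
    refers the z statistic to the standard normal.  A degenerate background
    proportion (0 or 1) yields p = 1 with a flag.
    """
    prioritised, background, group = set(prioritised), set(background), set(group)
    if not prioritised:
        raise ValueError("prioritised set is empty")
    if not prioritised <= background:
        raise ValueError("prioritised proteins must be a subset of the background")
    if not group:
        raise ValueError("group is empty")
    k1, n1 = len(prioritised & group), len(prioritised)
    k0, n0 = len(background & group), len(background)
    p1, p0 = k1 / n1, k0 / n0
    if p0 in (0.0, 1.0):
        return EnrichmentResult(group_label, k1, n1, k0, n0, 0.0, 1.0, degenerate=True)
    if pooled:
        se = math.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / n0))
    else:
        se = math.sqrt(p0 * (1 - p0) / n1)
    z = (p1 - p0) / se
    if two_sided:
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(z)
    return EnrichmentResult(group_label, k1, n1, k0, n0, float(z), float(max(p, np.finfo(float).tiny)))


def annotate_druggability(
    proteins: Sequence[str], druggability: pd.DataFrame
) -> pd.DataFrame:
    """Left-join druggability onto the protein list; absentees become 'none'."""
    base = pd.DataFrame({"protein_id": list(proteins)})
    out = base.merge(druggability, on="protein_id", how="left")
    out["status"] = out["status"].fillna("none")
    if "n_drugs" in out.columns:
        out["n_drugs"] = out["n_drugs"].fillna(0).astype(int)
    for col in ("cardiac_indication", "cardiac_side_effect"):
        if col in out.columns:
            out[col] = out[col].astype("boolean").fillna(False).astype(bool)
    return out


def assess_replication(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    n_tested: int,
    alpha: float = 0.05,
) -> tuple[list[ReplicationVerdict], dict]:
    """Judge replication of discovery associations in independent studies.

    ``discovery`` needs columns ``protein_id, outcome_id, beta``;
    ``replication`` needs ``protein_id, outcome_id, study_id, beta,
    p_value``.  An association replicates nominally when some replication
    study shows the same effect direction with p < ``alpha``, and
    conservatively at p < ``alpha / n_tested``.  The summary counts distinct
    proteins and reports percentages of ``n_tested`` rounded to one decimal.
    """
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    conservative_cut = alpha / n_tested
    verdicts: list[ReplicationVerdict] = []
    rep_groups = dict(iter(replication.groupby(["protein_id", "outcome_id"])))
    for row in discovery.itertuples(index=False):
        key = (row.protein_id, row.outcome_id)
        if key not in rep_groups:
            continue
        disc_sign = int(np.sign(row.beta))
        verdict = ReplicationVerdict(
            protein_id=row.protein_id,
            outcome_id=row.outcome_id,
            discovery_sign=disc_sign,
        )
        for rep in rep_groups[key].itertuples(index=False):
            sign = int(np.sign(rep.beta))
            verdict.entries.append((rep.study_id, sign, float(rep.p_value)))
            if sign == disc_sign and rep.p_value < alpha:
                verdict.nominal = True
            if sign == disc_sign and rep.p_value < conservative_cut:
                verdict.conservative = True
        verdicts.append(verdict)

    nominal_proteins = {v.protein_id for v in verdicts if v.nominal}
    conservative_proteins = {v.protein_id for v in verdicts if v.conservative}
    summary = {
        "n_tested": n_tested,
        "conservative_cut": conservative_cut,
        "n_nominal": len(nominal_proteins),
        "pct_nominal": round(100.0 * len(nominal_proteins) / n_tested, 1),
        "n_conservative": len(conservative_proteins),
        "pct_conservative": round(100.0 * len(conservative_proteins) / n_tested, 1),
    }
    return verdicts, summary
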