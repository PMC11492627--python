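"""Multiplicity thresholds, primary-study selection, and triangulation.

A protein is prioritised when three independent MR analyses agree: the
protein affects a metabolite, the metabolite affects a cardiac outcome, and
the protein affects that same outcome in the direction the first two edges
predict (sign(protein->metabolite) * sign(metabolite->outcome) ==
sign(protein->outcome)).  Each edge must pass its own Bonferroni threshold.
Signs are always taken on the slope scale (mean difference or log-odds),
never on the odds-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSpec",
    "Triangle",
    "bonferroni_threshold",
    "select_primary_study",
    "concordant",
    "build_triangles",
    "pleiotropic_summary",
    "triangles_to_network",
]

TRIANGLE_COLUMNS = [
    "protein_id",
    "metabolite_id",
    "outcome_id",
    "beta_protein_metabolite",
    "beta_metabolite_outcome",
    "beta_protein_outcome",
    "p_protein_metabolite",
    "p_metabolite_outcome",
    "p_protein_outcome",
    "concordant",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A Bonferroni threshold: the exact value is used for filtering, the
    one-significant-figure value only for reporting (filtering at the rounded
    value would be more lenient than alpha/m)."""

    alpha: float
    n_exposures: int
    n_outcomes: int
    threshold: float
    threshold_reported: float


@dataclass(frozen=True)
class Triangle:
    """One (protein, metabolite, outcome) triple with three signed effects."""

    protein_id: str
    metabolite_id: str
    outcome_id: str
    beta_protein_metabolite: float
    beta_metabolite_outcome: float
    beta_protein_outcome: float
    p_protein_metabolite: float
    p_metabolite_outcome: float
    p_protein_outcome: float
    concordant: bool


def bonferroni_threshold(
    alpha: float, n_exposures: int, n_outcomes: int
) -> ThresholdSpec:
    """Family-wise threshold ``alpha / (n_exposures * n_outcomes)``."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("counts must be >= 1")
    exact = alpha / (n_exposures * n_outcomes)
    return ThresholdSpec(
        alpha=alpha,
        n_exposures=n_exposures,
        n_outcomes=n_outcomes,
        threshold=exact,
        threshold_reported=float(f"{exact:.1g}"),
    )


def select_primary_study(studies: Sequence[tuple[str, int]]) -> str:
    """The study with the largest sample size; ties break lexicographically."""
    if not studies:
        raise ValueError("no studies supplied")
    return min(studies, key=lambda s: (-s[1], s[0]))[0]


def concordant(sign_pm: int, sign_mo: int, sign_po: int) -> bool:
    """Directional concordance of a triple of signed effects.

    True iff ``sign_pm * sign_mo == sign_po``; a zero sign has no defined
    direction and raises.
    """
    if 0 in (sign_pm, sign_mo, sign_po):
        raise ValueError("undefined direction: all three signs must be non-zero")
    return int(np.sign(sign_pm)) * int(np.sign(sign_mo)) == int(np.sign(sign_po))


def _edge_table(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    required = {"exposure_id", "outcome_id", "beta", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    mask = (table["p_value"] < threshold) & (table["beta"] != 0)
    return table.loc[mask, ["exposure_id", "outcome_id", "beta", "p_value"]]


def build_triangles(
    metabolite_outcome: pd.DataFrame,
    protein_metabolite: pd.DataFrame,
    protein_outcome: pd.DataFrame,
    thresholds: dict[str, float],
    concordant_only: bool = True,
) -> pd.DataFrame:
    """Assemble directionally concordant triangles from three edge tables.

    Each table needs columns ``exposure_id, outcome_id, beta, p_value`` with
    ``beta`` on the slope (MD / log-odds) scale.  ``thresholds`` maps
    ``metabolite_outcome``, ``protein_metabolite`` and ``protein_outcome`` to
    the exact multiplicity thresholds for the three steps.  One row is
    emitted per qualifying (protein, metabolite, outcome) triple; a protein
    may appear in many triangles.
    """
    for key in ("metabolite_outcome", "protein_metabolite", "protein_outcome"):
        if key not in thresholds:
            raise ValueError(f"missing threshold for edge {key!r}")
    mo = _edge_table(metabolite_outcome, thresholds["metabolite_outcome"]).rename(
        columns={
            "exposure_id": "metabolite_id",
            "outcome_id": "outcome_id",
            "beta": "beta_metabolite_outcome",
            "p_value": "p_metabolite_outcome",
        }
    )
    pm = _edge_table(protein_metabolite, thresholds["protein_metabolite"]).rename(
        columns={
            "exposure_id": "protein_id",
            "outcome_id": "metabolite_id",
            "beta": "beta_protein_metabolite",
            "p_value": "p_protein_metabolite",
        }
    )
    po = _edge_table(protein_outcome, thresholds["protein_outcome"]).rename(
        columns={
            "exposure_id": "protein_id",
            "outcome_id": "outcome_id",
            "beta": "beta_protein_outcome",
            "p_value": "p_protein_outcome",
        }
    )
    merged = pm.merge(mo, on="metabolite_id").merge(po, on=["protein_id", "outcome_id"])
    if merged.empty:
        return pd.DataFrame(columns=TRIANGLE_COLUMNS)
    sign = np.sign(merged["beta_protein_metabolite"]) * np.sign(
        merged["beta_metabolite_outcome"]
    )
    merged["concordant"] = sign == np.sign(merged["beta_protein_outcome"])
    if concordant_only:
        merged = merged.loc[merged["concordant"]]
    out = merged[TRIANGLE_COLUMNS].sort_values(
        ["protein_id", "metabolite_id", "outcome_id"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def pleiotropic_summary(triangles: pd.DataFrame) -> pd.DataFrame:
    """Per-protein count of distinct outcomes affected; >= 2 flags pleiotropy."""
    if triangles.empty:
        return pd.DataFrame(columns=["protein_id", "n_outcomes", "pleiotropic"])
    counts = (
        triangles.groupby("protein_id")["outcome_id"]
        .nunique()
        .rename("n_outcomes")
        .reset_index()
        .sort_values("protein_id", kind="mergesort")
        .reset_index(drop=True)
    )
    counts["pleiotropic"] = counts["n_outcomes"] >= 2
    return counts


def triangles_to_network(
    triangles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export triangles as typed node and signed edge tables."""
    nodes = pd.concat(
        [
            pd.DataFrame({"node_id": triangles["protein_id"], "node_type": "protein"}),
            pd.DataFrame(
                {"node_id": triangles["metabolite_id"], "node_type": "metabolite"}
            ),
            pd.DataFrame({"node_id": triangles["outcome_id"], "node_type": "outcome"}),
        ]
    ).drop_duplicates()
    nodes = nodes.sort_values(["node_type", "node_id"], kind="mergesort").reset_index(
        drop=True
    )

    def edges(src, dst, beta):
        return pd.DataFrame(
            {
                "source": triangles[src],
                "target": triangles[dst],
                "sign": np.sign(triangles[beta]).astype(int),
            }
        )

    edge_table = (
        pd.concat(
            [
                edges("protein_id", "metabolite_id", "beta_protein_metabolite"),
                edges("metabolite_id", "outcome_id", "beta_metabolite_outcome"),
                edges("protein_id", "outcome_id", "beta_protein_outcome"),
            ]
        )
        .drop_duplicates()
        .sort_values(["source", "target"], kind="mergesort")
        .reset_index(drop=True)
    )
    return nodes, edge_table
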