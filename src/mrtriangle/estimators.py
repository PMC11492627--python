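"""Correlation-aware IVW and Egger estimators with model selection.

The causal slope of an exposure on an outcome is estimated by generalised
least squares (GLS): outcome per-allele effects ``y`` are regressed on
exposure per-allele effects ``x`` with weight matrix ``Omega^-1``, where
``Omega = D R D`` for ``D = diag(outcome SEs)`` and ``R`` the signed LD
correlation matrix of the instruments.  Without an intercept this is the
inverse-variance-weighted (IVW) estimator generalised to correlated
instruments; with a free intercept it is the MR-Egger estimator, whose
intercept absorbs directional horizontal pleiotropy.

Heterogeneity is summarised by Cochran's Q computed on the whitened
residuals; the per-coordinate squared whitened residuals serve as outlier
statistics and the diagonal of the whitened hat matrix as leverage.  The
Ruecker framework selects Egger over IVW when the drop in Q attributable to
the intercept exceeds the chi-square(1 df) critical value.

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with a trailing underscore) so they compose
with sklearn tooling; :func:`fit_gls` and :func:`run_mr` are the thin
functional layer the pipeline uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .instruments import (
    GeneAnnotation,
    InstrumentSet,
    HarmonizationError,
    clump,
    filter_instruments,
    harmonize,
    select_cis_window,
)

__all__ = [
    "GLSMendelianRandomization",
    "IVWEstimator",
    "EggerEstimator",
    "IllConditionedLDError",
    "MRFit",
    "MRResult",
    "fit_gls",
    "prune_variants",
    "influential_variants",
    "rucker_select",
    "to_reported_effect",
    "run_mr",
    "results_to_frame",
]

IVW = "IVW"
EGGER = "Egger"
DISCARDED = "discarded"

#: 95% CI multiplier, used verbatim so printed intervals round-trip
Z_95 = 1.96


class IllConditionedLDError(ValueError):
    """The instrument correlation matrix is singular after regularisation."""


@dataclass
class MRFit:
    """One GLS fit: estimates, heterogeneity, and influence diagnostics."""

    estimator: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    q_statistic: float
    df: int
    n_variants_used: int
    leverage: np.ndarray
    outlier_stats: np.ndarray
    variant_ids: list[str] = field(default_factory=list)
    excluded_leverage: list[str] = field(default_factory=list)
    excluded_outlier: list[str] = field(default_factory=list)


@dataclass
class MRResult:
    """The reported exposure -> outcome effect for one analysis."""

    exposure_id: str
    outcome_id: str
    chosen_estimator: str  # IVW, Egger, or discarded
    effect_scale: str  # "mean difference" or "odds ratio"
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_variants_used: int
    slope: float = math.nan
    slope_se: float = math.nan
    q_ivw: float = math.nan
    q_egger: float = math.nan
    excluded_leverage: list[str] = field(default_factory=list)
    excluded_outlier: list[str] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)


class GLSMendelianRandomization(RegressorMixin, BaseEstimator):
    """GLS regression of outcome betas on exposure betas.

    Parameters
    ----------
    fit_intercept : bool
        False gives the IVW estimator (regression through the origin), True
        the MR-Egger estimator.
    ridge : float
        Small value added to the diagonal of the LD correlation matrix before
        inversion; clumping at r^2 = 0.3 leaves correlated instruments and a
        near-singular matrix must fail loudly rather than silently.

    Attributes
    ----------
    slope_, slope_se_ : float
        Causal slope estimate and its GLS standard error.
    intercept_, intercept_se_ : float
        Egger intercept and SE (0 by construction when ``fit_intercept`` is
        False).
    q_statistic_, df_ : float, int
        Cochran's Q on the whitened residuals and its degrees of freedom.
    leverage_ : ndarray
        Diagonal of the whitened hat matrix; entries in [0, 1] summing to the
        number of fitted parameters.
    outlier_stats_ : ndarray
        Per-variant squared standardised residuals; they sum to Q.
    """

    def __init__(self, fit_intercept: bool = False, ridge: float = 1e-8):
        self.fit_intercept = fit_intercept
        self.ridge = ridge

    def fit(self, X, y, *, outcome_se=None, ld=None):
        X, y = check_X_y(X, y, ensure_min_features=1, y_numeric=True)
        if X.shape[1] != 1:
            raise ValueError("expected a single exposure-beta column")
        n = len(y)
        n_params = 2 if self.fit_intercept else 1
        if n < n_params + 1:
            raise ValueError(
                f"need at least {n_params + 1} variants, got {n}"
            )
        se = np.ones(n) if outcome_se is None else np.asarray(outcome_se, float)
        if se.shape != (n,) or np.any(se <= 0):
            raise ValueError("outcome_se must be positive with one entry per variant")
        R = np.eye(n) if ld is None else np.asarray(ld, float)
        if R.shape != (n, n):
            raise ValueError("ld must be square and aligned to the variants")
        omega = se[:, None] * (R + self.ridge * np.eye(n)) * se[None, :]
        try:
            L = linalg.cholesky(omega, lower=True)
        except linalg.LinAlgError as exc:
            raise IllConditionedLDError(
                "ill-conditioned LD: covariance not positive definite"
            ) from exc
        design = np.column_stack([np.ones(n), X[:, 0]]) if self.fit_intercept else X
        Xw = linalg.solve_triangular(L, design, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        gram = Xw.T @ Xw
        try:
            cov = linalg.inv(gram)
        except linalg.LinAlgError as exc:
            raise IllConditionedLDError("degenerate design after whitening") from exc
        theta = cov @ (Xw.T @ yw)
        resid = yw - Xw @ theta
        self.n_features_in_ = 1
        self.n_variants_ = n
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(theta[0]), theta[1:].copy()
            self.intercept_se_ = float(np.sqrt(cov[0, 0]))
            self.slope_se_ = float(np.sqrt(cov[1, 1]))
        else:
            self.intercept_, self.coef_ = 0.0, theta.copy()
            self.intercept_se_ = 0.0
            self.slope_se_ = float(np.sqrt(cov[0, 0]))
        self.slope_ = float(self.coef_[0])
        self.q_statistic_ = float(resid @ resid)
        self.df_ = n - n_params
        self.leverage_ = np.einsum("ij,jk,ik->i", Xw, cov, Xw)
        self.outlier_stats_ = resid**2
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = check_array(X)
        return self.intercept_ + X[:, 0] * self.slope_


class IVWEstimator(GLSMendelianRandomization):
    """Inverse-variance-weighted GLS estimator (no intercept)."""

    def __init__(self, ridge: float = 1e-8):
        super().__init__(fit_intercept=False, ridge=ridge)

    def get_params(self, deep=True):  # keep sklearn param introspection honest
        return {"ridge": self.ridge}


class EggerEstimator(GLSMendelianRandomization):
    """MR-Egger GLS estimator (free intercept absorbing pleiotropy)."""

    def __init__(self, ridge: float = 1e-8):
        super().__init__(fit_intercept=True, ridge=ridge)

    def get_params(self, deep=True):
        return {"ridge": self.ridge}


def fit_gls(instr: InstrumentSet, with_intercept: bool = False, ridge: float = 1e-8) -> MRFit:
    """Fit the IVW (or, with intercept, Egger) GLS model on an instrument set."""
    est = GLSMendelianRandomization(fit_intercept=with_intercept, ridge=ridge).fit(
        instr.variants[["beta_exposure"]].to_numpy(),
        instr.variants["beta_outcome"].to_numpy(),
        outcome_se=instr.variants["se_outcome"].to_numpy(),
        ld=instr.ld,
    )
    return MRFit(
        estimator=EGGER if with_intercept else IVW,
        slope=est.slope_,
        slope_se=est.slope_se_,
        intercept=est.intercept_,
        intercept_se=est.intercept_se_,
        q_statistic=est.q_statistic_,
        df=est.df_,
        n_variants_used=est.n_variants_,
        leverage=est.leverage_,
        outlier_stats=est.outlier_stats_,
        variant_ids=instr.variant_ids,
    )


def influential_variants(
    fit: MRFit, leverage_factor: float = 3.0, outlier_cut: float = 10.83
) -> tuple[list[str], list[str]]:
    """Variant ids flagged for high leverage and for outlying residuals."""
    lev_mask = fit.leverage > leverage_factor * fit.leverage.mean()
    out_mask = fit.outlier_stats > outlier_cut
    ids = np.asarray(fit.variant_ids)
    return list(ids[lev_mask]), list(ids[out_mask])


def prune_variants(
    instr: InstrumentSet,
    fit: MRFit,
    leverage_factor: float = 3.0,
    outlier_cut: float = 10.83,
) -> InstrumentSet:
    """Drop the union of high-leverage and outlier variants from the set."""
    lev, out = influential_variants(fit, leverage_factor, outlier_cut)
    drop = set(lev) | set(out)
    if not drop:
        return instr
    keep = ~instr.variants["variant_id"].isin(drop).to_numpy()
    return instr.subset(keep)


def rucker_select(ivw_fit: MRFit, egger_fit: MRFit, alpha: float = 0.05) -> str:
    """Choose IVW or Egger from the drop in heterogeneity.

    Egger is preferred iff ``Q_IVW - Q_Egger`` exceeds the upper-``alpha``
    chi-square quantile with 1 df (3.841 at alpha = 0.05).
    """
    q_diff = ivw_fit.q_statistic - egger_fit.q_statistic
    if q_diff < -1e-6 * max(1.0, ivw_fit.q_statistic):
        raise ValueError(
            f"Q_IVW ({ivw_fit.q_statistic:.6g}) < Q_Egger "
            f"({egger_fit.q_statistic:.6g}): fits are inconsistent"
        )
    return EGGER if q_diff > stats.chi2.ppf(1 - alpha, df=1) else IVW


def to_reported_effect(
    slope: float, slope_se: float, outcome_type: str
) -> tuple[float, float, float]:
    """Map a slope and SE to the reporting scale with a 95% CI.

    Binary outcomes are reported as odds ratios, ``exp(slope)`` with
    ``exp(slope +/- 1.96 se)``; continuous outcomes as mean differences on
    the identity scale.
    """
    if slope_se <= 0:
        raise ValueError("slope_se must be strictly positive")
    lo, hi = slope - Z_95 * slope_se, slope + Z_95 * slope_se
    if outcome_type == "binary":
        return math.exp(slope), math.exp(lo), math.exp(hi)
    return slope, lo, hi


def _discarded(
    exposure_id, outcome_id, outcome_type, n_variants, stage_counts
) -> MRResult:
    return MRResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        chosen_estimator=DISCARDED,
        effect_scale="odds ratio" if outcome_type == "binary" else "mean difference",
        estimate=math.nan,
        ci_lower=math.nan,
        ci_upper=math.nan,
        p_value=math.nan,
        n_variants_used=n_variants,
        stage_counts=stage_counts,
    )


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld=None,
    gene: GeneAnnotation | None = None,
    *,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    outcome_type: str = "binary",
    f_min: float = 24.0,
    maf_min: float = 0.01,
    flank: int = 200_000,
    r2_max: float = 0.3,
    min_variants: int = 6,
    leverage_factor: float = 3.0,
    outlier_cut: float = 10.83,
    selection_alpha: float = 0.05,
    ridge: float = 1e-8,
    max_prune_rounds: int = 10,
) -> MRResult:
    """Run one full two-sample MR analysis.

    Pipeline: strength/MAF filter -> cis-window restriction (when ``gene`` is
    given) -> harmonisation -> LD clumping -> iterated IVW-based pruning of
    high-leverage and outlier variants -> Ruecker model selection -> effect
    on the reporting scale.  Analyses that fall below ``min_variants`` at any
    stage are reported as discarded with no estimate.
    """
    stage_counts = {"input": len(exposure)}
    exposure = filter_instruments(exposure, f_min=f_min, maf_min=maf_min)
    stage_counts["filtered"] = len(exposure)
    if gene is not None:
        exposure = select_cis_window(gene, exposure, flank=flank)
        stage_counts["cis"] = len(exposure)
    if len(exposure) < min_variants:
        return _discarded(exposure_id, outcome_id, outcome_type, len(exposure), stage_counts)
    try:
        instr = harmonize(
            exposure,
            outcome,
            ld,
            exposure_id=exposure_id,
            outcome_id=outcome_id,
            outcome_type=outcome_type,
        )
    except HarmonizationError:
        stage_counts["harmonised"] = 0
        return _discarded(exposure_id, outcome_id, outcome_type, 0, stage_counts)
    stage_counts["harmonised"] = instr.n_variants
    clumped = clump(
        instr.variants.rename(
            columns={"p_value_exposure": "p_value"}
        )[["variant_id", "chromosome", "position", "p_value"]],
        pd.DataFrame(instr.ld, index=instr.variant_ids, columns=instr.variant_ids),
        r2_max=r2_max,
    )
    instr = instr.subset(np.asarray(clumped["variant_id"]))
    stage_counts["clumped"] = instr.n_variants
    if instr.n_variants < min_variants:
        return _discarded(
            exposure_id, outcome_id, outcome_type, instr.n_variants, stage_counts
        )

    excluded_leverage: list[str] = []
    excluded_outlier: list[str] = []
    for _ in range(max_prune_rounds):
        ivw = fit_gls(instr, with_intercept=False, ridge=ridge)
        lev, out = influential_variants(ivw, leverage_factor, outlier_cut)
        drop = set(lev) | set(out)
        if not drop:
            break
        excluded_leverage += lev
        excluded_outlier += out
        instr = instr.subset(~instr.variants["variant_id"].isin(drop).to_numpy())
        if instr.n_variants < min_variants:
            stage_counts["pruned"] = instr.n_variants
            return _discarded(
                exposure_id, outcome_id, outcome_type, instr.n_variants, stage_counts
            )
    stage_counts["pruned"] = instr.n_variants

    ivw = fit_gls(instr, with_intercept=False, ridge=ridge)
    egger = fit_gls(instr, with_intercept=True, ridge=ridge)
    chosen = rucker_select(ivw, egger, alpha=selection_alpha)
    fit = egger if chosen == EGGER else ivw
    estimate, lo, hi = to_reported_effect(fit.slope, fit.slope_se, outcome_type)
    z = fit.slope / fit.slope_se
    p = max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)
    return MRResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        chosen_estimator=chosen,
        effect_scale="odds ratio" if outcome_type == "binary" else "mean difference",
        estimate=estimate,
        ci_lower=lo,
        ci_upper=hi,
        p_value=float(p),
        n_variants_used=instr.n_variants,
        slope=fit.slope,
        slope_se=fit.slope_se,
        q_ivw=ivw.q_statistic,
        q_egger=egger.q_statistic,
        excluded_leverage=excluded_leverage,
        excluded_outlier=excluded_outlier,
        stage_counts=stage_counts,
    )


def results_to_frame(results) -> pd.DataFrame:
    """Collect MRResult records into the tidy per-analysis result table."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_id,
                "outcome": r.outcome_id,
                "estimator": r.chosen_estimator,
                "n_variants": r.n_variants_used,
                "slope": r.slope,
                "se": r.slope_se,
                "estimate": r.estimate,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p": r.p_value,
                "q_ivw": r.q_ivw,
                "q_egger": r.q_egger,
                "excluded_leverage": ";".join(r.excluded_leverage),
                "excluded_outlier": ";".join(r.excluded_outlier),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure",
            "outcome",
            "estimator",
            "n_variants",
            "slope",
            "se",
            "estimate",
            "ci_lower",
            "ci_upper",
            "p",
            "q_ivw",
            "q_egger",
            "excluded_leverage",
            "excluded_outlier",
        ],
    )
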