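"""Quadratic trends of opsin expression against local androchrome frequency.

The biological question: does a male's opsin expression track the female
morph composition of his population?  A U-shaped (convex) relationship —
elevated expression where the androchrome morph is either rare or nearly
fixed — is the signature of interest, so the core fit is ordinary least
squares of per-individual log relative expression on androchrome frequency
and its square, run separately per opsin × maturity stage on replicate-
averaged values.  (Site/individual/year random effects are deliberately
out of scope; this is the marginal fixed-effects analogue of the full
mixed model.)

Convexity is "detected" when the quadratic coefficient is positive with
|t| > 2; when many opsin × stage fits are screened at once,
:func:`convexity_screen` applies a Holm correction across the family so a
single convex relationship can be isolated without multiplicity false
alarms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrendFit",
    "quadratic_trend",
    "trend_curvature_contrast",
    "fit_all_trends",
    "convexity_screen",
]


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of y on (1, x, x²) for one opsin × stage."""

    opsin: str
    stage: str
    coefficients: np.ndarray  # (intercept, linear, quadratic)
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    n: int

    @property
    def convex(self) -> bool:
        return bool(self.coefficients[2] > 0)

    @property
    def significant_curvature(self) -> bool:
        return bool(abs(self.t_values[2]) > 2)

    @property
    def vertex_frequency(self) -> float | None:
        """Stationary frequency −β1/(2β2); reported only when the curvature
        is statistically supported (|t| > 2)."""
        b0, b1, b2 = self.coefficients
        if b2 == 0 or not self.significant_curvature:
            return None
        return float(-b1 / (2.0 * b2))

    def predict(self, x: np.ndarray) -> np.ndarray:
        b0, b1, b2 = self.coefficients
        return b0 + b1 * x + b2 * x**2


def quadratic_trend(
    x: np.ndarray, y: np.ndarray, opsin: str = "", stage: str = ""
) -> TrendFit:
    """OLS fit of ``y`` (log relative expression) on androchrome frequency
    ``x`` and its square.

    Requires n ≥ 4 with at least 3 distinct x values (otherwise the design
    matrix is rank deficient and the quadratic is unidentifiable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values")
    X = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient quadratic design")
    res = sm.OLS(y, X).fit()
    return TrendFit(
        opsin=opsin,
        stage=stage,
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        n=int(x.size),
    )


def trend_curvature_contrast(
    fit_mature: TrendFit, fit_immature: TrendFit
) -> tuple[float, float]:
    """Difference in quadratic coefficients between two stages.

    Returns (Δβ2, s.e.) with the standard error pooled under independence
    of the two fits: se = sqrt(se_mature² + se_immature²).
    """
    d = float(fit_mature.coefficients[2] - fit_immature.coefficients[2])
    se = float(np.hypot(fit_mature.standard_errors[2], fit_immature.standard_errors[2]))
    return d, se


def fit_all_trends(
    expression: pd.DataFrame,
    frequencies: pd.DataFrame,
    stages: tuple[str, ...] = ("immature", "mature"),
    value_col: str = "log_relative_expression",
) -> list[TrendFit]:
    """Fit the quadratic trend for every opsin × stage combination.

    ``expression`` is the replicate-averaged per-individual table (columns
    ``individual_id, stage, site_id, year, gene`` and ``value_col``);
    ``frequencies`` maps site × year to the mature-female androchrome
    frequency (columns ``site_id, year, frequency``).  The UV calibrator is
    skipped (its log relative expression is identically 0).
    """
    freq = frequencies.set_index(["site_id", "year"])["frequency"]
    df = expression[expression["stage"].isin(stages)].copy()
    df["x"] = [freq.get((s, y), np.nan) for s, y in zip(df["site_id"], df["year"])]
    df = df.dropna(subset=["x", value_col])
    fits = []
    for (gene, stage), grp in df.groupby(["gene", "stage"], sort=True):
        if grp[value_col].abs().max() < 1e-12:  # calibrator gene
            continue
        fits.append(quadratic_trend(grp["x"], grp[value_col], opsin=gene, stage=stage))
    return fits


def convexity_screen(fits: list[TrendFit], alpha: float = 0.05) -> list[TrendFit]:
    """Holm-corrected screen for convex (U-shaped) trends across a family
    of opsin × stage fits.

    Returns the fits whose quadratic coefficient is positive and whose
    two-sided curvature p-value survives Holm correction at level alpha.
    """
    if not fits:
        return []
    pvals = [f.p_values[2] for f in fits]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return [f for f, r in zip(fits, reject) if r and f.convex]
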