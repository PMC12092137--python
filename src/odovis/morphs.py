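"""Female colour-morph frequency summaries and between-year comparisons.

Counts are of mature females only — immature females change colour during
maturation, so only mature coloration identifies the genetic morph.  The
three Ischnura elegans morphs are the male-coloured androchrome and the
green (infuscans) and brown (infuscans-obsoleta) gynochromes.

Between-year tests on a 2 × k contingency table use the Pearson chi-square
statistic, falling back to a full-enumeration Fisher exact test whenever
any expected cell count drops below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MORPHS",
    "morph_frequencies",
    "compare_years",
    "YearComparison",
    "fisher_exact_2xk",
]

MORPHS = ("androchrome", "infuscans", "infuscans_obsoleta")


def morph_frequencies(counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Morph frequencies per site × year plus across-site yearly summaries.

    Parameters
    ----------
    counts
        Long table with columns ``site_id, year, morph, count`` (mature
        females only).  Sites with zero total in a year are flagged and
        excluded from the yearly summaries.

    Returns
    -------
    dict with ``"per_site"`` (site, year, morph, count, n, frequency) and
    ``"per_year"`` (year, morph, mean, sd, min, max of frequency across
    sites) DataFrames.
    """
    df = counts.copy()
    if (df["count"] < 0).any():
        raise ValueError("negative morph counts")
    totals = df.groupby(["site_id", "year"])["count"].transform("sum")
    df["n"] = totals
    df["excluded"] = df["n"] == 0
    with np.errstate(invalid="ignore"):
        df["frequency"] = np.where(df["n"] > 0, df["count"] / df["n"].where(df["n"] > 0), np.nan)

    valid = df[~df["excluded"]]
    per_year = (
        valid.groupby(["year", "morph"])["frequency"]
        .agg(mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    # per-site frequencies must sum to 1 over morphs
    sums = valid.groupby(["site_id", "year"])["frequency"].sum()
    assert np.allclose(sums, 1.0, atol=1e-12)
    return {"per_site": df, "per_year": per_year}


@dataclass(frozen=True)
class YearComparison:
    statistic: float
    df: int
    p_value: float
    method: str  # "pearson_chi2" | "fisher_exact"
    table: np.ndarray


def _pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    expected = stats.contingency.expected_freq(table)
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, dof


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2 × k table by full enumeration.

    Enumerates every table with the observed margins, computing each
    table's multivariate hypergeometric probability, and sums those no
    larger than the observed table's (with a 1+1e-9 slack for float ties).
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    row1 = int(table[0].sum())
    cols = table.sum(axis=0)
    n = int(table.sum())

    def log_comb(nn: int, kk: int) -> float:
        return lgamma(nn + 1) - lgamma(kk + 1) - lgamma(nn - kk + 1)

    def log_prob(first_row: tuple[int, ...]) -> float:
        # P(table | margins) = prod_j C(c_j, a_j) / C(n, row1)
        num = sum(log_comb(int(c), int(a)) for c, a in zip(cols, first_row))
        return num - log_comb(n, row1)

    p_obs = log_prob(tuple(table[0]))
    total = 0.0
    ranges = [range(0, int(c) + 1) for c in cols[:-1]]
    for partial in product(*ranges):
        last = row1 - sum(partial)
        if last < 0 or last > cols[-1]:
            continue
        lp = log_prob((*partial, last))
        if lp <= p_obs + 1e-9:
            total += float(np.exp(lp))
    return min(total, 1.0)


def compare_years(
    counts_y1: dict[str, int] | np.ndarray,
    counts_y2: dict[str, int] | np.ndarray,
    morphs: tuple[str, ...] = MORPHS,
) -> YearComparison:
    """Test whether morph frequencies differ between two years at one site.

    Builds the 2 × k table (years × morphs), drops morph columns that are
    zero in both years, and applies the Pearson chi-square test, switching
    to the enumeration Fisher exact test when any expected count is < 5.
    """
    def as_row(c):
        if isinstance(c, dict):
            return np.array([c.get(m, 0) for m in morphs], dtype=int)
        return np.asarray(c, dtype=int)

    table = np.vstack([as_row(counts_y1), as_row(counts_y2)])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 informative morph columns")

    stat, dof = _pearson_chi2(table)
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        p = fisher_exact_2xk(table)
        return YearComparison(stat, dof, p, "fisher_exact", table)
    p = float(stats.chi2.sf(stat, dof))
    return YearComparison(stat, dof, p, "pearson_chi2", table)
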