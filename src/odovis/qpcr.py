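"""Efficiency-corrected relative and proportional opsin expression from qPCR.

Expression is quantified by the efficiency-corrected ΔΔCT family of methods:
each target gene's quantity ``(1+E)^-Ct`` is normalized to the geometric
mean of two housekeeping genes and then calibrated against the UV opsin
measured in the same individual and qPCR replicate, so the UV opsin's
relative expression is 1 by construction.  Proportional expression divides
each compound-eye opsin's relative expression by the summed relative
expression of the configured compound-eye opsin set.

All tables are long-format pandas DataFrames with one row per measurement:
``individual_id, stage, site_id, year, gene, replicate, ct``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QpcrConfig",
    "standard_curve_efficiency",
    "relative_expression",
    "replicate_average",
    "proportional_expression",
    "expression_pipeline",
]

log = logging.getLogger(__name__)

#: opsins attributed to the main compound eye; LWE is excluded because its
#: orthologues show ocellus-restricted expression.
DEFAULT_COMPOUND_EYE_GENES = ("UV", "SW1", "SW2", "LWA", "LWF1", "LWF2", "LWF3", "LWF4")


@dataclass(frozen=True)
class QpcrConfig:
    housekeeping: tuple[str, str] = ("EF1a", "RPL13")
    calibrator: str = "UV"
    compound_eye_genes: tuple[str, ...] = DEFAULT_COMPOUND_EYE_GENES
    #: if an individual is missing one housekeeping Ct: "skip" the individual
    #: or fall back to "single" reference with a warning
    missing_housekeeping: str = "skip"
    #: maximum number of opsins that may be missing before an individual is
    #: excluded entirely
    max_missing_opsins: int = 2


def validate_efficiencies(eff: dict[str, float]) -> dict[str, float]:
    """Check primer efficiencies are physically plausible.

    E must lie in [0.7, 1.15]; values outside [0.9, 1.1] trigger a warning
    (the assay is usable but poorly optimized).
    """
    for gene, e in eff.items():
        if not (0.7 <= e <= 1.15):
            raise ValueError(f"primer efficiency for {gene} = {e} outside [0.7, 1.15]")
        if not (0.9 <= e <= 1.1):
            warnings.warn(f"primer efficiency for {gene} = {e} outside [0.9, 1.1]", stacklevel=2)
    return dict(eff)


def standard_curve_efficiency(ct_by_log10_dilution) -> float:
    """Primer efficiency from a dilution-series standard curve.

    Parameters
    ----------
    ct_by_log10_dilution
        Sequence of ``(log10_dilution, ct)`` pairs, at least 3 points
        spanning at least 2 log10 units.

    Returns
    -------
    E = 10**(-1/slope) - 1 where slope is the least-squares slope of Ct on
    log10 dilution.  A perfect-doubling assay has slope -3.3219 and E = 1.
    """
    arr = np.asarray(list(ct_by_log10_dilution), dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 dilution points")
    x, y = arr[:, 0], arr[:, 1]
    if x.max() - x.min() < 2.0:
        raise ValueError("dilutions must span at least 2 log10 units")
    slope = np.polyfit(x, y, 1)[0]
    if slope >= 0:
        raise ValueError(f"non-negative standard-curve slope ({slope:.3f}): failed assay")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def _quantity(ct: pd.Series, eff: dict[str, float], genes: pd.Series) -> pd.Series:
    e = genes.map(eff).astype(float)
    return np.power(1.0 + e, -ct)


def relative_expression(
    ct: pd.DataFrame,
    efficiencies: dict[str, float],
    config: QpcrConfig = QpcrConfig(),
) -> pd.DataFrame:
    """Per-replicate relative expression, UV-calibrated and reference-normalized.

    For every individual × replicate, each target gene's quantity
    ``(1+E_g)^-Ct_g`` is divided by the geometric mean of the two
    housekeeping quantities, and the resulting ratio divided by the same
    ratio for the calibrator (UV) gene.  Returns a long DataFrame with
    ``relative_expression`` and natural-``log_relative_expression`` columns;
    housekeeping genes are dropped from the output.

    Individuals missing the calibrator Ct (or too many opsins, per config)
    are skipped with a logged warning.
    """
    eff = validate_efficiencies(efficiencies)
    hk1, hk2 = config.housekeeping
    df = ct.copy()
    bad_ct = df["ct"].notna() & ((df["ct"] <= 5) | (df["ct"] >= 45))
    if bad_ct.any():
        raise ValueError(f"{int(bad_ct.sum())} Ct values outside (5, 45)")
    missing = [g for g in set(df["gene"]) - set(eff)]
    if missing:
        raise ValueError(f"no primer efficiency for genes: {sorted(missing)}")
    df = df.dropna(subset=["ct"])
    df["quantity"] = _quantity(df["ct"], eff, df["gene"])

    meta_cols = [c for c in ("stage", "site_id", "year") if c in df.columns]
    out_rows = []
    for (ind, rep), grp in df.groupby(["individual_id", "replicate"], sort=True):
        by_gene = grp.set_index("gene")["quantity"]
        hk_present = [h for h in (hk1, hk2) if h in by_gene.index]
        if len(hk_present) < 2:
            if config.missing_housekeeping == "single" and hk_present:
                log.warning(
                    "individual %s replicate %s: single housekeeping reference %s",
                    ind, rep, hk_present[0],
                )
            else:
                log.warning("individual %s replicate %s: missing housekeeping, skipped", ind, rep)
                continue
        if config.calibrator not in by_gene.index:
            log.warning("individual %s replicate %s: missing %s Ct, skipped",
                        ind, rep, config.calibrator)
            continue
        hk_geo = float(np.exp(np.mean(np.log(by_gene.loc[hk_present]))))
        ratios = by_gene.drop(index=hk_present) / hk_geo
        rel = ratios / ratios.loc[config.calibrator]
        meta = grp.iloc[0]
        for gene, value in rel.items():
            out_rows.append(
                {
                    "individual_id": ind,
                    **{c: meta[c] for c in meta_cols},
                    "gene": gene,
                    "replicate": rep,
                    "relative_expression": float(value),
                    "log_relative_expression": float(np.log(value)),
                }
            )
    out = pd.DataFrame(out_rows)
    if out.empty:
        return out
    n_opsins = out.groupby(["individual_id", "replicate"])["gene"].nunique()
    expected = df["gene"].nunique() - 2  # minus housekeeping
    too_few = n_opsins[n_opsins < expected - config.max_missing_opsins]
    if not too_few.empty:
        drop = set(too_few.index)
        log.warning("excluding %d individual/replicate groups missing > %d opsins",
                    len(drop), config.max_missing_opsins)
        keep = ~out.set_index(["individual_id", "replicate"]).index.isin(drop)
        out = out[keep].reset_index(drop=True)
    return out


def replicate_average(records: pd.DataFrame) -> pd.DataFrame:
    """Average qPCR replicates on the log scale, one row per individual × gene.

    Relative expression is re-reported as ``exp(mean log)`` so the averaged
    record is internally consistent (geometric mean on the linear scale).
    """
    meta_cols = [c for c in ("stage", "site_id", "year") if c in records.columns]
    grouped = records.groupby(["individual_id", *meta_cols, "gene"], sort=True, dropna=False)
    out = grouped["log_relative_expression"].mean().reset_index()
    out["relative_expression"] = np.exp(out["log_relative_expression"])
    out["n_replicates"] = grouped.size().values
    return out


def proportional_expression(
    records: pd.DataFrame,
    compound_eye_genes: tuple[str, ...] = DEFAULT_COMPOUND_EYE_GENES,
) -> pd.DataFrame:
    """Proportion of total compound-eye opsin expression per individual.

    Each gene's (replicate-averaged) relative expression is divided by the
    sum across the configured compound-eye gene set; proportions per
    individual sum to 1.  Genes outside the set (e.g. the ocellar LWE) get
    no proportion.
    """
    recs = records[records["gene"].isin(compound_eye_genes)].copy()
    counts = recs.groupby("individual_id")["gene"].nunique()
    incomplete = counts[counts < len(compound_eye_genes)]
    if not incomplete.empty:
        raise ValueError(
            f"individuals missing compound-eye genes: {sorted(incomplete.index)[:5]}"
        )
    totals = recs.groupby("individual_id")["relative_expression"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("zero total compound-eye expression")
    recs["proportion"] = recs["relative_expression"] / totals
    return recs


@dataclass
class ExpressionResult:
    per_replicate: pd.DataFrame
    per_individual: pd.DataFrame
    proportions: pd.DataFrame
    config: QpcrConfig = field(default_factory=QpcrConfig)
    log_base: str = "natural"


def expression_pipeline(
    ct: pd.DataFrame,
    efficiencies: dict[str, float],
    config: QpcrConfig = QpcrConfig(),
) -> ExpressionResult:
    """Run the full expression chain: ΔΔCT per replicate, replicate averaging
    on the log scale, then compound-eye proportions."""
    per_rep = relative_expression(ct, efficiencies, config)
    per_ind = replicate_average(per_rep)
    props = proportional_expression(per_ind, config.compound_eye_genes)
    return ExpressionResult(per_rep, per_ind, props, config)
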