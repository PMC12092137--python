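"""Synthetic generators for every input the analysis chain consumes.

Each generator draws data with the statistical structure the downstream
estimators assume, with every true parameter recorded in a manifest, so
the whole pipeline is testable end-to-end without any field or laboratory
data:

* absorbance spectra — A1 pigment templates at the eight measured
  Ischnura elegans opsin λ_max values plus i.i.d. Gaussian noise;
* qPCR Ct tables — per-individual opsin quantities with stage-specific
  fold-changes (LWF2 rising and LWF1 falling over maturation), a convex
  quadratic dependence of mature-male LWF2 expression on the site's
  androchrome frequency, two stable housekeeping references and known
  primer efficiencies;
* reflectance spectra — smooth peaked curves for the blue androchrome and
  green infuscans female morphs (≈2-fold brightness apart), green and
  brown vegetation backgrounds and a flat photon illuminant;
* morph counts — multinomial draws of mature females per site × year.

All randomness flows through ``numpy.random.default_rng`` seeded from a
single top-level seed, with a fixed stream id per generator, so a given
config reproduces byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra import AbsorbanceSpectrum, template_sensitivity
from .visual_models import SpectrumFunction, flat_illuminant

__all__ = [
    "SimulationConfig",
    "AbsorbanceSim",
    "QpcrSim",
    "ReflectanceSim",
    "MorphCountSim",
    "simulate_absorbance",
    "simulate_ct_table",
    "simulate_reflectance",
    "simulate_morph_counts",
    "simulate_all",
]

# fixed per-generator stream ids (seed fan-out)
_STREAMS = {"absorbance": 1, "qpcr": 2, "reflectance": 3, "morph_counts": 4}

#: in-vitro λ_max (nm) of the eight expressed opsins
OPSIN_LAMBDA_MAX = {
    "SWb1": 397.0,
    "SWb2": 416.0,
    "LWF1": 531.0,
    "LWE1": 533.0,
    "LWF4": 541.0,
    "LWF2": 543.0,
    "LWF3": 545.0,
    "LWA2": 548.0,
}

#: androchrome frequency among mature females per site (2021 conditions);
#: span mirrors the observed 0.57-0.86 range
SITE_ANDRO_FREQ = {
    "S1": 0.571, "S2": 0.62, "S3": 0.66, "S4": 0.70,
    "S5": 0.74, "S6": 0.78, "S7": 0.82, "S8": 0.857,
}

# per-stage mean log2 expression relative to the UV calibrator; shaped so
# LWF4 dominates teneral heads while LWF2 dominates (and LWF1 declines in)
# immature and mature heads, and the ocellar LWE sits lowest throughout
_STAGE_MEANS_LOG2 = {
    "teneral":  {"UV": 0.0, "SW1": 1.0, "SW2": 1.0, "LWA": 2.0, "LWF1": 3.0,
                 "LWF2": 2.5, "LWF3": 2.0, "LWF4": 5.0, "LWE": -1.0},
    "immature": {"UV": 0.0, "SW1": 1.5, "SW2": 1.0, "LWA": 2.0, "LWF1": 2.0,
                 "LWF2": 5.0, "LWF3": 2.0, "LWF4": 3.5, "LWE": -1.5},
    "mature":   {"UV": 0.0, "SW1": 2.0, "SW2": 1.0, "LWA": 2.0, "LWF1": 1.5,
                 "LWF2": 5.5, "LWF3": 2.0, "LWF4": 3.2, "LWE": -2.0},
}

_EFFICIENCIES = {
    "UV": 1.00, "SW1": 0.97, "SW2": 0.95, "LWA": 0.98, "LWF1": 0.96,
    "LWF2": 1.02, "LWF3": 0.94, "LWF4": 0.99, "LWE": 0.93,
    "EF1a": 1.00, "RPL13": 0.97,
}


@dataclass
class AbsorbanceSim:
    lambda_max: dict[str, float] = field(default_factory=lambda: dict(OPSIN_LAMBDA_MAX))
    noise_sd: float = 0.02          # on the peak-normalized scale
    n_replicates: int = 3
    grid_nm: tuple[float, float, float] = (300.0, 700.0, 1.0)


@dataclass
class QpcrSim:
    genes: tuple[str, ...] = ("UV", "SW1", "SW2", "LWA", "LWF1", "LWF2", "LWF3", "LWF4", "LWE")
    housekeeping: tuple[str, str] = ("EF1a", "RPL13")
    stage_n: dict[str, int] = field(
        default_factory=lambda: {"teneral": 8, "immature": 36, "mature": 43}
    )
    stage_means_log2: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(g) for s, g in _STAGE_MEANS_LOG2.items()}
    )
    efficiencies: dict[str, float] = field(default_factory=lambda: dict(_EFFICIENCIES))
    site_andro_freq: dict[str, float] = field(default_factory=lambda: dict(SITE_ANDRO_FREQ))
    # convex frequency dependence of mature-male LWF2 expression
    quadratic_gene: str = "LWF2"
    quadratic_stage: str = "mature"
    quadratic_beta2: float = 50.0   # natural-log units per squared frequency
    quadratic_vertex: float = 0.72
    biological_sd: float = 0.3      # natural-log per-individual scatter
    replicate_sd: float = 0.15      # Ct units per technical replicate
    housekeeping_sd: float = 0.05   # natural-log scatter of reference quantities
    housekeeping_log2: dict[str, float] = field(
        default_factory=lambda: {"EF1a": 7.0, "RPL13": 6.0}
    )
    n_replicates: int = 2
    year: int = 2022
    baseline_log2_quantity: float = -28.0  # sets the Ct scale (~22-30 cycles)


@dataclass
class PeakShape:
    center_nm: float
    width_nm: float
    amplitude: float
    baseline: float = 0.05


@dataclass
class ReflectanceSim:
    # blue male-like androchrome vs green infuscans; amplitudes give the
    # ~2-fold overall brightness separation seen between the morphs
    androchrome: PeakShape = field(default_factory=lambda: PeakShape(450.0, 40.0, 0.55))
    infuscans: PeakShape = field(default_factory=lambda: PeakShape(550.0, 45.0, 0.28))
    vegetation_green: PeakShape = field(default_factory=lambda: PeakShape(555.0, 60.0, 0.20, 0.03))
    # brown vegetation: reflectance rising monotonically with wavelength
    brown_ramp_midpoint_nm: float = 600.0
    brown_ramp_scale_nm: float = 50.0
    brown_amplitude: float = 0.25
    brown_baseline: float = 0.04
    # jitter applied when drawing random morph-pair realizations
    center_jitter_sd: float = 5.0
    width_jitter_sd: float = 2.0
    amplitude_rel_sd: float = 0.05
    grid_nm: tuple[float, float, float] = (300.0, 700.0, 1.0)


@dataclass
class MorphCountSim:
    site_andro_freq: dict[str, float] = field(default_factory=lambda: dict(SITE_ANDRO_FREQ))
    obsoleta_freq: float = 0.03
    n_per_site: int = 60
    years: tuple[int, int] = (2021, 2022)
    # one site's frequencies shift between years; one site loses the rare
    # morph entirely in the second year
    shifted_site: str = "S5"
    shifted_andro_freq: float = 0.45
    dimorphic_site: str = "S8"


@dataclass
class SimulationConfig:
    seed: int = 0
    absorbance: AbsorbanceSim = field(default_factory=AbsorbanceSim)
    qpcr: QpcrSim = field(default_factory=QpcrSim)
    reflectance: ReflectanceSim = field(default_factory=ReflectanceSim)
    morph_counts: MorphCountSim = field(default_factory=MorphCountSim)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, _STREAMS[stream]]))

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_absorbance(
    config: SimulationConfig,
) -> tuple[list[AbsorbanceSpectrum], dict]:
    """Template-shaped absorbance spectra with Gaussian noise.

    One spectrum per pigment × replicate on the configured 1-nm grid; the
    manifest records the true λ_max per pigment and the noise level.
    """
    cfg = config.absorbance
    rng = config.rng("absorbance")
    lo, hi, step = cfg.grid_nm
    wl = np.arange(lo, hi + step / 2, step)
    spectra = []
    for label in sorted(cfg.lambda_max):
        truth = cfg.lambda_max[label]
        clean = template_sensitivity(truth, wl)
        for rep in range(1, cfg.n_replicates + 1):
            noisy = clean + rng.normal(0.0, cfg.noise_sd, size=wl.size)
            spectra.append(AbsorbanceSpectrum(wl, noisy, label=label, replicate_id=rep))
    manifest = {"lambda_max": dict(cfg.lambda_max), "noise_sd": cfg.noise_sd,
                "n_replicates": cfg.n_replicates}
    return spectra, manifest


def simulate_ct_table(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format Ct table with known expression structure.

    Each individual's true opsin quantity (relative to UV) combines the
    stage mean, per-individual biological scatter, and — for the
    configured gene × stage — a convex quadratic term
    β2·(x − vertex)² in the site's androchrome frequency x.  Quantities are
    converted to Ct through each primer's efficiency:
    Ct = −ln(quantity·scale) / ln(1+E), plus technical replicate noise.
    """
    cfg = config.qpcr
    rng = config.rng("qpcr")
    sites = sorted(cfg.site_andro_freq)
    ln2 = math.log(2.0)
    rows = []
    truth_individuals = []
    ind_counter = 0
    for stage in ("teneral", "immature", "mature"):
        n = cfg.stage_n.get(stage, 0)
        for k in range(n):
            ind_counter += 1
            ind = f"M{ind_counter:03d}"
            site = sites[k % len(sites)]
            x = cfg.site_andro_freq[site]
            ln_c = {}
            for gene in cfg.genes:
                mu = ln2 * cfg.stage_means_log2[stage][gene]
                if gene == cfg.quadratic_gene and stage == cfg.quadratic_stage:
                    mu += cfg.quadratic_beta2 * (x - cfg.quadratic_vertex) ** 2
                ln_c[gene] = mu + rng.normal(0.0, cfg.biological_sd)
            for hk, mean2 in cfg.housekeeping_log2.items():
                ln_c[hk] = ln2 * mean2 + rng.normal(0.0, cfg.housekeeping_sd)
            truth_individuals.append(
                {"individual_id": ind, "stage": stage, "site_id": site,
                 "andro_frequency": x,
                 **{f"ln_rel_{g}": ln_c[g] - ln_c["UV"] for g in cfg.genes}}
            )
            for gene, lc in ln_c.items():
                e = cfg.efficiencies[gene]
                ct_true = -(lc + ln2 * cfg.baseline_log2_quantity) / math.log1p(e)
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append(
                        {"individual_id": ind, "stage": stage, "site_id": site,
                         "year": cfg.year, "gene": gene, "replicate": rep,
                         "ct": ct_true + rng.normal(0.0, cfg.replicate_sd)}
                    )
    df = pd.DataFrame(rows)
    manifest = {
        "stage_means_log2": {s: dict(g) for s, g in cfg.stage_means_log2.items()},
        "quadratic": {"gene": cfg.quadratic_gene, "stage": cfg.quadratic_stage,
                      "beta2": cfg.quadratic_beta2, "vertex": cfg.quadratic_vertex},
        "efficiencies": dict(cfg.efficiencies),
        "site_andro_freq": dict(cfg.site_andro_freq),
        "individuals": truth_individuals,
    }
    return df, manifest


def _gaussian_peak(wl: np.ndarray, shape: PeakShape) -> np.ndarray:
    return shape.baseline + shape.amplitude * np.exp(
        -(((wl - shape.center_nm) / shape.width_nm) ** 2)
    )


def _jitter(shape: PeakShape, cfg: ReflectanceSim, rng: np.random.Generator) -> PeakShape:
    return PeakShape(
        center_nm=shape.center_nm + rng.normal(0.0, cfg.center_jitter_sd),
        width_nm=max(10.0, shape.width_nm + rng.normal(0.0, cfg.width_jitter_sd)),
        amplitude=shape.amplitude * math.exp(rng.normal(0.0, cfg.amplitude_rel_sd)),
        baseline=shape.baseline,
    )


def simulate_reflectance(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, SpectrumFunction]:
    """Smooth reflectance spectra for the two common morphs, two vegetation
    backgrounds, and a flat photon illuminant.

    With ``rng`` given, peak position, width and amplitude are jittered
    (per the config's jitter fields) to draw random morph realizations;
    without it the nominal shapes are returned deterministically.
    """
    cfg = config.reflectance
    lo, hi, step = cfg.grid_nm
    wl = np.arange(lo, hi + step / 2, step)

    def peak(shape: PeakShape) -> np.ndarray:
        if rng is not None:
            shape = _jitter(shape, cfg, rng)
        return np.clip(_gaussian_peak(wl, shape), 0.0, 1.0)

    brown = cfg.brown_baseline + cfg.brown_amplitude / (
        1.0 + np.exp(-(wl - cfg.brown_ramp_midpoint_nm) / cfg.brown_ramp_scale_nm)
    )
    return {
        "androchrome": SpectrumFunction(wl, peak(cfg.androchrome)),
        "infuscans": SpectrumFunction(wl, peak(cfg.infuscans)),
        "vegetation_green": SpectrumFunction(wl, peak(cfg.vegetation_green)),
        "vegetation_brown": SpectrumFunction(wl, np.clip(brown, 0.0, 1.0)),
        "illuminant": flat_illuminant(wl),
    }


def simulate_morph_counts(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Multinomial mature-female morph counts per site × year."""
    cfg = config.morph_counts
    rng = config.rng("morph_counts")
    rows = []
    truth = {}
    for year in cfg.years:
        for site in sorted(cfg.site_andro_freq):
            a = cfg.site_andro_freq[site]
            o = cfg.obsoleta_freq
            if site == cfg.shifted_site and year == cfg.years[1]:
                a = cfg.shifted_andro_freq
            if site == cfg.dimorphic_site and year == cfg.years[1]:
                o = 0.0
            probs = np.array([a, 1.0 - a - o, o])
            if probs.min() < 0 or not math.isclose(probs.sum(), 1.0):
                raise ValueError("morph frequencies must be non-negative and sum to 1")
            counts = rng.multinomial(cfg.n_per_site, probs)
            truth[(site, year)] = probs.tolist()
            for morph, c in zip(("androchrome", "infuscans", "infuscans_obsoleta"), counts):
                rows.append({"site_id": site, "year": year, "morph": morph, "count": int(c)})
    return pd.DataFrame(rows), {"true_frequencies": {f"{s}_{y}": p for (s, y), p in truth.items()},
                                "n_per_site": cfg.n_per_site}


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every synthetic input the pipeline consumes, with manifests."""
    spectra, spec_manifest = simulate_absorbance(config)
    ct, ct_manifest = simulate_ct_table(config)
    reflectance = simulate_reflectance(config)
    counts, count_manifest = simulate_morph_counts(config)
    return {
        "absorbance": spectra,
        "absorbance_manifest": spec_manifest,
        "ct": ct,
        "ct_manifest": ct_manifest,
        "reflectance": reflectance,
        "morph_counts": counts,
        "morph_counts_manifest": count_manifest,
    }
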