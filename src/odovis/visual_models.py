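"""Receptor-noise-limited (RNL) visual modelling of colour discrimination.

Implements the standard log-linear RNL chromatic-contrast model: quantum
catches are integrals of receptor sensitivity × stimulus reflectance ×
illuminant, von Kries adaptation normalizes each catch by the catch of the
adapting background, receptor signals are log-transformed, and channel
noise ω_i = ν · sqrt(η_ref / η_i) scales with the Weber fraction ν of the
reference (most abundant) receptor class and the relative receptor
abundances η.  Chromatic distance ΔS (in just-noticeable-difference units,
threshold ΔS = 1) uses the closed dichromat/trichromat forms; a single
log-contrast channel provides achromatic JNDs.

Three damselfly visual-system variants are dispatched by name: one based
on whole-eye electroretinogram sensitivities (a placeholder that must be
overridden from config with measured curves) and two based on measured
opsin absorbance, differing only in which long-wavelength opsin sets the
LW receptor: LWF1 (λ_max 531 nm) or LWF2 (λ_max 543 nm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import template_sensitivity

__all__ = [
    "SpectrumFunction",
    "Receptor",
    "VisualSystem",
    "JndResult",
    "quantum_catch",
    "von_kries",
    "receptor_noise",
    "chromatic_jnd",
    "achromatic_jnd",
    "build_visual_system",
    "delta_jnd",
]

DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

# opsin λ_max values measured in vitro for Ischnura elegans
LWF1_LAMBDA_MAX = 531.0
LWF2_LAMBDA_MAX = 543.0


@dataclass(frozen=True)
class SpectrumFunction:
    """A sampled spectral function: reflectance, illuminant or sensitivity.

    Reflectance is clipped to [0, 1]; evaluation elsewhere uses linear
    interpolation on a shared 1-nm grid restricted to the overlapping
    wavelength range (no extrapolation).
    """

    wavelength_nm: np.ndarray
    value: np.ndarray
    role: str = "reflectance"  # reflectance | illuminant | sensitivity

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if wl.size != v.size or wl.ndim != 1:
            raise ValueError("wavelength and value must be 1-d arrays of equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        if self.role == "reflectance":
            v = np.clip(v, 0.0, 1.0)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", v)

    def at(self, grid: np.ndarray) -> np.ndarray:
        if grid[0] < self.wavelength_nm[0] - 1e-9 or grid[-1] > self.wavelength_nm[-1] + 1e-9:
            raise ValueError("evaluation grid extends beyond the spectrum's support")
        return np.interp(grid, self.wavelength_nm, self.value)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])


def flat_illuminant(grid: np.ndarray = DEFAULT_GRID, scale: float = 1.0) -> SpectrumFunction:
    """Spectrally flat photon-flux illuminant (arbitrary scale)."""
    return SpectrumFunction(grid, np.full(grid.size, scale), role="illuminant")


@dataclass(frozen=True)
class Receptor:
    """One photoreceptor class: a peak-normalized sensitivity plus its
    relative abundance η in the retinal mosaic."""

    name: str
    lambda_max_nm: float
    abundance: float = 1.0
    sensitivity: SpectrumFunction | None = None

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("receptor abundance must be positive")
        if self.sensitivity is None:
            s = template_sensitivity(self.lambda_max_nm, DEFAULT_GRID)
            object.__setattr__(
                self, "sensitivity", SpectrumFunction(DEFAULT_GRID, s, role="sensitivity")
            )


@dataclass(frozen=True)
class VisualSystem:
    """An ordered receptor set plus viewing context (illuminant, background).

    ``weber_fraction`` is the noise-to-signal ratio ν of the reference
    receptor, by default the most abundant (index ``reference``)."""

    variant: str
    receptors: tuple[Receptor, ...]
    weber_fraction: float = 0.1
    illuminant: SpectrumFunction = None
    background: SpectrumFunction = None
    reference: int = -1

    def __post_init__(self) -> None:
        if len(self.receptors) < 2:
            raise ValueError("chromatic modelling needs at least 2 receptor classes")
        peaks = [r.lambda_max_nm for r in self.receptors]
        if not all(a < b for a, b in zip(peaks, peaks[1:])):
            raise ValueError("receptor lambda_max values must be strictly increasing")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        if self.illuminant is None:
            object.__setattr__(self, "illuminant", flat_illuminant())

    @property
    def abundances(self) -> np.ndarray:
        return np.array([r.abundance for r in self.receptors])

    def noise(self) -> np.ndarray:
        return receptor_noise(self.weber_fraction, self.abundances, self.reference)

    def catches(self, stimulus: SpectrumFunction) -> np.ndarray:
        return np.array(
            [quantum_catch(r, stimulus, self.illuminant) for r in self.receptors]
        )


@dataclass(frozen=True)
class JndResult:
    stimulus_a: str
    stimulus_b: str
    chromatic_jnd: float
    achromatic_jnd: float | None
    per_receptor_contrast: np.ndarray


def _shared_grid(*specs: SpectrumFunction) -> np.ndarray:
    lo = max(s.support[0] for s in specs)
    hi = min(s.support[1] for s in specs)
    if hi - lo < 100.0:
        raise ValueError(f"overlapping spectral support is only [{lo}, {hi}] nm (< 100 nm)")
    return np.arange(math.ceil(lo), math.floor(hi) + 1.0, 1.0)


def quantum_catch(
    receptor: Receptor, stimulus: SpectrumFunction, illuminant: SpectrumFunction
) -> float:
    """Photon catch Q = ∫ S(λ) R(λ) I(λ) dλ (trapezoid, shared 1-nm grid)."""
    grid = _shared_grid(receptor.sensitivity, stimulus, illuminant)
    integrand = receptor.sensitivity.at(grid) * stimulus.at(grid) * illuminant.at(grid)
    return float(np.trapezoid(integrand, grid))


def von_kries(q_stimulus: np.ndarray, q_background: np.ndarray) -> np.ndarray:
    """Adapted catches: each receptor's catch divided by its background catch."""
    qb = np.asarray(q_background, dtype=float)
    if np.any(qb <= 0):
        raise ValueError("background quantum catches must be positive")
    return np.asarray(q_stimulus, dtype=float) / qb


def receptor_noise(nu: float, abundances: np.ndarray, reference: int = -1) -> np.ndarray:
    """Channel noise ω_i = ν sqrt(η_ref / η_i); the reference channel gets ν."""
    if nu <= 0:
        raise ValueError("Weber fraction must be positive")
    eta = np.asarray(abundances, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("abundances must be positive")
    return nu * np.sqrt(eta[reference] / eta)


def _contrasts(
    system: VisualSystem, stimulus_a: SpectrumFunction, stimulus_b: SpectrumFunction
) -> np.ndarray:
    qa = system.catches(stimulus_a)
    qb = system.catches(stimulus_b)
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("zero quantum catch: stimuli must reflect within receptor support")
    if system.background is not None:
        q_bg = system.catches(system.background)
        qa, qb = von_kries(qa, q_bg), von_kries(qb, q_bg)
    return np.log(qa / qb)


def chromatic_jnd(
    system: VisualSystem, stimulus_a: SpectrumFunction, stimulus_b: SpectrumFunction
) -> JndResult:
    """Chromatic distance ΔS between two stimuli under one visual system.

    Receptor contrasts Δf_i = ln(q_i^A / q_i^B) (von-Kries-adapted catches)
    enter the closed-form RNL expressions:

    dichromat:  ΔS = |Δf_1 − Δf_2| / sqrt(ω_1² + ω_2²)
    trichromat: ΔS = sqrt( (ω_1²(Δf_2−Δf_3)² + ω_2²(Δf_1−Δf_3)²
                          + ω_3²(Δf_1−Δf_2)²)
                          / ((ω_1ω_2)² + (ω_1ω_3)² + (ω_2ω_3)²) )
    """
    n = len(system.receptors)
    if n > 3:
        raise ValueError("closed RNL forms implemented for 2 or 3 receptor classes only")
    df = _contrasts(system, stimulus_a, stimulus_b)
    w = system.noise()
    if n == 2:
        ds = abs(df[0] - df[1]) / math.sqrt(w[0] ** 2 + w[1] ** 2)
    else:
        num = (
            w[0] ** 2 * (df[1] - df[2]) ** 2
            + w[1] ** 2 * (df[0] - df[2]) ** 2
            + w[2] ** 2 * (df[0] - df[1]) ** 2
        )
        den = (w[0] * w[1]) ** 2 + (w[0] * w[2]) ** 2 + (w[1] * w[2]) ** 2
        ds = math.sqrt(num / den)
    return JndResult(
        stimulus_a=getattr(stimulus_a, "role", "a"),
        stimulus_b=getattr(stimulus_b, "role", "b"),
        chromatic_jnd=float(ds),
        achromatic_jnd=None,
        per_receptor_contrast=df,
    )


def achromatic_jnd(
    system: VisualSystem,
    stimulus_a: SpectrumFunction,
    stimulus_b: SpectrumFunction,
    channel: int = -1,
) -> float:
    """Single-channel brightness contrast |Δf| / ω for the given receptor."""
    df = _contrasts(system, stimulus_a, stimulus_b)
    w = system.noise()
    return float(abs(df[channel]) / w[channel])


_ERG_PLACEHOLDER = ((360.0, 1.0), (440.0, 1.0), (525.0, 2.0))


def build_visual_system(variant: str, config: dict | None = None) -> VisualSystem:
    """Construct a named visual-system variant.

    ``variant`` is one of ``"LWF1"``, ``"LWF2"``, ``"ERG"`` or ``"custom"``.
    The LWF1/LWF2 variants are trichromats {UV 350, SW 416, LW 531 or 543 nm}
    with template-generated sensitivities.  The ERG variant requires measured
    whole-eye sensitivity curves supplied via config; without them a
    placeholder receptor set is used and a warning names the missing source.

    Config keys (all optional except where noted): ``receptors`` — list of
    ``{name, lambda_max, abundance[, wavelength, sensitivity]}`` dicts
    (required for ``custom``); ``weber_fraction``; ``illuminant`` and
    ``background`` — SpectrumFunction.
    """
    config = dict(config or {})
    nu = float(config.get("weber_fraction", 0.1))
    illuminant = config.get("illuminant")
    background = config.get("background")

    def _from_entries(entries) -> tuple[Receptor, ...]:
        recs = []
        for e in entries:
            sens = None
            if "wavelength" in e and "sensitivity" in e:
                sens = SpectrumFunction(
                    np.asarray(e["wavelength"], float),
                    np.asarray(e["sensitivity"], float),
                    role="sensitivity",
                )
            recs.append(
                Receptor(e["name"], float(e["lambda_max"]), float(e.get("abundance", 1.0)), sens)
            )
        return tuple(recs)

    if variant in ("LWF1", "LWF2"):
        lw = LWF1_LAMBDA_MAX if variant == "LWF1" else LWF2_LAMBDA_MAX
        defaults = [
            {"name": "UV", "lambda_max": 350.0, "abundance": 1.0},
            {"name": "SW", "lambda_max": 416.0, "abundance": 1.0},
            {"name": "LW", "lambda_max": lw, "abundance": 2.0},
        ]
        receptors = _from_entries(config.get("receptors", defaults))
    elif variant == "ERG":
        if "receptors" in config:
            receptors = _from_entries(config["receptors"])
        else:
            warnings.warn(
                "ERG variant running with placeholder sensitivities; supply measured "
                "Ischnura heterosticta electroretinogram curves via config['receptors']",
                stacklevel=2,
            )
            receptors = tuple(
                Receptor(f"ERG{i+1}", lam, eta) for i, (lam, eta) in enumerate(_ERG_PLACEHOLDER)
            )
    elif variant == "custom":
        if "receptors" not in config:
            raise ValueError("custom variant requires config['receptors']")
        receptors = _from_entries(config["receptors"])
    else:
        raise ValueError(f"unknown visual-system variant {variant!r}")

    return VisualSystem(
        variant=variant,
        receptors=receptors,
        weber_fraction=nu,
        illuminant=illuminant,
        background=background,
    )


def delta_jnd(
    system_a: VisualSystem,
    system_b: VisualSystem,
    stimulus_a: SpectrumFunction,
    stimulus_b: SpectrumFunction,
    mode: str = "chromatic",
) -> float:
    """JND(system_a) − JND(system_b) on the same stimulus pair.

    Positive values mean system_a separates the pair more widely in
    perceptual space (better discrimination or detection, depending on
    whether ``stimulus_b`` is another morph or the viewing background).
    """
    if mode == "chromatic":
        ja = chromatic_jnd(system_a, stimulus_a, stimulus_b).chromatic_jnd
        jb = chromatic_jnd(system_b, stimulus_a, stimulus_b).chromatic_jnd
    elif mode == "achromatic":
        ja = achromatic_jnd(system_a, stimulus_a, stimulus_b)
        jb = achromatic_jnd(system_b, stimulus_a, stimulus_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(ja - jb)
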