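"""Tests of quantum catch, von Kries adaptation and RNL contrast."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odovis.visual_models import (
    Receptor,
    SpectrumFunction,
    VisualSystem,
    achromatic_jnd,
    build_visual_system,
    chromatic_jnd,
    delta_jnd,
    flat_illuminant,
    quantum_catch,
    receptor_noise,
    von_kries,
)

GRID = np.arange(300.0, 701.0, 1.0)


def rect_sensitivity(lo, hi, lam_max, abundance=1.0):
    """Receptor with a rectangular sensitivity band (for hand-computable catches)."""
    v = ((GRID >= lo) & (GRID <= hi)).astype(float)
    return Receptor("rect", lam_max, abundance, SpectrumFunction(GRID, v, role="sensitivity"))


def const_reflectance(value):
    return SpectrumFunction(GRID, np.full(GRID.size, value))


def gaussian_reflectance(center, width=40.0, amp=0.5, base=0.05):
    return SpectrumFunction(GRID, base + amp * np.exp(-(((GRID - center) / width) ** 2)))


class TestQuantumCatch:
    def test_zero_reflectance_zero_catch(self):
        r = Receptor("LW", 543.0)
        q = quantum_catch(r, const_reflectance(0.0), flat_illuminant(GRID))
        assert q == 0.0

    def test_unit_reflectance_equals_sensitivity_integral(self):
        """Independent rectangle-rule oracle agrees within 0.1%."""
        r = Receptor("LW", 543.0)
        q = quantum_catch(r, const_reflectance(1.0), flat_illuminant(GRID))
        rect = float(np.sum(r.sensitivity.value))  # 1-nm rectangle rule
        assert q == pytest.approx(rect, rel=1e-3)

    def test_linearity_in_illuminant(self):
        r = Receptor("SW", 416.0)
        stim = gaussian_reflectance(450.0)
        q1 = quantum_catch(r, stim, flat_illuminant(GRID, 1.0))
        q2 = quantum_catch(r, stim, flat_illuminant(GRID, 2.0))
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_disjoint_support_errors(self):
        r = Receptor("UV", 350.0)
        narrow = SpectrumFunction(np.arange(680.0, 700.0), np.ones(20))
        with pytest.raises(ValueError):
            quantum_catch(r, narrow, flat_illuminant(GRID))


class TestAdaptationAndNoise:
    def test_background_equals_stimulus_gives_unity(self):
        q = np.array([3.0, 7.0])
        assert np.allclose(von_kries(q, q), 1.0)

    def test_hand_arithmetic(self):
        assert np.allclose(von_kries([2.0, 4.0], [1.0, 2.0]), [2.0, 2.0])

    def test_zero_background_errors(self):
        with pytest.raises(ValueError):
            von_kries([1.0, 1.0], [1.0, 0.0])

    def test_noise_equal_abundances(self):
        assert np.allclose(receptor_noise(0.12, [2.0, 2.0, 2.0]), 0.12)

    def test_noise_hand_values(self):
        w = receptor_noise(0.1, [1.0, 4.0], reference=1)
        assert np.allclose(w, [0.2, 0.1])

    def test_noise_scale_invariance(self):
        w1 = receptor_noise(0.1, [1.0, 2.0, 4.0])
        w2 = receptor_noise(0.1, [10.0, 20.0, 40.0])
        assert np.allclose(w1, w2)

    def test_nonpositive_weber_rejected(self):
        with pytest.raises(ValueError):
            receptor_noise(0.0, [1.0, 1.0])


def dichromat_system():
    # two disjoint rectangular bands => catches are band integrals
    return VisualSystem(
        variant="custom",
        receptors=(rect_sensitivity(350, 450, 400.0), rect_sensitivity(500, 600, 550.0)),
        weber_fraction=0.1,
        reference=0,
    )


def step_reflectance(v_short, v_long, split=475.0):
    v = np.where(GRID <= split, v_short, v_long)
    return SpectrumFunction(GRID, v)


class TestChromaticJnd:
    def test_identical_stimuli_zero(self):
        sys = dichromat_system()
        s = gaussian_reflectance(500.0)
        assert chromatic_jnd(sys, s, s).chromatic_jnd == 0.0

    def test_dichromat_closed_form(self):
        """Catch ratio 2 on one band, 1 on the other, ω = (0.1, 0.1):
        ΔS = ln 2 / sqrt(0.02) = 4.9012."""
        sys = dichromat_system()
        a = step_reflectance(0.8, 0.4)
        b = step_reflectance(0.4, 0.4)
        ds = chromatic_jnd(sys, a, b).chromatic_jnd
        assert ds == pytest.approx(math.log(2.0) / math.sqrt(0.02), abs=1e-3)
        assert ds == pytest.approx(4.9012, abs=1e-3)

    def test_trichromat_matches_matrix_oracle(self):
        """Closed trichromat form equals the general quadratic-form RNL
        oracle on 50 random spectrum pairs to 1e-9."""
        rng = np.random.default_rng(0)
        sys = build_visual_system("LWF2", {})
        w = sys.noise()
        D = np.diag(1.0 / w**2)
        one = np.ones((3, 1))
        M = D - (D @ one @ one.T @ D) / (one.T @ D @ one).item()
        for _ in range(50):
            a = gaussian_reflectance(rng.uniform(380, 620), rng.uniform(20, 80),
                                     rng.uniform(0.2, 0.8))
            b = gaussian_reflectance(rng.uniform(380, 620), rng.uniform(20, 80),
                                     rng.uniform(0.2, 0.8))
            res = chromatic_jnd(sys, a, b)
            df = res.per_receptor_contrast
            oracle = math.sqrt(max((df @ M @ df).item(), 0.0))
            assert res.chromatic_jnd == pytest.approx(oracle, abs=1e-9)

    def test_symmetry(self):
        sys = build_visual_system("LWF1", {})
        a, b = gaussian_reflectance(430.0), gaussian_reflectance(560.0)
        assert chromatic_jnd(sys, a, b).chromatic_jnd == pytest.approx(
            chromatic_jnd(sys, b, a).chromatic_jnd, rel=1e-12
        )

    def test_proportional_catches_give_zero(self):
        """ΔS = 0 iff the per-receptor contrasts are all equal: scaling a
        stimulus uniformly changes no chromatic signal."""
        sys = build_visual_system("LWF2", {})
        a = gaussian_reflectance(500.0, amp=0.4, base=0.04)
        b = SpectrumFunction(GRID, a.value * 0.5)
        res = chromatic_jnd(sys, a, b)
        assert np.ptp(res.per_receptor_contrast) < 1e-12
        assert res.chromatic_jnd < 1e-9

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_illuminant_intensity_invariance(self, k):
        """Multiplying the illuminant by k changes no JND (von Kries)."""
        a, b = gaussian_reflectance(440.0), gaussian_reflectance(555.0)
        bg = const_reflectance(0.2)
        j = {}
        for scale in (1.0, k):
            sys = build_visual_system(
                "LWF2", {"illuminant": flat_illuminant(GRID, scale), "background": bg}
            )
            j[scale] = (chromatic_jnd(sys, a, b).chromatic_jnd,
                        achromatic_jnd(sys, a, b))
        assert j[1.0][0] == pytest.approx(j[k][0], rel=1e-9)
        assert j[1.0][1] == pytest.approx(j[k][1], rel=1e-9)

    def test_tetrachromat_unsupported(self):
        receptors = tuple(Receptor(f"r{i}", lam) for i, lam in enumerate([350, 420, 480, 540]))
        sys = VisualSystem("custom", receptors)
        with pytest.raises(ValueError):
            chromatic_jnd(sys, gaussian_reflectance(400), gaussian_reflectance(500))


class TestAchromaticJnd:
    def test_identical_stimuli_zero(self):
        sys = dichromat_system()
        s = gaussian_reflectance(520.0)
        assert achromatic_jnd(sys, s, s) == 0.0

    def test_hand_value(self):
        """q ratio 2 on the LW channel with ω = 0.16 → ln2/0.16 = 4.3322."""
        sys = VisualSystem(
            variant="custom",
            receptors=(rect_sensitivity(350, 450, 400.0),
                       rect_sensitivity(500, 600, 550.0, abundance=0.390625)),
            weber_fraction=0.1,
            reference=0,
        )
        # ω_LW = 0.1 * sqrt(1/0.390625) = 0.16
        a = step_reflectance(0.4, 0.8)
        b = step_reflectance(0.4, 0.4)
        assert achromatic_jnd(sys, a, b, channel=1) == pytest.approx(4.3322, abs=1e-3)

    def test_swap_symmetry(self):
        sys = dichromat_system()
        a, b = gaussian_reflectance(420.0), gaussian_reflectance(540.0)
        assert achromatic_jnd(sys, a, b) == pytest.approx(achromatic_jnd(sys, b, a))


class TestBuildVisualSystem:
    def test_lwf1_variant_peak(self):
        sys = build_visual_system("LWF1", {})
        assert sys.receptors[-1].lambda_max_nm == 531.0

    def test_lwf2_variant_peak(self):
        sys = build_visual_system("LWF2", {})
        assert sys.receptors[-1].lambda_max_nm == 543.0

    def test_erg_placeholder_warns(self):
        with pytest.warns(UserWarning, match="placeholder"):
            build_visual_system("ERG", {})

    def test_erg_with_supplied_curves_silent(self):
        cfg = {"receptors": [
            {"name": "S", "lambda_max": 420.0},
            {"name": "L", "lambda_max": 520.0, "abundance": 2.0},
        ]}
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            sys = build_visual_system("ERG", cfg)
        assert len(sys.receptors) == 2

    def test_custom_dichromat_dispatch(self):
        sys = build_visual_system("custom", {"receptors": [
            {"name": "S", "lambda_max": 416.0}, {"name": "L", "lambda_max": 543.0}]})
        res = chromatic_jnd(sys, gaussian_reflectance(440), gaussian_reflectance(560))
        assert res.per_receptor_contrast.size == 2

    def test_custom_without_receptors_errors(self):
        with pytest.raises(ValueError, match="receptors"):
            build_visual_system("custom", {})

    def test_unordered_receptor_peaks_rejected(self):
        with pytest.raises(ValueError):
            VisualSystem("custom", (Receptor("a", 500.0), Receptor("b", 400.0)))


class TestDeltaJnd:
    def test_same_system_zero(self):
        sys = build_visual_system("LWF2", {})
        a, b = gaussian_reflectance(440.0), gaussian_reflectance(560.0)
        assert delta_jnd(sys, sys, a, b) == 0.0

    def test_antisymmetry(self):
        s1, s2 = build_visual_system("LWF1", {}), build_visual_system("LWF2", {})
        a, b = gaussian_reflectance(440.0), gaussian_reflectance(560.0)
        assert delta_jnd(s1, s2, a, b) == pytest.approx(-delta_jnd(s2, s1, a, b))

    def test_composition_on_synthetic_spectra(self, sim_config):
        """ΔJND equals direct subtraction of separately computed JNDs on the
        generator's default morph and vegetation spectra."""
        from odovis.synthetic_data import simulate_reflectance

        refl = simulate_reflectance(sim_config)
        cfg = {"illuminant": refl["illuminant"], "background": refl["vegetation_green"]}
        s1 = build_visual_system("LWF1", dict(cfg))
        s2 = build_visual_system("LWF2", dict(cfg))
        a, b = refl["androchrome"], refl["infuscans"]
        direct = (chromatic_jnd(s2, a, b).chromatic_jnd
                  - chromatic_jnd(s1, a, b).chromatic_jnd)
        assert delta_jnd(s2, s1, a, b) == pytest.approx(direct, rel=1e-12)
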