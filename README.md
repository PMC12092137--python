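# odovis

Analysis tools for a question in sensory ecology: can changes in the
visual pigments (opsins) that mate-searching male damselflies express
plausibly track — and help discriminate — the colour morphs of the females
they encounter?

Female *Ischnura elegans* come in three genetically determined colour
morphs (the male-like blue **androchrome** and the green/brown gynochromes
***infuscans*** and ***infuscans-obsoleta***) whose local frequencies vary
between populations and years. `odovis` implements the quantitative chain
that connects pigment biophysics to that ecology:

1. **spectra** — fit UV-Vis absorbance curves of purified rhodopsins to a
   Govardovskii A1 visual-pigment template, estimate the wavelength of
   maximal absorbance λ_max by grid search with golden-section refinement,
   and attach residual-bootstrap percentile confidence intervals.
2. **qpcr** — efficiency-corrected ΔΔCT relative opsin expression
   (`(1+E)^−ΔΔCT`, two housekeeping references combined by geometric mean,
   UV opsin as calibrator) and proportional expression across the
   compound-eye opsin set.
3. **visual_models** — receptor-noise-limited (RNL) colour discrimination:
   quantum catches, von Kries adaptation, channel noise
   ω_i = ν√(η_ref/η_i), closed dichromat/trichromat ΔS formulas, and ΔJND
   comparisons between visual systems whose long-wavelength receptor is
   tuned to the LWF1 (531 nm) or LWF2 (543 nm) opsin.
4. **morphs** — mature-female morph frequencies per site × year, with
   Pearson chi-square / enumeration Fisher exact between-year tests.
5. **trends** — the quadratic (convex) relationship between log relative
   opsin expression and local androchrome frequency, per opsin × maturity
   stage, with a Holm-corrected convexity screen.
6. **synthetic_data** — seeded generators for every input above, with all
   true parameters recorded in manifests, so the whole chain is testable
   end-to-end without laboratory or field data.

A thin CLI (`odv`) orchestrates the stages; `odv run` executes all six and
writes a digest-bearing run manifest for reproducibility.

## Worked example

```python
import numpy as np
from odovis import (SimulationConfig, simulate_absorbance,
                    preprocess, fit_lambda_max, bootstrap_lambda_max)
from odovis.spectra import AbsorbanceSpectrum

cfg = SimulationConfig(seed=1)
spectra, truth = simulate_absorbance(cfg)          # 8 pigments x 3 replicates
reps = [s for s in spectra if s.label == "LWF2"]   # generated at 543 nm
mean = AbsorbanceSpectrum(reps[0].wavelength_nm,
                          np.mean([r.absorbance for r in reps], axis=0))
spec = preprocess(mean)
fit = fit_lambda_max(spec)
boot = bootstrap_lambda_max(spec, fit, n_boot=1000, seed=1)
print(f"lambda_max = {fit.lambda_max_nm:.2f} nm "
      f"(95% CI {boot.ci_low_nm:.2f}-{boot.ci_high_nm:.2f})")
```

prints

```
lambda_max = 542.88 nm (95% CI 542.71-543.02)
```

i.e. the fit recovers the generating λ_max of the LWF2 pigment to within
0.12 nm, with a bootstrap CI about 0.3 nm wide at the generator's noise
level (sd 0.02 of peak height). The same chain from the shell:

```sh
odv run --seed 1 --out results/run
```

writes `lambda_max_fits.csv`, relative/proportional expression tables,
morph frequencies with between-year tests, per-opsin quadratic trend fits
(flagging the convex LWF2 × mature trend), a JND table comparing the
LWF1- and LWF2-based visual systems on morph discrimination and detection
tasks, and `run_manifest.json` with SHA-256 digests of every output.

Model parameters that are not measured quantities (Weber fraction,
receptor abundances, illuminant, backgrounds, ERG sensitivities) live in
config and default to documented assumptions; see `docs/methods.md`.

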