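# tcyspect

Quantitative ⁹⁹ᵐTc SPECT imaging in the co-presence of ⁹⁰Y, as a tested,
desk-scale simulation and reconstruction study.

In radioembolization work-up, a ⁹⁹ᵐTc-MAA scout scan maps the hepatic
perfusion before ⁹⁰Y-microsphere therapy. Combining work-up and therapy in
one session puts both isotopes in the patient at imaging time, and the broad
⁹⁰Y bremsstrahlung continuum then contaminates the 140 keV ⁹⁹ᵐTc photopeak
window ("crosstalk"), degrading contrast, lung-shunt estimates and
extrahepatic-deposition readouts. This package reproduces the structure of
that problem end to end:

* a digital anthropomorphic torso phantom (liver with two tumor spheres,
  lungs, three extrahepatic spheres) with per-isotope activity maps solved
  from tumor-to-normal ratios, lung shunt fraction (LSF) and
  EHD-to-liver ratios;
* a deterministic SPECT system model (distance-dependent collimator PSF,
  attenuation, per-window spectral sensitivities for LEHR/ME/HE collimators)
  with an exact adjoint, plus Poisson acquisition, pseudo-list-mode
  thinning, synthetic dual-isotope combination and multinomial bootstrap;
* OSEM reconstruction with an additive crosstalk background term and three
  ⁹⁰Y background estimators — model-based (MC-style: auxiliary ⁹⁰Y
  reconstruction from the 226 keV window, CNR-based stopping, noise-free
  reprojection), dual-energy-window (k-factor scaling of the 226 keV
  window) and triple-energy-window (mean of the 125/155 keV windows);
* the evaluation harness: contrast recovery coefficient
  `CRC = [(⟨a_T⟩−⟨a_N⟩)/⟨a_N⟩] / (T/N − 1)`, lung shunt fraction
  `LSF = a_lungs/(a_lungs + a_liver)`, background noise (coefficient of
  variation, N−1), EHD activities, noise-matched iteration selection and
  aggregation over bootstrap noise realizations;
* paralyzable dead-time (`R_obs = R·exp(−Rτ)`) count-rate linearity
  analysis.

See `docs/methods.md` for the model, its assumptions and its limitations.

## Worked example

Ground truth and k-factor calibration (seconds):

```sh
$ python analysis/01_build_phantom.py
grid 64^3 at 9.6 mm; voxel counts: {'liver': 1279, 'tumor1': 28, 'tumor2': 18,
 'lung': 780, 'ehd1': 9, 'ehd2': 5, 'ehd3': 2}
Tc: total 98.0 MBq, LSF 15.0%, T/N 4.0/4.0, EHD 2.64/0.00/0.65 MBq
Y: total 1969.0 MBq, LSF 10.0%, T/N 1.0/4.0, EHD 53.21/26.86/0.00 MBq

$ python analysis/02_calibrate_kfactors.py
LEHR: k = 0.4780 (configured 0.478)
ME: k = 0.6320 (configured 0.632)
HE: k = 0.7450 (configured 0.745)
```

The first block is the phantom ground truth: the configured activity ratios
round-trip exactly (LSF 15 %/10 %, tumor-to-normal 4.0, extrahepatic
activities 2.64/0.00/0.65 MBq for ⁹⁹ᵐTc at 98 MBq total). The second block
closes the dual-energy-window calibration loop: a simulated ⁹⁰Y point source
in a water cylinder reproduces each collimator's 140/226 keV count ratio.

The crosstalk study itself (roughly 11 minutes on one core at the
desk-scale preset):

```sh
$ python analysis/04_crosstalk_study.py --methods none mc --ratios 1:20 1:60
noise target (Tc-only LEHR at iteration 10): 0.1931
== crc_tumor1_pct (mean +/- std over realizations)
method  collimator ratio     mean   std
mc      ME         1:20     57.50  3.45
                   1:60     44.37  2.48
none    ME         1:20     35.30  1.70
                   1:60     16.55  0.86
tc-only LEHR       tc-only  77.98  4.01
```

Read bottom-up: the clinical reference (⁹⁹ᵐTc-only, LEHR collimator)
recovers ~78 % of the true tumor contrast at this grid scale; adding ⁹⁰Y at
a 1:20 activity ratio without correction halves that (35 %), and tripling
the ⁹⁰Y (1:60) halves it again (17 %); the model-based correction recovers
most of the loss (58 %) and degrades more slowly with increasing ⁹⁰Y
(44 % at 1:60). The same run reports LSF (15.96 % MC-corrected vs 12.61 %
uncorrected at 1:60, against a 15 % ground truth) and extrahepatic
activities (MC restores EHD1 to 2.63 MBq against a 2.64 MBq truth, where
uncorrected data inflate it to 7.75 MBq at 1:60). This is the qualitative
finding of the study: crosstalk correction plus a medium-energy collimator
restores quantitative ⁹⁹ᵐTc imaging in the presence of therapy-level ⁹⁰Y.

`analysis/03_deadtime_linearity.py` runs the count-rate analysis (ideal
slopes extrapolated from low activities, paralyzable τ recovery, activity
limits for < 2 % deviation), and `--full-scale` on script 04 runs the full
128³ / 120-angle / 75-realization grid.

## Layout

```
src/tcyspect/      library: phantom, physics, acquisition, reconstruction,
                   corrections, evaluation, pipeline, io (+ packaged
                   defaults in data/defaults.yaml)
analysis/          numbered study drivers writing tables under results/
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model description, conventions, limitations
```
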