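# phaeotox

Analysis pipeline for diatom ecotoxicological bioassays, built around the
endpoints of a standard *Phaeodactylum tricornutum* exposure experiment
(6 toxicant doses × 3 replicates, 48 h exposure during exponential
growth). It is written for ecotoxicologists and algal ecophysiologists
who have per-replicate instrument tables (cell counts, OJIP fluorescence
transients, extract absorbance spectra, FAME chromatogram peak areas,
plate-reader kinetics) and want the derived physiological quantities plus
the multivariate classification of treatments.

## What it computes

* **Growth & dose-response** — specific growth rate
  μ = (ln N_f − ln N_i)/Δt (d⁻¹), relative growth inhibition
  (1 − N/N_ctrl)·100, and the IC50 from a two-parameter log-logistic fit
  I(d) = 100/(1 + (IC50/d)^h), with log-linear interpolation between the
  doses bracketing 50% as fallback and cross-check.
* **JIP-test** — cardinal points F0 (50 µs), F300, FJ (2 ms), FI (30 ms),
  FM from the Kautsky curve; V_J, V_I, M0, the complementary area, S_M,
  N, φ_P0 = 1 − F0/FM, ψ_E0, δ_R0, the phenomenological fluxes per cross
  section (ABS/CS, TR/CS, ET/CS, DI/CS, RC/CS) and their ratios; active
  OEC fraction and an experimental antenna-connectivity estimate.
* **Pigments** — Gauss-peak spectral unmixing of 350–750 nm whole-cell
  extract spectra into chl *a*, chl *c*, pheophytin *a*, β-carotene,
  fucoxanthin, diadinoxanthin and diatoxanthin by non-negative linear
  least squares over a fixed Gaussian band library.
* **Fatty acids** — internal-standard (C15:0) quantification of FAME peak
  tables, saturation classes (SFA/MUFA/PUFA/UFA) and the double-bond
  index DBI = 2·(%monoenes + 2·%dienes + … + 5·%pentaenes)/100.
* **Oxidative stress** — MDA (ε = 155 mM⁻¹cm⁻¹ on A532−A600), catalase
  (ε = 39.4, 240 nm), ascorbate peroxidase (ε = 2.8, 290 nm) and SOD
  (pyrogallol autoxidation inhibition, 1 U = 50%), protein-normalised.
* **Energy budget** — available energy Ea from combustion equivalents
  (17 500 / 24 000 / 39 500 mJ mg⁻¹ for carbohydrate / protein / lipid),
  energy consumption Ec from ETS INT-formazan kinetics (2 µmol formazan
  per µmol O₂, 480 kJ mol O₂⁻¹), CEA = Ea/Ec, all per 10⁶ cells.
* **Statistics** — Kruskal–Wallis with Dunn/Holm compact letter
  displays, Spearman dose correlations, and canonical analysis of
  principal coordinates (CAP) with true leave-one-out classification and
  a permutation test of the canonical trace.

A synthetic-data generator (`phaeotox.synthetic`) produces complete
dose-structured experiments with known ground truth, so the whole chain
is testable without instrument data; noiseless generation inverts
exactly through each analysis stage.

## Worked example

The one dose-response computation that needs nothing but three numbers:
growth inhibition of 39% at 40 µg/L and 83% at 80 µg/L (control 0%).

```python
>>> from phaeotox import fit_ic50
>>> fit = fit_ic50([0.0, 40.0, 80.0], [0.0, 39.0, 83.0])
>>> round(fit.ic50, 2), round(fit.hill_slope, 2), fit.method
(46.59, 2.93, 'log-logistic fit')
>>> fit = fit_ic50([0.0, 40.0, 80.0], [0.0, 39.0, 83.0], method="interpolation")
>>> round(fit.ic50, 2)
47.57
```

Both estimators land near 47 µg/L: the concentration at which this
toxicant halves diatom growth. The log-logistic fit passes exactly
through the two observed points (two parameters, two informative
observations); the interpolation value is the closed-form log-linear
crossing of 50%.

Running the full pipeline on a synthetic experiment:

```
phaeotox all --seed 1 --out myrun
```

writes per-stage CSVs (`growth.csv`, `jip.csv`, `pigments.csv`, `fa.csv`,
`assays.csv`, `energy.csv`, `stats.csv`, `cap.csv`), the generated input
tables, `summary.json` (with seed, config hash and per-stage output
hashes) and `run.log`. With the default generator settings (noise
CV 0.1) the fitted IC50 comes back at 45.6 µg/L against a generating
value of 47.3, and the CAP leave-one-out classification of the six
treatment groups reaches 66.7% on the raw fluorescence curves and 44.4%
on the fatty-acid profiles (18 samples, chance level ≈ 15%).

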