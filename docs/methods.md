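# Methods

This note documents the models, conventions, numerical choices and known
limitations of the phaeotox pipeline, stage by stage.

## Experimental design assumed

A chronic microalgal bioassay: cultures inoculated at 2.7 × 10⁵
cells mL⁻¹, grown 48 h to exponential phase, then exposed for 48 h to a
toxicant gradient (default 0, 0.3, 0.6, 20, 40, 80 µg L⁻¹) with three
biological replicates per dose. Cell counts are taken daily; all
biochemical endpoints are measured at the 96 h harvest. The analysis
stages do not depend on these particular values — they are the defaults
of the synthetic generator and of the pipeline configuration.

## Growth and dose-response

The specific growth rate is μ = (ln N_final − ln N_initial)/Δt with Δt
in days. Inhibition is computed on **densities** at the exposure
endpoint, (1 − N/N̄_ctrl)·100, not on rates: the two differ (rates are a
log transform of densities), and the density convention matches how
growth inhibition is usually reported for this design. A rate-based
inhibition can be obtained by applying `relative_inhibition` to rates.

IC50 estimation offers two methods, with the method always recorded in
the result:

* **log-logistic fit** (default): least squares of
  I(d) = 100/(1 + (IC50/d)^h) on the per-dose inhibitions. The control
  (d = 0) cannot enter log-dose space; it anchors the 0% asymptote,
  which the model satisfies identically at d = 0. Bounds keep IC50
  positive and h ∈ [10⁻³, 50]; the starting point is the interpolation
  estimate when available.
* **log-linear interpolation**: the 50% crossing of inhibition vs
  log₁₀(dose) between the two bracketing doses — a closed form that
  needs no iteration and serves as an independent cross-check.

If 50% is never reached and the fit cannot produce an estimate, the
result is explicitly flagged `reached = False` with IC50 = NaN rather
than an extrapolated number. Negative inhibition (stimulation) is kept
and flagged, never clipped.

## JIP-test

Cardinal points are read off the transient by linear interpolation in
log time at exactly 50 µs (F0), 300 µs (F300), 2 ms (FJ) and 30 ms (FI);
FM is the maximum over the transient. Derived parameters follow the
standard JIP-test definitions, each stated next to its computation in
`ojip.py`: V_J, V_I, V_K as relative variable fluorescences;
M0 = 4(F300 − F0)/F_V per ms; the complementary area above the curve by
trapezoids on the raw (linear) time grid from the first sample to the
time of FM; S_M = Area/F_V (reported in ms); N = S_M·M0/V_J;
φ_P0 = 1 − F0/FM; ψ_E0 = 1 − V_J; δ_R0 = (1 − V_I)/(1 − V_J); and the
flux ratios built from them.

ABS/CS needs a proxy for absorption per cross-section. The default is
F0 (the "CS0" convention); FM ("CSM") is available via a switch, and the
choice is recorded in every output because instrument protocols differ
silently on this point. The other per-CS fluxes follow:
TR/CS = φ_P0·ABS/CS, ET/CS = φ_P0·ψ_E0·ABS/CS, DI/CS = ABS/CS − TR/CS
(so ABS/CS = TR/CS + DI/CS holds to machine precision by construction),
RC/ABS = φ_P0·V_J/M0 and RC/CS = RC/ABS·ABS/CS.

The fraction of active oxygen-evolving complexes is computed against a
control reference, AOEC = [1 − V_K/V_J]_sample/[1 − V_K/V_J]_control: a
K band rising toward the J step (V_K/V_J → 1) marks donor-side
inactivation. The antenna grouping probability P_G is estimated from
the 100–300 µs L band of W = (F − F0)/(F_J − F0) against the control
transient; because no printed formula for the instrument's own P_G is
available, this estimate is **flagged experimental** and should be read
comparatively (sample vs control), not absolutely. Degenerate
transients (FM ≤ F0) return all-NaN parameters with a flag.

## Pigment unmixing

Each pigment's extract spectrum (100% acetone context) is a fixed sum of
Gaussian bands; an extract spectrum is modelled as a non-negative linear
combination of the pigment templates plus a constant + linear baseline
on the exact 350–750 nm, 0.5 nm grid (801 points). Fitting is bounded
linear least squares (`scipy.optimize.lsq_linear`): pigment scales ≥ 0,
baseline unconstrained — the linear Gauss-peak variant with fixed band
positions, chosen because the experimental workflow fits a fixed
library. Band positions are not refined; scattering correction is out
of scope beyond the linear baseline.

The shipped template table, `data/gps_library_synthetic.csv`, is a
**constructed stand-in**: literature-plausible band positions per
pigment assembled into an internally consistent basis, not a
transcription of a published library. Its widths were chosen so the
seven templates remain distinguishable (Gram-matrix condition number
≈ 234, reported with every fit): the three carotenoids share the
440–490 nm window and are separated mainly by band width (broad
β-carotene and fucoxanthin vs narrow xanthophylls). Round-trip
guarantees (recovery ≤ 1% noiseless, ≤ 10% at 1% multiplicative noise)
are properties of fitting with whatever library generated the spectrum,
and hold for any replacement library of comparable conditioning;
absolute concentrations are meaningful only in template units until a
calibrated library is substituted.

## Fatty acids

Masses follow the peak-surface method against the C15:0 internal
standard, mass_i = area_i/area_IS · mass_IS; relative percentages are
over identified fatty acids excluding the standard. Classes by
double-bond count: 0 → SFA, 1 → MUFA, ≥ 2 → PUFA. The double-bond
index is DBI = 2·Σ(n·%_n)/100 where %_n is the percentage of acids with
n double bonds; the printed formula stops at pentaenes, and acids with
more than five double bonds extend the pattern (coefficient = bond
count) with a warning. Positional isomer suffixes (n-7, n-3) are
parsed and carried but affect no statistic. Unidentified trace peaks
are assumed excluded from the percentages.

## Assay conversions

All conversions are Beer–Lambert arithmetic with explicit volume
bookkeeping (`AssayConstants`): substrate turnover in the cuvette is
|ΔA/min|/(ε·path) in mM min⁻¹, scaled by the reaction volume to
µmol min⁻¹ and normalised by the extract aliquot and its protein mass.
Kinetic rates are least-squares slopes over a configurable window
(default: the full trace), sign preserved. The SOD unit is the
conventional pyrogallol definition — 1 U = 50% inhibition of the
autoxidation rate — since the assay description does not define a unit;
inhibition outside [0, 100] is clipped with a flag. The APX wavelength
and coefficient (290 nm, ε = 2.8 mM⁻¹cm⁻¹) are used as specified by the
source protocol even though 290 nm is an unusual ascorbate wavelength.
MDA with a negative turbidity-corrected absorbance reports 0 µM with a
flag.

## Energy budget

Ea = (17 500·carb + 24 000·protein + 39 500·lipid) mJ, per 10⁶ cells.
Ec converts the INT-formazan formation rate at 490 nm to O₂ consumption
(2:1 stoichiometry) and then to energy at 480 kJ mol O₂⁻¹
(= 480 mJ µmol⁻¹), linearly extrapolated from the kinetic read to one
hour. CEA = Ea/Ec; Ec = 0 yields an explicit undefined flag, not
infinity.

**Formazan extinction coefficient**: the source protocol prints
ε = 15 900 mM⁻¹ cm⁻¹, while the spectrophotometric literature for
INT-formazan reports the same digits per M. Both are supported through
`EnergyConstants.epsilon_unit`; the default follows the protocol as
printed ("mM"). The choice rescales Ec — and therefore CEA — by 10³,
so it is recorded in every output; comparisons across runs are valid
only at a fixed setting.

## Multivariate statistics

*Kruskal–Wallis* uses the tie-corrected H (scipy). When the global test
is significant, pairwise Dunn rank-sum z tests with Holm adjustment
define the compact letter display; letters are the maximal cliques of
the not-significantly-different graph (enumerable for bioassay-sized
group counts), so groups sharing a letter never differ significantly.

*Spearman* correlations are reported as ρ, ρ² and signed ρ² (the sign
of ρ carried onto ρ², a convention common in dose-response screening
tables), with constant inputs flagged undefined.

*CAP* follows the Anderson–Willis construction: (1) the distance matrix
(Euclidean by default, any `pdist` metric accepted) is Gower-centred and
eigendecomposed (PCoA); meaningfully negative eigenvalues are excluded
with a warning. (2) Canonical discriminant analysis runs on the first
m axis scores; a singular within-group scatter triggers a flagged ridge
fallback. (3) Leave-one-out allocation is **true** LOO: for every
held-out sample the PCoA axes and the discriminant space are recomputed
without it, the sample is projected onto those axes by the Gower
add-a-point formula and allocated to the nearest group centroid in
canonical space — held-out samples never influence the axes they are
judged on. (4) m is chosen to maximise LOO success (smallest m on
ties), m ≤ n − g; a fixed m can be forced. (5) The permutation test
permutes group labels (default 9 999 permutations, seed always
recorded) and recomputes the canonical trace tr(Q′_m H Q_m) — the sum
of squared canonical correlations — on the fixed (label-independent)
axes; p = (1 + #{perm ≥ obs})/(B + 1).

Two calibration facts, established with an independent brute-force
oracle, matter when interpreting null-data behaviour. First, LOO
nearest-centroid allocation at three samples per group is structurally
biased *below* the idealized 1/g chance level (the held-out sample's
own centroid keeps only two members): with 6 × 3 samples the measured
chance level is ≈ 0.152, not 1/6. Second, the maximise-LOO rule is
optimistically biased on null data (measured ≈ 0.24) because it selects
the best of many m values; null-calibration checks therefore run at
fixed m, while the max-LOO rule remains the default for real analyses,
where its selection bias is the price of the standard heuristic.

## Synthetic-data generator

The generator emulates the full experiment with known ground truth.
Design constants: the 6 × 3 dose design, 2.7 × 10⁵ cells mL⁻¹ start,
daily counts over 96 h, control growth rate 0.9 d⁻¹, generating
IC50 = 47.3 µg L⁻¹ with hill slope 2.9 (this slope makes the noiseless
inhibition curve pass within the reported uncertainty of the 39%/83%
inhibitions at 40/80 µg L⁻¹; solving the two-point closed form exactly
gives h ≈ 2.7–3.0). Treated cultures are constructed so that their
*density* reduction at the exposure endpoint equals the log-logistic
inhibition at their dose — the generator inverts the analysis-side
definition, so noiseless IC50 recovery is exact by construction.

Endpoint trends are driven by a sign map (direction) and fixed relative
effect strengths at 100% inhibition; the default signs mirror the
dose-response directions such exposures report (energy fluxes,
chlorophyll *a*, fucoxanthin, diadinoxanthin, C16:0/C16:1 down;
quinone-pool turnover, pheophytin *a*, β-carotene, C16:2/C16:3/C20:5,
oxidative-stress markers, Ea and respiration up). Trend-sign
guarantees (Spearman ±1 in noiseless data) apply to the generator's own
endpoint knobs; derived quantities respond jointly — e.g. S_M reflects
both the rise-kinetics slowdown and the V_I increase, and the latter
dominates at high inhibition — and fatty-acid renormalisation lets
nominally flat acids drift slightly opposite to the trending ones.

The OJIP transient is a sum of four sigmoidal rise phases in log time
(K, J, I, P at log₁₀ t ≈ −3.8, −3.0, −2.1, −0.9, widths 0.15–0.20
decades). Phase amplitudes and an offset solve a 5 × 5 linear system so
the noiseless curve passes *exactly* through (50 µs, F0), (300 µs,
F0 + V_K F_V), (2 ms, F0 + V_J F_V), (30 ms, F0 + V_I F_V) and the
final-sample plateau FM; the sampling grid includes the cardinal times
exactly, so cardinal extraction is exact on noiseless data.
Monotonicity is verified after construction and violating parameter
combinations are rejected. This form guarantees the cardinal points by
construction; it is not a mechanistic model of PSII kinetics.

Noise is multiplicative lognormal (mean-preserving, CV = `noise_cv`) on
counts, peak areas, rates and masses — these are positive,
CV-stable quantities — and additive Gaussian on transients
(SD = CV·0.02·FM) and spectra (SD = CV·0.01 AU). The experimental
record gives no replicate variance model, so the default CV 0.1 is an
invented, documented choice of ordinary counting/pipetting precision.
Randomness flows from one master seed; each (dose, replicate) pair owns
a `SeedSequence` substream keyed by its design position, so generated
replicates are independent of iteration order and bit-reproducible.

What the generator does **not** emulate: mechanistic photosynthesis or
enzyme kinetics, GC chromatogram raw signals (peak tables only),
instrument drift, batch effects, or between-replicate correlation.
Passing round-trip tests therefore demonstrates correctness of the
conversion arithmetic and estimators under the stated noise model, not
robustness to real instrument artefacts.

## Pipeline and I/O

All I/O is CSV (UTF-8, comma-delimited, dot decimal; a dialect switch
supports semicolon/comma-decimal exports). Readers validate against
per-table schemas and, in permissive mode, drop corrupted rows while
reporting their line numbers. The pipeline runs
simulate → growth/IC50 → JIP → pigments → fatty acids → assays →
energy → univariate stats → CAP, writes one CSV per stage, and records
seed, config hash, input hashes and per-stage output hashes in
`summary.json` — two runs with the same configuration and seed are
byte-identical in all analysis outputs. The pipeline default of 999
CAP permutations keeps interactive runs fast; the `cap()` function
default is 9 999.

Problem sizes in the shipped test and acceptance runs (300–1 000 random
transients, 100 pigment mixtures, 50–100 IC50 seeds, 200–400 CAP null
datasets × 499 permutations) were chosen as the smallest sets at which
the Monte-Carlo bands in the corresponding checks are decisive.

## Known limitations

* Pigment concentrations are in template units until a calibrated GPS
  library replaces the synthetic stand-in.
* P_G is an experimental comparative estimate and is not expected to
  reproduce any instrument's built-in connectivity output.
* The formazan ε unit ambiguity rescales Ec/CEA by 10³ between settings.
* CAP accuracy under the max-LOO rule is optimistic on weakly structured
  data; use the fixed-m mode for unbiased null calibration.
* The IC50 log-logistic fit with only two informative doses reproduces
  those points exactly; its hill slope is then determined, not tested.
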