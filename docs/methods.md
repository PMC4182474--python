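# Methods

`dcequant` implements a quantitative MRI analysis chain for small-animal
tumour treatment-response studies — T1 mapping, DCE pharmacokinetic
mapping, ADC mapping, histology indices, and cohort-level inference —
together with seeded digital phantoms that let every stage be validated
by parameter recovery.  This note records the models, the assumptions
behind the defaults, and the design choices made where the design was
genuinely open.

## Pharmacokinetic model

Tissue tracer concentration follows the extended Tofts two-compartment
model,

    C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^{-(K^trans/v_e)(t-τ)} dτ ,

with `K^trans` (1/min) the plasma-to-interstitium transfer constant,
`v_e` the extravascular extracellular volume fraction, and `v_p` the
plasma volume fraction.  All three parameters are fitted per voxel
(bounded least squares, `K^trans ∈ [0, 5]` 1/min, `v_e ∈ [10⁻³, 1]`,
`v_p ∈ [0, 1]`, three fixed starting points with best-RSS selection, so
the fit is deterministic); a `fix_vp` option pins `v_p` instead.
`v_e = 0` with `K^trans > 0` is rejected — the efflux rate is undefined.

The arterial input function is a biexponential,
`C_p(t) = D (a₁ e^{-m₁(t-t₀)} + a₂ e^{-m₂(t-t₀)})` for `t ≥ t₀`.  With
this form the convolution has a closed form (differences of
exponentials, with the `m = k_ep` degeneracy handled by its `τ e^{-mτ}`
limit), which the fitter evaluates; an independent fine-grid trapezoidal
convolution (default Δt = 10 ms, integrating from `t₀` so the bolus
discontinuity sits on a grid node) exists as a cross-check oracle and
agrees with the closed form to ~10⁻⁹ mM on the default grids.  The
shipped AIF parameters (`a₁ = 5.8`, `a₂ = 0.7` kg/L; `m₁ = 4.2`,
`m₂ = 0.016` 1/min; dose 0.2 mmol/kg, peak ≈ 1.3 mM) describe a
plausible rat plasma curve for a gadodiamide-class agent.  **They are
literature-derived working values, not measurements**; any real
analysis should replace them with a measured or published AIF via
configuration.  No haematocrit correction is applied (a hook exists).

`AUC_1min` is the trapezoidal integral of tissue concentration from
bolus arrival (the first frame after the 20-frame baseline block) over
60 s, with the endpoint interpolated; it is model-free and reported in
mM·s.  Bolus arrival is fixed at the end of the baseline block rather
than detected from data.

## Signal model and its inversion

The dynamic series and the T1-mapping series share a saturation-recovery
signal equation

    S = s₀ (1 − e^{−TR·R1}),   R1 = 1/T1 + r₁ C .

The acquisition this emulates is a short-TR RARE sequence; the
saturation-recovery form is the standard approximation for it, adopted
here as a documented assumption since no signal equation is uniquely
implied by the sequence name.  Relaxivity defaults to
r₁ = 3.9 L·mmol⁻¹·s⁻¹ (gadodiamide-class at high field) — an assumption,
configurable.  Concentration is recovered by calibrating s₀ per voxel
from the mean of the 20 pre-contrast frames and the voxel's own
pre-contrast T1, inverting the exponential per frame, and subtracting
the baseline R1.  Frames at or beyond the saturation asymptote are
clipped to the largest invertible concentration and flagged; voxels with
non-positive baseline or no valid T1 are excluded.  The T1 map and the
dynamic series are assumed co-registered on the same grid — grid
mismatch is an error, never an interpolation.

## T1 and ADC fitting

T1 mapping fits the two-parameter `(s₀, T1)` saturation-recovery model
to the seven-TR series (TR = 0.125 … 10 s), with T1 bounded to
[0.01 s, 20 s], initialised from the TR at which the signal reaches half
its longest-TR value.  Saturated (constant) voxels run to the lower
bound and are flagged invalid.  When no mask is given, background is
excluded at 5× a robust noise floor (1.4826·MAD of a corner patch).

ADC mapping regresses ln S on b per direction (OLS; there is no b = 0
image, so the intercept extrapolates ln S₀) and averages the three
orthogonal directions (trace ADC, arithmetic mean — the geometric mean
was the alternative).  A weighted option (weights ∝ S²) is available.
In heavy noise the Rician floor flattens the decay tail and biases ADC
low; at the simulated SNR of 20 this bias is negligible relative to the
random error.

## Digital phantoms

Voxel-level phantoms use a small 3D grid (default 32×32×4) holding a
spherical "tumour" in homogeneous background, with piecewise-constant
truth maps (tumour defaults: `K^trans` 0.15/min, `v_e` 0.30, `v_p` 0.03,
T1 1.8 s, ADC 1.1×10⁻³ mm²/s; background 0.01/min, 0.10, 0.01, 1.5 s,
0.7×10⁻³).  Tissue T1 and SNR at high field are not pinned down by any
source this package relies on; these values are stated assumptions of
the phantom.  Acquisition timing follows the emulated protocol: 206
dynamic frames at 4.8 s with 20 pre-bolus baseline frames and
TR = 200 ms; seven TRs for T1 mapping; b = 300/500/800/1200 s/mm² along
three directions.  Noise is Rician — the magnitude of complex Gaussian —
with a Gaussian option for debugging.  SNR is quoted as mean acquired
signal over σ (for the dynamic series, pre-contrast baseline signal over
σ), i.e. relative to the signal actually present in the images rather
than to the unattenuated magnetisation.  All generators take a seed and
are bit-reproducible.

The summary-level cohort generator emulates a two-cohort, four-arm
study (control, antibody monotherapy, NK-cell monotherapy, combination)
with 2–6 animals per arm measured at two post-treatment timepoints.
Per animal and timepoint, `v_e` = group mean + animal random effect
(SD 0.05) + residual (SD 0.03), truncated to (0, 1) with a warning if
more than 10% of draws truncate.  The default effect pattern raises the
combination arm's `v_e` by +0.15 over control (0.45 vs 0.30) and lowers
the NK monotherapy arm by −0.10 (0.20) — cell killing enlarges the
interstitium; an ineffective cell infusion packs it.  ADC is generated
with a group-specific linear dependence on `v_e` (slope −1.0×10⁻³ mm²/s
per unit `v_e` in the NK-containing arms, 0 elsewhere), so the negative
ADC–`v_e` association is reproducible by construction.  Tumour volume
follows exponential group×time growth; `K^trans` and `v_p` carry no
group effect by default.  The generator emits summary tables (fast
statistics testing); voxel-level per-animal phantoms are available
through the imaging generators.

What passing tests on these phantoms do **not** show: robustness to
motion, B0/B1 inhomogeneity, partial-volume mixing, AIF mis-specification
(the phantom is generated and fitted with the same AIF), or deviations
from the monoexponential/two-compartment forward models.  Recovery
results here bound optimiser and noise error only.

## Cohort statistics

MRI parameters (repeated measures per animal) are analysed by OLS with
group and timepoint fixed effects ("combining the first two timepoints"
as a timepoint effect, interaction optional) and a cluster-robust
sandwich covariance grouped by animal, followed by Scheffé-adjusted
pairwise group contrasts (`F* = t²/(g−1)` against `F(g−1, df)`;
simultaneous CI half-width `√((g−1)F_crit)·SE`).  Scheffé protects all
linear contrasts, so it is conservative for the few pairwise
comparisons reported.

With 3–6 animals per arm the small-sample convention dominates the
operating characteristics, and no single convention is canonical.  Two
are implemented:

* **CR2 + Satterthwaite (default).**  Bell–McCaffrey bias-reduced
  residuals `(I − H_cc)^{−1/2} e_c` and per-contrast Satterthwaite
  degrees of freedom.  Chosen as default because it is the convention
  recommended for few-cluster designs and the one whose simulated
  operating characteristics are calibrated at this package's design
  sizes (family-wise error ≈ 0.05, CI coverage ≈ 94–95% on 5000 null
  cohorts — recomputed by the validation suite, not quoted from
  elsewhere).
* **CR1 + df = G−1.**  The classic `G/(G−1)·(N−1)/(N−k)` scaling with
  cluster-count degrees of freedom (Stata's `vce(cluster)` convention).
  Available via `cov_type="CR1", df_rule="clusters"`; anti-conservative
  at these sizes (simulated family-wise error ≈ 0.09).

Histology indices (one value per animal) use one-way ANOVA with
pooled-variance pairwise t tests and Bonferroni multiplication — a
deliberately separate, simpler inference path.  The Growth Index is the
mean over animals of each animal's proliferation/apoptosis ratio
("mean of ratios"; ratio-of-means is exposed as an option).  The TUNEL
area fraction uses strict `>` at the threshold, since any real
microscope software's tie convention is unknowable; the threshold
itself is an input.  Associations between parameters (ADC vs `v_e`) use
ordinary simple regression with the F-test p-value.

Tumour volume is an ROI voxel count, with an optional post/pre
enhancement-ratio refinement as a reproducible stand-in for manual ROI
drawing.

## Numerical and QC choices

* One time-unit conversion point (seconds → minutes) in the kinetics
  module; rates are 1/min internally.
* The numeric convolution uses exponential-weighted cumulative
  trapezoids, switching to a stable stepwise recursion when
  `k_ep · T` would overflow the weighting.
* All-zero concentration voxels short-circuit to
  `K^trans = 0, v_p = 0`, `v_e` at its lower bound, flagged
  non-converged (unidentifiable).
* Voxels with non-convergent fits are excluded from map validity
  masks; map summaries (median, mean, IQR) are computed over valid
  voxels only.  Animal-level QC is a `qc_pass` flag in the cohort
  table; flagged rows are dropped before model fitting.
* Pipeline outputs are deterministic given config + seed; provenance
  (config hash, seed, version) is written alongside results.

## Validation experiment sizes

The validation suite uses 27 parameter combinations for the
convolution-oracle check, 500 voxels for noisy kinetic recovery
(SNR 20), 1000 voxels each for ADC (SNR 20) and T1 (SNR 50) recovery,
5000 replicate null cohorts for calibration, and 200 replicate studies
for effect-direction power — sizes chosen so each experiment's Monte
Carlo error is small against the thresholds it checks while the whole
suite runs in well under a minute.

## Known limitations

* No k-space simulation, motion, partial-volume or field-inhomogeneity
  effects; no DICOM ingestion or registration.
* No shutter-speed or two-compartment-exchange kinetic models; no IVIM,
  kurtosis or tensor diffusion models; no inversion-recovery T1
  variants.
* The AIF is assumed known and common to all animals; `v_p` estimates
  are particularly sensitive to this assumption.
* No mixed-effects (REML) estimation — clustering is handled entirely
  through the robust covariance.
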