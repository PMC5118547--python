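# Methods

This note documents the models behind `photokin`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices a maintainer should know about.

## Photocycle model

The photocycle is a continuous-time first-order linear system d**p**/dt =
**K p** over named states.  The rate matrix uses the column convention
K[i, j] = rate of the j → i transition (i ≠ j) with diagonals equal to the
negated column sums, so 1ᵀK = 0 and total population is conserved exactly,
not approximately.

The default scheme is the strictly sequential irreversible chain
K → L → M1 → M2 → P13C → ground, parameterized directly by the five phase
lifetimes (2 µs, 210 µs, 6.0 ms, 200 ms, 91 s).  The M intermediate rises
with two distinct time constants, which implies two kinetically distinct
states on the L→M stretch; we represent them as M1 and M2 and give M1 a
50/50 superposition of the L and M absorption bands.  This choice makes
both M-rise phases carry non-zero decay-associated amplitude (two states
with identical spectra would render one phase spectroscopically silent)
while keeping the chain strictly sequential.  Reversible steps (e.g. an
L ⇌ M equilibrium) are supported by the scheme machinery but are not part
of the default: the forward/backward rates of that equilibrium are not
determined by the five observable lifetimes, so equilibrium schemes must
be user-supplied rather than guessed.

**Propagation.**  The populations span ~8 decades in time, which makes
step-wise integration stiff.  We therefore diagonalize K and evaluate
p(t) = V e^{Λt} V⁻¹ p₀ directly; this is exact at arbitrary times and
conserves population to ~1e−15.  If the eigensystem is defective or
near-degenerate (relative eigenvalue gap < 1e−9, e.g. two identical rates
in a chain), the propagator falls back to dense BDF integration
(rtol 1e−10) and flags it in the returned metadata.  Apparent time
constants are −1/Re(λ) over the non-zero eigenvalues; for triangular
(irreversible sequential) matrices the diagonal is used directly so the
lifetimes are exact, and complex eigenvalues are rejected as unphysical
for this model class.

**Surfaces.**  ΔA(t, λ) = f_ex Σ_s p_s(t) (ε_s(λ) − ε_ground(λ)), linear in
the photoexcited fraction f_ex and in every species spectrum.  The
photoexcited fraction per flash is not an observable of the fit (it only
scales amplitudes) and defaults to 0.05, a typical single-flash turnover
for a 3 mJ nanosecond pulse on an optically thin sample.

## Global fitting (variable projection)

The fitted model is ΔA(t, λ) = Σᵢ DASᵢ(λ) e^{−t/τᵢ} + A∞(λ).  For any
candidate τ set the amplitudes are the exact solution of a linear least
squares problem solved wavelength-by-wavelength in one `lstsq` call, so the
nonlinear search runs over the τ only (separable least squares).  Choices:

* τ are optimized as log₁₀ τ with box bounds one decade beyond the
  observation window; log-space is the natural parameterization for
  lifetimes spanning 8 decades.
* Multi-start: the first initialization places the τ at log-quantiles of
  the observation window; the remaining restarts (default 8 total) draw
  sorted log-uniform τ from a seeded generator.  The best restart by RSS
  wins; exact RSS ties break toward the smallest log-τ dispersion, making
  the result deterministic given the seed.
* The non-decaying offset A∞ is enabled by default: with a 2 s window and
  a 91 s recovery the slowest process is indistinguishable from a
  constant, and omitting it would alias that amplitude into the slowest
  fitted phase.
* Uniform weights by default; per-time-point 1/σ weights are accepted.
* Two recovered τ within 5% of each other add an "unresolved components"
  warning to the metadata; an observation window shorter than 3× the
  slowest recovered τ adds a "weakly constrained" warning (relevant when a
  recovery trace is truncated).

Model-order selection fits n = 0…n_max and stops at the first n whose
relative RSS improvement over n−1 falls below 5% (configurable), returning
n−1 and the full RSS table.  An RSS that is already numerically zero
relative to the data counts as non-improvable, so noiseless data selects
the true order rather than chasing rounding error.

The M-decay pH analysis fits each M-band trace with a rise+decay
biexponential (smaller τ = rise) and classifies the reprotonation donor:
aqueous H⁺ uptake must slow the M decay at high pH, so a decay lifetime
that is non-increasing with pH (within a 1.5× factor) indicates an
internal donor; a strictly increasing lifetime (overall change > 1.5×)
indicates aqueous uptake; anything else is reported indeterminate.

## Isomer spectroscopy

Pure-species synthetic bands are Gaussians in wavenumber (1/λ), FWHM
3,800 cm⁻¹ — the physically standard lineshape for retinal-protein bands;
the peak in λ is unaffected by the monotone reparameterization.  Unmixing
solves the per-wavelength 2×2 mixture system; it is rejected as
ill-conditioned when the two all-*trans* fractions differ by < 0.05 (the
determinant of the mixing matrix).  Negative recovered absorbances are
reported with a warning, never clipped: they diagnose wrong input
fractions.  λmax is located by a parabola through the maximal sample and
its neighbours and reported at a fixed 0.1 nm resolution so results are
deterministic; boundary maxima raise an error and flat plateaus return
their midpoint with a warning.

## HPLC quantification

Peaks are detected by prominence (default threshold 3× a robust noise
estimate from the median absolute first difference) on a lightly smoothed
copy of the trace, so white detector noise does not register as peaks.
Areas are trapezoidal over each isomer's assignment window after
subtracting a linear baseline anchored at short medians around the window
edges — single-sample anchors would inject noise directly into the small
13-*cis* areas.  Up to two windows per isomer (syn and anti oxime) are
summed before ratioing; equal molar detector response across oxime species
is assumed, as is standard when areas are ratioed directly.  Fractions are
invariant to uniform signal rescaling, and integration error for
well-separated Gaussian peaks at S/N > 50 is below 1%.

## Pumping assay

Initial slopes are OLS over a 30 s window from light-on (the illumination
window is 0–150 s; 30 s keeps the saturating cell response approximately
linear while averaging enough samples).  pH is analyzed in pH units, not
moles of H⁺, because the buffer capacity of a cell suspension is not
generally known; a conversion hook can be layered on top if it is.
Classification thresholds: "abolished" means |slope| < 20% of the
CCCP-free slope, "accelerated" means > 150%, and slopes below a 2×10⁻⁴
pH/s floor count as flat; all three are configurable.  Expression
normalization uses the retinal-oxime reference (ε = 33,600 M⁻¹ cm⁻¹ at
360 nm) with a 1 cm path and 3 ml assay volume by default; activity
*ratios* between samples are independent of the oxime reference by
construction.  Mutant/wildtype comparisons average the CCCP-free initial
slopes over the three salts before normalizing, which roughly halves the
variance of the ratio without changing its expectation.

## Synthetic generators

Defaults encode the characterized system: the five lifetimes above;
ground/pure-all-*trans* band at 568 nm, pure 13-*cis* at 549 nm, K at
+20 nm, L at −30 nm, and the deprotonated-Schiff-base (M) band at 410 nm
(a standard M-state position; adopted as an assumption, since only the
blue-shift direction is observable in the difference data); dark
composition 92:8 relaxing to 50:50 under light; surface noise s.d. 5×10⁻⁴
on wavelengths 360–710 nm at 10 nm steps and 30 log-spaced points per
decade from 100 ns to 2 s; dark-adaptation trace at 1 s sampling over
600 s with noise 1×10⁻³; chromatogram peak pairs at 8/16 min (13-*cis*)
and 11/20 min (all-*trans*), σ 0.15 min, 60:40 syn:anti, detector noise
5×10⁻³ of a unit total area; assay base slope 1×10⁻³ pH/s with a 200 s
cell-response time and pH noise 2×10⁻³; genotype table with D216E at 3×
wildtype activity and the other carboxylate mutants strongly reduced.

All randomness derives from one master seed through fixed per-generator
substreams (`default_rng([seed, stream_id])`).  The generators emulate the
*statistical structure* of the measurements — kinetics, band shapes, peak
areas, slopes, additive Gaussian noise — not instrument physics: no
instrument response function, no photoselection or actinic-light
artifacts, no HPLC gradient or retention drift, no pH-electrode drift or
buffer-capacity nonlinearity.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to systematic instrument error.

## Problem sizes

The canonical fixtures are deliberately modest: a 221 × 36 surface for the
global fit, 600-point recovery traces, 2,501-point chromatograms and
281-point pH traces, with 8 restarts for headline fits and 4 for replicate
sweeps.  These sizes resolve all five phases comfortably and keep the
whole suite fast on a single core.

## Known limitations

* DAS-level analysis only: branched or equilibrium target schemes are not
  fitted directly to data (the kinetics module can simulate them, and the
  fitted DAS can be compared against simulated surfaces).
* The 91 s recovery is measured from the dedicated dark-adaptation trace,
  not jointly with the ≤2 s flash window, where it is not identifiable
  beyond its standing offset.
* Blue-shifted mutants measured with different excitation cutoffs are
  reported without action-spectrum correction.
* Uncertainties on fitted τ are limited to the diagnostic warnings above;
  no bootstrap or profile-likelihood intervals yet.
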