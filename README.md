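# photokin

Quantitative analysis tools for light-driven ion pumps, built around the
characterization of a natural **inward proton-pumping microbial rhodopsin**:
photocycle kinetic modelling, global analysis of transient-absorption data,
chromophore-isomer spectroscopy and HPLC quantification, and pH-based
ion-pumping assay analysis.  A seeded synthetic-data generator emulates every
measurement the pipeline consumes, so the full chain is testable end to end
without instrument data.

The package is a library: import it from Python, or start from the short
narrative scripts in `examples/`.

## The science

A microbial rhodopsin absorbs a photon and cycles through spectrally
distinct intermediates before returning to its ground state.  For the
dark-adapted inward H⁺ pump modelled here the cycle is sequential and
irreversible,

```
K ──2 µs──▶ L ──210 µs──▶ M1 ──6.0 ms──▶ M2 ──200 ms──▶ P13C ──91 s──▶ ground
```

with the early red-shifted K state, the blue-shifted L state, two
kinetically distinct deprotonated-Schiff-base (M) states, and a long-lived
13-*cis* ground state (P13C) whose slow thermal reversion (a bicycle-pedal
isomerization) closes the cycle.  The model is a first-order linear system
d**p**/dt = **K p**, solved analytically by eigendecomposition
(`photokin.kinetics`).

Flash-photolysis surfaces ΔA(t, λ) are analyzed by a **global
multi-exponential fit** with shared time constants and free per-wavelength
amplitudes,

ΔA(t, λ) = Σᵢ DASᵢ(λ) e^(−t/τᵢ) + A∞(λ),

where the amplitude spectra DASᵢ (decay-associated spectra) are solved
exactly by linear least squares for every candidate τ set and only the τᵢ
are optimized nonlinearly, in log₁₀ space — variable projection /
separable least squares (`photokin.globalfit`).

Around the kinetics sit three quantification stages:

* **Isomer unmixing** (`photokin.spectra`) — the dark- and light-adapted
  absorption spectra are two known linear mixtures (92:8 and 50:50) of the
  pure all-*trans* and 13-*cis* chromophore spectra; a per-wavelength 2×2
  solve recovers the pure bands (λmax 568 and 549 nm).
* **HPLC composition** (`photokin.hplc`) — retinal-oxime chromatograms are
  integrated per isomer (syn + anti oxime peaks summed) and ratioed into
  molar fractions with replicate statistics.
* **Pumping assay** (`photokin.assay`) — initial slopes of light-induced pH
  traces across salt × CCCP condition panels classify the transport mode
  (inward H⁺ pump / inward Cl⁻ pump), and hydroxylamine-bleach spectra
  (retinal oxime, ε = 33,600 M⁻¹ cm⁻¹ at 360 nm) normalize activities by
  expression level.

## Worked example

```python
import photokin as pk

cfg = pk.ScenarioConfig(seed=0)                       # default study conditions
surface = pk.synth.make_transient_dataset(cfg)        # 360–710 nm, 100 ns–2 s
fit = pk.fit_global_multiexp(surface, n_components=4, with_offset=True, seed=0)
print(fit.taus)
```

prints

```
[1.99652387e-06 2.09965919e-04 5.97380512e-03 2.00372219e-01]
```

— the four decaying lifetimes (2 µs, 210 µs, 6.0 ms, 200 ms) recovered from
the noisy surface to better than 1%, with `fit.das` holding one amplitude
spectrum per phase and `fit.offset` the standing 13-*cis*-minus-ground
spectrum left behind by the 91 s recovery.  Running
`python examples/05_pump_assay.py` ends with

```
D216E / WT activity ratio = 2.97
```

— the hyperactive D216E mutant pumps about threefold faster than wildtype
after expression normalization.

## Layout

```
src/photokin/    kinetics, globalfit, spectra, hplc, assay, synth, io
examples/        one short runnable script per capability
tests/           unit, property (hypothesis) and end-to-end recovery tests
docs/methods.md  model assumptions, defaults, numerical choices, limitations
```
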