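# Methods

This note records the models, numerical methods and design choices behind
`t1mt`, in the spirit of a methods section: what is computed, under which
assumptions, with which defaults, and what the synthetic experiments do and
do not demonstrate.

## 1. Two-pool magnetization-transfer model

Tissue is a two-pool system: a free (water) pool observed directly and a
semi-solid (macromolecular) pool that is invisible at imaging echo times but
coupled to the water via magnetization exchange. Pool sizes are normalized
to one; the semi-solid fraction is `m0s`. State is the 5-vector
`(xf, yf, zf, zs, 1)` — free-pool transverse and longitudinal components,
semi-solid longitudinal component, and a constant homogeneous component that
carries the relaxation drive so that every propagator is a plain affine
matrix. Semi-solid transverse magnetization exists only *inside* RF-pulse
propagators (its lifetime, ~T2s ≈ 12.5 µs, is far shorter than any
inter-pulse gap) and is discarded at pulse ends.

Free precession couples the longitudinal components as

    d/dt [zf]   [−(1/T1f + Rx·m0s)      Rx·(1−m0s)       ] [zf]   [(1−m0s)/T1f]
         [zs] = [ Rx·m0s          −(1/T1s + Rx·(1−m0s)) ] [zs] + [ m0s/T1s   ]

(the standard binary-spin-bath form; Henkelman et al., MRM 29:759, 1993),
with free transverse decay `exp(−t/T2f)`. The propagator uses the analytic
eigendecomposition of the 2×2 drift; both eigenvalues are real, and the fast
exchange limit of the slow eigenvalue is the population-weighted mean rate
`(1−m0s)/T1f + m0s/T1s` (property-tested).

### Lineshapes

The semi-solid absorption lineshape `g(Δ)` and its Fourier-pair
free-induction decay `G(t)` (`G(0) = 1`) follow Morrison & Henkelman
(JMR B 108:103, 1995):

* Lorentzian: `g = (T2s/π)/(1+(2πΔT2s)²)`, `G = exp(−t/T2s)`;
* Gaussian: `g = T2s/√(2π)·exp(−(2πΔT2s)²/2)`, `G = exp(−t²/2T2s²)`;
* super-Lorentzian:
  `g = √(2/π)·T2s ∫₀^{π/2} sinθ/|3cos²θ−1| · exp(−2(2πΔT2s/(3cos²θ−1))²) dθ`,
  `G = ∫₀^{π/2} sinθ · exp(−(3cos²θ−1)²·t²/(8T2s²)) dθ`.

All lineshapes are normalized to unit integral over *angular* frequency
(`∫g dω = 1`, i.e. `∫g dΔ = 1/2π` in Hz); this is the convention under which
the classical continuous-wave saturation rate is `Rrf = π ω1² g(Δ)`
(`= ω1²T2s` for an on-resonant Lorentzian). The super-Lorentzian integral is
evaluated by 256-node Gauss–Legendre quadrature over the orientation angle;
the integrand is finite at every node, so the on-resonance value is finite,
but note that the true `Δ → 0` limit diverges logarithmically — any quoted
on-resonance super-Lorentzian value is a quadrature convention, and the
quantities that matter (Graham integrals) are insensitive to it.

### Graham's spectral model

During a pulse of duration τ with complex waveform
`ω(t) = ω1(t)·exp(iφ(t))` the semi-solid longitudinal magnetization decays
at the pulse-averaged rate

    Rrf = (π/τ) ∫ |S(f)|² g(f) df ,   S(f) = ∫₀^τ ω(t) e^{−2πi f t} dt

(Graham & Henkelman, JMRI 7:903, 1997 — the spectral intermediate step of
that derivation, which integrates *over* the lineshape singularity and is
therefore well-defined on resonance). The FFT-based implementation resamples
the waveform finely enough to resolve its highest instantaneous frequency
and reduces to `π ω1² g(Δ)` for continuous-wave irradiation (tested against
a closed form and a brute-force quadrature oracle). The free pool
simultaneously obeys the full Bloch equations with the waveform, and
relaxation/exchange stay active.

### Generalized Bloch model

The generalized Bloch model (Assländer et al., MRM 87:2003, 2022) treats RF
pulses as rotations of the semi-solid magnetization whose transverse
component relaxes non-exponentially with the Green's function `G(t)`:

    ∂t zs(t) = −Re[ ω(t) ∫₀ᵗ G(t−s) ω̄(s) zs(s) ds ] + exchange + relaxation.

Rather than stepping this Volterra equation directly, `G(t)` is expanded in
a small sum of exponentials, `G(t) ≈ Σ_j a_j e^{−r_j t}` (amplitudes by
regularized least squares on a log-spaced rate dictionary, 5–6 rates per
decade, a zero rate always included so the `T2s → ∞` rotation limit is
exact; max error ≲ 1–2×10⁻³, asserted in tests). Each exponential mode
becomes one complex auxiliary state with linear dynamics, so on every
constant-amplitude, linear-phase waveform segment the full system
(free pool + zs + modes) is a linear ODE solved *exactly* by a matrix
exponential; frequency sweeps are handled per segment in a co-rotating frame
with an explicit frame-restoring rotation at segment ends. Consequences:

* rectangular pulses are propagated exactly (refinement changes nothing);
* shaped/swept pulses discretize only the waveform (48 segments for the
  default 10 ms HS1 pulse; halving or 10×-refining the segmentation moves
  the end-of-pulse zs by < 1e−4 of the pool size);
* the whole pulse map is affine, so periodic steady states are direct
  linear solves for every spin model.

The solver is validated against an independent brute-force product
integration (Heun) of the Volterra system and against a Bloch-ODE
integration of the free pool (agreement ~1e−5).

The magic-angle orientations of the super-Lorentzian ensemble
(`3cos²θ ≈ 1`) have effectively long transverse lifetimes — the slow tail of
`G(t)` — and the tail is therefore fitted to *relative* accuracy: it is what
lets a frequency sweep adiabatically invert part of the semi-solid pool
(§5).

## 2. Sequences

Protocols are ordered event lists (RF pulse / delay / readout / spoil /
saturation block), optionally split into independent acquisitions (one per
flip angle or inversion time); each acquisition is driven to its periodic
steady state (affine fixed point) before the readouts are recorded, unless
the protocol declares thermal-equilibrium start. MT is simulated during
*all* RF pulses — inversion, excitation, readout trains. Idealizations:
homogeneous B0/B1 (a global or per-voxel B1 factor scales all amplitudes),
perfect spoiling, no imaging gradients, readout trains without refocusing
pulses are approximated by a single sample (the RARE readout of the
saturation-prepared IR protocol samples zf at the echo-train start), and the
saturation block destroys the magnetization of both pools, matching the fit
assumption of that protocol family.

Three in vivo protocols are preset with their published numbers: the
saturation-prepared IR (TD ∈ {684, 4171, 2730, 10} ms,
TI ∈ {15, 15, 278, 1007} ms, 1 ms rectangular inversion), the variable flip
angle protocol (TR = 21 ms, flips {4°, 25°}, 100 µs rectangular pulses) and
the MP2RAGE (TI ∈ {0.92, 2.88} s, cycle TR = 5 s, adiabatic inversion,
192-pulse centric trains spaced 7.08 ms, flips {4°, 5°}). The remaining 22
roster presets are representative per-family heuristics (flagged
`heuristic` in their metadata); their timings, pulse durations and flip
angles span the ranges found across published implementations, including an
IR variant with a 10 µs hard inversion — the case that separates the
spectral and rotation treatments of the semi-solid pool.

The adiabatic inversion is an HS1 pulse: duration 10 ms, sweep ±1.2 kHz,
sech truncation 1% (β ≈ 5.30), peak amplitude set by requiring adiabaticity
`q = ω1max²/|dΔω/dt| = 10` at the resonance crossing (ω1max ≈ 8.9×10³
rad/s). Vendor pulses are proprietary; this default inverts the free pool
cleanly (> 96%) and is solidly above the adiabatic threshold.

Preset flip angles and pulse durations for the Look-Locker and variable
flip angle families are chosen where the *published fitting procedures are
self-consistent*: the Look-Locker correction `T1 = T1*(B/A − 1)` carries an
intrinsic bias of about `−flip²/4` plus the inversion-efficiency deficit, so
the LL presets use 2–3° readout flips and a 50 µs hard inversion; DESPOT1
assumes instantaneous pulses, so vFA excitations are kept ≤ 200 µs. This
keeps the mono-model round trip of *every* fitter within 0.1%, which is the
property that isolates MT (rather than fitter bias) as the source of the
simulated spread.

## 3. Mono-exponential fitters

Each family's published recipe, with variable-projection grid seeding
(T1 profiled over a log grid, linear nuisance amplitudes solved in closed
form) followed by bounded least squares (T1 ∈ [0.05, 10] s), analytic
Jacobians, and diagnostics on every return:

* saturation-prepared IR:
  `s = M0(1 − (1 + ε(1 − e^{−TD/T1}))e^{−TI/T1})` over (T1, ε, M0); for
  magnitude data the polarity is restored from the sign pattern of the
  best-fitting magnitude model (candidate patterns from the seed grid,
  lowest signed residual wins);
* classic IR: `s = a + b·e^{−TI/T1}` (Barral et al., MRM 64:1057, 2010);
* saturation recovery: `M0(1 − e^{−t/T1})`;
* Look-Locker: `A − B·e^{−t/T1*}` along the train, then
  `T1 = T1*(B/A − 1)` (Deichmann & Haase, JMR 96:608, 1992);
* DESPOT1: regress `s/sin(b1·α)` on `s/tan(b1·α)`; slope `e^{−TR/T1}`
  (Deoni et al., MRM 49:515, 2003), slope outside (0,1) is an error;
* MP2RAGE: `UNI = s1s2/(s1²+s2²) ∈ [−0.5, 0.5]` inverted through a
  dictionary built by simulating the *same protocol* under the mono model
  over T1 ∈ [0.2, 5] s in 1 ms steps, restricted to its longest monotonic
  branch (Marques et al., NeuroImage 49:1271, 2010); out-of-range UNI is
  flagged, not fatal. The dictionary uses a vectorized mono-model walker
  (shared rotations across the T1 grid, Strang splitting with ≤ 10 µs
  substeps, exact affine steady-state solve) validated against the scalar
  simulator to ~1e−6.

## 4. Global fit, statistics, voxel replication

`GlobalMTFit` nests the entire simulate-and-fit pipeline of all methods in
one least-squares problem over θ ⊆ {m0s, T1f, T1s}, with T2f = 76.9 ms,
T2s = 12.5 µs and Rx fixed (13.6 s⁻¹, or 23.0 s⁻¹ under the historical
constraint T1s = T1f, following the convention of constrained fits).
Default optimizer: bounded trust-region least squares with finite
differences (relative step 1e−3; the objective is smooth at the inner-fit
convergence tolerance of ~1e−12); a bounded Nelder–Mead with jittered
restarts is available for rough objectives. Bounds: m0s ∈ [0, 0.5],
times ∈ [0.05, 10] s. Residuals are unweighted; a failed inner fit
contributes a fixed bounded penalty and is reported, not raised. Model
comparison uses the least-squares information criteria
`AIC = n·ln(RSS/n) + 2k`, `BIC = n·ln(RSS/n) + k·ln(n)` relative to the
mono-exponential baseline, with k = number of free global parameters
(mono 1, tied 2, free 3).

Spread statistics: inter-method coefficient of variation (sample sd/mean)
and the robust `mad_explained = 1 − MAD(residuals)/MAD(observed)` with MAD
the median absolute deviation from the median.

The voxelwise path synthesizes raw images from per-voxel parameter maps
(B1 factor scaling all flips, proton density scaling the signal; voxels
independent), re-runs the identical per-voxel mono fits, and summarizes ROI
medians (even counts average the central pair; failed voxels are masked out
and counted).

## 5. Synthetic data: what it shows and what it does not

`generate_roster` draws per-method observations as forward predictions at a
known truth plus i.i.d. Gaussian noise (default sd 0.02 s, ~2% of
white-matter T1), truncated positive; Gaussian noise is what the
least-squares estimator assumes, and a Student-t (3 df) mode exists to probe
outlier sensitivity. The default roster is the full 25-preset list and the
default truth the fitted white-matter set (m0s = 0.21, T1f = 2.06 s,
T1s = 0.26 s). `generate_qmt_maps` builds smooth (Gaussian-filtered,
±3 sd-truncated) parameter fields around reference quantitative-MT values
for white matter (m0s = 0.21, T1f = 1.84 s, T1s = 0.34 s), a blob-shaped
mask and a smooth ±10% B1 field on a 32×32 single-slice grid.

Passing recovery and model-selection tests on these rosters shows that the
nested estimator is consistent and that the information criteria rank the
models correctly *when the generating model is the generalized Bloch model
and the noise is well-behaved*. It does not validate the physics against
measured data, does not cover protocol misdocumentation (a dominant error
source for literature compilations), and the synthetic maps contain no
anatomy, no Rician noise floor and no B0-related artifacts.

Study sizes used by the shipped experiments: 100 replicate rosters
(25 methods each, noise 0.02 s) fitted with three models; the first 50
replicates form the recovery study. Observed outcomes (recomputed by the
test suite): mean recovery bias ≈ +1% (m0s), +2% (T1f), +1% (T1s), and the
AIC/BIC ordering "free T1s < tied T1s < mono" in 100/100 replicates.

## 6. The adiabatic-inversion quantity

`scripts/acceptance.py` reports `100·zs(end)/zs(0)` for the default HS1
pulse on the fitted white-matter set under the generalized Bloch model:
**−2.5%**. The pool is almost completely saturated (the classical
statement "less than 1% of the longitudinal magnetization remains" holds
for the signed value), but the residual is *inverted*: the near-magic-angle
orientations of the super-Lorentzian ensemble decay slowly enough to follow
the sweep adiabatically. The magnitude of the residual is 1.8–4% across
adiabaticity 5–40 and sweeps ±0.6–2.5 kHz, so it is a property of the
rotation-based model, not of the particular pulse; Graham's spectral model,
which cannot invert the pool by construction, leaves < 1% in magnitude.

## 7. Numerical conventions and limitations

* Units: seconds, rad/s for ω1, Hz for frequency offsets; degrees only at
  I/O boundaries. Rotation convention `dM/dt = M × ω`.
* Pulse timing is referenced to pulse centers (TI from inversion center to
  readout).
* Matrix exponentials via scipy's Padé implementation; steady states via
  direct affine solves (singular cycles raise).
* Inner fits are deterministic (fixed seed grids); CSV/JSON outputs use
  pinned float formatting, so identical configurations give bit-identical
  artifacts.
* Not modelled: Sled–Pike pulse-averaged dynamics (the spectral model
  stands in for the saturation-rate family), dipolar-order reservoirs,
   4-pool white matter, slice profiles, gradient/k-space effects, B0
  inhomogeneity, refocusing-train MT in RARE readouts (single-sample
  approximation), and vendor-exact adiabatic pulse shapes.
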