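# Methods

This note documents the models behind `epighost`, the calibration of its
synthetic fixtures, and the numerical choices a user should know before
trusting or extending the results.

## Acquisition model

A 2D EPI readout is a train of sign-alternating trapezoidal gradient
lobes, one per echo spacing, with instantaneous phase-encode blips at the
lobe transitions and prephasers modeled as ideal k-space offsets. Lobe
design fixes the duration to the echo spacing, runs the ramps at the slew
limit (quantized to the 1 μs internal grid), and minimizes the amplitude
subject to the prescribed kx area: the full lobe area equals N/FOV when
ramp sampling is on, the flat-top area alone when it is off. The ADC
covers the whole lobe (ramp sampling) or only the flat top, at the
protocol's dwell. All times are microseconds, gradients mT/m, k-space
cycles/mm with γ̄ = 42.577 kHz/mT; image grids are even-N with DC at
index N/2.

Echo time is referenced to the center sample of the DC line; the train
start is snapped to the 1 μs grid. GRAPPA undersampling acquires every
R-th line plus a contiguous block of ACS lines at the ky center, all
within one train.

The waveform model deliberately excludes oblique axes, concomitant
fields, gradient heating, and 3D/multiband encoding; blip shape is
irrelevant to the kx mechanism under study and is idealized.

## Imperfection model

The realized readout gradient is the demanded one plus a linear
time-invariant perturbation with three terms:

* **Eddy currents.** Each mode (a, τ) contributes
  `−a · (dG/dt ⊛ e^{−t/τ} u(t))`. On the piecewise-linear waveform the
  convolution obeys an exact one-pole recursion per 1 μs cell (evaluated
  with `scipy.signal.lfilter`), and its running integral — the
  trajectory error Δkx — is accumulated with the matching exact
  per-cell quadrature, so no integration error enters the k-space error.
  The default modes, a = 0.003 at τ = 70 μs and a = 0.002 at τ = 300 μs,
  span the short-term band (50–500 μs) that scanner tune-up procedures,
  which characterize constants from ~0.7 ms upward, leave uncorrected.
* **Resonant shim coupling.** Inductive coupling between the readout
  gradient and a high-order shim circuit is modeled as a complex
  Lorentzian notch of depth `coupling` in the gradient transfer
  function, `H(f) = 1 − c·[L(f−f0) + L(f+f0)]` with
  `L(x) = (w/2)/((w/2) + ix)`, applied by FFT with padding beyond the
  ring-down time. Hermitian symmetry keeps the perturbation real. The
  defaults f0 = 1100 Hz and width 150 Hz are the mechanical-resonance
  band of the emulated gradient set; whether the physical coupling is
  amplitude-like or purely oscillatory is not known from hardware — the
  notch (amplitude + phase) is a modeling choice.
* **Timing delay.** `delay_us` evaluates the nominal trajectory at
  t − δ, the classic global odd-even mismatch.

Linearity and time invariance are contract, not accident: the
perturbation — hence Δkx — flips sign exactly (bit-for-bit) under
readout polarity inversion. That antisymmetry is the entire basis of
dual-polarity mitigation and is asserted in the tests.

**Delay tune-up.** Production scanners null the global readout delay
during calibration, so artifact studies see only the *residue* of the
short-term terms. `presets.tuned(model, protocol)` emulates this by
adding the compensating delay that zeroes Δkx at the echo center of a
steady-state line. All artifact fixtures are used delay-compensated;
the uncompensated delay fixture exists separately to demonstrate what
the line-wise correction *can* fix.

**Calibration constants.** Mode amplitudes and the coupling depth are
simulation calibration constants, not measured values: the coupling
0.15 puts the single-polarity post-correction ghost-to-signal ratio of
the full fixture at ~3% (the few-to-ten-percent severity seen on
affected systems); the single fast mode (a = 0.05, τ = 70 μs) used by
the ramp-sampling factorial keeps its time constant well below the
flat-top duration of the no-ramp lobe, which is the premise of flat-top
sampling escaping corner errors. The thresholds asserted in the tests
(3× ramp dependence, 10× dual-polarity cancellation, 50×/5× correction
scopes) are likewise repo-calibrated constants implementing
directionally expected orderings; the directions, not the magnitudes,
are the scientific claims.

## Phantoms and forward model

The object is an analytic ellipse phantom (the classic head phantom,
scaled to 45% of the FOV so the FOV/2 ghost lands on background — the
same generous-FOV trick used in phantom/in-vivo ghost studies). Its
Fourier transform is closed-form (Bessel-J1 per ellipse), so samples are
evaluated at the *actual*, perturbed k-space points with no gridding in
the forward direction. An optional Gaussian edge profile multiplies the
spectrum by `exp(−2π²σ²|k|²)`.

Three forward paths share one contract:

* single uniform coil, no field map — the closed form directly;
* coils, no field map — a discrete source sum over the band-limited
  raster (inverse DFT of the analytic spectrum on a 4× oversampled
  grid). Because the object's support lies strictly inside the FOV, the
  trigonometric interpolation is exact and this path matches the closed
  form to ~1e−8; the y-axis is collapsed per line since kx couples only
  to x.
* field map — a per-line source sum with per-pixel off-resonance phase
  `exp(−i2πΔf t)`, restricted to the numerically nonzero support of the
  band-limited raster (edge-smoothed phantoms make it compact).

Ground truth is the band-limited image — the centered inverse DFT of the
analytic spectrum on the N×N grid — which isolates pipeline error from
Gibbs truncation of the sharp-edged phantom. The reconstruction never
shares a transform with the forward model (no inverse crime).

**Two phantom presets.** Desk-scale matrices put the spectral band
cutoff (structures of 5% FOV) at only ~40% of kmax, which creates a
tension a full-size matrix would not have: heavy edge smoothing (1
pixel, `default_phantom`) is needed to keep truncation ringing out of
the ghost-region floor for ghost-*ratio* fixtures, while band-*split*
fixtures need sharper edges (0.8 mm, `band_phantom`) so edge-ghost power
stays above the cutoff. Both are used where stated in the tests and the
acceptance script.

Coil sets are parameterized rings of Gaussian sensitivity profiles with
smooth random phases (seeded), sampled on whatever grid a path needs.
Field maps are second-order polynomials with peak 10 Hz ("good") or
150 Hz ("bad").

## Reconstruction

Each line is interpolated from its nominal kx coordinates onto the
uniform grid by complex cubic spline (a least-squares alternative was
considered and rejected as indistinguishable at these ADC densities).
The line-wise two-parameter correction is calibrated from a 3-line
blip-off reference: parity-averaged projections, magnitude-weighted
linear fit of the odd−even phase difference, half applied with opposite
signs per parity. GRAPPA uses a 2 (PE) × 5 (RO) kernel over all coils
with relative Tikhonov damping 1e−4, trained on the in-train ACS block;
acquired lines are reinserted verbatim. Coil combination is
root-sum-of-squares magnitude with the first coil's phase, keeping the
image complex so dual-polarity averaging after combination remains
meaningful (per-coil averaging before combination is equivalent in this
noiseless setting).

The **oracle reconstruction** solves each line's 1D non-uniform Fourier
system with the true per-sample kx (regularized normal equations,
λ_rel = 1e−9), then an inverse DFT along ky. It uses information a
standard reconstruction does not have and serves as the artifact-free
bound; it requires full ky sampling.

The **simplified dual-polarity GRAPPA** trains one shift-invariant
kernel (7 readout taps × all coils, Tikhonov 1e−4) on a 24-line center
block to map each negative-readout-direction line to its
positive-direction counterpart, then synthesizes a direction-consistent
k-space. The finite readout extent captures global odd-even mismatches
(a sub-sample shift is well approximated by a short interpolation
kernel) but not kx-localized errors — which is exactly the ordering the
tests assert against complex averaging. Its temporal-SNR behavior is
out of scope.

## Metrics

GSR = mean |image| in the ghost mask / mean |image| in the object mask;
object mask = raster support dilated by 2 pixels, ghost mask = object
mask circularly shifted by N/2 along phase-encode minus the object mask.
The band split integrates the 2D spectral energy of an artifact map
below/above the radial cutoff 1/(0.05·FOV) cycles/mm — the lower edge
of the reported 5–15%-of-FOV artifact-size range, so the whole range
falls in the low band — excluding DC from both bands. Artifact maps are
polarity-difference images, which cancel the common (polarity-even)
reconstruction error and double the ghost term.

## Experiment presets and problem sizes

The factorial suite runs five arms (no-ramp / ramp / ramp+GRAPPA R=3 /
bad-shim / dual-polarity averaging) at N = 128 by default; the
echo-spacing sweep covers 0.9–1.5 ms in 9 steps at N = 96 with per-esp
tune-up and correction, for shim-on, shim-off, and shim-on +
dual-polarity arms. The tests and the acceptance script run at N = 96
(N = 128 for the clean-identity check), which keeps the full suite
under a few minutes on one core while preserving every ordering; the
ramp-sampling fraction (0.78) and echo spacing (1.26 ms) match the
encoding-limited regime of submillimeter protocols, with gradient
limits rescaled for the smaller matrix.

The sweep's shim-on curve peaks at the grid point nearest to where the
readout's third harmonic crosses the resonance (3/(2·f0) ≈ 1.36 ms);
with the fixture's parameters the measured argmax is 1.425 ms, one grid
step away, because the correctability of the oscillatory residue also
varies with the phase relation between lobe and resonance — the peak
location, not its exact shape, is the robust feature.

## Numerical choices

* Internal waveform grid 1 μs; trapezoid breakpoints snapped to it, so
  trapezoid-rule integration of nominal lobes is exact.
* Eddy responses and their integrals use exact exponential recursions;
  trajectory errors are interpolated to ADC times with a cubic Hermite
  spline using the known derivative (error ≪ 1e−8 relative).
* Resonant responses use rfft/irfft with `next_fast_len` padding past
  the ring-down (5/(π·width) seconds).
* Degenerate inputs raise: infeasible lobes/TE, non-monotone regrid
  coordinates, empty masks, underdetermined GRAPPA/DPG fits, zero-
  gradient two-parameter fits (flat-top-only windows fall back to an
  offset-only fit since a delay is then unidentifiable).
* All randomness (noise, coil geometry) flows through explicit seeds;
  default fixture seed 20250402. Noiseless fixtures are bit-reproducible.

## Limitations

The generator emulates the *mechanism*, not a scanner: one 2D slice, no
T1 steady state, no motion or physiological noise, single-resonance LTI
coupling, polynomial field maps, and synthetic coil profiles. Passing
tests demonstrate internal consistency of the mechanism and the
directional behavior of the mitigation strategies under these
conditions; they do not certify artifact magnitudes on real hardware,
where gradient transfer functions contain multiple resonances and
thermal drift, and where dual-polarity averaging additionally interacts
with motion and physiological phase. The band-split discrimination
depends on the phantom's edge spectrum relative to the 5%-FOV cutoff,
which is matrix-size dependent at desk scale (hence the two phantom
presets).
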