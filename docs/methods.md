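# Methods

This note documents the models the package implements, the defaults and
their rationale, the numerical conventions, and what the synthetic fixtures
do and do not establish about real data.

## Signal model

The object is a per-slice tissue label map (background, white matter, gray
matter, CSF) with class-wise proton density, T2 and isotropic ADC
(defaults: WM 0.7e-3, GM 0.9e-3, CSF 3.0e-3 mm²/s; T2 80/95/2000 ms —
standard literature values for brain at 3T, configurable). The complex
object signal at echo time TE and diffusion weighting b is

```
S = PD · exp(−TE/T2) · exp(−b · ADC) · exp(i φ_bg)
```

with a smooth, slice-specific static background phase `φ_bg` (low-order
polynomial, ~0.6 rad scale). Diffusion is isotropic: direction affects only
the motion-phase statistics, not the magnitude. Receive coils are loop
elements on a ring (radius 0.55·FOV) with inverse-square-law magnitude in
3D distance and smooth random phase; loop centers are staggered along the
slice axis (two rows up to 8 channels, four rows above, spanning 80 mm) so
that simultaneously excited slices see measurably different channel
weightings — the physical requirement for slice separation.

## Acquisition model

k-space is acquired in `n_segments` contiguous bands along kx; every shot
also samples a navigator band (the central `1/n_segments` of kx — the
navigator's resolution is not standardised anywhere, so this default is a
configuration choice). Phase-encode lines are decimated by `R_PE`;
acquired-line counter `m` runs 0, 1, 2, … Per-line slice phases follow the
blipped-CAIPI scheme: slice j of a group receives `m · Δθ_j` with
`Δθ = (0, π)` for pairs (FOV/2 shift of the sampled FOV; FOV/4 of the full
FOV once GRAPPA has filled the skipped lines). Alternating blip polarity
means an off-isocenter group acquires a constant extra phase on odd lines
(`offset · blip moment`), which the reconstruction removes first. Nyquist
ghosts are modeled as a constant + linear phase over the readout samples of
odd echoes. Complex Gaussian noise of standard deviation `noise_sigma` is
added per channel and sample. All complex data are double precision; k-space
arrays are center-origin (DC at index N/2) with the unnormalized forward
DFT — one convention, used by every module through `fourier.py`.

Slice ordering is interleaved: group g contains anatomical slices
{g, g + n_groups, …}, so simultaneously excited slices sit half a stack
apart, as they do in practice; the 4-slice fixtures use 20 mm spacing,
placing aliasing partners 40 mm apart.

Reference scans (single-band, no CAIPI phase): per anatomical slice, one
fully sampled central segment (GRAPPA and slice-GRAPPA calibration) and one
non-phase-encoded echo train (ghost reference). Their cost is the
`2 · R_slice · TR` overhead the timing functions account for.

### Motion model

Shot-wise motion phase is constant + linear + quadratic (radial) in the
image domain, applied to one slice of the excited group before collapse.
Events hit diffusion-weighted shots only, with probability
`rate · (0.5 + susceptibility) · (0.5 + |d_z|)` (inferior slices and
superior–inferior diffusion encoding are worse, mirroring pulsatile brain
motion). The default event strength — linear ~0.6 rad/px, quadratic
~0.03 rad/px² — is chosen to represent a *systolic* event: the linear term
displaces the k-space peak by roughly a band width and the quadratic term
spreads it by several pixels, i.e. corruption that navigator phase removal
cannot fully undo. That is deliberate: shots with mild corruption are fixed
by the navigator correction, and reacquisition exists precisely for the
shots that are not fixable. Tests that need *correctable* corruption inject
explicit mild events (linear ~0.15 rad/px, quadratic ~0.004 rad/px²).

## Reconstruction

Stage order: isocenter offset removal → ghost correction → slice-GRAPPA →
in-plane GRAPPA → navigator phase correction → splicing → POCS → inverse
FFT → root-sum-of-squares combination.

* **Ghost correction** estimates the odd/even phase from accumulated
  odd·conj(even) echo cross-products of the non-phase-encoded reference
  (magnitude-weighted constant+linear fit; no unwrapping — ghost phases are
  small). It is applied to the collapsed data with a slice-group-averaged
  reference *before* kernel calibration, because the separation kernels are
  fit on ghost-corrected references. The simulated ghost is
  slice-independent, so per-slice re-correction after separation would be a
  no-op and is not implemented.
* **Slice-GRAPPA**: per excited slice, a 3×3 kernel (all channels → each
  output channel) on the acquired, undersampled grid, fit by
  trace-normalized ridge least squares (λ = 1e-4; λ = 0 requests plain
  least squares and falls back to ridge only on rank deficiency). The
  calibration collapse is synthesized from the single-band references with
  their CAIPI phases — no separately acquired collapsed calibration is
  needed. Kernels are fit to the *phased* targets and the known CAIPI
  phase is conjugated away after application, which makes the fit exact on
  calibration data. Boundary samples use zero-padded neighborhoods.
* **In-plane GRAPPA**: 2 source lines × 5 readout taps per channel
  (geometry configurable), calibrated on the fully sampled central-segment
  reference, applied per band; navigators share the undersampling and the
  same kernels.
* **Navigator correction** zero-pads the navigator to the segment grid,
  removes its image phase from the segment image per channel (magnitudes
  untouched), and transforms back. No smoothing or apodization is applied
  to the phase estimate. This full-phase removal has a known floor: the
  corrected band image is effectively rectified (|·|), and band
  re-extraction discards the energy that phase removal pushed out of the
  band — about 0.06–0.08 NRMSE on the fixtures here even with *no*
  corruption. The correction is therefore judged by the error *ratio*
  against the uncorrected splice (>2× on mild corruption), not by an
  absolute near-zero error.
* **POCS** fills the unacquired readout bands (readout partial Fourier,
  e.g. 6/7) by alternating a phase constraint — the phase of the largest
  symmetric central kx band — with data consistency on acquired columns;
  50 iterations or a 1e-9 relative-update stop. Splicing is band placement
  (bands are disjoint by construction; an overlap rule, averaging, exists
  but is unused). The spliced-then-filled order is used because the fill
  operates on the assembled kx grid; it is mathematically the same
  operation as filling before splicing since the bands do not overlap.
* **Reacquisition driver**: after each volume, shots are ranked by
  `W_x · central_weight(segment)` computed on the raw aliased navigators
  (no reconstruction — the "real time" constraint), the worst
  `ceil(fraction·N)` (default 20%) are re-issued to the simulator with a
  fresh motion draw, and replacements overwrite the originals. One round.
  The central weight is a Gaussian in segment distance (amplitude 2, width
  1 segment, floor 1); whether the scanner weights the score or the rank is
  not standardised, so the weighted-score form is a package decision, as is
  the root-sum-of-squares channel combination inside `Ω_x` (a
  per-channel-max variant is available).

## Theory module

`compute_t2prime` inverts `1/T2* = 1/T2 + 1/T2′` (infinite T2′ at
equality; T2* > T2 is rejected as unphysical). `effective_pe_resolution`
evaluates `Δy′ = Δy (3/T2 + 1/T2′) T_acq/π` literally, so `T_acq = 0`
yields 0. Because published blur figures depend on an unstated
echo-train-duration convention, `echo_train_duration` takes a mandatory
explicit convention — `full_train` (all acquired lines) or `post_center`
(ky = 0 to the end of the train) — and reports label which was used; the
package asserts only the rs-vs-ss *ordering* of predicted blur, which holds
under both conventions for every bundled matched-resolution pair. Times are
milliseconds internally; seconds appear only at interfaces (TR, scan
times), matching how acquisition tables mix units.

## Fixture sizes and statistical checks

Fixtures are sized for seconds-scale runs without changing the physics:
matrix 32–70, 2–4 slices, 8 channels, 3–7 segments. The standard SMS
fixture (matrix 64, 8 coils, 3 segments, R_PE = 2) uses
`noise_sigma = 0.28`, which yields a reconstructed white-matter image SNR
of ≈30 for the SMS arm. Motion-detection power is evaluated over 200
seeded runs.

The SMS vs single-band ADC comparison recovers WM ADC to well under 1%
agreement between arms. One caveat is documented rather than hidden: the
SMS arm's mean WM ADC sits ~0.5% above the single-band arm's, because
slice-GRAPPA leakage of bright CSF inflates the SMS b = 0 image slightly
while the diffusion-weighted CSF (attenuated e⁻³) contributes almost
nothing, shifting the log-ratio. At the power of a full synthetic WM mask
(thousands of voxels, CI half-width ~0.3%) this offset is statistically
detectable even though it is far below any practically relevant threshold —
an equivalence an in-vivo ROI comparison could not resolve. Split-slice-
GRAPPA would remove the leakage but is outside this package's scope.

## What the synthetic data do not show

The phantom has piecewise-constant tissue (no microstructural ADC
heterogeneity, no anisotropy — so no tensor fitting), no B0-induced
distortion or chemical shift (the echo-spacing benefit of readout
segmentation is represented in the theory module only), no ramp sampling
(the flow chart's regridding stage is a documented no-op), no T1
saturation, and coil profiles are idealized smooth fields. Passing tests
therefore establish the correctness and internal consistency of the
reconstruction operators under their stated models, not in-vivo image
quality.
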