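# rsepi-sms

Simulation and reconstruction of **simultaneous-multislice (SMS)
readout-segmented EPI (rs-EPI) diffusion MRI**, as a desk-scale, fully
testable Python library.

## The problem

Single-shot EPI, the workhorse of diffusion-weighted imaging, suffers
distortion and T2\* blurring that grow with resolution and field strength:
both scale with the echo spacing and the echo-train duration. rs-EPI fixes
this by splitting k-space into narrow bands along the readout axis and
acquiring one band per shot — short echo trains, low distortion — at the
cost of one TR per band. Slice acceleration wins that time back: multiband
RF pulses excite `R_slice` slices at once, and the collapsed signal is
separated in reconstruction using coil sensitivity information.

Multi-shot diffusion imaging adds its own complication: cardiac-driven
brain pulsation imprints a different nonlinear image phase on every shot.
Each shot therefore carries a low-resolution 2D **navigator** (a second
echo train through central k-space) used to (a) score motion corruption in
real time via the k-space **distribution width**

```
W_x = Σ_i Σ_ky Σ_kx |S_i(kx, ky)| · |kx − Ω_x|
```

(`Ω_x` = the kx column of peak channel-combined magnitude; the worst 20% of
shots are reacquired, weighted toward central segments), and (b) remove the
shot-wise phase in image space before the segments are spliced into one
k-space plane.

This package implements every stage as independently testable operations on
synthetic raw data:

* a **synthetic scanner**: digital multi-tissue brain phantoms, smooth
  complex multi-channel coils, readout segmentation with navigators,
  blipped-CAIPI per-line slice phases (`Δθ` difference of π between two
  simultaneously excited slices → FOV/2 shift of the sampled FOV, FOV/4 of
  the full FOV at `R_PE = 2`), off-isocenter constant phase, even/odd
  Nyquist-ghost phase, systole-like motion phase (constant + linear +
  quadratic), complex Gaussian noise, and single-band reference scans
  (costing `2·R_slice·TR`);
* the **reconstruction chain**: isocenter phase removal → ghost correction
  from the non-phase-encoded reference → slice-GRAPPA (3×3 k-space kernels
  fit to CAIPI-phased single-band references) → in-plane GRAPPA
  (`R_PE = 2`) → navigator phase correction → segment splicing → POCS
  readout partial-Fourier filling → root-sum-of-squares coil combination,
  plus the simulator-in-the-loop reacquisition driver;
* **diffusion contrasts**: trace-weighted images (geometric mean of three
  orthogonal b = 1000 s/mm² volumes) and ADC maps,
  `ADC = −ln(S_trw / S_b0) / b`, with ROI statistics and difference
  histograms;
* **closed-form theory**: `1/T2* = 1/T2 + 1/T2′` and the effective
  phase-encode resolution `Δy′ = Δy (3/T2 + 1/T2′) · T_acq / π`, evaluated
  over a bundled set of 3T/7T protocol definitions.

## Worked example

Closed-form theory for a bundled protocol:

```bash
$ rsepi-sms theory --protocol 3t_rs_trw_1.0 --convention full_train
{
  "protocol_name": "3t_rs_trw_1.0",
  "convention_label": "full_train",
  "nominal_pixel_mm": 1.0,
  "effective_pixel_mm": 0.5185064869410855,
  "t_acq_ms": 35.2,
  "echo_count": 110,
  "reference_overhead_s": 9.2,
  ...
}
```

110 acquired lines at 0.32 ms echo spacing give a 35.2 ms echo train; the
T2/T2′ filter width (0.52 mm) stays below the nominal 1 mm pixel, i.e. this
readout-segmented protocol is not blur-limited — and the single-band
reference scans cost `2 · R_slice · TR = 9.2 s`.

Simulate, reconstruct and map a two-slice SMS acquisition:

```python
import numpy as np
from rsepi_sms import *

phantom = generate_phantom(64, 2, seed=1)
coils = generate_coils(8, 64, phantom.slice_positions_mm, seed=2)
protocol = Protocol(name="demo_sms", matrix_read=64, matrix_pe=64,
                    fov_mm=(220.0, 220.0), n_segments=3, echo_spacing_ms=0.4,
                    r_slice=2, r_pe=2, tr_s=2.4, te_ms=70.0, n_slices=2,
                    slice_thickness_mm=5.0, n_directions=3)
sim = Simulator(phantom, coils, protocol, seed=11, noise_sigma=0.28)
dataset = sim.acquire()            # 12 shots: 3 segments x 1 group x 4 volumes
result = reconstruct(dataset)

dwi = DwiSet(b0=result.volumes[0], dwi=result.volumes[1:4])
adc = adc_map(result.volumes[0], trace_weighted(dwi))
mean, ci = roi_mean_adc(adc, phantom.label_map == 1)
print(mean, ci)
```

This prints a white-matter mean ADC of `7.096e-04` mm²/s with 95% CI
`(7.068e-04, 7.124e-04)` — recovering the phantom's configured WM
diffusivity of 0.7e-3 mm²/s to ~1% through the full collapsed-acquisition →
slice-GRAPPA → GRAPPA → navigator → splice pipeline (b = 0 magnitude NRMSE
vs ground truth ≈ 0.074 per slice at WM SNR ≈ 30).

The `rsepi-sms simulate / recon / maps` commands run the same chain from a
JSON config to HDF5 raw data, NIfTI volumes and a QC report (see
`rsepi-sms --help`).

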