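"""Synthetic SMS rs-EPI scanner.

Simulates raw multi-coil k-space for a readout-segmented EPI diffusion
acquisition with simultaneous-multislice (SMS) excitation:

* k-space is split into ``n_segments`` contiguous bands along the readout
  (kx) axis; each band is one shot, and every shot additionally samples a
  low-resolution central-kx "navigator" band as a second echo train;
* the ``r_slice`` slices of a slice group are collapsed after each receives
  its blipped-CAIPI per-line phase;
* shot-wise motion-induced phase (constant + linear + quadratic in the image
  domain, the signature of systolic brain pulsation) corrupts a configurable
  fraction of diffusion-weighted shots, preferentially in inferior slices
  and for diffusion encoding near the slice (superior-inferior) axis;
* even/odd echo inconsistency adds a Nyquist-ghost phase, and complex
  Gaussian noise is added per channel;
* single-band reference scans (a fully sampled central segment per slice for
  kernel calibration, and a non-phase-encoded echo train per slice for ghost
  correction) are produced alongside.

All complex data are double precision throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .caipi import CaipiScheme, make_fov_shift_scheme, slice_line_phase
from .fourier import fft2c
from .phantom import CoilProfileSet, Phantom, simulate_contrast
from .protocol import Protocol

__all__ = [
    "GhostModel", "MotionEvent", "MotionModel", "ShotRecord", "ReferenceData",
    "SimulatedDataset", "Simulator", "segment_bounds", "navigator_bounds",
    "acquired_ky", "slice_groups", "motion_phase_map", "simulate_shot",
    "multiband_pulse", "make_sinc_pulse",
]


# ---------------------------------------------------------------------------
# sampling geometry

def segment_bounds(matrix_read: int, n_segments: int) -> list[tuple[int, int]]:
    """Half-open kx column ranges of the readout segments (bands)."""
    edges = [round(i * matrix_read / n_segments) for i in range(n_segments + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n_segments)]


def center_segment_index(n_segments: int) -> int:
    return n_segments // 2


def navigator_bounds(matrix_read: int, n_segments: int,
                     nav_fraction: float | None = None) -> tuple[int, int]:
    """kx columns of the navigator band (central ``1/n_segments`` by default)."""
    if nav_fraction is None:
        return segment_bounds(matrix_read, n_segments)[center_segment_index(n_segments)]
    w = max(2, round(matrix_read * nav_fraction))
    lo = matrix_read // 2 - w // 2
    return lo, lo + w


def acquired_ky(protocol: Protocol) -> np.ndarray:
    """Full-grid phase-encode rows acquired per shot (R_PE decimation)."""
    if protocol.pf_pe != 1.0:
        raise NotImplementedError(
            "phase-encode partial Fourier is a theory-only parameter; "
            "the scanner simulates pf_pe = 1")
    return np.arange(0, protocol.matrix_pe, protocol.r_pe)


def slice_groups(protocol: Protocol) -> list[tuple[int, ...]]:
    """Interleaved grouping: group g holds slices {g, g + n_groups, ...}."""
    n_groups = protocol.n_slice_groups
    return [tuple(range(g, protocol.n_slices, n_groups)) for g in range(n_groups)]


# ---------------------------------------------------------------------------
# corruption models

@dataclass(frozen=True)
class GhostModel:
    """Even/odd echo phase inconsistency: odd echoes get a constant plus a
    linear phase across the readout samples (centered index)."""

    const_rad: float = 0.0
    linear_rad_per_sample: float = 0.0

    def phase(self, n_samples: int) -> np.ndarray:
        s = np.arange(n_samples) - (n_samples - 1) / 2.0
        return self.const_rad + self.linear_rad_per_sample * s


@dataclass(frozen=True)
class MotionEvent:
    """Image-domain phase applied to one slice of one shot."""

    shot_id: str
    slice_index: int                       # anatomical slice index
    constant_rad: float
    linear_rad_per_px: tuple[float, float]  # (y, x)
    quadratic_rad_per_px2: float

    def __post_init__(self):
        vals = (self.constant_rad, *self.linear_rad_per_px, self.quadratic_rad_per_px2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("motion phase coefficients must be finite")


def motion_phase_map(event: MotionEvent, ny: int, nx: int) -> np.ndarray:
    """Evaluate the constant + linear + quadratic (radial) phase surface."""
    y = (np.arange(ny) - (ny - 1) / 2.0)[:, None]
    x = (np.arange(nx) - (nx - 1) / 2.0)[None, :]
    ly, lx = event.linear_rad_per_px
    return (event.constant_rad + ly * y + lx * x
            + event.quadratic_rad_per_px2 * (y ** 2 + x ** 2))


@dataclass(frozen=True)
class MotionModel:
    """Stochastic systole model: events hit diffusion-weighted shots only.

    ``rate`` is the baseline per-shot event probability; it is modulated by
    the susceptibility of the group's most inferior slice and by the overlap
    of the diffusion direction with the slice (superior-inferior) axis.  The
    default event strength models a systolic event — strong enough that the
    shot's k-space energy is pushed beyond its readout band (linear term of
    order ``2*pi*band_width/matrix`` per pixel, quadratic spread of several
    pixels), i.e. corruption the navigator correction cannot fully undo,
    which is precisely what reacquisition exists for.  The quadratic term is
    what defeats purely linear corrections.
    """

    rate: float = 0.1
    linear_scale_rad_per_px: float = 0.6
    quad_scale_rad_per_px2: float = 0.03

    def event_probability(self, susceptibility: float,
                          direction: np.ndarray | None) -> float:
        w_slice = 0.5 + susceptibility
        dz = abs(direction[2]) if direction is not None else 0.5
        w_dir = 0.5 + dz
        return float(np.clip(self.rate * w_slice * w_dir, 0.0, 1.0))

    def draw_event(self, rng: np.random.Generator, shot_id: str,
                   slice_index: int) -> MotionEvent:
        ang = rng.uniform(0, 2 * np.pi)
        lmag = self.linear_scale_rad_per_px * rng.uniform(0.7, 1.3)
        quad = rng.choice([-1.0, 1.0]) * self.quad_scale_rad_per_px2 * rng.uniform(0.7, 1.3)
        return MotionEvent(
            shot_id=shot_id, slice_index=slice_index,
            constant_rad=rng.uniform(-np.pi, np.pi),
            linear_rad_per_px=(lmag * math.sin(ang), lmag * math.cos(ang)),
            quadratic_rad_per_px2=quad,
        )


# ---------------------------------------------------------------------------
# data records

@dataclass
class ShotRecord:
    """One excitation: a segment band plus its navigator band."""

    shot_id: str
    segment_index: int
    volume_index: int
    slice_group_index: int
    imaging_band: np.ndarray        # (nc, n_ky_acq, band_width) complex
    navigator_band: np.ndarray      # (nc, n_ky_acq, nav_width) complex
    kx_offset: int                  # band origin on the full kx grid
    nav_kx_offset: int
    corrupted: bool = False         # simulation truth, hidden from recon


@dataclass
class ReferenceData:
    """Single-band calibration scans (acquired without slice collapse)."""

    central_segments: np.ndarray    # (n_slices, nc, matrix_pe, center_width)
    phase_reference: np.ndarray     # (n_slices, nc, n_echo, matrix_read)
    center_kx_offset: int

    @property
    def n_slices(self) -> int:
        return self.central_segments.shape[0]


@dataclass
class SimulatedDataset:
    """Everything one acquisition produces, plus the hidden ground truth."""

    protocol: Protocol
    shots: dict[str, ShotRecord]
    reference: ReferenceData
    schemes: list[CaipiScheme]              # one per slice group
    groups: list[tuple[int, ...]]
    volumes: list[dict]                     # {'b': .., 'direction': ..}
    truth: dict                             # 'volumes' (nv, ns, ny, nx) magnitude, 'adc'
    ghost: GhostModel
    noise_sigma: float
    seed: int

    def shots_for_volume(self, v: int) -> list[ShotRecord]:
        return [s for s in self.shots.values() if s.volume_index == v]


# ---------------------------------------------------------------------------
# core shot physics

def _band_ghost(band: np.ndarray, ghost: GhostModel | None, sign: float = 1.0) -> np.ndarray:
    """Apply (or remove, sign=-1) the odd-line ghost phase to a band."""
    if ghost is None or (ghost.const_rad == 0 and ghost.linear_rad_per_sample == 0):
        return band
    out = band.copy()
    ph = np.exp(1j * sign * ghost.phase(band.shape[-1]))
    out[..., 1::2, :] *= ph
    return out


def simulate_shot(slice_images: np.ndarray, coil_sens: np.ndarray,
                  protocol: Protocol, scheme: CaipiScheme, segment_index: int,
                  *, motion_event: MotionEvent | None = None,
                  group_slices: tuple[int, ...] | None = None,
                  ghost: GhostModel | None = None, noise_sigma: float = 0.0,
                  rng: np.random.Generator | None = None,
                  shot_id: str = "", volume_index: int = 0,
                  slice_group_index: int = 0,
                  precomputed_kspace: np.ndarray | None = None) -> ShotRecord:
    """Simulate one SMS rs-EPI shot.

    *slice_images*: (r_slice, ny, nx) object signal of the excited group.
    *coil_sens*: (r_slice, nc, ny, nx) receive sensitivities per slice.
    Order of operations: motion phase (image domain, targeted slice) ->
    Fourier transform -> per-line CAIPI phase incl. off-isocenter offset ->
    slice summation -> band extraction (segment + navigator) -> even/odd
    ghost phase -> R_PE line decimation (implicit: only acquired lines are
    formed) -> additive complex Gaussian noise.
    """
    n_seg = protocol.n_segments
    if not 0 <= segment_index < n_seg:
        raise ValueError(f"segment_index={segment_index} out of range [0, {n_seg})")
    r_slice = slice_images.shape[0]
    ky_idx = acquired_ky(protocol)
    m = np.arange(ky_idx.size)
    if group_slices is None:
        group_slices = tuple(range(r_slice))

    collapsed = None
    corrupted = False
    for j in range(r_slice):
        if precomputed_kspace is not None and not (
                motion_event is not None
                and motion_event.slice_index == group_slices[j]):
            k_full = precomputed_kspace[j]
        else:
            img = slice_images[j][None, :, :] * coil_sens[j]
            if motion_event is not None and motion_event.slice_index == group_slices[j]:
                ny, nx = img.shape[-2:]
                img = img * np.exp(1j * motion_phase_map(motion_event, ny, nx))
                corrupted = True
            k_full = fft2c(img)
        k_acq = k_full[:, ky_idx, :]
        phases = slice_line_phase(scheme, j, m)
        k_acq = k_acq * np.exp(1j * phases)[None, :, None]
        collapsed = k_acq if collapsed is None else collapsed + k_acq

    lo, hi = segment_bounds(protocol.matrix_read, n_seg)[segment_index]
    nav_lo, nav_hi = navigator_bounds(protocol.matrix_read, n_seg)
    band = _band_ghost(collapsed[:, :, lo:hi], ghost)
    nav = _band_ghost(collapsed[:, :, nav_lo:nav_hi], ghost)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        band = band + noise_sigma * (rng.standard_normal(band.shape)
                                     + 1j * rng.standard_normal(band.shape))
        nav = nav + noise_sigma * (rng.standard_normal(nav.shape)
                                   + 1j * rng.standard_normal(nav.shape))
    return ShotRecord(shot_id=shot_id, segment_index=segment_index,
                      volume_index=volume_index,
                      slice_group_index=slice_group_index,
                      imaging_band=band, navigator_band=nav,
                      kx_offset=lo, nav_kx_offset=nav_lo, corrupted=corrupted)


# ---------------------------------------------------------------------------
# full-acquisition simulator

class Simulator:
    """Stateful synthetic scanner: can emit a full dataset and re-issue
    individual shots (fresh motion realization) for reacquisition."""

    def __init__(self, phantom: Phantom, coils: CoilProfileSet,
                 protocol: Protocol, *, motion_model: MotionModel | None = None,
                 ghost: GhostModel | None = None, noise_sigma: float = 0.0,
                 blip_moment_rad_per_mm: float = 0.0, seed: int = 0,
                 forced_events: dict | None = None):
        if phantom.n_slices != protocol.n_slices:
            raise ValueError("phantom slice count must match protocol")
        if coils.n_channels < protocol.r_slice * protocol.r_pe:
            import warnings
            warnings.warn("fewer channels than total acceleration; "
                          "unaliasing will be ill-conditioned")
        self.phantom = phantom
        self.coils = coils
        self.protocol = protocol
        self.motion_model = motion_model
        self.ghost = ghost
        self.noise_sigma = noise_sigma
        self.seed = seed
        # (v, g, seg) -> MotionEvent applied deterministically on attempt 0
        self.forced_events = forced_events or {}
        self.groups = slice_groups(protocol)
        self.schemes = []
        for g in self.groups:
            offsets = phantom.slice_positions_mm[list(g)]
            self.schemes.append(make_fov_shift_scheme(
                offsets, group_center_mm=float(np.mean(offsets)),
                blip_moment_rad_per_mm=blip_moment_rad_per_mm))
        self.volumes = self._volume_table()
        self._contrast = {}     # vol -> (n_slices, ny, nx) complex
        self._kspace = {}       # (vol, slice) -> (nc, ny, nx) complex

    def _volume_table(self) -> list[dict]:
        p = self.protocol
        dirs = np.eye(3)
        vols = [{"b": 0.0, "direction": None}]
        b_dw = max(p.b_values_s_per_mm2)
        for d in range(p.n_directions):
            vols.append({"b": b_dw, "direction": dirs[d % 3]})
        return vols

    def contrast(self, v: int) -> np.ndarray:
        if v not in self._contrast:
            vol = self.volumes[v]
            self._contrast[v] = simulate_contrast(
                self.phantom, vol["b"], vol["direction"], te_ms=self.protocol.te_ms)
        return self._contrast[v]

    def _slice_kspace(self, v: int, s: int) -> np.ndarray:
        key = (v, s)
        if key not in self._kspace:
            img = self.contrast(v)[s][None, :, :] * self.coils.for_slice(s)
            self._kspace[key] = fft2c(img)
        return self._kspace[key]

    def _shot_rng(self, v: int, g: int, seg: int, attempt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, v, g, seg, attempt])

    def shot(self, v: int, g: int, seg: int, *, attempt: int = 0,
             motion: str | MotionEvent | None = "auto") -> ShotRecord:
        """Simulate (or re-simulate, with a new ``attempt``) one shot.

        ``motion="auto"`` draws from the motion model; ``None`` disables
        motion; an explicit :class:`MotionEvent` is applied as given.
        """
        rng = self._shot_rng(v, g, seg, attempt)
        gslices = self.groups[g]
        shot_id = f"v{v:03d}_g{g:02d}_s{seg:02d}"
        event = None
        if isinstance(motion, MotionEvent):
            event = motion
        elif motion == "auto" and attempt == 0 and (v, g, seg) in self.forced_events:
            event = self.forced_events[(v, g, seg)]
        elif motion == "auto" and self.motion_model is not None \
                and self.volumes[v]["b"] > 0:
            target = gslices[int(np.argmax(
                self.phantom.motion_susceptibility[list(gslices)]))]
            p = self.motion_model.event_probability(
                float(self.phantom.motion_susceptibility[target]),
                self.volumes[v]["direction"])
            if rng.uniform() < p:
                event = self.motion_model.draw_event(rng, shot_id, target)
        imgs = self.contrast(v)[list(gslices)]
        sens = np.stack([self.coils.for_slice(s) for s in gslices])
        pre = np.stack([self._slice_kspace(v, s) for s in gslices])
        return simulate_shot(imgs, sens, self.protocol, self.schemes[g], seg,
                             motion_event=event, group_slices=gslices,
                             ghost=self.ghost, noise_sigma=self.noise_sigma,
                             rng=rng, shot_id=shot_id, volume_index=v,
                             slice_group_index=g,
                             precomputed_kspace=pre)

    def reference_data(self) -> ReferenceData:
        """Single-band reference scans: one fully sampled central segment and
        one non-phase-encoded echo train per anatomical slice."""
        p = self.protocol
        lo, hi = segment_bounds(p.matrix_read, p.n_segments)[
            center_segment_index(p.n_segments)]
        n_echo = 16
        cs = np.zeros((p.n_slices, self.coils.n_channels, p.matrix_pe, hi - lo),
                      dtype=complex)
        pr = np.zeros((p.n_slices, self.coils.n_channels, n_echo, p.matrix_read),
                      dtype=complex)
        rng = np.random.default_rng([self.seed, 10_000_019])
        for s in range(p.n_slices):
            k_full = self._slice_kspace(0, s)
            seg = _band_ghost(k_full[:, :, lo:hi], self.ghost)
            dc_line = k_full[:, p.matrix_pe // 2, :]
            echoes = np.repeat(dc_line[:, None, :], n_echo, axis=1)
            echoes = _band_ghost(echoes, self.ghost)
            if self.noise_sigma > 0:
                seg = seg + self.noise_sigma * (rng.standard_normal(seg.shape)
                                                + 1j * rng.standard_normal(seg.shape))
                echoes = echoes + self.noise_sigma * (
                    rng.standard_normal(echoes.shape)
                    + 1j * rng.standard_normal(echoes.shape))
            cs[s] = seg
            pr[s] = echoes
        return ReferenceData(central_segments=cs, phase_reference=pr,
                             center_kx_offset=lo)

    def truth(self) -> dict:
        p = self.protocol
        vols = np.zeros((len(self.volumes), p.n_slices, p.matrix_pe, p.matrix_read))
        for v in range(len(self.volumes)):
            con = self.contrast(v)
            for s in range(p.n_slices):
                img = con[s][None, :, :] * self.coils.for_slice(s)
                vols[v, s] = np.sqrt((np.abs(img) ** 2).sum(axis=0))
            # coil-free object magnitude is also useful for contrast checks
        return {
            "volumes": vols,
            "adc": self.phantom.class_map("adc_mm2_per_s"),
            "b_values": [vol["b"] for vol in self.volumes],
            "directions": [None if vol["direction"] is None
                           else vol["direction"].tolist() for vol in self.volumes],
        }

    def acquire(self) -> SimulatedDataset:
        """Emit all shots for all volumes / slice groups / acquired segments."""
        p = self.protocol
        shots = {}
        for v in range(len(self.volumes)):
            for g in range(len(self.groups)):
                for seg in range(p.n_segments_acquired):
                    rec = self.shot(v, g, seg)
                    shots[rec.shot_id] = rec
        return SimulatedDataset(
            protocol=p, shots=shots, reference=self.reference_data(),
            schemes=self.schemes, groups=self.groups, volumes=self.volumes,
            truth=self.truth(), ghost=self.ghost or GhostModel(),
            noise_sigma=self.noise_sigma, seed=self.seed)


# ---------------------------------------------------------------------------
# multiband RF

def make_sinc_pulse(n_samples: int = 256, n_lobes: int = 3,
                    duration_ms: float = 2.56) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed sinc pulse; returns (t_ms centered at 0, samples)."""
    t = (np.arange(n_samples) / (n_samples - 1) - 0.5) * duration_ms
    x = 2 * n_lobes * t / duration_ms
    wave = np.sinc(x) * np.hanning(n_samples)
    return t, wave


def multiband_pulse(slice_offsets_mm, base_pulse: tuple[np.ndarray, np.ndarray],
                    grad_khz_per_mm: float = 1.0) -> tuple[np.ndarray, float]:
    """Sum of frequency-modulated copies of a base pulse, one per slice.

    Each copy is modulated to the frequency of its slice position under the
    slice-select gradient.  Returns the complex waveform and its peak
    magnitude; because the copies all peak at t = 0, the peak amplitude
    scales linearly with the number of excited slices.
    """
    t_ms, wave = base_pulse
    offsets = np.atleast_1d(np.asarray(slice_offsets_mm, dtype=float))
    out = np.zeros(wave.shape, dtype=complex)
    for z in offsets:
        f_khz = grad_khz_per_mm * z
        out += wave * np.exp(2j * np.pi * f_khz * t_ms)
    return out, float(np.max(np.abs(out)))
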