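"""Full reconstruction pipeline and the reacquisition driver.

Stage order (the default path): off-isocenter constant-phase removal ->
Nyquist ghost correction -> slice-GRAPPA separation -> in-plane GRAPPA ->
2D navigator phase correction -> segment splicing -> POCS partial-Fourier
filling -> inverse FFT -> root-sum-of-squares coil combination.  Ghost
correction is applied to the collapsed data with a slice-group-averaged
phase reference *before* kernel fitting/application, because the separation
kernels are themselves calibrated on ghost-corrected references.

Reacquisition happens before reconstruction: after each volume's shots, the
distribution widths of the raw aliased navigators rank the shots, the worst
fraction is re-issued to the simulator (one round), and the replacements
overwrite the originals outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .caipi import remove_isocenter_offset
from .fourier import fft2c, ifft2c
from .grappa import (InplaneKernelSet, SliceKernelSet, apply_inplane_kernels,
                     apply_slice_kernels, fit_inplane_kernels, fit_slice_kernels)
from .navigator import (ReacqPolicy, distribution_width,
                        navigator_phase_correct, select_reacquisitions)
from .scanner import GhostModel, SimulatedDataset, Simulator, segment_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "ReconConfig", "ReconResult", "estimate_ghost", "ghost_correct",
    "pocs_readout_pf", "splice_segments", "coil_combine", "reconstruct",
    "reacquisition_driver",
]


# ---------------------------------------------------------------------------
# Nyquist ghost correction

def estimate_ghost(phase_reference: np.ndarray,
                   fit_order: str = "constant+linear") -> GhostModel:
    """Estimate the even/odd echo phase difference from a non-phase-encoded
    reference echo train (nc, n_echo, n_kx).

    Consecutive odd/even echo pairs are cross-correlated per readout sample;
    the phase of the accumulated cross-product is fit (magnitude-weighted)
    with a constant or constant+linear model in the centered sample index.
    """
    if fit_order not in ("constant", "constant+linear"):
        raise ValueError(f"unknown ghost_fit_order {fit_order!r}")
    ref = np.asarray(phase_reference)
    if ref.ndim == 2:
        ref = ref[None]
    nc, ne, w = ref.shape
    if ne < 2:
        raise ValueError("need at least two echoes to estimate ghost phase")
    cross = (ref[:, 1::2, :][:, : (ne // 2), :]
             * np.conj(ref[:, 0::2, :][:, : (ne // 2), :])).sum(axis=(0, 1))
    weights = np.abs(cross)
    if not np.any(weights > 0):
        return GhostModel()
    ang = np.angle(cross)
    s = np.arange(w) - (w - 1) / 2.0
    if fit_order == "constant":
        g0 = float(np.angle((cross).sum()))
        return GhostModel(const_rad=g0)
    # weighted linear fit of ang vs s (ghost phases are small; no unwrap)
    wsum = weights.sum()
    sm = (weights * s).sum() / wsum
    am = (weights * ang).sum() / wsum
    denom = (weights * (s - sm) ** 2).sum()
    g1 = float((weights * (s - sm) * (ang - am)).sum() / denom) if denom > 0 else 0.0
    g0 = float(am - g1 * sm)
    return GhostModel(const_rad=g0, linear_rad_per_sample=g1)


def ghost_correct(band: np.ndarray, ghost: GhostModel) -> np.ndarray:
    """Remove the estimated odd-echo phase from a band (odd acquired lines)."""
    out = np.asarray(band).copy()
    out[..., 1::2, :] *= np.exp(-1j * ghost.phase(band.shape[-1]))
    return out


# ---------------------------------------------------------------------------
# POCS readout partial Fourier

def pocs_readout_pf(kspace: np.ndarray, acquired_cols: np.ndarray, *,
                    n_iterations: int = 50, tolerance: float = 1e-9
                    ) -> tuple[np.ndarray, list[float]]:
    """Fill unacquired readout (kx) columns by phase-constrained projection.

    *kspace*: (..., n_ky, n_kx) zero-filled full grid; *acquired_cols*:
    boolean mask over kx.  The low-resolution phase estimate comes from the
    largest symmetric central band inside the acquired region; iterations
    alternate between enforcing that image phase and restoring the acquired
    samples, stopping at ``n_iterations`` or when the relative update norm
    drops below ``tolerance``.  Returns the filled k-space and the update
    norm trace.
    """
    acquired_cols = np.asarray(acquired_cols, dtype=bool)
    n_kx = kspace.shape[-1]
    if acquired_cols.shape != (n_kx,):
        raise ValueError("acquired_cols must be a kx-length boolean mask")
    if acquired_cols.all():
        return kspace.copy(), []
    c = n_kx // 2
    idx = np.flatnonzero(acquired_cols)
    lo, hi = idx.min(), idx.max()
    half = min(c - lo, hi - c)
    if half <= 0 or not acquired_cols[c]:
        raise ValueError("acquired region leaves no symmetric central band; "
                         "readout partial Fourier must exceed 1/2")
    sym = np.zeros(n_kx, dtype=bool)
    sym[c - half:c + half + 1] = True
    low = np.where(sym, kspace, 0.0)
    phase = np.exp(1j * np.angle(ifft2c(low)))
    k0 = kspace
    k = kspace.copy()
    norms: list[float] = []
    ref_norm = float(np.linalg.norm(k0))
    for _ in range(n_iterations):
        img = ifft2c(k)
        img = np.real(img * np.conj(phase)) * phase
        k_new = fft2c(img)
        k_new[..., acquired_cols] = k0[..., acquired_cols]
        upd = float(np.linalg.norm(k_new - k) / (ref_norm + 1e-30))
        norms.append(upd)
        k = k_new
        if upd < tolerance:
            break
    return k, norms


# ---------------------------------------------------------------------------
# splicing & combination

def splice_segments(segments: dict[int, np.ndarray], matrix_read: int,
                    n_segments: int, required: list[int] | None = None
                    ) -> np.ndarray:
    """Place per-segment bands at their kx offsets to form full k-space.

    *segments* maps segment index -> (nc, n_ky, band_width).  Bands are
    non-overlapping by construction, so splicing is placement; an averaging
    rule (mean) would apply to overlaps but is unused by the default
    geometry.  Missing required segments are a hard error listing them.
    """
    bounds = segment_bounds(matrix_read, n_segments)
    if required is None:
        required = list(range(n_segments))
    missing = [i for i in required if i not in segments]
    if missing:
        raise ValueError(f"missing segments {missing}; cannot splice")
    first = next(iter(segments.values()))
    out = np.zeros(first.shape[:-1] + (matrix_read,), dtype=complex)
    count = np.zeros(matrix_read)
    for i in sorted(segments):
        lo, hi = bounds[i]
        if segments[i].shape[-1] != hi - lo:
            raise ValueError(f"segment {i} width {segments[i].shape[-1]} != "
                             f"band width {hi - lo}")
        out[..., lo:hi] += segments[i]
        count[lo:hi] += 1
    np.divide(out, count, where=count > 0, out=out)
    return out


def coil_combine(images: np.ndarray, axis: int = 0) -> np.ndarray:
    """Root-sum-of-squares magnitude combination over the channel axis."""
    return np.sqrt((np.abs(images) ** 2).sum(axis=axis))


# ---------------------------------------------------------------------------
# configuration / result containers

@dataclass
class ReconConfig:
    """Toggles and numerical settings; the defaults run the full path."""

    pocs_iterations: int = 50
    pocs_tolerance: float = 1e-9
    reacq_policy: ReacqPolicy = field(default_factory=ReacqPolicy)
    ghost_fit_order: str = "constant+linear"
    do_ghost_correction: bool = True
    do_navigator_correction: bool = True
    do_pocs: bool = True
    pocs_before_navigator: bool = False   # ablation: degrade on corrupted data
    lam_slice: float = 1e-4
    lam_inplane: float = 1e-4
    keep_intermediates: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.pocs_iterations < 1:
            raise ValueError("pocs_iterations must be positive")
        if self.pocs_tolerance <= 0:
            raise ValueError("pocs_tolerance must be positive")


@dataclass
class ReconResult:
    """Magnitude volumes plus per-shot QC."""

    volumes: np.ndarray                 # (n_volumes, n_slices, ny, nx), >= 0
    qc: list[dict]
    slice_kernels: list[SliceKernelSet] | None = None
    inplane_kernels: list[InplaneKernelSet] | None = None
    intermediates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# full reconstruction

def _group_ghost(models: list[GhostModel]) -> GhostModel:
    return GhostModel(
        const_rad=float(np.mean([m.const_rad for m in models])),
        linear_rad_per_sample=float(np.mean([m.linear_rad_per_sample for m in models])))


def reconstruct(dataset: SimulatedDataset | str, config: ReconConfig | None = None
                ) -> ReconResult:
    """Run the full reconstruction on a raw dataset (object or HDF5 path)."""
    if isinstance(dataset, str):
        from .io import read_raw
        dataset = read_raw(dataset)
    cfg = config or ReconConfig()
    ds = dataset
    p = ds.protocol
    n_vol = len(ds.volumes)
    ny, nx = p.matrix_pe, p.matrix_read
    bounds = segment_bounds(nx, p.n_segments)
    acq_segments = list(range(p.n_segments_acquired))
    acquired_cols = np.zeros(nx, dtype=bool)
    for i in acq_segments:
        lo, hi = bounds[i]
        acquired_cols[lo:hi] = True

    # --- calibration ---------------------------------------------------
    ghost_per_slice = [estimate_ghost(ds.reference.phase_reference[s],
                                      cfg.ghost_fit_order)
                       if cfg.do_ghost_correction else GhostModel()
                       for s in range(p.n_slices)]
    ref_corr = np.stack([
        ghost_correct(ds.reference.central_segments[s], ghost_per_slice[s])
        if cfg.do_ghost_correction else ds.reference.central_segments[s]
        for s in range(p.n_slices)])

    slice_kernels: list[SliceKernelSet | None] = []
    for g, gslices in enumerate(ds.groups):
        if p.r_slice > 1:
            slice_kernels.append(fit_slice_kernels(
                ref_corr[list(gslices)], ds.schemes[g], r_pe=p.r_pe,
                lam=cfg.lam_slice))
        else:
            slice_kernels.append(None)
    inplane_kernels = [fit_inplane_kernels(ref_corr[s], p.r_pe, lam=cfg.lam_inplane)
                       for s in range(p.n_slices)]

    # --- per-shot processing -------------------------------------------
    volumes = np.zeros((n_vol, p.n_slices, ny, nx))
    qc: list[dict] = []
    intermediates: dict = {}
    for v in range(n_vol):
        # (slice -> segment -> full-grid corrected k-space)
        seg_store: dict[int, dict[int, np.ndarray]] = {s: {} for s in range(p.n_slices)}
        nav_store: dict[int, dict[int, np.ndarray]] = {s: {} for s in range(p.n_slices)}
        for g, gslices in enumerate(ds.groups):
            scheme = ds.schemes[g]
            gghost = _group_ghost([ghost_per_slice[s] for s in gslices])
            for seg in acq_segments:
                shot_id = f"v{v:03d}_g{g:02d}_s{seg:02d}"
                if shot_id not in ds.shots:
                    raise ValueError(f"raw data incomplete: shot {shot_id} missing")
                shot = ds.shots[shot_id]
                wrep = distribution_width(shot.navigator_band, shot_id=shot_id,
                                          segment_index=seg)
                qc.append({"shot_id": shot_id, "volume": v, "group": g,
                           "segment": seg, "w_x": wrep.w_x,
                           "omega_x": wrep.omega_x, "reacquired": False})
                band = remove_isocenter_offset(shot.imaging_band, scheme)
                nav = remove_isocenter_offset(shot.navigator_band, scheme)
                if cfg.do_ghost_correction:
                    band = ghost_correct(band, gghost)
                    nav = ghost_correct(nav, gghost)
                if p.r_slice > 1:
                    sep_band = apply_slice_kernels(band, slice_kernels[g])
                    sep_nav = apply_slice_kernels(nav, slice_kernels[g])
                else:
                    sep_band, sep_nav = band[None], nav[None]
                for jj, s in enumerate(gslices):
                    full_band = apply_inplane_kernels(sep_band[jj],
                                                      inplane_kernels[s],
                                                      full_ky=ny)
                    full_nav = apply_inplane_kernels(sep_nav[jj],
                                                     inplane_kernels[s],
                                                     full_ky=ny)
                    lo, hi = bounds[seg]
                    grid = np.zeros((full_band.shape[0], ny, nx), dtype=complex)
                    grid[..., lo:hi] = full_band
                    if cfg.do_navigator_correction and not cfg.pocs_before_navigator:
                        grid = navigator_phase_correct(
                            grid, full_nav, nav_kx_offset=shot.nav_kx_offset)
                    seg_store[s][seg] = grid[..., lo:hi]
                    nav_store[s][seg] = full_nav
        for s in range(p.n_slices):
            spliced = splice_segments(seg_store[s], nx, p.n_segments,
                                      required=acq_segments)
            if cfg.do_pocs and not acquired_cols.all():
                spliced, _ = pocs_readout_pf(spliced, acquired_cols,
                                             n_iterations=cfg.pocs_iterations,
                                             tolerance=cfg.pocs_tolerance)
            if cfg.pocs_before_navigator and cfg.do_navigator_correction:
                # ablation path: navigator phases are removed only after the
                # partial-Fourier fill has already mixed inconsistent shots
                for seg in acq_segments:
                    lo, hi = bounds[seg]
                    grid = np.zeros_like(spliced)
                    grid[..., lo:hi] = spliced[..., lo:hi]
                    grid = navigator_phase_correct(
                        grid, nav_store[s][seg],
                        nav_kx_offset=navigator_offset(p))
                    spliced[..., lo:hi] = grid[..., lo:hi]
            volumes[v, s] = coil_combine(ifft2c(spliced))
            if cfg.keep_intermediates:
                intermediates[(v, s)] = spliced
    return ReconResult(volumes=volumes, qc=qc, slice_kernels=slice_kernels,
                       inplane_kernels=inplane_kernels,
                       intermediates=intermediates)


def navigator_offset(p) -> int:
    from .scanner import navigator_bounds
    return navigator_bounds(p.matrix_read, p.n_segments)[0]


# ---------------------------------------------------------------------------
# reacquisition driver

def reacquisition_driver(simulator: Simulator, config: ReconConfig | None = None
                         ) -> tuple[SimulatedDataset, list[dict]]:
    """Acquire, rank shots by raw-navigator width per volume, reacquire the
    worst fraction (single round), and return the final shot set + QC table.
    """
    cfg = config or ReconConfig()
    ds = simulator.acquire()
    p = ds.protocol
    qc: list[dict] = []
    for v in range(len(ds.volumes)):
        shots_v = ds.shots_for_volume(v)
        reports = [distribution_width(s.navigator_band, shot_id=s.shot_id,
                                      segment_index=s.segment_index)
                   for s in shots_v]
        selected = select_reacquisitions(reports, cfg.reacq_policy, p.n_segments)
        for rep in reports:
            qc.append({"shot_id": rep.shot_id, "volume": v,
                       "w_x": rep.w_x, "omega_x": rep.omega_x,
                       "weighted_score": rep.weighted_score, "rank": rep.rank,
                       "reacquired": rep.shot_id in selected})
        for shot_id in selected:
            old = ds.shots[shot_id]
            new = simulator.shot(old.volume_index, old.slice_group_index,
                                 old.segment_index, attempt=1)
            ds.shots[shot_id] = new
    return ds, qc
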