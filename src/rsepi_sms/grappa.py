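"""k-space unaliasing: slice-GRAPPA and in-plane GRAPPA.

Slice-GRAPPA separates the collapsed multi-slice data: for each excited
slice, a 3x3 k-space kernel per output channel maps every channel's local
neighborhood of the collapsed data to that slice's sample.  Kernels are fit
on calibration data in which the collapse is *synthesized* from the
single-band reference segments with their blipped-CAIPI line phases applied,
so no separately acquired collapsed calibration is needed.  The fitted
kernels reproduce the phased (apparently shifted) slices; the known CAIPI
phase is then removed analytically.

In-plane GRAPPA synthesizes the skipped phase-encode lines from acquired
neighbors (default geometry: 2 source lines x 5 readout taps per channel),
calibrated on the fully sampled single-band central segment.

Both fits are ridge-regularized least squares with a trace-normalized
regularizer; ``lam=0`` requests a plain least-squares fit and falls back to
ridge only if the problem is rank-deficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .caipi import CaipiScheme, caipi_line_phase

logger = logging.getLogger(__name__)

__all__ = [
    "SliceKernelSet", "InplaneKernelSet",
    "fit_slice_kernels", "apply_slice_kernels",
    "fit_inplane_kernels", "apply_inplane_kernels", "fit_apply_inplane_grappa",
]

_RIDGE_FALLBACK = 1e-8


def _solve(a: np.ndarray, b: np.ndarray, lam: float) -> tuple[np.ndarray, float, float]:
    """Least-squares / ridge solve; returns (weights, residual_norm, lam_used)."""
    if lam == 0.0:
        w, res, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank < a.shape[1]:
            logger.warning("rank-deficient fit (rank %d < %d); falling back to "
                           "ridge lam=%g", rank, a.shape[1], _RIDGE_FALLBACK)
            return _solve(a, b, _RIDGE_FALLBACK)
        rnorm = float(np.linalg.norm(a @ w - b))
        return w, rnorm, 0.0
    ah = a.conj().T
    gram = ah @ a
    lam_eff = lam * np.trace(gram).real / a.shape[1]
    w = np.linalg.solve(gram + lam_eff * np.eye(a.shape[1]), ah @ b)
    return w, float(np.linalg.norm(a @ w - b)), lam_eff


def _neighborhoods_3x3(data: np.ndarray) -> np.ndarray:
    """(nc, nky, nkx) -> (nky*nkx, nc*9) zero-padded 3x3 neighborhoods."""
    nc, nky, nkx = data.shape
    padded = np.pad(data, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(padded, (3, 3), axis=(1, 2))   # (nc, nky, nkx, 3, 3)
    return win.transpose(1, 2, 0, 3, 4).reshape(nky * nkx, nc * 9)


@dataclass
class SliceKernelSet:
    """Fitted slice-separation weights for one simultaneously excited group."""

    weights: np.ndarray            # (r_slice, nc*9, nc)
    scheme: CaipiScheme
    residual_norms: tuple[float, ...]
    lam_used: float

    @property
    def r_slice(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]


def fit_slice_kernels(ref_segments: np.ndarray, scheme: CaipiScheme,
                      r_pe: int = 1, lam: float = 1e-4) -> SliceKernelSet:
    """Fit 3x3 slice-separation kernels from single-band reference segments.

    *ref_segments*: (r_slice, nc, full_ky, width) Nyquist-phase-corrected
    single-band central segments of the group's slices, fully sampled in ky.
    The calibration collapse is synthesized by decimating to the acquired
    lines (every ``r_pe``-th), applying each slice's CAIPI line phase, and
    summing.
    """
    r_slice, nc, full_ky, width = ref_segments.shape
    ky_idx = np.arange(0, full_ky, r_pe)
    m = np.arange(ky_idx.size)
    targets = []
    for j in range(r_slice):
        ph = np.exp(1j * caipi_line_phase(scheme, j, m))
        targets.append(ref_segments[j][:, ky_idx, :] * ph[None, :, None])
    collapsed = np.sum(targets, axis=0)
    a = _neighborhoods_3x3(collapsed)
    weights = np.zeros((r_slice, nc * 9, nc), dtype=complex)
    residuals = []
    lam_used = lam
    for j in range(r_slice):
        b = targets[j].transpose(1, 2, 0).reshape(-1, nc)
        w, rnorm, lam_used = _solve(a, b, lam)
        weights[j] = w
        residuals.append(rnorm)
    return SliceKernelSet(weights=weights, scheme=scheme,
                          residual_norms=tuple(residuals), lam_used=lam_used)


def apply_slice_kernels(collapsed: np.ndarray, kernels: SliceKernelSet,
                        remove_caipi_phase: bool = True) -> np.ndarray:
    """Separate collapsed band data into per-slice estimates.

    *collapsed*: (nc, n_ky_acq, width); returns (r_slice, nc, n_ky_acq,
    width).  Boundary samples use zero-padded neighborhoods.  With
    ``remove_caipi_phase`` the known per-line CAIPI phase is conjugated away
    so each slice comes back unshifted.
    """
    nc, nky, nkx = collapsed.shape
    if nc != kernels.n_channels:
        raise ValueError(f"channel mismatch: data {nc}, kernels {kernels.n_channels}")
    a = _neighborhoods_3x3(collapsed)
    m = np.arange(nky)
    out = np.zeros((kernels.r_slice, nc, nky, nkx), dtype=complex)
    for j in range(kernels.r_slice):
        est = (a @ kernels.weights[j]).reshape(nky, nkx, nc).transpose(2, 0, 1)
        if remove_caipi_phase:
            est = est * np.exp(-1j * caipi_line_phase(kernels.scheme, j, m))[None, :, None]
        out[j] = est
    return out


@dataclass
class InplaneKernelSet:
    """GRAPPA weights mapping acquired-line neighborhoods to skipped lines."""

    weights: dict                   # offset d -> (nc*n_src*n_taps, nc)
    r_pe: int
    n_src_lines: int
    n_kx_taps: int
    lam_used: float

    @property
    def n_channels(self) -> int:
        first = next(iter(self.weights.values()))
        return first.shape[1]


def _source_windows(data: np.ndarray, n_src: int, n_taps: int) -> np.ndarray:
    """(nc, n_acq, w) -> (n_acq, w, nc*n_src*n_taps) source matrices.

    Block q pairs acquired lines q .. q+n_src-1 (zero-padded past the end)
    with ``n_taps`` zero-padded readout taps.
    """
    nc, n_acq, w = data.shape
    pad = n_taps // 2
    padded = np.pad(data, ((0, 0), (0, n_src - 1), (pad, pad)))
    stacked = np.stack([padded[:, q:q + n_acq, :] for q in range(n_src)], axis=2)
    win = sliding_window_view(stacked, n_taps, axis=3)  # (nc, n_acq, n_src, w, n_taps)
    return win.transpose(1, 3, 0, 2, 4).reshape(n_acq, w, nc * n_src * n_taps)


def fit_inplane_kernels(acs: np.ndarray, r_pe: int, *, n_src_lines: int = 2,
                        n_kx_taps: int = 5, lam: float = 1e-4) -> InplaneKernelSet:
    """Calibrate GRAPPA weights on a fully sampled ACS block.

    *acs*: (nc, n_acs_ky, width) with consecutive ky lines.  Requires at
    least ``3 * r_pe`` ACS lines.
    """
    nc, n_acs, width = acs.shape
    if n_acs < 3 * r_pe:
        raise ValueError(f"ACS too small: {n_acs} lines < 3*r_pe = {3 * r_pe}")
    if r_pe == 1:
        return InplaneKernelSet(weights={}, r_pe=1, n_src_lines=n_src_lines,
                                n_kx_taps=n_kx_taps, lam_used=0.0)
    pad = n_kx_taps // 2
    acs_padded = np.pad(acs, ((0, 0), (0, 0), (pad, pad)))
    # source line block starts: ky0 such that ky0 + (n_src-1)*r_pe < n_acs
    starts = np.arange(0, n_acs - (n_src_lines - 1) * r_pe)
    win = sliding_window_view(acs_padded, n_kx_taps, axis=2)  # (nc, n_acs, w, taps)
    weights = {}
    lam_used = lam
    for d in range(1, r_pe):
        rows_a, rows_b = [], []
        for ky0 in starts:
            tgt = ky0 + d
            if tgt >= n_acs:
                continue
            src = np.stack([win[:, ky0 + s * r_pe] for s in range(n_src_lines)],
                           axis=1)                    # (nc, n_src, w, taps)
            rows_a.append(src.transpose(2, 0, 1, 3).reshape(width, -1))
            rows_b.append(acs[:, tgt, :].T)           # (w, nc)
        a = np.concatenate(rows_a, axis=0)
        b = np.concatenate(rows_b, axis=0)
        w, _, lam_used = _solve(a, b, lam)
        weights[d] = w
    return InplaneKernelSet(weights=weights, r_pe=r_pe, n_src_lines=n_src_lines,
                            n_kx_taps=n_kx_taps, lam_used=lam_used)


def apply_inplane_kernels(under: np.ndarray, kernels: InplaneKernelSet,
                          full_ky: int | None = None) -> np.ndarray:
    """Fill skipped phase-encode lines of one band.

    *under*: (nc, n_acq, width) data on the acquired lines (full-grid rows
    ``0, r_pe, 2*r_pe, ...``).  Acquired lines pass through unchanged.
    """
    nc, n_acq, width = under.shape
    r = kernels.r_pe
    if r == 1:
        return under.copy()
    if full_ky is None:
        full_ky = n_acq * r
    out = np.zeros((nc, full_ky, width), dtype=complex)
    out[:, ::r, :] = under
    src = _source_windows(under, kernels.n_src_lines, kernels.n_kx_taps)
    for d, w in kernels.weights.items():
        est = src.reshape(-1, src.shape[-1]) @ w          # (n_acq*w, nc)
        est = est.reshape(n_acq, width, nc).transpose(2, 0, 1)
        rows = np.arange(n_acq) * r + d
        keep = rows < full_ky
        out[:, rows[keep], :] = est[:, keep, :]
    return out


def fit_apply_inplane_grappa(band_under: np.ndarray, acs: np.ndarray,
                             r_pe: int, **kw) -> np.ndarray:
    """Convenience wrapper: calibrate on *acs* and fill *band_under*."""
    kernels = fit_inplane_kernels(acs, r_pe, **kw)
    return apply_inplane_kernels(band_under, kernels)
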