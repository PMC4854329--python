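"""Navigator-based motion QC and phase correction.

Each shot's 2D navigator (a low-resolution central-kx echo train) measures
the motion-induced image phase of that shot.  Three uses:

* the **distribution width** ``W_x = sum_i sum_ky sum_kx |S_i| * |kx - Omega_x|``
  scores motion corruption directly on the raw, aliased, undersampled
  navigator k-space (no reconstruction needed, hence usable in real time);
  ``Omega_x`` is the kx column with maximum channel-combined magnitude;
* shots ranked worst by a centrally weighted width are selected for
  **reacquisition** (default: worst 20%, center-of-k-space segments
  preferred);
* after reconstruction to single-slice full-FOV data, the navigator's image
  phase is removed from its segment (**nonlinear phase correction**) so the
  segments splice coherently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fourier import fft2c, ifft2c
from .grappa import SliceKernelSet, apply_slice_kernels

__all__ = [
    "WidthReport", "ReacqPolicy", "distribution_width",
    "select_reacquisitions", "navigator_phase_correct", "per_slice_widths",
]


@dataclass
class WidthReport:
    """Distribution-width QC record for one shot (or one unaliased slice)."""

    shot_id: str
    w_x: float
    omega_x: int
    valid: bool = True
    segment_index: int = 0
    weighted_score: float = 0.0
    rank: int = -1


def distribution_width(navigator_band: np.ndarray, shot_id: str = "",
                       segment_index: int = 0,
                       channel_combine: str = "rss") -> WidthReport:
    """Score motion corruption of one navigator band.

    *navigator_band*: (nc, n_ky, n_kx) raw k-space.  ``Omega_x`` is the
    argmax over kx of the root-sum-of-squares magnitude over channels and ky
    (``channel_combine="max"`` uses the single largest sample instead);
    ties break to the lowest kx index.  ``W_x`` sums ``|S| * |kx - Omega_x|``
    over channels, ky and kx, so it is zero iff all signal sits in the
    single column ``Omega_x``.
    """
    band = np.asarray(navigator_band)
    if band.ndim == 2:
        band = band[None]
    mag = np.abs(band)
    if not np.any(mag > 0):
        return WidthReport(shot_id=shot_id, w_x=0.0, omega_x=-1, valid=False,
                           segment_index=segment_index)
    if channel_combine == "rss":
        profile = np.sqrt((mag ** 2).sum(axis=(0, 1)))
    elif channel_combine == "max":
        profile = mag.max(axis=(0, 1))
    else:
        raise ValueError(f"unknown channel_combine {channel_combine!r}")
    omega = int(np.argmax(profile))      # first occurrence = lowest index
    kx = np.arange(band.shape[-1])
    w_x = float((mag * np.abs(kx - omega)[None, None, :]).sum())
    return WidthReport(shot_id=shot_id, w_x=w_x, omega_x=omega,
                       segment_index=segment_index)


@dataclass(frozen=True)
class ReacqPolicy:
    """Which shots to reacquire: worst ``fraction`` by centrally weighted width.

    The weight is a Gaussian in segment distance from the central segment
    (width one segment, floored at 1) so equal raw widths rank central
    segments first — corruption near the k-space center does the most
    damage.
    """

    fraction: float = 0.2
    central_amplitude: float = 2.0
    central_sigma_segments: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction={self.fraction} outside [0, 1]")

    def central_weight(self, segment_index: int, n_segments: int) -> float:
        d = segment_index - n_segments // 2
        return max(1.0, self.central_amplitude
                   * math.exp(-d ** 2 / (2 * self.central_sigma_segments ** 2)))


def select_reacquisitions(reports: list[WidthReport], policy: ReacqPolicy,
                          n_segments: int) -> list[str]:
    """Rank shots by ``w_x * central_weight`` and return the worst
    ``ceil(fraction * N)`` shot ids (deterministic tie-breaking: larger
    score first, then central-most segment, then lowest shot id)."""
    n_pick = math.ceil(policy.fraction * len(reports) - 1e-12)
    center = n_segments // 2
    for r in reports:
        r.weighted_score = r.w_x * policy.central_weight(r.segment_index, n_segments)
    order = sorted(reports, key=lambda r: (-r.weighted_score,
                                           abs(r.segment_index - center),
                                           r.shot_id))
    for rank, r in enumerate(order):
        r.rank = rank
    return [r.shot_id for r in order[:n_pick]]


def navigator_phase_correct(segment_kspace: np.ndarray,
                            navigator_kspace: np.ndarray,
                            nav_kx_offset: int | None = None) -> np.ndarray:
    """Remove the navigator's image phase from a segment (both single-slice,
    full ky after unaliasing).

    The navigator is zero-padded in kx to the segment's grid (placed at
    ``nav_kx_offset``, or centered when omitted), both are transformed to
    image space, the segment is multiplied by the conjugate navigator phase
    (magnitudes untouched), and the result is transformed back to k-space.
    """
    seg = np.asarray(segment_kspace)
    nav = np.asarray(navigator_kspace)
    if seg.shape[:-1] != nav.shape[:-1]:
        raise ValueError(f"geometry mismatch: segment {seg.shape} vs navigator "
                         f"{nav.shape} (only kx may differ)")
    n_kx = seg.shape[-1]
    w = nav.shape[-1]
    if w > n_kx:
        raise ValueError("navigator wider than segment grid")
    lo = (n_kx - w) // 2 if nav_kx_offset is None else nav_kx_offset
    nav_full = np.zeros(seg.shape, dtype=complex)
    nav_full[..., lo:lo + w] = nav
    nav_img = ifft2c(nav_full)
    seg_img = ifft2c(seg)
    phase = np.exp(-1j * np.angle(nav_img))
    # where the navigator has no signal the phase estimate is meaningless,
    # but so is the segment's (same object support) — leave as-is
    return fft2c(seg_img * phase)


def per_slice_widths(collapsed_navigator: np.ndarray,
                     kernels: SliceKernelSet, shot_id: str = "",
                     segment_index: int = 0) -> list[WidthReport]:
    """Distribution width per simultaneously excited slice.

    Applies the slice-separation kernels to the collapsed navigator band and
    scores each unaliased slice separately — the more expensive alternative
    to the single aliased width, sensitive to corruption confined to one
    slice.
    """
    separated = apply_slice_kernels(collapsed_navigator, kernels)
    return [distribution_width(separated[j],
                               shot_id=f"{shot_id}/slice{j}",
                               segment_index=segment_index)
            for j in range(separated.shape[0])]
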