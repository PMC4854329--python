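"""Blipped-CAIPI phase bookkeeping.

During the EPI readout, small slice-gradient blips of alternating polarity
impart a per-line phase that depends on slice position.  For two
simultaneously excited slices a per-line phase difference of pi (the
0 - pi - 0 - ... pattern) makes the second slice appear shifted by half of
the *sampled* phase-encode FOV; with in-plane undersampling R_PE = 2 that is
a quarter of the full FOV after GRAPPA.  Slice groups centered away from the
gradient isocenter pick up an extra constant phase on the blipped lines,
which must be removed before any kernel calibration.

``fov_shift_fraction`` is always stored relative to the sampled
(undersampled) FOV; full-FOV shifts are derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = ["CaipiScheme", "make_fov_shift_scheme", "caipi_line_phase",
           "isocenter_offset_phase", "slice_line_phase", "remove_isocenter_offset"]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CaipiScheme:
    """Per-line phase recipe for one simultaneously excited slice group."""

    delta_theta: tuple[float, ...]        # rad per line, one per excited slice
    slice_offsets_mm: tuple[float, ...]   # absolute slice positions
    group_center_mm: float = 0.0          # group center offset from isocenter
    blip_moment_rad_per_mm: float = 0.0   # constant-offset phase per mm offset
    alternating: bool = True              # blip polarity alternates (no accumulation)
    fov_shift_fraction: Fraction = Fraction(1, 2)  # of the sampled FOV

    def __post_init__(self):
        if len(self.delta_theta) != len(self.slice_offsets_mm):
            raise ValueError("one delta_theta per excited slice required")

    @property
    def r_slice(self) -> int:
        return len(self.delta_theta)


def make_fov_shift_scheme(slice_offsets_mm, *, group_center_mm: float = 0.0,
                          blip_moment_rad_per_mm: float = 0.0,
                          shift_fraction: Fraction | None = None) -> CaipiScheme:
    """Standard scheme: slice j gets ``delta_theta = 2*pi*shift*j``.

    The default shift is 1/2 of the sampled FOV for two slices (the pi
    difference) and ``1/r_slice`` for more.
    """
    r = len(slice_offsets_mm)
    if shift_fraction is None:
        shift_fraction = Fraction(1, 2) if r == 2 else Fraction(1, max(r, 1))
    dtheta = tuple(float(TWO_PI * shift_fraction * j) for j in range(r))
    return CaipiScheme(delta_theta=dtheta,
                       slice_offsets_mm=tuple(float(z) for z in slice_offsets_mm),
                       group_center_mm=group_center_mm,
                       blip_moment_rad_per_mm=blip_moment_rad_per_mm,
                       fov_shift_fraction=shift_fraction)


def caipi_line_phase(scheme: CaipiScheme, slice_j: int, line_m) -> np.ndarray:
    """CAIPI phase ``(m * delta_theta_j) mod 2*pi`` for acquired-line counter m."""
    if not 0 <= slice_j < scheme.r_slice:
        raise ValueError(f"slice_j={slice_j} out of range for r_slice={scheme.r_slice}")
    m = np.asarray(line_m)
    return np.mod(m * scheme.delta_theta[slice_j], TWO_PI)


def isocenter_offset_phase(scheme: CaipiScheme, line_m) -> np.ndarray:
    """Constant phase offset on blipped lines for an off-isocenter group.

    With alternating blip polarity the net blip moment is nonzero on odd
    lines only, so the offset ``group_center * blip_moment`` appears with the
    line parity; without alternation it accumulates with m.
    """
    m = np.asarray(line_m)
    pattern = (m % 2) if scheme.alternating else m
    return pattern * scheme.blip_moment_rad_per_mm * scheme.group_center_mm


def slice_line_phase(scheme: CaipiScheme, slice_j: int, line_m) -> np.ndarray:
    """Total simulated per-line phase for one excited slice (CAIPI + offset)."""
    return caipi_line_phase(scheme, slice_j, line_m) + isocenter_offset_phase(scheme, line_m)


def remove_isocenter_offset(kspace: np.ndarray, scheme: CaipiScheme) -> np.ndarray:
    """Subtract the off-isocenter constant phase from collapsed raw data.

    *kspace* has acquired lines along axis -2 (counter m = 0, 1, ...).  A
    group at isocenter passes through unchanged.
    """
    if scheme.blip_moment_rad_per_mm != 0.0 and scheme.group_center_mm != 0.0 \
            and not np.isfinite(scheme.group_center_mm):
        raise ValueError("group_center_mm metadata missing or invalid")
    m = np.arange(kspace.shape[-2])
    psi = isocenter_offset_phase(scheme, m)
    return kspace * np.exp(-1j * psi)[:, None]
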