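"""Digital multi-slice brain phantoms, coil sensitivities, and contrast.

The phantom is a per-slice tissue label map (background / white matter /
gray matter / CSF by default) with class-wise proton density, T2 and
isotropic apparent diffusion coefficient (ADC).  It stands in for the imaged
object: structured enough to expose aliasing and blurring, simple enough
that every reconstruction test has an exact ground truth.

Coil profiles are smooth complex fields from loop elements placed on a ring
around the object with staggered positions along the slice axis, so that
simultaneously excited slices see measurably different channel weightings —
the property that makes slice unaliasing possible at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueClass",
    "Phantom",
    "CoilProfileSet",
    "DEFAULT_TISSUES",
    "generate_phantom",
    "generate_coils",
    "simulate_contrast",
]


@dataclass(frozen=True)
class TissueClass:
    name: str
    proton_density: float
    t2_ms: float
    adc_mm2_per_s: float


# Literature-typical brain values at 3T; configurable, not fitted.
DEFAULT_TISSUES: tuple[TissueClass, ...] = (
    TissueClass("background", 0.0, 1.0, 0.0),
    TissueClass("wm", 0.70, 80.0, 0.7e-3),
    TissueClass("gm", 0.85, 95.0, 0.9e-3),
    TissueClass("csf", 1.00, 2000.0, 3.0e-3),
)


@dataclass
class Phantom:
    """Multi-slice digital object with per-class relaxation and diffusion."""

    label_map: np.ndarray                    # (n_slices, ny, nx) int
    tissues: tuple[TissueClass, ...]
    slice_positions_mm: np.ndarray           # (n_slices,) offsets from isocenter
    background_phase: np.ndarray             # (n_slices, ny, nx) rad, smooth
    motion_susceptibility: np.ndarray        # (n_slices,) in [0, 1], inferior high
    pixel_mm: float = 1.7

    def __post_init__(self):
        if self.tissues[0].proton_density != 0.0:
            raise ValueError("class 0 (background) must have zero proton density")
        for t in self.tissues:
            if not 0.0 <= t.adc_mm2_per_s <= 4e-3:
                raise ValueError(f"ADC of {t.name} outside [0, 4e-3] mm^2/s")

    @property
    def n_slices(self) -> int:
        return self.label_map.shape[0]

    @property
    def matrix(self) -> int:
        return self.label_map.shape[-1]

    def class_map(self, attr: str) -> np.ndarray:
        """Per-voxel map of a tissue attribute (e.g. ``'adc_mm2_per_s'``)."""
        lut = np.array([getattr(t, attr) for t in self.tissues])
        return lut[self.label_map]

    def support(self) -> np.ndarray:
        return self.label_map > 0


@dataclass
class CoilProfileSet:
    """Complex receive sensitivities, (n_channels, n_slices, ny, nx)."""

    sensitivities: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[0]

    def for_slice(self, s: int) -> np.ndarray:
        return self.sensitivities[:, s]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.sensitivities) ** 2).sum(axis=0))


def _ellipse(ny, nx, cy, cx, ry, rx, theta=0.0):
    y, x = np.mgrid[0:ny, 0:nx]
    y = y - cy
    x = x - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _smooth_field(rng, ny, nx, order=2, scale=1.0):
    """Low-order 2D polynomial field with seeded coefficients."""
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    out = np.zeros((ny, nx))
    for i in range(order + 1):
        for j in range(order + 1 - i):
            out = out + rng.normal(0, 1) * (y ** i) * (x ** j)
    return scale * out


def generate_phantom(matrix: int, n_slices: int, seed: int = 0, *,
                     tissues: tuple[TissueClass, ...] = DEFAULT_TISSUES,
                     slice_spacing_mm: float = 15.0,
                     pixel_mm: float = 1.7) -> Phantom:
    """Deterministic brain-like phantom with WM/GM/CSF structure.

    Each slice is an elliptical head: a gray-matter shell, a white-matter
    interior, paired CSF ventricles, and a few seeded CSF/GM blobs so slices
    and hemispheres are asymmetric.  Slice positions are symmetric about
    isocenter; ``motion_susceptibility`` decreases linearly from the most
    inferior slice (index 0) to the most superior, mimicking the greater
    pulsatile brain motion near the brainstem.
    """
    if matrix < 32:
        raise ValueError("matrix must be >= 32 to place phantom structures")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    ny = nx = matrix
    labels = np.zeros((n_slices, ny, nx), dtype=np.int8)
    phases = np.zeros((n_slices, ny, nx))
    c = (matrix - 1) / 2.0
    for s in range(n_slices):
        # head size varies gently across slices
        shrink = 1.0 - 0.08 * abs(s - (n_slices - 1) / 2) / max(n_slices - 1, 1)
        ry, rx = 0.44 * matrix * shrink, 0.38 * matrix * shrink
        head = _ellipse(ny, nx, c, c, ry, rx)
        inner = _ellipse(ny, nx, c, c, 0.82 * ry, 0.80 * rx)
        labels[s][head] = 2          # GM shell
        labels[s][inner] = 1         # WM interior
        # paired ventricles
        vy, vx = 0.16 * matrix, 0.05 * matrix
        off = 0.08 * matrix
        for sgn in (-1, 1):
            vent = _ellipse(ny, nx, c - 0.04 * matrix, c + sgn * off, vy, vx,
                            theta=sgn * 0.25)
            labels[s][vent & inner] = 3
        # seeded blobs (one CSF-like, one GM-like) break symmetry per slice
        for cls in (3, 2):
            by = c + rng.uniform(-0.18, 0.18) * matrix
            bx = c + rng.uniform(-0.18, 0.18) * matrix
            br = rng.uniform(0.025, 0.05) * matrix
            blob = _ellipse(ny, nx, by, bx, br, br)
            labels[s][blob & inner] = cls
        phases[s] = _smooth_field(rng, ny, nx, order=2, scale=0.6)
    positions = (np.arange(n_slices) - (n_slices - 1) / 2.0) * slice_spacing_mm
    if n_slices > 1:
        susceptibility = 1.0 - np.arange(n_slices) / (n_slices - 1)
    else:
        susceptibility = np.ones(1)
    return Phantom(label_map=labels, tissues=tissues,
                   slice_positions_mm=positions, background_phase=phases,
                   motion_susceptibility=susceptibility, pixel_mm=pixel_mm)


def generate_coils(n_channels: int, matrix: int,
                   slice_positions_mm: np.ndarray, seed: int = 0, *,
                   ring_radius_factor: float = 0.55,
                   z_extent_mm: float = 80.0,
                   z_levels: int | None = None,
                   pixel_mm: float = 1.7) -> CoilProfileSet:
    """Smooth complex coil profiles on a ring with staggered slice-axis centers.

    Channel magnitudes fall off with 3D distance from loop centers placed on
    a ring of radius ``ring_radius_factor * FOV`` around the object; the loop
    z-positions are staggered over ``z_levels`` rows spanning ``z_extent_mm``
    (two rows up to 8 channels, four above, mimicking multi-row head arrays)
    so channels weight distant slices differently.  Each channel also
    carries a smooth seeded phase.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2 for any acceleration")
    if z_levels is None:
        z_levels = 2 if n_channels <= 8 else 4
    rng = np.random.default_rng(seed)
    slice_positions_mm = np.asarray(slice_positions_mm, dtype=float)
    n_slices = slice_positions_mm.size
    fov = matrix * pixel_mm
    c = (matrix - 1) / 2.0
    y = (np.arange(matrix) - c)[:, None] * pixel_mm
    x = (np.arange(matrix) - c)[None, :] * pixel_mm
    sens = np.zeros((n_channels, n_slices, matrix, matrix), dtype=complex)
    radius = ring_radius_factor * fov
    for ch in range(n_channels):
        ang = 2 * np.pi * ch / n_channels + rng.normal(0, 0.05)
        cy, cx = radius * np.sin(ang), radius * np.cos(ang)
        # stagger along z with a seeded jitter so no two channels coincide
        cz = z_extent_mm * ((ch % z_levels) / max(z_levels - 1, 1) - 0.5) \
            + rng.normal(0, 0.1) * z_extent_mm / 4
        d2 = (y - cy) ** 2 + (x - cx) ** 2
        for s in range(n_slices):
            dz2 = (slice_positions_mm[s] - cz) ** 2
            mag = radius ** 2 / (d2 + dz2 + (0.25 * radius) ** 2)
            phase = _smooth_field(np.random.default_rng(seed + 7919 * ch + 13 * s),
                                  matrix, matrix, order=1, scale=0.8)
            sens[ch, s] = mag * np.exp(1j * phase)
    # normalize so the root-sum-of-squares is ~1 at object center
    center_rss = np.sqrt((np.abs(sens[:, :, matrix // 2, matrix // 2]) ** 2
                          ).sum(axis=0)).mean()
    sens /= center_rss
    return CoilProfileSet(sensitivities=sens)


def simulate_contrast(phantom: Phantom, b_value: float,
                      direction: np.ndarray | None = None,
                      te_ms: float = 70.0) -> np.ndarray:
    """Per-slice complex object signal at the given diffusion weighting.

    ``signal = PD * exp(-TE/T2) * exp(-b * ADC)`` per tissue class, carrying
    the phantom's smooth static background phase.  Diffusion is isotropic,
    so the direction affects only the motion-phase realizations drawn by the
    scanner, not the magnitude.
    """
    if b_value < 0:
        raise ValueError("b_value must be non-negative")
    pd = phantom.class_map("proton_density")
    t2 = phantom.class_map("t2_ms")
    adc = phantom.class_map("adc_mm2_per_s")
    mag = pd * np.exp(-te_ms / t2) * np.exp(-b_value * adc)
    return mag * np.exp(1j * phantom.background_phase)
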