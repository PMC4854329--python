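"""Acquisition protocols, relaxation parameters, and closed-form readout theory.

The physics here is scalar: the reversible (:math:`T_2`) and irreversible
(:math:`T_2'`) decay constants combine as ``1/T2* = 1/T2 + 1/T2'``, and for a
spin-echo EPI readout of duration :math:`T_{acq}` the effective phase-encode
pixel size is

.. math::  \\Delta y' = \\Delta y \\left(\\frac{3}{T_2} + \\frac{1}{T_2'}\\right)
           \\frac{T_{acq}}{\\pi}

so a longer echo train blurs the image linearly.  Readout-segmented EPI keeps
:math:`T_{acq}` short by acquiring k-space in narrow readout bands (one shot
each) at the cost of more repetition times per volume; simultaneous-multislice
(SMS) excitation buys that time back by collapsing ``r_slice`` slices per
shot, paying only a fixed calibration overhead of ``2 * r_slice`` TR periods
for the single-band reference scans.

Because the echo-train-duration bookkeeping admits more than one reasonable
convention, ``echo_train_duration`` takes an explicit ``convention`` argument
with no default: ``"full_train"`` counts every acquired phase-encode line,
``"post_center"`` only the lines from the k-space center to the end of the
train (the part that low-pass filters the image in a spin echo).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Protocol",
    "RelaxationParams",
    "TheoryReport",
    "compute_t2prime",
    "effective_pe_resolution",
    "echo_train_duration",
    "reference_overhead",
    "imaging_scan_time",
    "theory_report",
    "load_protocols",
    "matched_pairs",
    "RELAXATION_3T_WM",
    "RELAXATION_7T_WM",
]

_CONVENTIONS = ("full_train", "post_center")


@dataclass(frozen=True)
class Protocol:
    """One acquisition protocol (geometry, acceleration, timing)."""

    name: str
    matrix_read: int
    matrix_pe: int
    fov_mm: tuple[float, float]
    n_segments: int
    echo_spacing_ms: float
    r_slice: int
    r_pe: int
    tr_s: float
    te_ms: float
    n_slices: int
    slice_thickness_mm: float
    pf_readout: float = 1.0
    pf_pe: float = 1.0
    b_values_s_per_mm2: tuple[float, ...] = (0.0, 1000.0)
    n_directions: int = 3
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.matrix_read < 1 or self.matrix_pe < 1:
            raise ValueError("matrix dimensions must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be positive")
        if min(self.echo_spacing_ms, self.tr_s, self.te_ms,
               self.slice_thickness_mm) <= 0:
            raise ValueError("all timings and thicknesses must be positive")
        if self.r_slice < 1 or self.r_pe < 1:
            raise ValueError("acceleration factors must be >= 1")
        if self.n_slices % self.r_slice != 0:
            raise ValueError(
                f"n_slices={self.n_slices} not divisible by r_slice={self.r_slice}"
            )
        if self.matrix_pe % self.r_pe != 0:
            raise ValueError(
                f"matrix_pe={self.matrix_pe} not divisible by r_pe={self.r_pe}"
            )
        for pf, label in ((self.pf_readout, "pf_readout"), (self.pf_pe, "pf_pe")):
            if not 0.5 < pf <= 1.0:
                raise ValueError(f"{label}={pf} outside (0.5, 1.0]")
        if any(b < 0 for b in self.b_values_s_per_mm2):
            raise ValueError("b-values must be non-negative")
        if self.n_directions < 0:
            raise ValueError("n_directions must be non-negative")

    @property
    def nominal_pixel_pe_mm(self) -> float:
        return self.fov_mm[1] / self.matrix_pe

    @property
    def n_slice_groups(self) -> int:
        return self.n_slices // self.r_slice

    @property
    def n_segments_acquired(self) -> int:
        """Readout bands actually acquired under readout partial Fourier."""
        return math.ceil(self.n_segments * self.pf_readout - 1e-9)


@dataclass(frozen=True)
class RelaxationParams:
    """T2/T2*/T2' triple for one tissue/field combination (all ms)."""

    t2_ms: float
    t2_star_ms: float
    t2_prime_ms: float
    field_label: str = ""

    def __post_init__(self):
        if self.t2_ms <= 0 or self.t2_star_ms <= 0:
            raise ValueError("T2 and T2* must be positive")
        if self.t2_star_ms > self.t2_ms:
            raise ValueError("T2* cannot exceed T2")
        expected = compute_t2prime(self.t2_star_ms, self.t2_ms)
        if math.isinf(expected):
            ok = math.isinf(self.t2_prime_ms)
        else:
            ok = abs(self.t2_prime_ms - expected) <= 1e-9 * expected
        if not ok:
            raise ValueError(
                f"inconsistent T2'={self.t2_prime_ms} (expected {expected})"
            )

    @classmethod
    def from_t2_t2star(cls, t2_ms: float, t2_star_ms: float,
                       field_label: str = "") -> "RelaxationParams":
        return cls(t2_ms=t2_ms, t2_star_ms=t2_star_ms,
                   t2_prime_ms=compute_t2prime(t2_star_ms, t2_ms),
                   field_label=field_label)


@dataclass(frozen=True)
class TheoryReport:
    """Closed-form blur/timing predictions for one protocol."""

    protocol_name: str
    convention_label: str
    nominal_pixel_mm: float
    effective_pixel_mm: float
    t_acq_ms: float
    echo_count: int
    reference_overhead_s: float
    blur_ratio_percent: float      # effective / nominal, in percent
    blur_excess_percent: float     # (effective - nominal) / nominal, in percent

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_t2prime(t2_star_ms: float, t2_ms: float) -> float:
    """Irreversible-dephasing constant T2' from T2* and T2 (ms).

    ``1/T2' = 1/T2* - 1/T2``; returns ``math.inf`` when T2* equals T2
    (no external-field dephasing).  T2* > T2 is unphysical and raises.
    """
    if t2_star_ms <= 0 or t2_ms <= 0:
        raise ValueError("relaxation times must be positive")
    if t2_star_ms > t2_ms:
        raise ValueError("T2* > T2 would imply negative T2'")
    if t2_star_ms == t2_ms:
        return math.inf
    return 1.0 / (1.0 / t2_star_ms - 1.0 / t2_ms)


def effective_pe_resolution(nominal_pixel_mm: float, t2_ms: float,
                            t2_prime_ms: float, t_acq_ms: float) -> float:
    """Effective phase-encode pixel size after T2/T2' echo-train filtering.

    Literal evaluation of ``dy' = dy * (3/T2 + 1/T2') * Tacq / pi``; linear
    in both the nominal pixel and the readout duration.  An infinite T2'
    drops its term.
    """
    if nominal_pixel_mm < 0 or t_acq_ms < 0:
        raise ValueError("pixel size and Tacq must be non-negative")
    if t2_ms <= 0:
        raise ValueError("T2 must be positive")
    if t2_prime_ms <= 0:
        raise ValueError("T2' must be positive (possibly inf)")
    inv_t2p = 0.0 if math.isinf(t2_prime_ms) else 1.0 / t2_prime_ms
    return nominal_pixel_mm * (3.0 / t2_ms + inv_t2p) * t_acq_ms / math.pi


def echo_train_duration(protocol: Protocol, convention: str) -> tuple[float, int]:
    """(Tacq in ms, echo count) for the phase-encode echo train.

    ``full_train`` counts all acquired lines: ``matrix_pe * pf_pe / r_pe``.
    ``post_center`` counts only echoes from the ky=0 line to the end of the
    train (partial Fourier omits early lines, so the center sits
    asymmetrically).
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {_CONVENTIONS}")
    n_full_grid = round(protocol.matrix_pe * protocol.pf_pe)
    echo_count = round(n_full_grid / protocol.r_pe)
    if convention == "post_center":
        # acquired full-grid lines span [matrix_pe - n_full_grid, matrix_pe);
        # the center line matrix_pe//2 sits at train index
        # (matrix_pe//2 - first_line) / r_pe.
        first_line = protocol.matrix_pe - n_full_grid
        center_idx = (protocol.matrix_pe // 2 - first_line) // protocol.r_pe
        echo_count = echo_count - center_idx
    return echo_count * protocol.echo_spacing_ms, echo_count


def reference_overhead(protocol: Protocol) -> float:
    """Extra seconds spent on single-band reference scans: ``2 * r_slice * TR``.

    One TR per single-band slice group for the ghost-phase reference and one
    for the GRAPPA / slice-unaliasing calibration segment; acquiring them
    without slice collapse costs ``r_slice`` times more groups.
    """
    return 2.0 * protocol.r_slice * protocol.tr_s


def imaging_scan_time(protocol: Protocol, n_volumes: int) -> float:
    """Total seconds for ``n_volumes`` plus the reference-scan overhead."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    return (protocol.tr_s * protocol.n_segments_acquired * n_volumes
            + reference_overhead(protocol))


def theory_report(protocol: Protocol, relaxation: RelaxationParams,
                  convention: str) -> TheoryReport:
    """Bundle the closed-form predictions for one protocol."""
    t_acq_ms, echo_count = echo_train_duration(protocol, convention)
    dy = protocol.nominal_pixel_pe_mm
    dy_eff = effective_pe_resolution(dy, relaxation.t2_ms,
                                     relaxation.t2_prime_ms, t_acq_ms)
    return TheoryReport(
        protocol_name=protocol.name,
        convention_label=convention,
        nominal_pixel_mm=dy,
        effective_pixel_mm=dy_eff,
        t_acq_ms=t_acq_ms,
        echo_count=echo_count,
        reference_overhead_s=reference_overhead(protocol),
        blur_ratio_percent=100.0 * dy_eff / dy,
        blur_excess_percent=100.0 * (dy_eff - dy) / dy,
    )


# White-matter relaxation defaults used by the theory CLI.
RELAXATION_3T_WM = RelaxationParams.from_t2_t2star(80.0, 47.0, "3T")
RELAXATION_7T_WM = RelaxationParams.from_t2_t2star(48.5, 28.0, "7T")


def _protocol_from_dict(d: dict) -> Protocol:
    known = {
        "name", "matrix_read", "matrix_pe", "fov_mm", "n_segments",
        "echo_spacing_ms", "r_slice", "r_pe", "tr_s", "te_ms", "n_slices",
        "slice_thickness_mm", "pf_readout", "pf_pe", "b_values_s_per_mm2",
        "n_directions",
    }
    kwargs = {k: v for k, v in d.items() if k in known}
    kwargs["fov_mm"] = tuple(kwargs["fov_mm"])
    kwargs["b_values_s_per_mm2"] = tuple(kwargs.get("b_values_s_per_mm2", (0.0, 1000.0)))
    meta = {k: v for k, v in d.items() if k not in known}
    return Protocol(meta=meta, **kwargs)


def load_protocols(path: str | Path | None = None) -> dict[str, Protocol]:
    """Load protocols from a JSON config (bundled set when *path* is None)."""
    if path is None:
        text = resources.files("rsepi_sms.data").joinpath("protocols.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    rows = payload["protocols"] if isinstance(payload, dict) else payload
    out = {}
    for row in rows:
        p = _protocol_from_dict(row)
        out[p.name] = p
    return out


def matched_pairs(protocols: dict[str, Protocol]) -> list[tuple[Protocol, Protocol]]:
    """(rs, ss) protocol pairs acquired at matched nominal resolution."""
    pairs = []
    for p in protocols.values():
        if p.meta.get("sequence") == "rs":
            partner = p.meta.get("matched_pair")
            if partner and partner in protocols:
                pairs.append((p, protocols[partner]))
    return pairs
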