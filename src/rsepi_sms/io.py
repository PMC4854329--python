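"""Raw-data container (HDF5) and reconstructed-volume output (NIfTI).

HDF5 layout of a simulated acquisition::

    /protocol                 JSON string attribute block (acquisition params)
    /shots/<id>/imaging       complex (nc, n_ky_acq, band_width)
    /shots/<id>/navigator     complex (nc, n_ky_acq, nav_width)
        attrs: segment_index, volume_index, slice_group, kx_offset,
               nav_kx_offset, corrupted
    /reference/central_segments   complex (n_slices, nc, matrix_pe, width)
    /reference/phase_reference    complex (n_slices, nc, n_echo, matrix_read)
        attrs: center_kx_offset
    /truth/volumes            float (n_volumes, n_slices, ny, nx)
    /truth/adc                float (n_slices, ny, nx)
    /scheme/...               per-group CAIPI phase recipes
    /volumes/...              b-values and diffusion directions

Everything needed to reconstruct travels inside the file; the ground truth
group is carried for validation only and is never read by the pipeline.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np

from .caipi import CaipiScheme
from .protocol import Protocol
from .scanner import (GhostModel, ReferenceData, ShotRecord, SimulatedDataset)

__all__ = ["write_raw", "read_raw", "save_nifti"]


def _protocol_to_json(p: Protocol) -> str:
    d = {k: getattr(p, k) for k in (
        "name", "matrix_read", "matrix_pe", "n_segments", "echo_spacing_ms",
        "r_slice", "r_pe", "tr_s", "te_ms", "n_slices", "slice_thickness_mm",
        "pf_readout", "pf_pe", "n_directions")}
    d["fov_mm"] = list(p.fov_mm)
    d["b_values_s_per_mm2"] = list(p.b_values_s_per_mm2)
    return json.dumps(d)


def _protocol_from_json(s: str) -> Protocol:
    d = json.loads(s)
    d["fov_mm"] = tuple(d["fov_mm"])
    d["b_values_s_per_mm2"] = tuple(d["b_values_s_per_mm2"])
    return Protocol(**d)


def write_raw(path: str | Path, ds: SimulatedDataset) -> None:
    """Write a simulated acquisition to the documented HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = _protocol_to_json(ds.protocol)
        f.attrs["noise_sigma"] = ds.noise_sigma
        f.attrs["seed"] = ds.seed
        f.attrs["ghost_const_rad"] = ds.ghost.const_rad
        f.attrs["ghost_linear_rad_per_sample"] = ds.ghost.linear_rad_per_sample
        shots = f.create_group("shots")
        for shot_id, rec in sorted(ds.shots.items()):
            g = shots.create_group(shot_id)
            g.create_dataset("imaging", data=rec.imaging_band)
            g.create_dataset("navigator", data=rec.navigator_band)
            g.attrs["segment_index"] = rec.segment_index
            g.attrs["volume_index"] = rec.volume_index
            g.attrs["slice_group"] = rec.slice_group_index
            g.attrs["kx_offset"] = rec.kx_offset
            g.attrs["nav_kx_offset"] = rec.nav_kx_offset
            g.attrs["corrupted"] = rec.corrupted
        ref = f.create_group("reference")
        ref.create_dataset("central_segments", data=ds.reference.central_segments)
        ref.create_dataset("phase_reference", data=ds.reference.phase_reference)
        ref.attrs["center_kx_offset"] = ds.reference.center_kx_offset
        truth = f.create_group("truth")
        truth.create_dataset("volumes", data=ds.truth["volumes"])
        truth.create_dataset("adc", data=ds.truth["adc"])
        scheme = f.create_group("scheme")
        for g_idx, sch in enumerate(ds.schemes):
            sg = scheme.create_group(f"group{g_idx:02d}")
            sg.attrs["delta_theta"] = list(sch.delta_theta)
            sg.attrs["slice_offsets_mm"] = list(sch.slice_offsets_mm)
            sg.attrs["group_center_mm"] = sch.group_center_mm
            sg.attrs["blip_moment_rad_per_mm"] = sch.blip_moment_rad_per_mm
            sg.attrs["alternating"] = sch.alternating
            sg.attrs["fov_shift_fraction"] = [sch.fov_shift_fraction.numerator,
                                              sch.fov_shift_fraction.denominator]
            sg.attrs["slices"] = list(ds.groups[g_idx])
        vols = f.create_group("volumes")
        vols.attrs["b"] = [v["b"] for v in ds.volumes]
        dirs = np.array([v["direction"] if v["direction"] is not None
                         else [np.nan] * 3 for v in ds.volumes])
        vols.create_dataset("directions", data=dirs)


def read_raw(path: str | Path) -> SimulatedDataset:
    """Load a raw acquisition written by :func:`write_raw`."""
    with h5py.File(path, "r") as f:
        protocol = _protocol_from_json(f.attrs["protocol"])
        ghost = GhostModel(const_rad=float(f.attrs["ghost_const_rad"]),
                           linear_rad_per_sample=float(
                               f.attrs["ghost_linear_rad_per_sample"]))
        shots = {}
        for shot_id, g in f["shots"].items():
            shots[shot_id] = ShotRecord(
                shot_id=shot_id,
                segment_index=int(g.attrs["segment_index"]),
                volume_index=int(g.attrs["volume_index"]),
                slice_group_index=int(g.attrs["slice_group"]),
                imaging_band=g["imaging"][()],
                navigator_band=g["navigator"][()],
                kx_offset=int(g.attrs["kx_offset"]),
                nav_kx_offset=int(g.attrs["nav_kx_offset"]),
                corrupted=bool(g.attrs["corrupted"]))
        reference = ReferenceData(
            central_segments=f["reference/central_segments"][()],
            phase_reference=f["reference/phase_reference"][()],
            center_kx_offset=int(f["reference"].attrs["center_kx_offset"]))
        schemes, groups = [], []
        for name in sorted(f["scheme"]):
            sg = f["scheme"][name]
            num, den = (int(v) for v in sg.attrs["fov_shift_fraction"])
            schemes.append(CaipiScheme(
                delta_theta=tuple(float(v) for v in sg.attrs["delta_theta"]),
                slice_offsets_mm=tuple(float(v) for v in sg.attrs["slice_offsets_mm"]),
                group_center_mm=float(sg.attrs["group_center_mm"]),
                blip_moment_rad_per_mm=float(sg.attrs["blip_moment_rad_per_mm"]),
                alternating=bool(sg.attrs["alternating"]),
                fov_shift_fraction=Fraction(num, den)))
            groups.append(tuple(int(s) for s in sg.attrs["slices"]))
        b_vals = list(f["volumes"].attrs["b"])
        dirs = f["volumes/directions"][()]
        volumes = [{"b": float(b),
                    "direction": None if np.isnan(d).any() else d}
                   for b, d in zip(b_vals, dirs)]
        truth = {"volumes": f["truth/volumes"][()], "adc": f["truth/adc"][()]}
        return SimulatedDataset(
            protocol=protocol, shots=shots, reference=reference,
            schemes=schemes, groups=groups, volumes=volumes, truth=truth,
            ghost=ghost, noise_sigma=float(f.attrs["noise_sigma"]),
            seed=int(f.attrs["seed"]))


def save_nifti(volume: np.ndarray, path: str | Path,
               voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a (possibly 4D) volume as NIfTI with a diagonal affine.

    Array axes (..., slice, y, x) are reordered to NIfTI (x, y, slice, ...).
    """
    import nibabel as nib
    vol = np.asarray(volume)
    if vol.ndim == 3:
        data = vol.transpose(2, 1, 0)
    elif vol.ndim == 4:
        data = vol.transpose(3, 2, 1, 0)
    else:
        raise ValueError("expected a 3D or 4D volume")
    affine = np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
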