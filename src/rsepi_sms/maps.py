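"""Trace-weighted images, ADC maps, and comparison statistics.

From one b = 0 volume and three orthogonal b = 1000 s/mm^2 volumes:

* the trace-weighted image is the voxelwise geometric mean of the three
  diffusion-weighted volumes (rotationally invariant contrast);
* the apparent diffusion coefficient is ``ADC = -ln(S_trw / S_b0) / b``
  inside a signal mask (low-signal voxels make the log ratio unstable and
  are excluded);
* region-of-interest means carry a 95% t-based confidence interval, and
  voxelwise difference histograms summarize agreement between two
  reconstructions of the same object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DwiSet", "AdcMap", "trace_weighted", "adc_map", "roi_mean_adc",
           "adc_difference_histogram", "ADC_SENTINEL"]

ADC_SENTINEL = -1.0


@dataclass
class DwiSet:
    """One b=0 volume plus three orthogonal DW volumes (co-registered)."""

    b0: np.ndarray
    dwi: np.ndarray          # (3, ...) three orthogonal directions
    b_value: float = 1000.0

    def __post_init__(self):
        self.b0 = np.asarray(self.b0, dtype=float)
        self.dwi = np.asarray(self.dwi, dtype=float)
        if self.dwi.shape[0] != 3:
            raise ValueError("exactly three orthogonal DW volumes required")
        if self.dwi.shape[1:] != self.b0.shape:
            raise ValueError("DW volumes must match the b0 shape")
        if (self.b0 < 0).any() or (self.dwi < 0).any():
            raise ValueError("magnitude volumes must be non-negative")


@dataclass
class AdcMap:
    """Voxelwise ADC (mm^2/s) with a validity mask; invalid voxels carry
    the sentinel value."""

    adc: np.ndarray
    mask: np.ndarray

    def masked(self) -> np.ndarray:
        return self.adc[self.mask]


def trace_weighted(dwi_set: DwiSet) -> np.ndarray:
    """Voxelwise geometric mean (cube root of the product) of the three DW
    volumes."""
    d = dwi_set.dwi
    return np.cbrt(d[0] * d[1] * d[2])


def adc_map(b0: np.ndarray, trw: np.ndarray, b: float = 1000.0, *,
            mask_threshold_frac: float = 0.05) -> AdcMap:
    """ADC from the b=0 and trace-weighted images.

    The mask keeps voxels where ``S_b0`` exceeds ``mask_threshold_frac``
    times its robust (98th percentile) maximum and ``S_trw > 0``; everywhere
    else the map holds the sentinel.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    b0 = np.asarray(b0, dtype=float)
    trw = np.asarray(trw, dtype=float)
    robust_max = np.percentile(b0, 98.0)
    mask = (b0 > mask_threshold_frac * robust_max) & (trw > 0)
    adc = np.full(b0.shape, ADC_SENTINEL)
    adc[mask] = -np.log(trw[mask] / b0[mask]) / b
    return AdcMap(adc=adc, mask=mask)


def roi_mean_adc(adc: AdcMap | np.ndarray, roi_mask: np.ndarray,
                 confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mean ADC over an ROI with a t-based confidence interval on the mean."""
    if isinstance(adc, AdcMap):
        roi_mask = roi_mask & adc.mask
        values = adc.adc[roi_mask]
    else:
        values = np.asarray(adc)[roi_mask]
    n = values.size
    if n == 0:
        raise ValueError("ROI is empty (or fully outside the validity mask)")
    mean = float(values.mean())
    if n == 1:
        return mean, (mean, mean)
    sem = values.std(ddof=1) / np.sqrt(n)
    if sem == 0:
        return mean, (mean, mean)
    lo, hi = stats.t.interval(confidence, n - 1, loc=mean, scale=sem)
    return mean, (float(lo), float(hi))


def adc_difference_histogram(adc_a: AdcMap, adc_b: AdcMap,
                             roi_mask: np.ndarray | None = None, *,
                             bin_width: float = 5e-5, bin_range: float = 5e-4
                             ) -> dict:
    """Histogram of voxelwise ADC differences (a minus b) inside both masks.

    Returns bin edges/counts plus the mean and standard deviation of the
    differences; values beyond the range land in the edge bins so counts
    always sum to the mask size.
    """
    if adc_a.adc.shape != adc_b.adc.shape:
        raise ValueError("ADC maps must have identical shapes")
    mask = adc_a.mask & adc_b.mask
    if roi_mask is not None:
        mask = mask & roi_mask
    if not mask.any():
        raise ValueError("masks are disjoint; nothing to compare")
    diff = adc_a.adc[mask] - adc_b.adc[mask]
    n_half = round(bin_range / bin_width)
    edges = bin_width * np.arange(-n_half, n_half + 1)   # exact zero edge
    counts, _ = np.histogram(np.clip(diff, edges[0], edges[-1] - 1e-12), edges)
    return {"edges": edges, "counts": counts,
            "mean": float(diff.mean()), "std": float(diff.std()),
            "n": int(mask.sum())}
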