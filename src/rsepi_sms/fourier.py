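"""Centered FFT helpers.

All k-space arrays in this package are center-origin: the DC sample sits at
index ``N // 2`` along every transformed axis.  The forward transform
(image -> k-space) is the unnormalized DFT; the ``1/N`` factor lives on the
inverse.  Every module transforms through these four functions so the
convention is stated exactly once.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "fftc", "ifftc"]


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Image -> centered k-space over the last two axes (unnormalized)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered k-space -> image over the last two axes (1/N normalized)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes
    )


def fftc(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis), axes=axis
    )


def ifftc(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis), axes=axis
    )
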