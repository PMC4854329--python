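"""Shared synthetic fixtures.

Everything is generated programmatically and deterministically; the heavier
acquisition/reconstruction fixtures are session-scoped so several test
modules can share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from rsepi_sms import (Protocol, Simulator, generate_coils, generate_phantom,
                       simulate_contrast)


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized RMS error of *a* against reference *b*."""
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b))
                 / np.linalg.norm(np.asarray(b)))


@pytest.fixture(scope="session")
def phantom32():
    return generate_phantom(32, 2, seed=6)


@pytest.fixture(scope="session")
def coils32(phantom32):
    return generate_coils(8, 32, phantom32.slice_positions_mm, seed=7)


@pytest.fixture(scope="session")
def phantom64_pair():
    """Two-slice matrix-64 phantom + 8-channel coils (standard SMS fixture)."""
    ph = generate_phantom(64, 2, seed=1)
    coils = generate_coils(8, 64, ph.slice_positions_mm, seed=2)
    return ph, coils


@pytest.fixture(scope="session")
def phantom48_stack():
    """Four-slice interleaved stack (20 mm spacing) + 8-channel coils."""
    ph = generate_phantom(48, 4, seed=1, slice_spacing_mm=20.0)
    coils = generate_coils(8, 48, ph.slice_positions_mm, seed=2)
    return ph, coils


def make_protocol(name="test", matrix=48, n_segments=3, r_slice=2, r_pe=2,
                  n_slices=2, tr_s=2.4, n_directions=3, pf_readout=1.0,
                  echo_spacing_ms=0.4, te_ms=70.0, pf_pe=1.0):
    return Protocol(name=name, matrix_read=matrix, matrix_pe=matrix,
                    fov_mm=(220.0, 220.0), n_segments=n_segments,
                    echo_spacing_ms=echo_spacing_ms, r_slice=r_slice,
                    r_pe=r_pe, tr_s=tr_s, te_ms=te_ms, n_slices=n_slices,
                    slice_thickness_mm=5.0, pf_readout=pf_readout,
                    pf_pe=pf_pe, n_directions=n_directions)


@pytest.fixture(scope="session")
def sms64_clean(phantom64_pair):
    """Noiseless 2-slice SMS acquisition, matrix 64, 3 segments, R_PE=2."""
    ph, coils = phantom64_pair
    p = make_protocol(name="sms64", matrix=64, n_slices=2)
    sim = Simulator(ph, coils, p, seed=3)
    return sim.acquire()


@pytest.fixture(scope="session")
def degenerate_dataset(phantom64_pair):
    """Unaccelerated, single-segment, noiseless acquisition (identity path)."""
    ph, coils = phantom64_pair
    p = make_protocol(name="degen", matrix=64, n_segments=1, r_slice=1,
                      r_pe=1, n_slices=2, tr_s=4.8, n_directions=1)
    return Simulator(ph, coils, p, seed=3).acquire()
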