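import numpy as np
import pytest

import ptychostream as ps

PX = 16.0  # object pixel, nm


@pytest.fixture(scope="session")
def probe32():
    return ps.make_probe(object_pixel_nm=PX, style="annulus", fwhm_nm=440,
                         n_pixels=32)


@pytest.fixture(scope="session")
def phantom():
    return ps.make_phantom((192, 192), PX, (-0.4, 0.0), "random_etch", seed=11,
                           feature_size_px=6)


@pytest.fixture(scope="session")
def dense_scan(phantom, probe32):
    """60-point spiral at overlap 0.9 over the phantom centre, noiseless."""
    b = probe32.fwhm_nm
    s = ps.simkit.step_for_overlap(0.9, b)
    center = (96 * PX, 96 * PX)
    plan = ps.make_spiral_scan(60, s, b, center_nm=center)
    stack = ps.simulate_scan(phantom, probe32, plan, exposure_ms=1.0,
                             flux_scale=1e8, poisson=False, seed=0)
    return plan, stack


@pytest.fixture(scope="session")
def quick_recon(dense_scan, probe32):
    plan, stack = dense_scan
    opts = ps.RpieOptions(iterations=120, n_modes=1, update_probe=False, seed=3)
    recon, trace = ps.rpie_reconstruct(stack, probe32, opts)
    return recon, trace
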