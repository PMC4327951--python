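import numpy as np
import pytest

from spinecurve import BackScan, SyntheticSpec, generate_scan


@pytest.fixture(scope="session")
def small_spec():
    """Compact synthetic back: fast enough for per-test detection runs."""
    return SyntheticSpec(n_rows=200, n_cols=120, seed=7)


@pytest.fixture(scope="session")
def small_scan(small_spec):
    return generate_scan(small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free variant of the compact back."""
    return SyntheticSpec(n_rows=200, n_cols=120, noise_sd_mm=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_scan(clean_spec):
    return generate_scan(clean_spec)


def make_flat_plate(n_rows=12, n_cols=10, z=5.0, brightness=1.0):
    """A flat plate scan: zero curvature everywhere."""
    x, y = np.meshgrid(np.arange(n_rows, dtype=float),
                       np.arange(n_cols, dtype=float), indexing="ij")
    return BackScan(
        x=x, y=y, z=np.full_like(x, z),
        brightness=np.full_like(x, brightness),
        valid_mask=np.ones_like(x, dtype=bool),
        profile_spacing_mm=1.0,
    )


def seed_point_on_furrow(spec, truth, scan):
    """Image coordinates of a click on the furrow at mid-scan."""
    vmid = spec.n_rows // 2
    umid = (truth.spine_y[vmid] - scan.y[0, 0]) / spec.col_spacing_mm
    return (umid, vmid)
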