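import numpy as np
import pytest

from gutopt import make_annulus_phantom, make_gut_phantom, unfold_volume
from gutopt.pipeline import DEFAULT_CONFIG, _build_phantom_spec, load_config, run_pipeline


@pytest.fixture(scope="session")
def gut_spec():
    """Default synthetic gut segment: 96^3 voxels at 5 um, 8 villi per ring
    over 6 rings (48 apexes), 3 submucosal follicles at 150 um spacing."""
    return _build_phantom_spec(DEFAULT_CONFIG["phantom"], seed=0)


@pytest.fixture(scope="session")
def gut_phantom(gut_spec):
    return make_gut_phantom(gut_spec)


@pytest.fixture(scope="session")
def gut_unfolded(gut_phantom):
    autofluo, _, _ = gut_phantom
    return unfold_volume(
        autofluo, angle_deg=45.0, band_inner_um=200.0, band_outer_um=10.0, step_um=5.0
    )


@pytest.fixture()
def apex_layer(gut_unfolded):
    """Unfolded layer at the radial depth where villi show as isolated blobs."""
    row = int(round((155.0 + gut_unfolded.band_outer_um) / gut_unfolded.step_um))
    return gut_unfolded.unfolded_volume[row]


@pytest.fixture(scope="session")
def annulus_volume():
    """3-slice annulus, r_in 80 um, r_out 120 um, 1 um voxels."""
    return make_annulus_phantom(80.0, 120.0, (3, 260, 260), 1.0)


@pytest.fixture(scope="session")
def disk_slice():
    """Two-layer disk phantom slice on a 128x128 grid (unit voxel)."""
    n = 128
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - n // 2, xx - n // 2)
    return np.where(r < 20, 1.0, 0.0) + np.where((r >= 30) & (r < 50), 0.6, 0.0)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two full pipeline runs with the same seed, for end-to-end + determinism."""
    cfg = load_config(overrides={"seed": 11})
    outs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp(name)
        report = run_pipeline(cfg, out)
        outs.append((report, out))
    return outs
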