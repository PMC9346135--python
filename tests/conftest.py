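import numpy as np
import pytest

from choroidref import EyeParams, ScanGeometry, generate_eye


@pytest.fixture(scope="session")
def geometry():
    """The default volume-scan geometry (512 x 496 px, 25 B-scans)."""
    return ScanGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced pixel counts at the same physical extent, for faster tests."""
    return ScanGeometry(
        width_px=256, depth_px=248, n_bscans=9,
        width_um=5300.0, depth_um=1900.0, bscan_spacing_um=221.0,
    )


@pytest.fixture(scope="session")
def small_eye_params():
    return EyeParams(
        pit_bscan=4,
        pit_lateral_um=2650.0,
        landmark_thicknesses_um=(205.0, 199.0, 195.0, 192.0, 190.0, 193.0,
                                 197.0, 200.0, 206.0),
    )


@pytest.fixture(scope="session")
def small_eye(small_geometry, small_eye_params):
    """One generated eye on the reduced geometry: (volume, masks, truth)."""
    return generate_eye(small_geometry, small_eye_params, seed=7)


def make_constant_boundaries(geometry, inner_um=650.0, thickness_um=193.0,
                             ilm_um=320.0):
    """Analytic (non-rasterized) boundary curves with constant layers."""
    from choroidref import BoundaryCurves

    shape = (geometry.n_bscans, geometry.width_px)
    ax = geometry.axial_scale
    return BoundaryCurves(
        ilm=np.full(shape, ilm_um / ax),
        choroid_inner=np.full(shape, inner_um / ax),
        choroid_outer=np.full(shape, (inner_um + thickness_um) / ax),
    )
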