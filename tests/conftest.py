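import numpy as np
import pytest

from onhvol import BMRepresentation, PhantomParams, make_radial_phantom
from onhvol.types import REQUIRED_ANGLES, SegmentedBScan


@pytest.fixture(scope="session")
def swollen_params() -> PhantomParams:
    """Mildly swollen nerve head with posterior BM bow (package defaults)."""
    return PhantomParams(bump_amp_mm=0.5, bump_sigma_mm=0.8, bm_bow_mm=0.1)


@pytest.fixture(scope="session")
def swollen_scan_set(swollen_params):
    return make_radial_phantom(swollen_params)


@pytest.fixture(params=["traditional", "estimated", "excluded"])
def representation(request) -> BMRepresentation:
    return BMRepresentation(mode=request.param)


def make_flat_scan(
    angle_deg: int = 0,
    n: int = 201,
    width_mm: float = 5.59,
    ilm_mm: float = 0.6,
    bm_mm: float = 0.9,
    opening_radius_mm: float = 0.75,
    scale_z_um: float = 3.87,
) -> SegmentedBScan:
    """Hand-built scan with flat boundaries and a central BM opening."""
    scale_x_um = width_mm * 1000.0 / (n - 1)
    x_mm = np.linspace(-width_mm / 2, width_mm / 2, n)
    ilm = np.full(n, ilm_mm * 1000.0 / scale_z_um)
    bm = np.full(n, bm_mm * 1000.0 / scale_z_um)
    ml = int(np.nonzero(x_mm <= -opening_radius_mm)[0][-1])
    mr = int(np.nonzero(x_mm >= opening_radius_mm)[0][0])
    bm[ml + 1 : mr] = np.nan
    return SegmentedBScan(
        angle_deg=angle_deg,
        x_px=np.arange(n, dtype=float),
        ilm_z_px=ilm,
        bm_z_px=bm,
        margin_left_idx=ml,
        margin_right_idx=mr,
        scale_x_um=scale_x_um,
        scale_z_um=scale_z_um,
    )


def make_flat_scan_sextet(**kwargs):
    return [make_flat_scan(angle_deg=a, **kwargs) for a in REQUIRED_ANGLES]
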