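import numpy as np
import pytest

from perimt.images import CellMask
from perimt.params import PixelCalibration
from perimt.synthetic import generate_cell_mask

CAL = PixelCalibration(pixel_size_um=0.1)


@pytest.fixture(scope="session")
def cal() -> PixelCalibration:
    return CAL


@pytest.fixture(scope="session")
def disk_cell() -> CellMask:
    """Disk of radius 10 µm in a 25.6 µm frame (0.1 µm pixels)."""
    return generate_cell_mask(
        shape="ellipse", size_um=(10.0, 10.0), calibration=CAL, seed=0,
        frame_um=(25.6, 25.6),
    )


@pytest.fixture(scope="session")
def small_cell() -> CellMask:
    """Smaller ellipse for fast render tests."""
    return generate_cell_mask(
        shape="ellipse", size_um=(6.0, 5.0), calibration=CAL, seed=3,
        frame_um=(16.0, 16.0),
    )


@pytest.fixture(scope="session")
def irregular_cell() -> CellMask:
    """Roughened boundary, for stress/oracle tests."""
    return generate_cell_mask(
        shape="smoothed_polygon", size_um=(8.0, 7.0), calibration=CAL, seed=7,
        frame_um=(22.4, 22.4), roughness=0.08,
    )
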