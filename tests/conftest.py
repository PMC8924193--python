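import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mxifseg.raster_core import IntensityRaster
from mxifseg.synthetic_mxif import SynthConfig, generate_roi


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def packed_roi():
    """Noiseless fully-packed synthetic ROI (cells tile the frame)."""
    cfg = SynthConfig(frame=(128, 128), n_cells=32, cell_radius=10, tissue="full", seed=0)
    return generate_roi(cfg)


@pytest.fixture
def small_roi():
    """Small packed ROI for model-training tests."""
    cfg = SynthConfig(frame=(64, 64), n_cells=8, cell_radius=10, tissue="full", seed=3)
    return generate_roi(cfg)


def raster8(arr) -> IntensityRaster:
    return IntensityRaster(np.asarray(arr, dtype=np.uint8), bit_depth=8)


def raster16(arr) -> IntensityRaster:
    return IntensityRaster(np.asarray(arr, dtype=np.uint16), bit_depth=16)
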