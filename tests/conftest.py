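import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pettex.image import TumorVOI, voi_from_mask
from pettex.matrices import QuantizedVOI
from pettex.phantoms import fixture_spec, generate_phantom
from pettex.segmentation import BoundingVolume, extract_voi, segment_flab


@pytest.fixture(scope="session")
def fixture_phantom():
    """The reference phantom: 6 mm sphere, 1.2 mm FWHM, 5% noise, seed 7."""
    return generate_phantom(fixture_spec(seed=7))


@pytest.fixture(scope="session")
def fixture_voi(fixture_phantom):
    """Ground-truth VOI of the reference phantom (segmentation bypassed)."""
    return voi_from_mask(fixture_phantom.image, fixture_phantom.truth_mask)


@pytest.fixture(scope="session")
def fixture_segmented_voi(fixture_phantom):
    bv = BoundingVolume(grid=fixture_phantom.image)
    return extract_voi(segment_flab(bv), bv)


def voi_from_values(values, spacing: float = 1.0, shape=None) -> TumorVOI:
    """Line VOI (1 x 1 x n) with the given uptake values."""
    values = np.asarray(values, dtype=float)
    coords = np.array([(0, 0, k) for k in range(len(values))])
    return TumorVOI(coords=coords, values=values, spacing=spacing)


def qvoi_from_grid(grid: np.ndarray, ng: int, spacing: float = 1.0) -> QuantizedVOI:
    """Wrap a dense bin grid (0 = outside) as a QuantizedVOI."""
    coords = np.argwhere(grid > 0)
    bins = grid[grid > 0].astype(int)
    return QuantizedVOI(coords=coords, bins=bins, Ng=ng,
                        bin_edges=np.linspace(0, 1, ng + 1), spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
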