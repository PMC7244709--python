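import numpy as np
import pytest

from macrogen.filters import GeoSequence, RangePolygon
from macrogen.projection import behrmann_inverse


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def square_range(species_id="S0000", x0=-500_000.0, y0=-500_000.0,
                 size=1_000_000.0, presence=1, origin=1):
    """Axis-aligned square polygon given in projected metres, stored as
    lon/lat vertices (exact under the cylindrical projection)."""
    xs = [x0, x0 + size, x0 + size, x0, x0]
    ys = [y0, y0, y0 + size, y0 + size, y0]
    lons, lats = behrmann_inverse(np.array(xs), np.array(ys))
    ring = list(zip(lons.tolist(), lats.tolist()))
    return RangePolygon(species_id=species_id, rings=[ring],
                        presence=presence, origin=origin)


def geoseq(seq_id="q1", species="S0000", bases="ACGT", lon=0.0, lat=0.0):
    return GeoSequence(seq_id, species, bases, lon, lat)


@pytest.fixture
def unit_square_range():
    return square_range()
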