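import numpy as np
import pytest

from dmscape import Extent, SiteMap, make_extent

PAPER_AREA = 7237.60
PAPER_MAX_DIST = 123.2
PAPER_DENSITY = 5000 / PAPER_AREA


@pytest.fixture(scope="session")
def paper_extent() -> Extent:
    return make_extent(PAPER_AREA, PAPER_MAX_DIST)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150422)


@pytest.fixture(scope="session")
def small_sitemap() -> SiteMap:
    """200 uniform sites on a 30x20 rectangle, fixed seed."""
    from dmscape import generate_sites

    return generate_sites(200, Extent(30.0, 20.0), seed=7)
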