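"""Shared fixtures: canonical rendered cells, reused across test modules.

Rendering a cell costs a few hundred ms, so the canonical Front- and
Side-view cells are session-scoped; tests that need bespoke geometry build
their own specs.
"""

import numpy as np
import pytest

from spindlequant.synthetic import (
    cosine_profile,
    front_view_cell,
    make_mitotic_cell,
    side_view_cell,
)


@pytest.fixture(scope="session")
def front_cell():
    """Front-view cell at 17 deg with 5 apical / 6 basal astrals."""
    rng = np.random.default_rng(101)
    spec = front_view_cell(
        rng,
        plate_angle_deg=17.0,
        n_apical=5,
        n_basal=6,
        n_central=3,
        profile_fn=cosine_profile(1.0, 0.5),
    )
    return make_mitotic_cell(spec, seed=101)


@pytest.fixture(scope="session")
def side_cell():
    """Side-view cell with the full 5 apical / 6 basal / 9 central census."""
    rng = np.random.default_rng(202)
    spec = side_view_cell(rng, n_apical=5, n_basal=6, n_central=9)
    return make_mitotic_cell(spec, seed=202)


@pytest.fixture(scope="session")
def noisy_side_cell():
    """Side-view cell with Gaussian noise at 10% of the rod level."""
    rng = np.random.default_rng(303)
    spec = side_view_cell(rng, n_apical=4, n_basal=5, n_central=6, noise=(12.0, None))
    return make_mitotic_cell(spec, seed=303)
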