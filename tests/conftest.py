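import warnings

import pytest

from motormetrics import synthetic as syn


@pytest.fixture(scope="session")
def variant_fixtures():
    """Synthetic coordinate fixtures for all six neck-linker variants."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, bonds in syn.VARIANT_BOND_ARRAYS.items():
            out[name] = syn.build_hbond_fixture(syn.BondFixtureSpec(bonds=bonds))
    return out


@pytest.fixture
def noiseless_staircase():
    """A clean 4-step bleaching staircase: 180 -> 135 -> 90 -> 45 -> 0."""
    import numpy as np

    from motormetrics import IntensityTrace

    times = np.arange(0.0, 50.0)
    levels = np.select(
        [times < 10, times < 20, times < 30, times < 40],
        [180.0, 135.0, 90.0, 45.0],
        default=0.0,
    )
    return IntensityTrace("clean", times, levels)
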