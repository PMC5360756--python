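from __future__ import annotations

import numpy as np
import pytest

from clovermark.formats import BandMatrix


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170322)


def band_matrix_from_profiles(profiles: dict[str, set[str]], marker: str = "m1") -> BandMatrix:
    """Build a one-marker BandMatrix from variety -> band-set profiles."""
    varieties = tuple(profiles)
    bands = sorted(set().union(*profiles.values())) or ["band_01"]
    presence = {
        marker: {
            band: {v: int(band in profiles[v]) for v in varieties} for band in bands
        }
    }
    return BandMatrix(varieties=varieties, markers=(marker,), presence=presence)


@pytest.fixture
def three_variety_bands() -> BandMatrix:
    """Profiles {a,b}, {a}, {c}: jaccard distances 0.5 / 1 / 1."""
    return band_matrix_from_profiles(
        {"v1": {"a", "b"}, "v2": {"a"}, "v3": {"c"}}
    )
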