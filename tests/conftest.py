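import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import woodnir as wn

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectra(n=8, p=20, rng=None, start=9000.0, step=-10.0, ec=None, angle=None):
    """Random SpectraSet on a uniform descending axis."""
    rng = rng or np.random.default_rng(0)
    wavenumbers = start + step * np.arange(p)
    absorbance = rng.normal(0.5, 0.1, size=(n, p))
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "core_id": [f"c{i // 2}" for i in range(n)],
            "ec": rng.uniform(1, 16, n) if ec is None else np.asarray(ec, float),
            "angle": rng.choice([0.0, 90.0], n) if angle is None else np.asarray(angle, float),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return wn.SpectraSet(wavenumbers=wavenumbers, absorbance=absorbance,
                         sample_ids=ids, meta=meta)


@pytest.fixture
def small_set(rng):
    return make_spectra(rng=rng)
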