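"""Shared fixtures.

The leave-one-out experiments are the expensive part of the suite; they
are computed once per session and shared by every test that consumes
them (recovery thresholds, EM monotonicity, posterior normalization).
"""

from __future__ import annotations

import numpy as np
import pytest

from malfseg.evaluation import leave_one_out_detailed
from malfseg.phantoms import PhantomSpec, make_base_phantom, make_phantom_set


@pytest.fixture(scope="session")
def highfield_spec() -> PhantomSpec:
    return PhantomSpec.highfield()


@pytest.fixture(scope="session")
def lowfield_spec() -> PhantomSpec:
    return PhantomSpec.lowfield()


@pytest.fixture(scope="session")
def base_phantom(highfield_spec):
    return make_base_phantom(highfield_spec)


@pytest.fixture(scope="session")
def loo_highfield(highfield_spec):
    """Six-phantom leave-one-out, high-contrast preset, seeds 0-5."""
    atlases = make_phantom_set(6, highfield_spec, first_seed=0)
    return leave_one_out_detailed(atlases)


@pytest.fixture(scope="session")
def loo_lowfield(lowfield_spec):
    """Six-phantom leave-one-out, low-contrast preset, seeds 0-5."""
    atlases = make_phantom_set(6, lowfield_spec, first_seed=0)
    return leave_one_out_detailed(atlases)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
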