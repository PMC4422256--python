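"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from dyssync.phantom import dyssynchronous_params, generate_phantom, synchronous_params


@pytest.fixture(scope="session")
def dys_truth():
    """Dyssynchronous (LBBB-like) phantom, 10 phases: the standard test subject."""
    return generate_phantom(dyssynchronous_params(n_phases=10))


@pytest.fixture(scope="session")
def sync_truth():
    """Synchronous phantom, 10 phases (all delays zero, SDI = 0)."""
    return generate_phantom(synchronous_params(n_phases=10))


@pytest.fixture(scope="session")
def split_truth():
    """8/8 segments delayed 0 / 100 ms over a 1000 ms cycle, 30 phases.

    The delayed half is the angularly coherent free wall (the LBBB-like
    pattern), so the two activation groups occupy disjoint sectors at
    every level of the ventricle.
    """
    return generate_phantom(dyssynchronous_params(delay_ms=100.0))


@pytest.fixture(scope="session")
def ed_geom(sync_truth):
    """End-diastolic LV geometry of the synchronous phantom."""
    return sync_truth.geometry_per_phase[0]
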