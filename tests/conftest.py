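"""Shared fixtures.

The expensive session fixtures synthesize full displacement fields at
the analysis sampling rate (2 kHz, 3 cardiac cycles, 50x32-node tubes);
everything else runs on much smaller geometries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from vaviq.synthetic import (
    GROUP_PRESETS,
    generate_wall_motion,
    make_cohort,
    make_tube,
)


@pytest.fixture(scope="session")
def tube():
    """Default-resolution tube: 50 rings x 32 nodes, r=3.5 mm, L=30 mm."""
    return make_tube()


@pytest.fixture(scope="session")
def small_tube():
    return make_tube(radius_mm=3.0, length_mm=30.0, n_axial=31, n_circ=16)


@pytest.fixture(scope="session")
def full_cohort():
    """Six-patient synthetic cohort (2 patency / 2 stenosis / 2 dilatation)
    with calibrated displacement fields at 2 kHz, 3 cycles."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_cohort(n_per_group=2, seed=1234)


@pytest.fixture(scope="session")
def preset_patients():
    """One patient per group generated at the *preset* targets (no
    between-patient draw), for spectral-regime checks."""
    mesh, cl = make_tube()
    seeds = {"patency": 20240, "stenosis": 20241, "dilatation": 20242}
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, preset in GROUP_PRESETS.items():
            out[name] = (
                mesh,
                cl,
                generate_wall_motion(mesh, cl, preset, seed=seeds[name]),
            )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
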