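"""Shared fixtures: reduced-size phantoms and cohorts.

Everything is generated at run time; reduced grids (e.g. 32 x 128 x 256)
keep the suite fast while preserving the 3x3-block geometry ((dim - 2)
divisible by 3) and the 8-layer anatomy.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from muroct.io import VolumeMeta
from muroct.phantom import PhantomSpec, generate_phantom

REDUCED_SHAPE = (32, 128, 256)


@pytest.fixture(scope="session")
def wt_spec() -> PhantomSpec:
    return PhantomSpec.for_group("WT")


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Zero-noise wild-type phantom spec."""
    return PhantomSpec.for_group("WT", speckle_sigma=0.0)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    """(volume, truth) of a zero-noise reduced phantom, OD, 1 month."""
    meta = VolumeMeta(eye="OD", age_months=1, group="WT", animal_id="p0")
    return generate_phantom(clean_spec, meta, seed=11, shape=REDUCED_SHAPE)


@pytest.fixture(scope="session")
def speckled_phantom(wt_spec):
    meta = VolumeMeta(eye="OD", age_months=1, group="WT", animal_id="p1")
    return generate_phantom(wt_spec, meta, seed=12, shape=REDUCED_SHAPE)


def brute_force_cuts(scores: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive search over every monotone cut vector for one A-scan.

    Returns (best objective, lexicographically smallest optimal cuts).
    Feasible only for tiny instances (n_samples <= ~10, few classes).
    """
    n, k = scores.shape
    best_val, best_cuts = -np.inf, None
    for cuts in itertools.combinations_with_replacement(range(n + 1), k - 1):
        lab = np.searchsorted(np.array(cuts), np.arange(n), side="right")
        val = scores[np.arange(n), lab].sum()
        if val > best_val + 1e-12:
            best_val, best_cuts = val, cuts
    return best_val, np.array(best_cuts)
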