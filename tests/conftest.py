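"""Shared fixtures: coarse phantoms and small influence sets so the
default suite stays fast; everything generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from arcplan.dose import BixelGrid, KernelConfig, assemble_influence
from arcplan.fluence import ObjectiveSpec
from arcplan.machine import DeliveryConstraints, MLCSpec, build_arc_trajectory
from arcplan.phantom import make_water_phantom


@pytest.fixture(scope="session")
def mlc() -> MLCSpec:
    return MLCSpec()


@pytest.fixture(scope="session")
def constraints() -> DeliveryConstraints:
    return DeliveryConstraints()


@pytest.fixture(scope="session")
def kernel() -> KernelConfig:
    return KernelConfig()


@pytest.fixture(scope="session")
def coarse_phantom():
    """10 mm voxel water phantom (fast; 30x30x20 grid)."""
    return make_water_phantom(spacing=10.0)


@pytest.fixture(scope="session")
def phantom_5mm():
    return make_water_phantom(spacing=5.0)


@pytest.fixture(scope="session")
def bixels(mlc) -> BixelGrid:
    return BixelGrid.centered(mlc)


@pytest.fixture(scope="session")
def small_arc():
    return build_arc_trajectory(1, [3], 5.0)


@pytest.fixture(scope="session")
def small_influence(small_arc, bixels, coarse_phantom, kernel):
    return assemble_influence(small_arc.control_points, bixels, coarse_phantom,
                              kernel)


@pytest.fixture(scope="session")
def phantom_objective() -> ObjectiveSpec:
    return ObjectiveSpec.phantom_default(10.0)


def random_aperture(rng: np.random.Generator, mlc: MLCSpec,
                    open_prob: float = 0.7):
    """Random (possibly rule-violating) aperture within the travel range."""
    from arcplan.plans import Aperture

    n = mlc.n_leaf_pairs
    left = np.zeros(n)
    right = np.zeros(n)
    for k in range(n):
        if rng.random() < open_prob:
            a, b = np.sort(rng.uniform(-mlc.travel_range, mlc.travel_range, 2))
            left[k], right[k] = a, b
    return Aperture(left, right, float(rng.uniform(0, 100)))
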