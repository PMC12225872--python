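import numpy as np
import pytest

from ngm.model import NGMParams, Representation
from ngm.world import (
    TIER_BASIC,
    TIER_IDIOSYNCRATIC,
    TIER_SUBORDINATE,
    TIER_SUPERORDINATE,
    FeatureSpace,
    HierarchyConfig,
    WorldObject,
    make_world,
)


@pytest.fixture(scope="session")
def world():
    """Default experiment world: 3 classes x 3 basics x 3 subs, 2
    idiosyncratic features per object."""
    return make_world(HierarchyConfig(), seed=7)


@pytest.fixture(scope="session")
def noidio_world():
    """World without idiosyncratic features: objects of the same subordinate
    category are featurally identical, as in the worked toy example."""
    return make_world(HierarchyConfig(n_idiosyncratic=0), seed=11)


def _toy_object(space, name, bits):
    return WorldObject(id=name, bits=np.array(bits, dtype=float), space=space)


@pytest.fixture(scope="session")
def table4():
    """The published worked example: a four-feature world, a stored
    representation (A:0.3, B:0.8, C:0.3, D:0), and four test objects."""
    space = FeatureSpace(
        features=("A", "B", "C", "D"),
        tiers={
            "A": TIER_SUBORDINATE,
            "B": TIER_BASIC,
            "C": TIER_SUPERORDINATE,
            "D": TIER_IDIOSYNCRATIC,
        },
    )
    rep = Representation.from_mapping(space, {"A": 0.3, "B": 0.8, "C": 0.3})
    objects = {
        "Bee": _toy_object(space, "Bee", [0, 0, 1, 0]),
        "Dalmatian": _toy_object(space, "Dalmatian", [1, 1, 1, 0]),
        "Poodle": _toy_object(space, "Poodle", [0, 1, 1, 0]),
        "Truck": _toy_object(space, "Truck", [0, 0, 0, 1]),
    }
    return space, rep, objects


@pytest.fixture
def deterministic_basic_params():
    """sigma = 0, mu_low = 0, mu_high = 1: only the basic-tier feature is
    ever stored, with weight exactly 1."""
    return NGMParams.from_values(
        mu_high=1.0, mu_low=0.0, sigma=0.0,
        distance_threshold=0.5, incompatibility_threshold=0.8,
    )
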