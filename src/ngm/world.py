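"""Synthetic hierarchical stimulus worlds and the 24-item generalization test grid.

Objects live in a three-tier taxonomy (subordinate < basic < superordinate,
e.g. dalmatian < dog < animal).  Every object carries exactly one feature from
each taxonomic tier plus a configurable number of idiosyncratic features that
belong to it alone.  The test grid mirrors the classic novel-noun
generalization paradigm: 3 superordinate classes x 8 objects, where relative
to a designated training exemplar each class contributes 2 subordinate
matches, 2 basic-level-only matches and 4 superordinate-only matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIER_SUPERORDINATE",
    "TIER_BASIC",
    "TIER_SUBORDINATE",
    "TIER_IDIOSYNCRATIC",
    "LEVEL_SUB",
    "LEVEL_BASIC",
    "LEVEL_SUPER",
    "LEVEL_OTHER",
    "HierarchyConfig",
    "FeatureSpace",
    "WorldObject",
    "TestGrid",
    "World",
    "build_feature_space",
    "make_test_grid",
    "make_training_set",
    "make_world",
    "world_to_frame",
]

TIER_SUPERORDINATE = "superordinate"
TIER_BASIC = "basic"
TIER_SUBORDINATE = "subordinate"
TIER_IDIOSYNCRATIC = "idiosyncratic"
TIERS = (TIER_SUPERORDINATE, TIER_BASIC, TIER_SUBORDINATE, TIER_IDIOSYNCRATIC)

# Generalization levels of a grid object relative to a training exemplar.
LEVEL_SUB = "subordinate-match"
LEVEL_BASIC = "basic-only"
LEVEL_SUPER = "superordinate-only"
LEVEL_OTHER = "other-class"

GRID_CLASSES = 3
GRID_PER_CLASS = 8
GRID_SUB_MATCHES = 2
GRID_BASIC_ONLY = 2
GRID_SUPER_ONLY = 4
#: number of extra training objects a full world needs beyond the grid
#: (anchor + 2 subordinate sibs + 2 basic sibs + 2 superordinate sibs)
N_TRAINING_OBJECTS = 7


@dataclass(frozen=True)
class HierarchyConfig:
    """Shape of the synthetic taxonomy.

    The defaults give the smallest world that supports all seven training
    configurations: basic-level training needs three *distinct* subordinates
    within one basic category, and superordinate training three distinct
    basic categories within one class.
    """

    n_classes: int = 3
    n_basic: int = 3            # basic categories per class
    n_subordinate: int = 3      # subordinate categories per basic
    n_idiosyncratic: int = 2    # idiosyncratic features per object
    idio_pool: int | None = None  # total idiosyncratic features; None -> sized for a full world

    def __post_init__(self):
        for name in ("n_classes", "n_basic", "n_subordinate"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_subordinate < 2:
            raise ValueError("need >= 2 subordinates per basic category")
        if self.n_idiosyncratic < 0:
            raise ValueError("n_idiosyncratic must be >= 0")

    @property
    def resolved_idio_pool(self) -> int:
        if self.idio_pool is not None:
            return self.idio_pool
        n_objects = GRID_CLASSES * GRID_PER_CLASS + N_TRAINING_OBJECTS
        return self.n_idiosyncratic * n_objects


class FeatureSpace:
    """Inventory of binary features, their salience tier and the conflict relation.

    ``incompatible`` is a symmetric, irreflexive relation over feature pairs:
    no object can possess both members of a pair, and a represented feature
    sampled above the semantic-incompatibility threshold blocks its conflicts
    from entering a representation.
    """

    def __init__(
        self,
        features: Sequence[str],
        tiers: Mapping[str, str],
        incompatible: Iterable[tuple[str, str]] = (),
        idio_order: Sequence[str] | None = None,
    ):
        self.features: tuple[str, ...] = tuple(features)
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature identifiers")
        self._index = {f: i for i, f in enumerate(self.features)}
        missing = [f for f in self.features if f not in tiers]
        if missing:
            raise ValueError(f"features without a tier: {missing}")
        bad = [f for f in self.features if tiers[f] not in TIERS]
        if bad:
            raise ValueError(f"unknown tier for features: {bad}")
        self.tiers: dict[str, str] = {f: tiers[f] for f in self.features}

        pairs = set()
        for a, b in incompatible:
            if a == b:
                raise ValueError(f"incompatibility must be irreflexive: {a!r}")
            if a not in self._index or b not in self._index:
                raise ValueError(f"unknown feature in incompatible pair ({a!r}, {b!r})")
            pairs.add((min(a, b), max(a, b)))
        self.incompatible: frozenset[tuple[str, str]] = frozenset(pairs)

        idio = [f for f in self.features if self.tiers[f] == TIER_IDIOSYNCRATIC]
        self.idio_order: tuple[str, ...] = tuple(idio_order) if idio_order is not None else tuple(idio)
        if set(self.idio_order) != set(idio):
            raise ValueError("idio_order must be a permutation of the idiosyncratic features")

        self._build_components()

    # -- derived structure -------------------------------------------------

    def _build_components(self) -> None:
        """Connected components of the conflict graph (scipy), flagged clique or not."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = len(self.features)
        self.pair_indices = np.array(
            [(self._index[a], self._index[b]) for a, b in sorted(self.incompatible)],
            dtype=np.intp,
        ).reshape(-1, 2)
        if len(self.pair_indices) == 0:
            self.components: list[np.ndarray] = []
            self.components_are_cliques = True
            return
        rows = self.pair_indices[:, 0]
        cols = self.pair_indices[:, 1]
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        comps = []
        for c in range(n_comp):
            idx = np.flatnonzero(labels == c)
            if len(idx) > 1:
                comps.append(idx)
        self.components = comps
        # a component with k nodes is a clique iff it contains k(k-1)/2 pairs
        clique = True
        for idx in comps:
            members = set(idx.tolist())
            within = sum(1 for a, b in self.pair_indices if a in members and b in members)
            if within != len(idx) * (len(idx) - 1) // 2:
                clique = False
        self.components_are_cliques = clique

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.features)

    def index_of(self, feature: str) -> int:
        return self._index[feature]

    def tier_of(self, feature: str) -> str:
        return self.tiers[feature]

    @property
    def tier_array(self) -> np.ndarray:
        return np.array([self.tiers[f] for f in self.features], dtype=object)

    @property
    def basic_mask(self) -> np.ndarray:
        return np.array([self.tiers[f] == TIER_BASIC for f in self.features])

    def features_of_tier(self, tier: str) -> list[str]:
        return [f for f in self.features if self.tiers[f] == tier]

    def is_incompatible(self, a: str, b: str) -> bool:
        return (min(a, b), max(a, b)) in self.incompatible

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureSpace)
            and self.features == other.features
            and self.tiers == other.tiers
            and self.incompatible == other.incompatible
            and self.idio_order == other.idio_order
        )


@dataclass(frozen=True)
class WorldObject:
    """One stimulus: a binary feature bundle plus its taxonomy labels."""

    id: str
    bits: np.ndarray
    sub_label: str | None = None
    basic_label: str | None = None
    class_label: str | None = None
    space: FeatureSpace | None = None

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.float64)
        if not np.isin(bits, (0.0, 1.0)).all():
            raise ValueError(f"object {self.id!r} has non-binary feature values")
        object.__setattr__(self, "bits", bits)
        if self.space is not None and len(bits) != len(self.space):
            raise ValueError(
                f"object {self.id!r} has {len(bits)} bits for a "
                f"{len(self.space)}-feature space"
            )

    @property
    def properties(self) -> dict[str, int]:
        """Mapping feature -> 0/1 (requires an attached space)."""
        if self.space is None:
            raise ValueError("object has no attached FeatureSpace")
        return {f: int(self.bits[i]) for i, f in enumerate(self.space.features)}

    def feature_set(self) -> set[str]:
        if self.space is None:
            raise ValueError("object has no attached FeatureSpace")
        return {f for i, f in enumerate(self.space.features) if self.bits[i] > 0}

    def validate_consistency(self) -> None:
        """Raise if two possessed features are incompatible."""
        if self.space is None:
            raise ValueError("object has no attached FeatureSpace")
        on = self.feature_set()
        for a, b in self.space.incompatible:
            if a in on and b in on:
                raise ValueError(f"object {self.id!r} possesses incompatible pair ({a}, {b})")


@dataclass(frozen=True)
class TestGrid:
    """The fixed 24-object test array: 3 classes x 8 objects."""

    objects: tuple[WorldObject, ...]
    space: FeatureSpace

    def __post_init__(self):
        if len(self.objects) != GRID_CLASSES * GRID_PER_CLASS:
            raise ValueError(f"grid must have {GRID_CLASSES * GRID_PER_CLASS} objects")

    @property
    def bits_matrix(self) -> np.ndarray:
        return np.stack([o.bits for o in self.objects])

    def level_of(self, training: WorldObject, obj: WorldObject) -> str:
        if obj.sub_label == training.sub_label:
            return LEVEL_SUB
        if obj.basic_label == training.basic_label:
            return LEVEL_BASIC
        if obj.class_label == training.class_label:
            return LEVEL_SUPER
        return LEVEL_OTHER

    def levels_for(self, training: WorldObject) -> np.ndarray:
        """Level of every grid object relative to ``training`` (object array)."""
        return np.array([self.level_of(training, o) for o in self.objects], dtype=object)

    def level_masks(self, training: WorldObject) -> dict[str, np.ndarray]:
        levels = self.levels_for(training)
        return {lv: levels == lv for lv in (LEVEL_SUB, LEVEL_BASIC, LEVEL_SUPER, LEVEL_OTHER)}


@dataclass(frozen=True)
class World:
    """A complete experiment world: space, grid and the training exemplars."""

    config: HierarchyConfig
    space: FeatureSpace
    grid: TestGrid
    training_sets: Mapping[str, tuple[WorldObject, ...]]
    seed: int | None = None

    @property
    def anchor(self) -> WorldObject:
        return self.training_sets["single"][0]


# ---------------------------------------------------------------------------
# construction

def _super_feature(c: int) -> str:
    return f"super:C{c}"


def _basic_feature(c: int, b: int) -> str:
    return f"basic:C{c}/B{b}"


def _sub_feature(c: int, b: int, s: int) -> str:
    return f"sub:C{c}/B{b}/S{s}"


def build_feature_space(
    config: HierarchyConfig = HierarchyConfig(),
    rng: np.random.Generator | int | None = None,
) -> FeatureSpace:
    """Build the feature inventory for a taxonomy.

    Sibling subordinate features (same basic parent) are pairwise
    incompatible, as are basic features of distinct basic categories: an
    object is a dalmatian *or* a poodle, a dog *or* a chair.  Deterministic
    given the rng seed (the seed only permutes idiosyncratic-feature
    allocation order).
    """
    rng = np.random.default_rng(rng)
    cfg = config
    features: list[str] = []
    tiers: dict[str, str] = {}
    for c in range(cfg.n_classes):
        f = _super_feature(c)
        features.append(f)
        tiers[f] = TIER_SUPERORDINATE
    basics: list[str] = []
    for c in range(cfg.n_classes):
        for b in range(cfg.n_basic):
            f = _basic_feature(c, b)
            features.append(f)
            tiers[f] = TIER_BASIC
            basics.append(f)
    sub_groups: list[list[str]] = []
    for c in range(cfg.n_classes):
        for b in range(cfg.n_basic):
            group = []
            for s in range(cfg.n_subordinate):
                f = _sub_feature(c, b, s)
                features.append(f)
                tiers[f] = TIER_SUBORDINATE
                group.append(f)
            sub_groups.append(group)
    idio = [f"idio:{i}" for i in range(cfg.resolved_idio_pool)]
    for f in idio:
        features.append(f)
        tiers[f] = TIER_IDIOSYNCRATIC

    pairs: list[tuple[str, str]] = []
    for group in sub_groups:
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                pairs.append((group[i], group[j]))
    for i in range(len(basics)):
        for j in range(i + 1, len(basics)):
            pairs.append((basics[i], basics[j]))

    order = [idio[i] for i in rng.permutation(len(idio))] if idio else []
    return FeatureSpace(features, tiers, pairs, idio_order=order)


def _make_object(
    space: FeatureSpace,
    obj_id: str,
    c: int,
    b: int,
    s: int,
    idio_features: Sequence[str],
) -> WorldObject:
    bits = np.zeros(len(space), dtype=np.float64)
    on = [_super_feature(c), _basic_feature(c, b), _sub_feature(c, b, s), *idio_features]
    for f in on:
        bits[space.index_of(f)] = 1.0
    return WorldObject(
        id=obj_id,
        bits=bits,
        sub_label=f"C{c}/B{b}/S{s}",
        basic_label=f"C{c}/B{b}",
        class_label=f"C{c}",
        space=space,
    )


def _idio_slice(space: FeatureSpace, start: int, k: int) -> tuple[list[str], int]:
    if k == 0:
        return [], start
    if start + k > len(space.idio_order):
        raise ValueError(
            f"idiosyncratic pool exhausted: need {k} features from offset {start}, "
            f"pool has {len(space.idio_order)}"
        )
    return list(space.idio_order[start : start + k]), start + k


def _infer_shape(space: FeatureSpace) -> tuple[int, int, int]:
    """(n_classes, n_basic per class, n_sub per basic) from feature names."""
    supers = space.features_of_tier(TIER_SUPERORDINATE)
    basics = space.features_of_tier(TIER_BASIC)
    subs = space.features_of_tier(TIER_SUBORDINATE)
    n_classes = len(supers)
    if n_classes == 0 or len(basics) % n_classes or len(subs) % len(basics):
        raise ValueError("feature space does not have a regular taxonomy")
    return n_classes, len(basics) // n_classes, len(subs) // len(basics)


def make_test_grid(
    space: FeatureSpace,
    n_idiosyncratic: int = 2,
    idio_start: int = 0,
) -> TestGrid:
    """Build the fixed 24-object test grid.

    Per class: 2 objects of the anchor subordinate, 2 objects of a sibling
    subordinate (basic-only matches), and 4 objects spread over the other
    basic categories (superordinate-only matches).  Idiosyncratic features
    are allocated uniquely per object from the space's (seed-permuted) pool.
    """
    n_classes, n_basic, n_sub = _infer_shape(space)
    if n_classes < GRID_CLASSES:
        raise ValueError(f"grid needs >= {GRID_CLASSES} classes, space has {n_classes}")
    if n_basic < 2 or n_sub < 2:
        raise ValueError("grid needs >= 2 basic categories per class and >= 2 subs per basic")
    pool_needed = n_idiosyncratic * GRID_CLASSES * GRID_PER_CLASS
    if idio_start + pool_needed > len(space.idio_order):
        raise ValueError("idiosyncratic pool too small for the grid")

    objects: list[WorldObject] = []
    cursor = idio_start
    for c in range(GRID_CLASSES):
        spec_rows: list[tuple[int, int]] = []
        spec_rows += [(0, 0)] * GRID_SUB_MATCHES          # anchor subordinate
        spec_rows += [(0, 1)] * GRID_BASIC_ONLY           # sibling subordinate
        other_basics = [b for b in range(1, n_basic)]
        for i in range(GRID_SUPER_ONLY):                  # other basic categories
            spec_rows.append((other_basics[i % len(other_basics)], 0))
        for k, (b, s) in enumerate(spec_rows):
            idio, cursor = _idio_slice(space, cursor, n_idiosyncratic)
            objects.append(_make_object(space, f"grid:C{c}-{k}", c, b, s, idio))
    grid = TestGrid(tuple(objects), space)
    for obj in grid.objects:
        obj.validate_consistency()
    return grid


def make_training_set(
    space: FeatureSpace,
    level: str,
    n: int,
    n_idiosyncratic: int = 2,
    idio_start: int | None = None,
) -> tuple[WorldObject, ...]:
    """Training exemplars for one condition.

    n=1 is the single-exemplar baseline (the anchor object).  n=3 at
    ``subordinate`` shares the anchor sub_label; at ``basic`` uses three
    distinct subordinates of the anchor basic; at ``superordinate`` three
    distinct basic categories of the anchor class.  The first item is always
    the anchor, whose idiosyncratic features sit directly after the grid's in
    the pool, so training sets built from one space share their anchor.
    """
    n_classes, n_basic, n_sub = _infer_shape(space)
    if idio_start is None:
        idio_start = n_idiosyncratic * GRID_CLASSES * GRID_PER_CLASS
    if n == 1:
        idio, _ = _idio_slice(space, idio_start, n_idiosyncratic)
        return (_make_object(space, "train:anchor", 0, 0, 0, idio),)
    if n != 3:
        raise ValueError(f"n must be 1 or 3, got {n}")

    if level == "subordinate":
        rows = [(0, 0), (0, 0), (0, 0)]
        offsets = [0, 1, 2]
    elif level == "basic":
        if n_sub < 3:
            raise ValueError("basic-level training needs >= 3 subordinates per basic")
        rows = [(0, 0), (0, 1), (0, 2)]
        offsets = [0, 3, 4]
    elif level == "superordinate":
        if n_basic < 3:
            raise ValueError("superordinate training needs >= 3 basic categories per class")
        rows = [(0, 0), (1, 0), (2, 0)]
        offsets = [0, 5, 6]
    else:
        raise ValueError(f"unsupported training level {level!r}")

    items = []
    for k, ((b, s), off) in enumerate(zip(rows, offsets)):
        idio, _ = _idio_slice(space, idio_start + off * n_idiosyncratic, n_idiosyncratic)
        name = "train:anchor" if off == 0 else f"train:{level}-{k}"
        items.append(_make_object(space, name, 0, b, s, idio))
    return tuple(items)


def make_world(
    config: HierarchyConfig = HierarchyConfig(),
    seed: int | np.random.Generator | None = None,
) -> World:
    """Build a complete, self-consistent experiment world from one seed."""
    rng = np.random.default_rng(seed)
    space = build_feature_space(config, rng)
    grid = make_test_grid(space, n_idiosyncratic=config.n_idiosyncratic)
    k = config.n_idiosyncratic
    training_sets = {
        "single": make_training_set(space, "single", 1, n_idiosyncratic=k),
        "subordinate": make_training_set(space, "subordinate", 3, n_idiosyncratic=k),
        "basic": make_training_set(space, "basic", 3, n_idiosyncratic=k),
        "superordinate": make_training_set(space, "superordinate", 3, n_idiosyncratic=k),
    }
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return World(config=config, space=space, grid=grid, training_sets=training_sets,
                 seed=seed_val)


# ---------------------------------------------------------------------------
# serialization

def world_to_frame(world: World) -> pd.DataFrame:
    """One row per object: id, kind, labels, feature bitstring."""
    rows = []
    seen = set()

    def add(obj: WorldObject, kind: str):
        if obj.id in seen:
            return
        seen.add(obj.id)
        rows.append({
            "id": obj.id,
            "kind": kind,
            "class_label": obj.class_label,
            "basic_label": obj.basic_label,
            "sub_label": obj.sub_label,
            "bits": "".join(str(int(v)) for v in obj.bits),
        })

    for obj in world.grid.objects:
        add(obj, "grid")
    for level, items in world.training_sets.items():
        for obj in items:
            add(obj, f"training:{level}")
    return pd.DataFrame(rows)
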