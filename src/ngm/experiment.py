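"""Simulated-participant generalization experiments.

Each trial trains one simulated participant on a configuration (single
exemplar, or three exemplars at the subordinate / basic / superordinate
level, shown simultaneously or sequentially), then scores which of the 24
test-grid objects fall within the learned category.  Selections are scored
per generalization level relative to the anchor training exemplar: the grid
holds 2 subordinate matches, 2 basic-only matches and 4 superordinate-only
matches in the anchor's class, and each proportion is selections divided by
that fixed denominator.  Cross-class objects are evaluated for membership
like any other grid object but never enter the three scored proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import NGMParams, asymmetric_distances, run_presentation, sample_salience_matrix
from .world import LEVEL_BASIC, LEVEL_SUB, LEVEL_SUPER, World

__all__ = [
    "TrialConfig",
    "TrialResult",
    "GeneralizationProfile",
    "ALL_CONDITIONS",
    "TRAIN_CONDITIONS_DEFAULT",
    "run_trial",
    "simulate_condition",
    "run_suite",
]

LEVEL_DENOMS = {LEVEL_SUB: 2, LEVEL_BASIC: 2, LEVEL_SUPER: 4}
LEVEL_NAMES = ("subordinate", "basic", "superordinate")


@dataclass(frozen=True)
class TrialConfig:
    """One training regime.

    ``level`` is "single" (one exemplar; presentation is irrelevant and
    normalized to "simultaneous") or the taxonomic level shared by three
    exemplars.  Sequential trials repeat the item sequence ``n_loops``
    times in full.
    """

    level: str
    presentation: str = "simultaneous"
    n_items: int = 3
    n_loops: int = 2

    def __post_init__(self):
        if self.level not in ("single", "subordinate", "basic", "superordinate"):
            raise ValueError(f"unknown training level {self.level!r}")
        if self.level == "single":
            object.__setattr__(self, "n_items", 1)
            object.__setattr__(self, "presentation", "simultaneous")
        elif self.n_items != 3:
            raise ValueError("multi-exemplar conditions use n_items = 3")
        if self.presentation not in ("simultaneous", "sequential"):
            raise ValueError(f"unknown presentation {self.presentation!r}")
        if self.n_loops < 1:
            raise ValueError("n_loops must be >= 1")

    @classmethod
    def single(cls) -> "TrialConfig":
        return cls(level="single")

    @property
    def key(self) -> str:
        if self.level == "single":
            return "single"
        return f"{self.level}/{self.presentation}"


#: The seven conditions of the paradigm: one single-exemplar baseline plus
#: {subordinate, basic, superordinate} x {simultaneous, sequential}.
ALL_CONDITIONS: tuple[TrialConfig, ...] = (
    TrialConfig.single(),
    TrialConfig("subordinate", "simultaneous"),
    TrialConfig("subordinate", "sequential"),
    TrialConfig("basic", "simultaneous"),
    TrialConfig("basic", "sequential"),
    TrialConfig("superordinate", "simultaneous"),
    TrialConfig("superordinate", "sequential"),
)

#: Conditions used for parameter fitting (the rest are held out).
TRAIN_CONDITIONS_DEFAULT = ("single", "basic/simultaneous", "basic/sequential")


@dataclass(frozen=True)
class TrialResult:
    """One simulated participant: selected grid objects and the per-level
    selection proportions (denominators fixed at 2 / 2 / 4)."""

    config: TrialConfig
    selected: tuple[str, ...]
    proportions: tuple[float, float, float]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(LEVEL_NAMES, self.proportions))


@dataclass(frozen=True)
class GeneralizationProfile:
    """Mean and SD of the three selection proportions over participants."""

    condition: str
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    n_participants: int

    def __post_init__(self):
        for m in self.mean:
            if not (0.0 <= m <= 1.0) or not np.isfinite(m):
                raise ValueError(f"profile means must be finite and in [0, 1], got {self.mean}")
        if not np.all(np.isfinite(self.sd)):
            raise ValueError("profile SDs must be finite")


def _training_bits(config: TrialConfig, world: World) -> np.ndarray:
    key = "single" if config.level == "single" else config.level
    try:
        items = world.training_sets[key]
    except KeyError:
        raise ValueError(f"world has no training set for level {key!r}") from None
    if len(items) != config.n_items:
        raise ValueError(
            f"training set {key!r} has {len(items)} items, condition expects {config.n_items}"
        )
    return np.stack([o.bits for o in items])


def _simulate_proportions(
    config: TrialConfig,
    world: World,
    params: NGMParams,
    n_participants: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(P, 3) per-participant proportions and the (P, 24) membership matrix."""
    bits = _training_bits(config, world)
    sal = sample_salience_matrix(world.space, params.salience, rng, n_participants)
    W, _ = run_presentation(bits, sal, world.space, params,
                            presentation=config.presentation, n_loops=config.n_loops)
    D = asymmetric_distances(W, world.grid.bits_matrix)
    member = D <= params.distance_threshold
    anchor = world.training_sets["single" if config.level == "single" else config.level][0]
    masks = world.grid.level_masks(anchor)
    props = np.empty((n_participants, 3))
    for j, lv in enumerate((LEVEL_SUB, LEVEL_BASIC, LEVEL_SUPER)):
        props[:, j] = member[:, masks[lv]].sum(axis=1) / LEVEL_DENOMS[lv]
    return props, member


def run_trial(
    config: TrialConfig,
    world: World,
    params: NGMParams,
    rng: np.random.Generator | int | None = None,
) -> TrialResult:
    """Simulate a single participant and score their grid selections."""
    rng = np.random.default_rng(rng)
    props, member = _simulate_proportions(config, world, params, 1, rng)
    ids = tuple(o.id for o, m in zip(world.grid.objects, member[0]) if m)
    return TrialResult(config=config, selected=ids,
                       proportions=tuple(float(v) for v in props[0]))


def simulate_condition(
    config: TrialConfig,
    world: World,
    params: NGMParams,
    n_participants: int,
    rng: np.random.Generator | int | None = None,
) -> GeneralizationProfile:
    """Independent participants (fresh salience draws each), aggregated to
    mean and sample SD per level.  SDs are 0 when n_participants == 1."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(rng)
    props, _ = _simulate_proportions(config, world, params, n_participants, rng)
    mean = props.mean(axis=0)
    sd = props.std(axis=0, ddof=1) if n_participants > 1 else np.zeros(3)
    return GeneralizationProfile(
        condition=config.key,
        mean=tuple(float(v) for v in mean),
        sd=tuple(float(v) for v in sd),
        n_participants=n_participants,
    )


def run_suite(
    world: World,
    params: NGMParams,
    n_participants: int,
    rng: np.random.Generator | int | None = None,
    conditions: Sequence[TrialConfig] = ALL_CONDITIONS,
) -> dict[str, GeneralizationProfile]:
    """Run every condition on an independent substream; 7 conditions x 3
    levels = 21 output means for the full suite."""
    rng = np.random.default_rng(rng)
    streams = rng.spawn(len(conditions))
    return {
        cfg.key: simulate_condition(cfg, world, params, n_participants, stream)
        for cfg, stream in zip(conditions, streams)
    }


def condition_by_key(key: str) -> TrialConfig:
    for cfg in ALL_CONDITIONS:
        if cfg.key == key:
            return cfg
    raise KeyError(f"unknown condition key {key!r}")
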