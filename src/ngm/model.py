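"""The Naive Generalization Model proper.

A word's meaning is a gradient feature vector built from labeled exemplars:
for every feature present in the training set the learner samples a salience
value (basic-tier features from the elevated-mean Gaussian, everything else
from the default one), sums it once per exemplar possessing the feature, and
clips the stored weight at the ceiling of 1.0.  A feature sampled above the
semantic-incompatibility threshold blocks its conflicting features from
entering the representation.

Category membership of a test object is decided by an asymmetric distance:
only representation mass missing from the object counts,

    D(r, t) = sum_n max(0, r_n - t_n),

compared (non-strictly) against a fixed distance threshold.  Under sequential
presentation the representation formed from the first exemplar persists as
long as later exemplars are consistent (distance within threshold); each
consistent exposure only raises a confidence counter, while an inconsistent
exposure triggers a revision restricted to the features shared between the
old representation's support and the new exemplar.

Everything is implemented over (participants x features) arrays so that
thousands of simulated participants run as a handful of numpy operations;
the scalar functional API and the scikit-learn estimator are the
single-participant slice of the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .world import TIER_BASIC, FeatureSpace, WorldObject

__all__ = [
    "SalienceParams",
    "NGMParams",
    "Representation",
    "NaiveGeneralizationModel",
    "sample_salience",
    "extract_representation",
    "distance",
    "is_member",
    "update_sequential",
]


@dataclass(frozen=True)
class SalienceParams:
    """The two salience Gaussians.  They differ only in mean: ``mu_high``
    for basic-tier (elevated prominence) features, ``mu_low`` for all
    others; draws are clipped to [0, 1]."""

    mu_high: float = 0.8
    mu_low: float = 0.3
    sigma: float = 0.1

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.mu_low <= self.mu_high <= 1):
            raise ValueError("require 0 <= mu_low <= mu_high <= 1")


@dataclass(frozen=True)
class NGMParams:
    """Full parameterization: salience Gaussians, the category distance
    threshold, and the semantic-incompatibility threshold."""

    salience: SalienceParams = SalienceParams()
    distance_threshold: float = 1.0
    incompatibility_threshold: float = 0.8

    def __post_init__(self):
        if self.distance_threshold < 0:
            raise ValueError("distance_threshold must be >= 0")
        if not (0 <= self.incompatibility_threshold <= 1):
            raise ValueError("incompatibility_threshold must be in [0, 1]")

    @classmethod
    def from_values(cls, mu_high, mu_low, sigma, distance_threshold,
                    incompatibility_threshold) -> "NGMParams":
        return cls(
            salience=SalienceParams(mu_high=mu_high, mu_low=mu_low, sigma=sigma),
            distance_threshold=distance_threshold,
            incompatibility_threshold=incompatibility_threshold,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "mu_high": self.salience.mu_high,
            "mu_low": self.salience.mu_low,
            "sigma": self.salience.sigma,
            "distance_threshold": self.distance_threshold,
            "incompatibility_threshold": self.incompatibility_threshold,
        }


@dataclass
class Representation:
    """A learner's stored meaning: per-feature weights in [0, 1] plus a
    confidence counter.  ``salience`` caches the participant's once-per-word
    salience draws so revisions reuse them rather than redrawing."""

    space: FeatureSpace
    weights: np.ndarray
    confidence: int = 1
    salience: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.space):
            raise ValueError("weights length does not match feature space")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValueError("weights must lie in [0, 1]")

    @classmethod
    def from_mapping(cls, space: FeatureSpace, weights: dict[str, float],
                     confidence: int = 1) -> "Representation":
        w = np.zeros(len(space))
        for f, v in weights.items():
            w[space.index_of(f)] = v
        return cls(space=space, weights=w, confidence=confidence)

    def as_dict(self) -> dict[str, float]:
        return {f: float(self.weights[i]) for i, f in enumerate(self.space.features)}

    @property
    def support(self) -> set[str]:
        return {f for i, f in enumerate(self.space.features) if self.weights[i] > 0}


# ---------------------------------------------------------------------------
# vectorized core (participants x features)

def salience_means(space: FeatureSpace, salience: SalienceParams) -> np.ndarray:
    mu = np.full(len(space), salience.mu_low)
    mu[space.basic_mask] = salience.mu_high
    return mu


def sample_salience_matrix(
    space: FeatureSpace,
    salience: SalienceParams,
    rng: np.random.Generator,
    n_participants: int = 1,
) -> np.ndarray:
    """Once-per-word salience draws for ``n_participants`` learners,
    shape (P, F), clipped to [0, 1]."""
    mu = salience_means(space, salience)
    draws = rng.normal(loc=mu, scale=salience.sigma, size=(n_participants, len(space)))
    return np.clip(draws, 0.0, 1.0)


def _allowed_sequential(sal_row: np.ndarray, present: np.ndarray,
                        pair_indices: np.ndarray, threshold: float) -> np.ndarray:
    """Reference incompatibility filter: process present features in
    descending sampled salience (stable, so ties keep feature order); the
    first feature exceeding the threshold blocks its conflicts."""
    n = len(sal_row)
    allowed = present.copy()
    order = np.argsort(-sal_row, kind="stable")
    conflicts: dict[int, list[int]] = {}
    for a, b in pair_indices:
        conflicts.setdefault(int(a), []).append(int(b))
        conflicts.setdefault(int(b), []).append(int(a))
    blocked = np.zeros(n, dtype=bool)
    for i in order:
        if not present[i] or blocked[i]:
            continue
        if sal_row[i] > threshold:
            for j in conflicts.get(int(i), ()):
                blocked[j] = True
    return allowed & ~blocked


def incompatibility_mask(
    sal: np.ndarray,
    present: np.ndarray,
    space: FeatureSpace,
    threshold: float,
) -> np.ndarray:
    """Boolean (P, F) mask of features admitted past the incompatibility
    filter.  ``present`` may be (F,) or (P, F).

    When every conflict component is a clique (the generator's worlds: sibling
    subordinates, the set of basic categories) the descending-salience rule
    reduces to "if the most salient present member exceeds the threshold, keep
    only it" — computed vectorized.  Other graphs fall back to the literal
    sequential rule per participant.
    """
    sal = np.atleast_2d(sal)
    P, F = sal.shape
    if present.ndim == 1:
        present = np.broadcast_to(present, (P, F))
    allowed = np.array(np.broadcast_to(present, (P, F)), dtype=bool)
    if not space.components:
        return allowed

    if space.components_are_cliques:
        for idx in space.components:
            sub_present = allowed[:, idx]
            n_present = sub_present.sum(axis=1)
            rows = n_present > 1
            if not rows.any():
                continue
            sub_sal = np.where(sub_present, sal[:, idx], -np.inf)
            top = np.argmax(sub_sal, axis=1)
            topval = np.take_along_axis(sub_sal, top[:, None], axis=1)[:, 0]
            fire = rows & (topval > threshold)
            if not fire.any():
                continue
            keep = np.zeros_like(sub_present)
            keep[np.arange(P), top] = True
            new_sub = np.where(fire[:, None], sub_present & keep, sub_present)
            allowed[:, idx] = new_sub
        return allowed

    for p in range(P):
        allowed[p] = _allowed_sequential(sal[p], allowed[p], space.pair_indices, threshold)
    return allowed


def representation_weights(
    training_bits: np.ndarray,
    sal: np.ndarray,
    space: FeatureSpace,
    incompatibility_threshold: float,
) -> np.ndarray:
    """Representation weights (P, F) from co-present exemplars (k, F).

    Each feature's weight is its sampled salience summed once per exemplar
    possessing it, clipped at the 1.0 ceiling, zeroed if the incompatibility
    filter excludes it."""
    training_bits = np.atleast_2d(training_bits)
    counts = training_bits.sum(axis=0)
    present = counts > 0
    sal = np.atleast_2d(sal)
    allowed = incompatibility_mask(sal, present, space, incompatibility_threshold)
    return np.clip(sal * counts, 0.0, 1.0) * allowed


def asymmetric_distances(weights: np.ndarray, objects_bits: np.ndarray) -> np.ndarray:
    """Pairwise D(r, t) = sum_n max(0, r_n - t_n), shape (P, m).

    For binary objects and weights <= 1 this is sum(w) - W @ X^T (a feature
    the object possesses cancels its full weight, one it lacks costs it)."""
    W = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    X = np.atleast_2d(np.asarray(objects_bits, dtype=np.float64))
    if W.shape[1] != X.shape[1]:
        raise ValueError(f"feature-count mismatch: {W.shape[1]} vs {X.shape[1]}")
    binary = np.isin(X, (0.0, 1.0)).all()
    if binary and W.max(initial=0.0) <= 1.0:
        return W.sum(axis=1)[:, None] - W @ X.T
    return np.maximum(W[:, None, :] - X[None, :, :], 0.0).sum(axis=2)


def sequential_pass(
    W: np.ndarray,
    confidence: np.ndarray,
    sal: np.ndarray,
    exposure_bits: np.ndarray,
    space: FeatureSpace,
    params: NGMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One sequential exposure, vectorized over participants.

    Consistent rows (distance within threshold) keep their weights and gain
    confidence; inconsistent rows rebuild from the cached salience draws over
    the features shared between the old support and the new exemplar, with
    confidence reset to 1."""
    x = np.asarray(exposure_bits, dtype=np.float64)
    d = asymmetric_distances(W, x[None, :])[:, 0]
    ok = d <= params.distance_threshold
    confidence = np.where(ok, confidence + 1, 1)
    if ok.all():
        return W, confidence
    shared = (W > 0) & (x > 0)
    allowed = incompatibility_mask(sal, shared, space, params.incompatibility_threshold)
    W_rev = np.clip(sal, 0.0, 1.0) * shared * allowed
    W = np.where(ok[:, None], W, W_rev)
    return W, confidence


def run_presentation(
    items_bits: np.ndarray,
    sal: np.ndarray,
    space: FeatureSpace,
    params: NGMParams,
    presentation: str,
    n_loops: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Weights and confidence after a full training phase, (P, F) and (P,).

    Simultaneous: one-shot extraction over all co-present exemplars.
    Sequential: extraction from the first exemplar, then one consistency
    check per subsequent exposure across ``n_loops`` full passes; the
    representation is frozen when the loops end (the convergence point)."""
    items_bits = np.atleast_2d(items_bits)
    P = np.atleast_2d(sal).shape[0]
    if presentation == "simultaneous" or len(items_bits) == 1:
        W = representation_weights(items_bits, sal, space, params.incompatibility_threshold)
        return W, np.ones(P, dtype=np.int64)
    if presentation != "sequential":
        raise ValueError(f"unknown presentation {presentation!r}")
    W = representation_weights(items_bits[:1], sal, space, params.incompatibility_threshold)
    confidence = np.ones(P, dtype=np.int64)
    exposures = list(items_bits[1:]) + list(items_bits) * (n_loops - 1)
    for x in exposures:
        W, confidence = sequential_pass(W, confidence, sal, x, space, params)
    return W, confidence


# ---------------------------------------------------------------------------
# functional API (single participant)

def sample_salience(
    feature: str,
    tier: str,
    params: SalienceParams,
    rng: np.random.Generator,
) -> float:
    """One salience draw for a feature: Normal(mu_high, sigma) for the basic
    tier, Normal(mu_low, sigma) otherwise, clipped to [0, 1]."""
    mu = params.mu_high if tier == TIER_BASIC else params.mu_low
    return float(np.clip(rng.normal(mu, params.sigma), 0.0, 1.0))


def _check_same_space(rep: Representation, obj: WorldObject) -> None:
    if obj.space is not None and obj.space is not rep.space and obj.space != rep.space:
        raise ValueError("representation and object come from different feature spaces")
    if len(obj.bits) != len(rep.weights):
        raise ValueError("representation and object have different feature counts")


def extract_representation(
    training: Sequence[WorldObject],
    params: NGMParams,
    rng: np.random.Generator,
) -> Representation:
    """One-shot representation from co-present exemplars (confidence 1)."""
    if len(training) == 0:
        raise ValueError("training set must be non-empty")
    space = training[0].space
    if space is None:
        raise ValueError("training objects must carry a FeatureSpace")
    for obj in training:
        if obj.space != space:
            raise ValueError("all training objects must share one feature space")
    sal = sample_salience_matrix(space, params.salience, rng, 1)
    bits = np.stack([o.bits for o in training])
    W = representation_weights(bits, sal, space, params.incompatibility_threshold)
    return Representation(space=space, weights=W[0], confidence=1, salience=sal[0])


def distance(rep: Representation, obj: WorldObject) -> float:
    """Asymmetric distance D(r, t): representation mass the object lacks."""
    _check_same_space(rep, obj)
    return float(asymmetric_distances(rep.weights[None, :], obj.bits[None, :])[0, 0])


def is_member(rep: Representation, obj: WorldObject, params: NGMParams) -> bool:
    """True iff D(r, t) <= distance_threshold (non-strict at the boundary)."""
    return distance(rep, obj) <= params.distance_threshold


def update_sequential(
    rep: Representation,
    obj: WorldObject,
    params: NGMParams,
    rng: np.random.Generator | None = None,
) -> Representation:
    """One sequential exposure.  Consistent: weights untouched, confidence
    +1.  Inconsistent: revised representation over the features shared by the
    old support and the exemplar, confidence reset to 1.  Reuses the cached
    salience draws; ``rng`` is only consulted if the representation carries
    none (e.g. hand-built)."""
    _check_same_space(rep, obj)
    if rep.salience is not None:
        sal = rep.salience[None, :]
    else:
        if rng is None:
            raise ValueError("representation has no cached salience draws; pass rng")
        sal = sample_salience_matrix(rep.space, params.salience, rng, 1)
    W, conf = sequential_pass(
        rep.weights[None, :],
        np.array([rep.confidence], dtype=np.int64),
        sal,
        obj.bits,
        rep.space,
        params,
    )
    return Representation(space=rep.space, weights=W[0], confidence=int(conf[0]),
                          salience=sal[0])


# ---------------------------------------------------------------------------
# estimator

class NaiveGeneralizationModel(BaseEstimator):
    """Scikit-learn style interface to the NGM.

    Parameters
    ----------
    space : FeatureSpace
        The feature inventory (tiers drive which salience Gaussian a feature
        samples from; the incompatibility relation drives conflict blocking).
    mu_high, mu_low, sigma : float
        Means and shared standard deviation of the two salience Gaussians.
    distance_threshold : float
        Category cutoff: an object is a member iff its asymmetric distance to
        the stored representation is <= this value.
    incompatibility_threshold : float
        Salience above which a sampled feature blocks its conflicts.
    presentation : {"simultaneous", "sequential"}
        Whether training exemplars are co-present (one-shot extraction) or
        shown one at a time (hypothesis-and-consistency dynamics).
    n_loops : int
        Number of full passes through the training sequence (sequential only).
    random_state : int, Generator or None
        Seed for the once-per-word salience draws.

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
        The learned gradient representation, each weight in [0, 1].
    confidence_ : int
        Count of consistent exposures absorbed into the representation.
    salience_ : ndarray of shape (n_features,)
        The participant's salience draws (fixed across exposures).
    """

    def __init__(
        self,
        space: FeatureSpace | None = None,
        mu_high: float = 0.8,
        mu_low: float = 0.3,
        sigma: float = 0.1,
        distance_threshold: float = 1.0,
        incompatibility_threshold: float = 0.8,
        presentation: str = "simultaneous",
        n_loops: int = 2,
        random_state=None,
    ):
        self.space = space
        self.mu_high = mu_high
        self.mu_low = mu_low
        self.sigma = sigma
        self.distance_threshold = distance_threshold
        self.incompatibility_threshold = incompatibility_threshold
        self.presentation = presentation
        self.n_loops = n_loops
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _params(self) -> NGMParams:
        return NGMParams.from_values(
            self.mu_high, self.mu_low, self.sigma,
            self.distance_threshold, self.incompatibility_threshold,
        )

    def _as_bits(self, X) -> np.ndarray:
        if len(X) and isinstance(X[0], WorldObject):
            return np.stack([o.bits for o in X])
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be a 2d binary array or a sequence of WorldObject")
        if self.space is not None and X.shape[1] != len(self.space):
            raise ValueError(
                f"X has {X.shape[1]} features, space has {len(self.space)}"
            )
        return X

    def _resolve_space(self, X) -> FeatureSpace:
        if self.space is not None:
            return self.space
        if len(X) and isinstance(X[0], WorldObject) and X[0].space is not None:
            return X[0].space
        raise ValueError("pass space= to the constructor or fit on WorldObject instances")

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None):
        """Learn a representation from the training exemplars in X.

        X is either a sequence of WorldObject or a binary (n_items,
        n_features) array; y is ignored (the word label is implicit)."""
        space = self._resolve_space(X)
        bits = self._as_bits(X)
        if bits.shape[0] == 0:
            raise ValueError("training set must be non-empty")
        params = self._params()
        rng = np.random.default_rng(self.random_state)
        sal = sample_salience_matrix(space, params.salience, rng, 1)
        W, conf = run_presentation(bits, sal, space, params,
                                   presentation=self.presentation,
                                   n_loops=self.n_loops)
        self.space_ = space
        self.n_features_in_ = bits.shape[1]
        self.salience_ = sal[0]
        self.weights_ = W[0]
        self.confidence_ = int(conf[0])
        return self

    def distances(self, X) -> np.ndarray:
        """Asymmetric distance from the stored representation to each row."""
        self._check_fitted()
        bits = self._as_bits(X)
        return asymmetric_distances(self.weights_[None, :], bits)[0]

    def decision_function(self, X) -> np.ndarray:
        """distance_threshold - D(r, t): positive or zero means member."""
        return self.distance_threshold - self.distances(X)

    def predict(self, X) -> np.ndarray:
        """Boolean category membership for each object."""
        return self.distances(X) <= self.distance_threshold

    def partial_fit(self, X, y=None):
        """Sequential exposures applied to an already-fitted representation."""
        self._check_fitted()
        bits = self._as_bits(X)
        params = self._params()
        W = self.weights_[None, :]
        conf = np.array([self.confidence_], dtype=np.int64)
        for x in bits:
            W, conf = sequential_pass(W, conf, self.salience_[None, :], x,
                                      self.space_, params)
        self.weights_ = W[0]
        self.confidence_ = int(conf[0])
        return self

    def representation_(self) -> Representation:
        self._check_fitted()
        return Representation(space=self.space_, weights=self.weights_.copy(),
                              confidence=self.confidence_,
                              salience=self.salience_.copy())

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ValueError("this NaiveGeneralizationModel instance is not fitted yet")
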