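import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from ngm.model import (
    NGMParams,
    NaiveGeneralizationModel,
    Representation,
    SalienceParams,
    asymmetric_distances,
    distance,
    extract_representation,
    incompatibility_mask,
    is_member,
    _allowed_sequential,
    sample_salience,
    sample_salience_matrix,
    update_sequential,
)
from ngm.world import (
    TIER_BASIC,
    TIER_IDIOSYNCRATIC,
    TIER_SUBORDINATE,
    FeatureSpace,
    WorldObject,
)

HYPO = settings(deadline=None, derandomize=True, max_examples=100)


def brute_force_distance(weights, bits):
    return sum(max(0.0, w - t) for w, t in zip(weights, bits))


# ---------------------------------------------------------------------------
# salience sampling

class TestSampleSalience:
    def test_degenerate_sigma_returns_means_exactly(self):
        params = SalienceParams(mu_high=0.8, mu_low=0.3, sigma=0.0)
        rng = np.random.default_rng(0)
        assert sample_salience("f", TIER_BASIC, params, rng) == 0.8
        assert sample_salience("f", TIER_IDIOSYNCRATIC, params, rng) == 0.3
        assert sample_salience("f", TIER_SUBORDINATE, params, rng) == 0.3

    def test_monte_carlo_mean(self):
        """10^5 draws at sigma=0.1 around mu_low=0.3: clipping is negligible,
        so the empirical mean must sit within 3 standard errors of 0.3."""
        params = SalienceParams(mu_high=0.8, mu_low=0.3, sigma=0.1)
        rng = np.random.default_rng(12345)
        draws = np.array([
            sample_salience("f", TIER_SUBORDINATE, params, rng) for _ in range(10**5)
        ])
        se = 0.1 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.3) < 3 * se
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_draws_clipped_to_unit_interval(self):
        params = SalienceParams(mu_high=0.9, mu_low=0.1, sigma=5.0)
        rng = np.random.default_rng(3)
        space = FeatureSpace(["a", "b"], {"a": TIER_BASIC, "b": TIER_SUBORDINATE})
        sal = sample_salience_matrix(space, params, rng, 1000)
        assert sal.min() >= 0.0 and sal.max() <= 1.0

    @pytest.mark.parametrize("kwargs", [
        {"sigma": -0.1}, {"mu_low": 0.9, "mu_high": 0.3}, {"mu_high": 1.5},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SalienceParams(**{"mu_high": 0.8, "mu_low": 0.3, "sigma": 0.1, **kwargs})


# ---------------------------------------------------------------------------
# representation extraction

class TestExtractRepresentation:
    def test_absent_feature_weight_is_exactly_zero(self, table4):
        space, _, objs = table4
        params = NGMParams()
        rep = extract_representation([objs["Dalmatian"]], params, np.random.default_rng(0))
        assert rep.as_dict()["D"] == 0.0
        assert rep.confidence == 1

    def test_ceiling_closed_form_three_identical_exemplars(self, world):
        """sigma=0, mu_low=0.4: every shared non-basic feature accumulates
        3 x 0.4 and clips at the 1.0 ceiling."""
        params = NGMParams.from_values(0.9, 0.4, 0.0, 1.0, 0.95)
        anchor = world.anchor
        rep = extract_representation([anchor] * 3, params, np.random.default_rng(0))
        d = rep.as_dict()
        for f, present in anchor.properties.items():
            tier = world.space.tier_of(f)
            if not present:
                assert d[f] == 0.0
            elif tier == TIER_BASIC:
                assert d[f] == 1.0  # 3 x 0.9, ceiling
            else:
                assert d[f] == pytest.approx(1.0)  # min(1, 3 x 0.4)

    def test_deterministic_limit_support_is_basic_only(self, world,
                                                       deterministic_basic_params):
        rep = extract_representation([world.anchor], deterministic_basic_params,
                                     np.random.default_rng(0))
        assert rep.support == {f for f in world.anchor.feature_set()
                               if world.space.tier_of(f) == TIER_BASIC}

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            extract_representation([], NGMParams(), np.random.default_rng(0))

    def test_weights_never_exceed_ceiling(self, world):
        params = NGMParams.from_values(0.9, 0.4, 0.4, 1.0, 0.9)
        items = list(world.training_sets["subordinate"]) * 5  # 15 exemplars
        rep = extract_representation(items, params, np.random.default_rng(5))
        assert rep.weights.max() <= 1.0

    def test_incompatible_pair_never_corepresented_above_threshold(self, world):
        """If either member of a conflict pair was sampled above the
        incompatibility threshold, the two are never both stored."""
        params = NGMParams.from_values(0.8, 0.3, 0.4, 1.0, 0.6)
        items = world.training_sets["superordinate"]  # 3 basics + 3 subs in conflict
        for seed in range(50):
            rep = extract_representation(items, params, np.random.default_rng(seed))
            w = rep.weights
            sal = rep.salience
            for a, b in world.space.pair_indices:
                if w[a] > 0 and w[b] > 0:
                    assert sal[a] <= params.incompatibility_threshold
                    assert sal[b] <= params.incompatibility_threshold


class TestIncompatibilityFilter:
    def _clique_space(self):
        feats = ["a", "b", "c", "x", "y", "z"]
        tiers = {f: TIER_SUBORDINATE for f in feats}
        tiers["z"] = TIER_BASIC
        pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("x", "y")]
        return FeatureSpace(feats, tiers, pairs)

    def test_vectorized_matches_sequential_reference(self):
        space = self._clique_space()
        rng = np.random.default_rng(99)
        for _ in range(200):
            sal = rng.uniform(0, 1, size=(1, len(space)))
            present = rng.uniform(size=len(space)) < 0.7
            tau = rng.uniform(0.2, 0.9)
            fast = incompatibility_mask(sal, present, space, tau)[0]
            ref = _allowed_sequential(sal[0], present, space.pair_indices, tau)
            assert np.array_equal(fast, ref)

    def test_highest_salience_above_threshold_wins_clique(self):
        space = self._clique_space()
        sal = np.array([[0.9, 0.8, 0.7, 0.1, 0.2, 0.5]])
        present = np.ones(6, dtype=bool)
        mask = incompatibility_mask(sal, present, space, threshold=0.6)[0]
        # a blocks b and c; x/y both below threshold -> both kept
        assert mask.tolist() == [True, False, False, True, True, True]

    def test_all_below_threshold_keeps_everything(self):
        space = self._clique_space()
        sal = np.full((1, 6), 0.5)
        mask = incompatibility_mask(sal, np.ones(6, dtype=bool), space, threshold=0.6)[0]
        assert mask.all()

    def test_non_clique_component_uses_sequential_rule(self):
        # path a-b-c: a and c are NOT in conflict, so both can survive
        feats = ["a", "b", "c"]
        space = FeatureSpace(feats, {f: TIER_SUBORDINATE for f in feats},
                             [("a", "b"), ("b", "c")])
        assert not space.components_are_cliques
        sal = np.array([[0.9, 0.5, 0.8]])
        mask = incompatibility_mask(sal, np.ones(3, dtype=bool), space, threshold=0.6)[0]
        assert mask.tolist() == [True, False, True]


# ---------------------------------------------------------------------------
# distance and membership

class TestDistance:
    def test_worked_example(self, table4):
        _, rep, objs = table4
        expected = {"Bee": 1.1, "Dalmatian": 0.0, "Poodle": 0.3, "Truck": 1.4}
        for name, value in expected.items():
            assert distance(rep, objs[name]) == pytest.approx(value, abs=1e-12)

    def test_membership_at_unit_cutoff(self, table4):
        _, rep, objs = table4
        params = NGMParams.from_values(0.8, 0.3, 0.1, 1.0, 0.8)
        members = {name for name, o in objs.items() if is_member(rep, o, params)}
        assert members == {"Dalmatian", "Poodle"}

    def test_superset_object_at_distance_zero(self, table4):
        space, rep, _ = table4
        everything = WorldObject(id="all", bits=np.ones(4), space=space)
        assert distance(rep, everything) == 0.0

    def test_threshold_zero_admits_only_exact_cover(self, table4):
        _, rep, objs = table4
        params = NGMParams.from_values(0.8, 0.3, 0.1, 0.0, 0.8)
        members = {name for name, o in objs.items() if is_member(rep, o, params)}
        assert members == {"Dalmatian"}

    def test_threshold_at_total_mass_admits_everything(self, table4):
        _, rep, objs = table4
        params = NGMParams.from_values(0.8, 0.3, 0.1, float(rep.weights.sum()), 0.8)
        assert all(is_member(rep, o, params) for o in objs.values())

    def test_mismatched_spaces_rejected(self, table4, world):
        _, rep, _ = table4
        with pytest.raises(ValueError):
            distance(rep, world.anchor)

    @HYPO
    @given(
        weights=st.lists(st.floats(0, 1, width=32), min_size=1, max_size=8),
        data=st.data(),
    )
    def test_matches_brute_force_and_bounds(self, weights, data):
        """Vectorized distance equals the elementwise max(0, r_n - t_n) sum;
        it is bounded by total representation mass, with equality iff the
        object carries none of the support."""
        bits = data.draw(st.lists(st.integers(0, 1), min_size=len(weights),
                                  max_size=len(weights)))
        w = np.array(weights)
        t = np.array(bits, dtype=float)
        d = asymmetric_distances(w[None, :], t[None, :])[0, 0]
        assert d == pytest.approx(brute_force_distance(w, t), abs=1e-12)
        assert 0.0 <= d <= w.sum() + 1e-12
        if (w * t).sum() > 0:
            assert d < w.sum()

    @HYPO
    @given(
        weights=st.lists(st.floats(0, 1, width=32), min_size=1, max_size=8),
        bits=st.data(),
    )
    def test_monotonicity(self, weights, bits):
        """Giving the object one more feature never increases distance;
        raising a representation weight never decreases it."""
        w = np.array(weights)
        t = np.array(bits.draw(st.lists(st.integers(0, 1), min_size=len(w),
                                        max_size=len(w))), dtype=float)
        d0 = asymmetric_distances(w[None, :], t[None, :])[0, 0]
        i = bits.draw(st.integers(0, len(w) - 1))
        t2 = t.copy(); t2[i] = 1.0
        assert asymmetric_distances(w[None, :], t2[None, :])[0, 0] <= d0 + 1e-12
        w2 = w.copy(); w2[i] = 1.0
        assert asymmetric_distances(w2[None, :], t[None, :])[0, 0] >= d0 - 1e-12

    def test_fast_path_matches_relu_path_on_nonbinary_objects(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, size=(5, 12))
        X_bin = (rng.uniform(size=(7, 12)) < 0.5).astype(float)
        fast = asymmetric_distances(W, X_bin)
        relu = np.maximum(W[:, None, :] - X_bin[None, :, :], 0).sum(axis=2)
        np.testing.assert_allclose(fast, relu, atol=1e-12)


# ---------------------------------------------------------------------------
# sequential dynamics

class TestSequentialUpdate:
    def test_consistent_exposure_is_noop_with_confidence_bump(self, world):
        params = NGMParams.from_values(0.8, 0.2, 0.1, 1.5, 0.8)
        rep = extract_representation([world.anchor], params, np.random.default_rng(0))
        updated = update_sequential(rep, world.anchor, params)
        assert np.array_equal(updated.weights, rep.weights)
        assert updated.confidence == rep.confidence + 1

    def test_consistent_sequence_never_changes_weights(self, world):
        """For any all-consistent exposure sequence the final weights equal
        the initial weights; only confidence grows."""
        params = NGMParams.from_values(0.8, 0.2, 0.1, 10.0, 0.8)  # everything consistent
        items = world.training_sets["superordinate"]
        rep = extract_representation([items[0]], params, np.random.default_rng(1))
        w0 = rep.weights.copy()
        for obj in [*items[1:], *items]:
            rep = update_sequential(rep, obj, params)
        assert np.array_equal(rep.weights, w0)
        assert rep.confidence == 1 + 5

    def test_inconsistent_exposure_narrows_support_to_shared_features(self, world):
        """A cross-basic exemplar that breaks consistency triggers a revision
        whose support is inside the old support intersected with the new
        object's features."""
        params = NGMParams.from_values(0.9, 0.4, 0.0, 0.5, 0.95)
        anchor = world.anchor
        other = world.training_sets["superordinate"][1]  # different basic category
        rep = extract_representation([anchor], params, np.random.default_rng(0))
        assert distance(rep, other) > params.distance_threshold
        revised = update_sequential(rep, other, params)
        assert revised.confidence == 1
        assert revised.support <= (rep.support & other.feature_set())
        # here the only shared feature is the superordinate one
        assert revised.support == {f for f in other.feature_set()
                                   if world.space.tier_of(f) == "superordinate"}

    def test_deterministic_limit_sequential_basic_equals_single(self, world,
                                                                deterministic_basic_params):
        """mu_low=0, mu_high=1, sigma=0: any same-basic exemplar is
        consistent, so sequential basic training ends with the
        single-exemplar representation."""
        params = deterministic_basic_params
        items = world.training_sets["basic"]
        rep = extract_representation([items[0]], params, np.random.default_rng(0))
        w0 = rep.weights.copy()
        for obj in [*items[1:], *items]:
            rep = update_sequential(rep, obj, params)
        assert np.array_equal(rep.weights, w0)

    def test_handbuilt_representation_needs_rng(self, table4):
        space, rep, objs = table4
        params = NGMParams.from_values(0.8, 0.3, 0.1, 0.1, 0.8)
        with pytest.raises(ValueError, match="rng"):
            update_sequential(rep, objs["Truck"], params)


# ---------------------------------------------------------------------------
# estimator surface

class TestEstimator:
    def test_fit_predict_on_grid(self, world):
        est = NaiveGeneralizationModel(space=world.space, random_state=0)
        est.fit(world.training_sets["single"])
        pred = est.predict(world.grid.objects)
        assert pred.dtype == bool and pred.shape == (24,)
        d = est.distances(world.grid.objects)
        np.testing.assert_array_equal(pred, d <= est.distance_threshold)
        np.testing.assert_array_equal(pred, est.decision_function(world.grid.objects) >= 0)

    def test_weights_attribute_contract(self, world):
        est = NaiveGeneralizationModel(space=world.space, random_state=1).fit(
            world.training_sets["subordinate"]
        )
        assert est.weights_.shape == (len(world.space),)
        assert est.weights_.min() >= 0 and est.weights_.max() <= 1
        assert est.confidence_ == 1

    def test_clone_and_get_params_round_trip(self, world):
        est = NaiveGeneralizationModel(space=world.space, mu_low=0.25, sigma=0.3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_same_seed_reproduces_fit(self, world):
        a = NaiveGeneralizationModel(space=world.space, random_state=5).fit(
            world.training_sets["basic"]
        )
        b = NaiveGeneralizationModel(space=world.space, random_state=5).fit(
            world.training_sets["basic"]
        )
        np.testing.assert_array_equal(a.weights_, b.weights_)

    def test_sequential_presentation_via_constructor(self, world):
        est = NaiveGeneralizationModel(space=world.space, presentation="sequential",
                                       n_loops=2, random_state=3)
        est.fit(world.training_sets["superordinate"])
        assert est.weights_.max() <= 1.0

    def test_unfitted_predict_raises(self, world):
        est = NaiveGeneralizationModel(space=world.space)
        with pytest.raises(ValueError, match="not fitted"):
            est.predict(world.grid.objects)

    def test_representation_export_matches_functional_api(self, world):
        est = NaiveGeneralizationModel(space=world.space, random_state=8).fit(
            world.training_sets["single"]
        )
        rep = est.representation_()
        func = extract_representation(world.training_sets["single"], est._params(),
                                      np.random.default_rng(8))
        np.testing.assert_array_equal(rep.weights, func.weights)


class TestRepresentationContainer:
    def test_rejects_out_of_range_weights(self, table4):
        space, _, _ = table4
        with pytest.raises(ValueError):
            Representation(space=space, weights=np.array([0.5, 1.2, 0, 0]))

    def test_mapping_round_trip(self, table4):
        space, rep, _ = table4
        again = Representation.from_mapping(space, rep.as_dict())
        np.testing.assert_array_equal(again.weights, rep.weights)
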