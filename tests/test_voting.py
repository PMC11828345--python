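"""Voting algebra: simplex contracts, exponential-accuracy coefficients,
multiplicative updates, group selection and the mixed blend."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mae.voting import (
    AccuracyVector,
    WeightVector,
    accuracy_coefficients,
    combine_individual,
    fit_individual_weight_set,
    generate_group_candidates,
    group_select,
    group_update,
    mixed_combine,
    primary_prior,
)

# Frozen from a 50-digit Decimal evaluation of exp(A_i)/sum_j exp(A_j) on the
# four base-model validation accuracies (0.9804, 0.9696, 0.9674, 0.9718).
ALPHA_ORACLE = np.array(
    [
        0.25203015838171643071030373174500392608914489889604,
        0.24932287829835529789001428519006358734234221716207,
        0.24877497088524264561445909127755607895832363201273,
        0.24987199243468562578522289178737640761018925192916,
    ]
)

simplexes = st.integers(2, 8).flatmap(
    lambda n: st.lists(st.floats(1e-3, 1.0), min_size=n, max_size=n)
).map(lambda raw: WeightVector(np.asarray(raw) / np.sum(raw)))


class TestWeightVector:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            WeightVector([0.7, -0.3, 0.6])
        with pytest.raises(ValueError):
            WeightVector([0.2, 0.2])
        with pytest.raises(ValueError):
            WeightVector([])

    def test_valid_simplex_accepted(self):
        w = WeightVector([0.25, 0.25, 0.25, 0.25])
        assert len(w) == 4 and w[0] == 0.25


class TestAccuracyCoefficients:
    def test_equal_accuracies_give_uniform(self):
        a = accuracy_coefficients(AccuracyVector([0.9, 0.9, 0.9, 0.9]))
        assert np.allclose(a, 0.25)

    def test_single_model(self):
        assert np.allclose(accuracy_coefficients(AccuracyVector([0.7])), [1.0])

    def test_matches_high_precision_oracle(self):
        a = accuracy_coefficients(AccuracyVector([0.9804, 0.9696, 0.9674, 0.9718]))
        assert np.allclose(a, ALPHA_ORACLE, atol=1e-14)

    def test_percent_scale_converts_to_fraction(self):
        frac = accuracy_coefficients(AccuracyVector([0.9804, 0.9696, 0.9674, 0.9718]))
        pct = accuracy_coefficients(AccuracyVector([98.04, 96.96, 96.74, 97.18], scale="percent"))
        assert np.allclose(frac, pct)

    def test_strictly_monotone(self, rng):
        for _ in range(100):
            a = rng.uniform(0, 1, size=5)
            alpha = accuracy_coefficients(AccuracyVector(a))
            order = np.argsort(a)
            assert np.all(np.diff(alpha[order]) > 0) or np.allclose(np.diff(a[order]), 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            AccuracyVector([])


class TestCombineIndividual:
    def test_one_hot_selects(self):
        sets = [WeightVector([1, 0]), WeightVector([0, 1])]
        assert np.allclose(combine_individual(sets, [0.0, 1.0]).w, [0, 1])

    def test_identical_sets_fixed_point(self):
        w = WeightVector([0.3, 0.7])
        assert np.allclose(combine_individual([w, w, w], [0.2, 0.3, 0.5]).w, w.w)

    def test_hand_arithmetic(self):
        sets = [WeightVector([1, 0]), WeightVector([0, 1])]
        assert np.allclose(combine_individual(sets, [0.5, 0.5]).w, [0.5, 0.5])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_individual([WeightVector([1, 0])], [0.5, 0.5])


class TestFitIndividualWeightSet:
    def test_prior_is_primary_heavy(self):
        assert np.allclose(primary_prior(4, 2).w, [0.15, 0.15, 0.55, 0.15])

    def test_constant_equal_accuracies_keep_prior(self):
        acc = [AccuracyVector([0.8, 0.8, 0.8, 0.8])] * 5
        w = fit_individual_weight_set(1, acc)
        assert np.allclose(w.w, primary_prior(4, 1).w)

    def test_absorbing_accuracy(self):
        w = fit_individual_weight_set(0, [AccuracyVector([1, 0, 0, 0])])
        assert np.allclose(w.w, [1, 0, 0, 0])

    def test_single_update_hand_arithmetic(self):
        w = fit_individual_weight_set(0, [AccuracyVector([0.9, 0.9, 0.6, 0.6])])
        expected = np.array([0.495, 0.135, 0.09, 0.09]) / 0.81
        assert np.allclose(w.w, expected)

    def test_scorer_picks_best_epoch(self):
        acc = [AccuracyVector([0.9, 0.1, 0.1, 0.1])] * 3
        # scorer preferring uniformity picks the prior over sharpened updates
        w = fit_individual_weight_set(0, acc, scorer=lambda wv: -np.max(wv.w))
        assert np.allclose(w.w, primary_prior(4, 0).w)

    def test_all_zero_accuracies_rejected(self):
        with pytest.raises(ValueError):
            fit_individual_weight_set(0, [AccuracyVector([0, 0, 0])])


class TestGroupUpdate:
    def test_equal_accuracies_identity(self):
        w = WeightVector([0.4, 0.3, 0.2, 0.1])
        assert np.allclose(group_update(w, AccuracyVector([0.7] * 4)).w, w.w)

    def test_zero_annihilation(self):
        w = WeightVector([0.4, 0.3, 0.2, 0.1])
        out = group_update(w, AccuracyVector([1, 0, 0, 0]))
        assert np.allclose(out.w, [1, 0, 0, 0])

    def test_hand_arithmetic(self):
        w = WeightVector([0.25] * 4)
        out = group_update(w, AccuracyVector([0.8, 0.4, 0.4, 0.4]))
        assert np.allclose(out.w, [0.4, 0.2, 0.2, 0.2])

    def test_scale_invariance(self, rng):
        for _ in range(20):
            w = WeightVector(rng.dirichlet(np.ones(4)))
            a = rng.uniform(0.1, 1.0, size=4)
            base = group_update(w, AccuracyVector(a))
            scaled = group_update(w, AccuracyVector(a * 0.5))
            assert np.allclose(base.w, scaled.w)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            group_update(WeightVector([0.5, 0.5]), AccuracyVector([0.0, 0.0]))


class TestGroupSelect:
    def test_single_candidate(self):
        w = WeightVector([0.6, 0.4])
        assert group_select([w], lambda c: 1.0) is w

    def test_matches_brute_force(self, rng):
        # fixed tiny prediction fixture: 2 models, 10 samples, 3 classes
        probs = rng.dirichlet(np.ones(3), size=(2, 10))
        y = rng.integers(0, 3, size=10)

        def scorer(wv):
            fused = np.einsum("i,ink->nk", wv.w, probs)
            return float((fused.argmax(1) == y).mean())

        cands = [WeightVector(rng.dirichlet(np.ones(2))) for _ in range(8)]
        best = group_select(cands, scorer)
        brute = max(enumerate(cands), key=lambda t: (scorer(t[1]), -t[0]))[1]
        assert np.allclose(best.w, brute.w)

    def test_tie_breaks_to_first(self):
        a, b = WeightVector([0.5, 0.5]), WeightVector([0.4, 0.6])
        assert group_select([a, b], lambda c: 1.0) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_select([], lambda c: 0.0)


class TestMixedCombine:
    def test_endpoints(self):
        wg, wi = WeightVector([0.4, 0.6]), WeightVector([0.9, 0.1])
        assert np.allclose(mixed_combine(wg, wi, 0.0).w, wi.w)
        assert np.allclose(mixed_combine(wg, wi, 1.0).w, wg.w)

    def test_selected_coefficient_hand_case(self):
        wg = WeightVector([0.4, 0.3, 0.2, 0.1])
        wi = WeightVector([0.25] * 4)
        out = mixed_combine(wg, wi, 0.2)
        assert np.allclose(out.w, [0.28, 0.26, 0.24, 0.22])

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(ValueError):
            mixed_combine(WeightVector([1.0]), WeightVector([1.0]), 1.5)

    @given(w1=simplexes, beta=st.floats(0, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_output_between_inputs(self, w1, beta):
        n = len(w1)
        w2 = WeightVector(np.full(n, 1.0 / n))
        out = mixed_combine(w1, w2, beta)
        lo = np.minimum(w1.w, w2.w) - 1e-12
        hi = np.maximum(w1.w, w2.w) + 1e-12
        assert np.all(out.w >= lo) and np.all(out.w <= hi)


@given(data=st.data())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_every_operation_returns_simplex(data):
    n = data.draw(st.integers(2, 6))
    raw = data.draw(st.lists(st.floats(1e-3, 1.0), min_size=n, max_size=n))
    w = WeightVector(np.asarray(raw) / np.sum(raw))
    acc = AccuracyVector(np.asarray(data.draw(st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n))))
    beta = data.draw(st.floats(0, 1))
    results = [
        accuracy_coefficients(acc),
        group_update(w, acc).w,
        mixed_combine(w, WeightVector(np.full(n, 1.0 / n)), beta).w,
        fit_individual_weight_set(0, [acc]).w,
    ]
    for r in results:
        assert np.all(np.asarray(r) >= -1e-12)
        assert np.isclose(np.sum(r), 1.0, atol=1e-9)


def test_better_model_gets_largest_final_weight(rng):
    """Full mixed pipeline on a fixture where model 0 is strictly better:
    the final mixed weight puts its largest mass on model 0 for a majority
    of seeds."""
    wins = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        y = r.integers(0, 3, size=40)
        n = 3
        probs = np.empty((n, 40, 3))
        quality = [0.9, 0.5, 0.5]
        accs = []
        for i in range(n):
            correct = r.random(40) < quality[i]
            pred = np.where(correct, y, r.integers(0, 3, size=40))
            probs[i] = 0.1
            probs[i, np.arange(40), pred] = 0.8
            accs.append(float((pred == y).mean()))
        acc_epochs = [AccuracyVector(np.asarray(accs))] * 3

        def scorer(wv):
            fused = np.einsum("i,ink->nk", wv.w, probs)
            return float((fused.argmax(1) == y).mean())

        sets = [fit_individual_weight_set(k, acc_epochs, scorer=scorer) for k in range(n)]
        alphas = accuracy_coefficients(AccuracyVector(np.asarray(accs)))
        w_i = combine_individual(sets, alphas)
        cands = generate_group_candidates(n, acc_epochs, restarts=16, seed=seed)
        w_g = group_select(cands, scorer)
        w = mixed_combine(w_g, w_i, 0.2)
        wins += int(np.argmax(w.w) == 0)
    assert wins > 5
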