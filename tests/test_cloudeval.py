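import numpy as np
import pytest

from aerowarn.cloudeval import (
    CloudEntry,
    CloudSpec,
    certainty,
    cloud_params,
    combine_weights,
    criteria_bounds,
    default_weights,
    entropy_weights,
    evaluate,
    pseudo_bound,
)
from aerowarn.synthetic import CRITERIA, load_fixture


class TestCloudParams:
    def test_interval_maps_to_midpoint_third_span(self):
        import pandas as pd
        bounds = pd.DataFrame(
            [{"criterion": "PM2.5", "level": "II", "bmin": 35.0, "bmax": 75.0}]
        )
        spec = cloud_params(bounds, k=0.1)
        e = spec[("PM2.5", "II")]
        assert e.Ex == pytest.approx(55.0)
        assert e.En == pytest.approx(13.3333, abs=1e-3)
        assert e.He == pytest.approx(1.3333, abs=1e-3)

    def test_zero_atomization_gives_deterministic_cloud(self):
        import pandas as pd
        bounds = pd.DataFrame(
            [{"criterion": "CO", "level": "I", "bmin": 0.0, "bmax": 2.0}]
        )
        e = cloud_params(bounds, k=0.0)[("CO", "I")]
        assert e.Ex == pytest.approx(1.0) and e.He == 0.0

    def test_inverted_bounds_rejected(self):
        import pandas as pd
        bounds = pd.DataFrame(
            [{"criterion": "CO", "level": "I", "bmin": 2.0, "bmax": 1.0}]
        )
        with pytest.raises(ValueError):
            cloud_params(bounds)


class TestPseudoBound:
    def test_quadratic_extrapolation_of_no2_bounds(self):
        assert pseudo_bound([40, 80, 180, 280, 565]) == pytest.approx(849.0, abs=1e-9)

    def test_collinear_bounds_extrapolate_linearly(self):
        assert pseudo_bound([10, 20, 30, 40, 50]) == pytest.approx(60.0, abs=1e-8)

    def test_pm25_extrapolation(self):
        assert pseudo_bound([35, 75, 115, 150, 250]) == pytest.approx(334.0, abs=0.1)

    def test_too_few_or_invalid_points_rejected(self):
        with pytest.raises(ValueError):
            pseudo_bound([10, 20])
        with pytest.raises(ValueError):
            pseudo_bound([10, 5, 20, 30, 40])


class TestEntropyWeights:
    def test_uniform_criteria_fall_back_to_equal_weights(self):
        # every sample spreads evenly over the bins: maximal entropy everywhere
        base = np.repeat(np.arange(10), 5) + 0.5
        samples = {c: base.copy() for c in CRITERIA}
        w = entropy_weights(samples, n_bins=10)
        np.testing.assert_allclose(w, 1 / 6)

    def test_concentrated_criterion_takes_all_weight(self):
        uniform = np.repeat(np.arange(10), 5) + 0.5
        concentrated = np.concatenate([np.zeros(49), [10.0]])
        # nearly all mass in one bin -> near-zero entropy -> weight ~1
        w = entropy_weights({"a": uniform, "b": concentrated}, n_bins=10)
        assert w[1] > 0.9
        assert w.sum() == pytest.approx(1.0)

    def test_matches_independent_histogram_entropy_computation(self, rng):
        samples = {c: rng.gamma(2.0, 20.0, 300) for c in CRITERIA}
        w = entropy_weights(samples, n_bins=10)
        # independent recomputation
        E = []
        for c in CRITERIA:
            counts, _ = np.histogram(samples[c], bins=10)
            F = counts / counts.sum()
            e = -sum(f * np.log(f) for f in F if f > 0)
            E.append(e / np.log(10))
        E = np.array(E)
        expected = (1 - E) / (6 - E.sum())
        np.testing.assert_allclose(w, expected, atol=1e-12)
        assert w.sum() == pytest.approx(1.0)

    def test_constant_sample_is_most_informative(self):
        spread = np.repeat(np.arange(10), 3) + 0.5
        w = entropy_weights({"flat": np.full(30, 5.0), "spread": spread})
        assert w[0] > w[1]


class TestCombineWeights:
    def test_reproduces_printed_combined_weight_for_pm25(self):
        tab = load_fixture("weights")
        W = combine_weights(tab["z"], tab["omega"])
        assert W[0] == pytest.approx(0.4292, abs=1e-4)

    def test_uniform_ahp_weights_reduce_to_entropy_weights(self):
        omega = np.array([0.5, 0.3, 0.2])
        W = combine_weights(np.full(3, 1 / 3), omega)
        np.testing.assert_allclose(W, omega)

    def test_zero_products_rejected(self):
        with pytest.raises(ValueError):
            combine_weights([1.0, 0.0], [0.0, 1.0])


class TestCertainty:
    def test_membership_one_at_expectation(self, rng):
        cl = CloudEntry(55.0, 13.33, 1.33)
        np.testing.assert_allclose(certainty(55.0, cl, rng, 100), 1.0)

    def test_closed_form_at_one_entropy_unit_without_jitter(self, rng):
        cl = CloudEntry(55.0, 13.33, 0.0)
        mu = certainty(55.0 + 13.33, cl, rng, 10)
        np.testing.assert_allclose(mu, np.exp(-0.5))

    def test_half_cloud_saturates_below_expectation(self, rng):
        cl = CloudEntry(25.0, 16.67, 1.67, half_side="lower")
        np.testing.assert_allclose(certainty(10.7273, cl, rng, 50), 1.0)
        assert certainty(30.0, cl, rng, 50).max() < 1.0

    def test_half_cloud_monotone_decreasing_above_expectation(self, rng):
        cl = CloudEntry(25.0, 16.67, 0.0, half_side="lower")
        xs = np.linspace(25, 120, 25)
        mus = [certainty(x, cl, rng, 1)[0] for x in xs]
        assert all(a >= b for a, b in zip(mus, mus[1:]))

    def test_upper_half_cloud_saturates_beyond_expectation(self, rng):
        cl = CloudEntry(291.99, 28.0, 2.8, half_side="upper")
        np.testing.assert_allclose(certainty(400.0, cl, rng, 50), 1.0)

    def test_vanishing_hyperentropy_converges_to_gaussian_membership(self):
        rng = np.random.default_rng(0)
        cl = CloudEntry(55.0, 13.33, 1e-9)
        mu = certainty(70.0, cl, rng, 2000)
        closed = np.exp(-((70.0 - 55.0) ** 2) / (2 * 13.33**2))
        assert abs(mu.mean() - closed) < 1e-3

    def test_membership_always_within_unit_interval(self, rng):
        cl = CloudEntry(100.0, 33.33, 3.33)
        mu = certainty(180.0, cl, rng, 500)
        assert np.all((mu >= 0) & (mu <= 1))


class TestEvaluate:
    def test_sample_at_level_three_expectations_is_certain_level_three(self):
        clouds = CloudSpec.from_fixture()
        sample = {c: clouds[(c, "III")].Ex for c in CRITERIA}
        res = evaluate(sample, clouds, default_weights(), reps=200, rng=0)
        assert res.certainty["III"] == pytest.approx(1.0)
        assert res.final_level == "III"

    def test_missing_criterion_rejected(self):
        clouds = CloudSpec.from_fixture()
        with pytest.raises(ValueError):
            evaluate({"PM2.5": 10.0}, clouds, default_weights())

    def test_certainties_bounded_and_deterministic_given_seed(self):
        clouds = CloudSpec.from_fixture()
        samples = load_fixture("eval_samples").set_index("case")
        s = {c: float(samples.loc["A_5", c]) for c in CRITERIA}
        r1 = evaluate(s, clouds, default_weights(), reps=500, rng=77)
        r2 = evaluate(s, clouds, default_weights(), reps=500, rng=77)
        assert r1.certainty == r2.certainty
        assert all(0 <= u <= 1 for u in r1.certainty.values())

    def test_reference_sample_graded_best_level_with_high_certainty(self):
        clouds = CloudSpec.from_fixture()
        samples = load_fixture("eval_samples").set_index("case")
        s = {c: float(samples.loc["A_3", c]) for c in CRITERIA}
        res = evaluate(s, clouds, default_weights(), reps=2000, rng=5)
        assert res.final_level == "I"
        assert res.certainty["I"] == pytest.approx(0.9119, abs=0.01)


class TestCriteriaBounds:
    def test_levels_are_nested_and_start_at_zero(self):
        tab = criteria_bounds()
        for crit in CRITERIA:
            sub = tab[tab["criterion"] == crit]
            assert sub.iloc[0]["bmin"] == 0.0
            np.testing.assert_allclose(sub["bmin"].values[1:], sub["bmax"].values[:-1])
            assert np.all(np.diff(sub["bmax"].values) > 0)

    def test_exact_ols_pseudo_bound_close_to_printed(self):
        printed = criteria_bounds(exact_ols=False)
        exact = criteria_bounds(exact_ols=True)
        vi_p = printed[printed["level"] == "VI"]["bmax"].values
        vi_e = exact[exact["level"] == "VI"]["bmax"].values
        np.testing.assert_allclose(vi_e, vi_p, atol=0.5)
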