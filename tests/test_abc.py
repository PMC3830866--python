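"""Tests of rejection ABC, distances, and the ridge regression adjustment."""

import numpy as np
import pytest

from mitoabc import (
    ParamTransform,
    PriorSpec,
    ReferenceTable,
    RejectionABC,
    build_reference_table,
    mad_scale,
)
from mitoabc.summaries import FULL_NAMES, set_names


def toy_table(theta, summaries, names=None, prior=None, **kw):
    names = names or tuple(f"s{i}" for i in range(np.asarray(summaries).shape[1]))
    return ReferenceTable(
        theta=theta,
        summaries=summaries,
        names=names,
        set_id=0,
        prior=prior or PriorSpec(),
        **kw,
    )


class TestMadScale:
    def test_known_values(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        assert mad_scale(x) == pytest.approx([1.0])

    def test_constant_column_falls_back_to_one(self):
        x = np.column_stack([np.full(5, 7.0), np.arange(5.0)])
        s = mad_scale(x)
        assert s[0] == 1.0 and s[1] == 1.0

    def test_half_constant_falls_back_to_sd(self):
        # median deviations zero but SD positive
        x = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 10.0])[:, None]
        s = mad_scale(x)
        assert np.isclose(s[0], np.std(x))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mad_scale(np.array([[1.0], [np.nan]]))

    def test_distance_invariant_to_column_rescaling(self, rng):
        theta = rng.uniform(size=(50, 3)) * [1e-3, 1e-3, 0.5] + [0, 0, 0.5]
        S = rng.normal(size=(50, 4))
        s_obs = rng.normal(size=4)
        d1 = RejectionABC(toy_table(theta, S), s_obs).distances()
        fac = np.array([1.0, 100.0, 1e-3, 42.0])
        d2 = RejectionABC(toy_table(theta, S * fac), s_obs * fac).distances()
        np.testing.assert_allclose(d1, d2, rtol=1e-10)


class TestRejection:
    def make_model(self, rng, n=1000, k=3):
        theta = PriorSpec().sample_array(n, rng)
        S = rng.normal(size=(n, k))
        return RejectionABC(toy_table(theta, S), np.zeros(k))

    def test_ten_percent_of_1000_gives_100(self, rng):
        res = self.make_model(rng).fit(accept_fraction=0.10)
        assert res.n_accepted == 100
        assert res.threshold == pytest.approx(np.max(res.distances))

    def test_accept_all(self, rng):
        res = self.make_model(rng, n=50).fit(accept_fraction=1.0)
        assert res.n_accepted == 50

    def test_accepted_are_the_closest(self, rng):
        m = self.make_model(rng, n=200)
        res = m.fit(accept_fraction=0.2)
        d = m.distances()
        cutoff = np.sort(d)[39]
        assert np.all(res.distances <= cutoff)
        assert res.threshold == pytest.approx(cutoff)

    def test_nearest_neighbour_identity(self, rng):
        # s_obs equal to one table row: that row is the first accepted
        theta = PriorSpec().sample_array(100, rng)
        S = rng.normal(size=(100, 3))
        m = RejectionABC(toy_table(theta, S), S[17])
        res = m.fit(accept_fraction=0.01)
        assert res.n_accepted == 1
        assert res.accepted_idx[0] == 17
        assert res.distances[0] == 0.0

    def test_dimension_mismatch_rejected(self, rng):
        theta = PriorSpec().sample_array(20, rng)
        S = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            RejectionABC(toy_table(theta, S), np.zeros(4))

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            self.make_model(rng, n=20).fit(accept_fraction=0.0)

    def test_permutation_invariance_of_posterior(self, rng):
        theta = PriorSpec().sample_array(300, rng)
        S = rng.normal(size=(300, 3))
        s_obs = rng.normal(size=3)
        res1 = RejectionABC(toy_table(theta, S), s_obs).fit(0.1)
        perm = rng.permutation(300)
        res2 = RejectionABC(toy_table(theta[perm], S[perm]), s_obs).fit(0.1)
        np.testing.assert_allclose(
            np.sort(res1.theta_accepted, axis=0),
            np.sort(res2.theta_accepted, axis=0),
        )

    def test_select_set_narrowing(self, rng):
        table = build_reference_table(
            PriorSpec(),
            20,
            rng,
            sim=__import__("mitoabc").SimulationSettings(horizon=30),
        )
        assert tuple(table.names) == FULL_NAMES
        sub = table.select_set(3)
        assert sub.names == set_names(3)
        assert sub.summaries.shape == (20, 5)
        np.testing.assert_array_equal(sub.summaries[:, 0], table.summaries[:, 0])
        with pytest.raises(ValueError):
            sub.select_set(1)


class TestTransform:
    def test_round_trip(self, rng):
        tr = ParamTransform()
        theta = PriorSpec().sample_array(100, rng)
        np.testing.assert_allclose(tr.backward(tr.forward(theta)), theta, rtol=1e-9)

    def test_range_of_backward(self, rng):
        tr = ParamTransform(tau_bounds=(0.5, 1.0))
        z = rng.normal(scale=10, size=(100, 3))
        out = tr.backward(z)
        assert np.all(out[:, 0] > 0) and np.all(out[:, 1] > 0)
        assert np.all((out[:, 2] > 0.5) & (out[:, 2] < 1.0))


class TestAdjustment:
    def test_identical_summaries_leave_theta_unchanged(self, rng):
        # every row's summaries equal s_obs: X = 0, adjustment is a no-op
        theta = PriorSpec().sample_array(50, rng)
        S = np.tile([1.0, 2.0, 3.0], (50, 1))
        res = RejectionABC(toy_table(theta, S), np.array([1.0, 2.0, 3.0])).fit(
            0.5, adjust=True
        )
        assert res.adjusted
        np.testing.assert_allclose(res.theta_adjusted, res.theta_accepted, rtol=1e-8)

    def test_huge_ridge_recovers_raw_draws(self, rng):
        theta = PriorSpec().sample_array(200, rng)
        S = rng.normal(size=(200, 3))
        res = RejectionABC(toy_table(theta, S), np.zeros(3)).fit(
            0.2, adjust=True, transform=False, ridge_lambda=1e12
        )
        np.testing.assert_allclose(res.theta_adjusted, res.theta_accepted, atol=1e-8)

    def test_exact_linear_model_is_corrected_exactly(self, rng):
        """theta depends linearly on the summaries with no noise: the
        adjusted draws all collapse onto the true parameter value."""
        n, k = 500, 3
        prior = PriorSpec(c1=(0.0, 1.0), c3=(0.0, 1.0), tau=(1e-6, 1.0))
        theta = prior.sample_array(n, rng)
        A = rng.normal(size=(3, k))
        S = theta @ A  # exact linear map
        theta_true = np.array([0.4, 0.6, 0.5])
        s_obs = theta_true @ A
        table = toy_table(theta, S, prior=prior)
        res = RejectionABC(table, s_obs).fit(
            0.2, adjust=True, transform=False, ridge_lambda=1e-10
        )
        np.testing.assert_allclose(
            res.theta_adjusted, np.tile(theta_true, (res.n_accepted, 1)), atol=1e-6
        )

    def test_refused_when_too_few_accepted(self, rng):
        theta = PriorSpec().sample_array(40, rng)
        S = rng.normal(size=(40, 5))
        res = RejectionABC(toy_table(theta, S), np.zeros(5)).fit(
            0.1, adjust=True
        )  # 4 accepted < k+2 = 7
        assert res.adjustment_refused
        assert res.theta_adjusted is None

    def test_adjusted_draws_stay_in_prior_box(self, rng):
        prior = PriorSpec()
        theta = prior.sample_array(500, rng)
        # summaries strongly informative of tau to force big moves
        S = np.column_stack([theta[:, 2] + rng.normal(0, 0.01, 500), rng.normal(size=500)])
        res = RejectionABC(
            toy_table(theta, S, prior=prior), np.array([0.99, 0.0])
        ).fit(0.2, adjust=True)
        b = prior.bounds
        assert np.all(res.theta_adjusted >= b[:, 0])
        assert np.all(res.theta_adjusted <= b[:, 1])


class TestResults:
    def test_posterior_mean_matches_numpy(self, rng):
        theta = PriorSpec().sample_array(100, rng)
        S = rng.normal(size=(100, 3))
        res = RejectionABC(toy_table(theta, S), np.zeros(3)).fit(0.3)
        np.testing.assert_allclose(res.params, res.theta_accepted.mean(axis=0))
        pm = res.posterior_mean()
        assert pm.tau == pytest.approx(res.params[2])

    def test_accept_everything_reproduces_prior_mean(self, rng):
        theta = PriorSpec().sample_array(100_000, rng)
        S = rng.normal(size=(100_000, 2))
        res = RejectionABC(toy_table(theta, S), np.zeros(2)).fit(1.0)
        se = (0.5 / np.sqrt(12)) / np.sqrt(100_000)
        assert abs(res.params[2] - 0.75) < 3 * se

    def test_conf_int_on_known_sample(self, rng):
        # draws tau = 1..100 scaled into the prior range via a toy prior
        prior = PriorSpec(c1=(0, 200), c3=(0, 200), tau=(0, 1))
        vals = np.arange(1.0, 101.0)
        theta = np.column_stack([vals, vals, vals / 200])
        S = rng.normal(size=(100, 2))
        res = RejectionABC(toy_table(theta, S, prior=prior), np.zeros(2)).fit(1.0)
        ci = res.conf_int(0.9)
        # np.quantile linear interpolation on 1..100
        assert ci[0, 0] == pytest.approx(5.95)
        assert ci[0, 1] == pytest.approx(95.05)

    def test_intervals_nested_in_level(self, rng):
        theta = PriorSpec().sample_array(1000, rng)
        S = rng.normal(size=(1000, 3))
        res = RejectionABC(toy_table(theta, S), np.zeros(3)).fit(0.1)
        prev = res.conf_int(0.05)
        for level in (0.25, 0.5, 0.75, 0.95):
            ci = res.conf_int(level)
            assert np.all(ci[:, 0] <= prev[:, 0]) and np.all(ci[:, 1] >= prev[:, 1])
            prev = ci

    def test_summary_text(self, rng):
        theta = PriorSpec().sample_array(100, rng)
        S = rng.normal(size=(100, 3))
        res = RejectionABC(toy_table(theta, S), np.zeros(3)).fit(0.1)
        text = res.summary()
        assert "10 of 100" in text
        for name in ("c1", "c3", "tau", "post_mean"):
            assert name in text

    def test_to_frame_with_adjustment(self, rng):
        theta = PriorSpec().sample_array(100, rng)
        S = rng.normal(size=(100, 3))
        res = RejectionABC(toy_table(theta, S), np.zeros(3)).fit(0.2, adjust=True)
        df = res.to_frame()
        assert len(df) == 40  # 20 raw + 20 adjusted
        assert df["adjusted"].sum() == 20


class TestMetricProperties:
    def test_triangle_inequality_sample(self, rng):
        theta = PriorSpec().sample_array(30, rng)
        S = rng.normal(size=(30, 4))
        table = toy_table(theta, S)
        a, b = rng.normal(size=4), rng.normal(size=4)
        da = RejectionABC(table, a).distances()
        db = RejectionABC(table, b).distances()
        dab = np.linalg.norm((a - b) / mad_scale(S))
        assert np.all(da <= db + dab + 1e-12)

    def test_self_distance_zero(self, rng):
        theta = PriorSpec().sample_array(30, rng)
        S = rng.normal(size=(30, 4))
        d = RejectionABC(toy_table(theta, S), S[5]).distances()
        assert d[5] == 0.0
        assert np.all(d >= 0)
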