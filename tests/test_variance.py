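"""Link- and data-scale variance decomposition against closed forms and
Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingmorph.animal_model import PosteriorSamples
from wingmorph.variance import (
    DISTRIBUTION_VARIANCE,
    CovariateMoments,
    conditional_decomposition,
    covariate_moments,
    data_scale_proportions,
    link_scale_proportions,
    marginalized_additive_variance,
    slope_exclusive_variance,
    summarize_components,
)

TABLE_MEDIANS = dict(V_A_I=1.485, V_A_S=0.191, C_A_IS=0.183)
#: per-class totals of the study's density table (densities 1..12)
CLASS_TOTALS = np.array([169, 378, 489, 624, 702, 644, 479, 440, 189, 80, 22, 12])


def _samples(n=2000, seed=0, mode="random_slope", **fixed):
    """Synthetic posterior draws with controllable values."""
    rng = np.random.default_rng(seed)
    base = {
        "alpha": 1.1 + 0.1 * rng.standard_normal(n),
        "beta": 0.6 + 0.05 * rng.standard_normal(n),
        "V_C": np.abs(0.55 + 0.1 * rng.standard_normal(n)),
    }
    if mode == "random_slope":
        v1 = np.abs(1.5 + 0.3 * rng.standard_normal(n))
        v2 = np.abs(0.2 + 0.05 * rng.standard_normal(n))
        rho = np.clip(0.3 + 0.2 * rng.standard_normal(n), -0.95, 0.95)
        base.update(V_A_I=v1, V_A_S=v2, C_A_IS=rho * np.sqrt(v1 * v2))
    else:
        base.update(V_A=np.abs(1.5 + 0.3 * rng.standard_normal(n)))
    for k, v in fixed.items():
        base[k] = np.full(n, v)
    return PosteriorSamples(draws={k: v[None, :] for k, v in base.items()})


class TestCovariateMoments:
    def test_centred_data_has_zero_mean(self):
        df = pd.DataFrame({"nymphal_density": [6.5, 6.5, 6.5], "y": [0, 1, 0]})
        with pytest.warns(UserWarning, match="constant"):
            m = covariate_moments(df)
        assert m.mu == 0.0 and m.V_x == 0.0

    def test_symmetric_pair(self):
        df = pd.DataFrame({"nymphal_density": [1.0, 12.0], "y": [0, 1]})
        m = covariate_moments(df)
        assert m.mu == pytest.approx(0.0)
        assert m.V_x == pytest.approx(30.25)

    def test_study_density_table_moments(self):
        """Weighted moments of the printed per-class totals, centred at 6.5."""
        dens = np.repeat(np.arange(1, 13, dtype=float), CLASS_TOTALS)
        df = pd.DataFrame({"nymphal_density": dens, "y": 0.0})
        m = covariate_moments(df)
        assert m.mu == pytest.approx(-1.29, abs=0.01)
        assert m.V_x == pytest.approx(5.06, abs=0.01)


class TestMarginalizedVariance:
    def test_no_slope_limit(self):
        m = CovariateMoments(mu=-1.3, V_x=5.0)
        assert marginalized_additive_variance(1.485, 0.0, 0.0, m) == 1.485

    def test_centred_covariate_limit(self):
        m = CovariateMoments(mu=0.0, V_x=4.0)
        assert marginalized_additive_variance(2.0, 0.5, 0.3, m) == \
            pytest.approx(2.0 + 0.5 * 4.0)

    def test_matches_monte_carlo_variance(self):
        """V_A,M equals the variance of a1 + a2 x over the covariate
        distribution at the study's posterior-median parameters."""
        m = CovariateMoments(mu=-1.29, V_x=5.06)
        val = marginalized_additive_variance(
            TABLE_MEDIANS["V_A_I"], TABLE_MEDIANS["V_A_S"],
            TABLE_MEDIANS["C_A_IS"], m,
        )
        rng = np.random.default_rng(8)
        n = 1_000_000
        G = np.array(
            [[TABLE_MEDIANS["V_A_I"], TABLE_MEDIANS["C_A_IS"]],
             [TABLE_MEDIANS["C_A_IS"], TABLE_MEDIANS["V_A_S"]]]
        )
        a = rng.multivariate_normal([0, 0], G, size=n)
        x = rng.normal(m.mu, np.sqrt(m.V_x), n)
        mc = np.var(a[:, 0] + a[:, 1] * x)
        assert val == pytest.approx(mc, rel=0.01)

    def test_slope_exclusive_identities(self):
        m = CovariateMoments(mu=0.0, V_x=2.0)
        assert slope_exclusive_variance(0.0, m) == 0.0
        assert slope_exclusive_variance(1.0, m) == pytest.approx(2.0)
        # V_S = V_A,M - V_A,I whenever the covariance is zero
        rng = np.random.default_rng(1)
        for _ in range(20):
            vi, vs = rng.random(2) * 3
            mu, vx = rng.normal(), rng.random() * 6
            mm = CovariateMoments(mu=mu, V_x=vx)
            assert slope_exclusive_variance(vs, mm) == pytest.approx(
                marginalized_additive_variance(vi, vs, 0.0, mm) - vi
            )

    def test_invariance_to_centring_constant(self):
        """Recentring the covariate (recomputing moments) leaves V_A,M
        unchanged when intercept/covariance are transformed consistently;
        with a fixed parameter set, shifting centre by +1 changes mu only."""
        dens = np.repeat(np.arange(1, 13, dtype=float), CLASS_TOTALS)
        df = pd.DataFrame({"nymphal_density": dens, "y": 0.0})
        m1 = covariate_moments(df, centre=6.5)
        m2 = covariate_moments(df, centre=7.5)
        assert m2.mu == pytest.approx(m1.mu - 1.0)
        assert m2.V_x == pytest.approx(m1.V_x)
        # the same random surface re-expressed at the new origin has
        # V_A,I' = Var(a1 + a2) = V_A,I + 2C + V_A,S and C' = C + V_A,S;
        # its marginalized variance (with the recomputed moments) is equal
        vi, vs, c = 1.485, 0.191, 0.183
        v_old = marginalized_additive_variance(vi, vs, c, m1)
        v_new = marginalized_additive_variance(
            vi + 2 * c + vs, vs, c + vs, m2
        )
        assert v_old == pytest.approx(v_new, rel=1e-12)


class TestLinkScaleProportions:
    def test_null_model_is_all_residual(self):
        s = _samples(mode="basic", beta=0.0, V_A=0.0, V_C=0.0)
        m = CovariateMoments(mu=0.0, V_x=4.0)
        props = link_scale_proportions(s, m, mode="basic")
        combined = props["prop_residual"] + props["prop_distribution"]
        np.testing.assert_allclose(combined, 1.0, atol=1e-12)

    def test_hand_computed_fixed_share(self):
        """beta=1, V_x=4.29, no random variance: V_F share =
        4.29 / (4.29 + 1 + pi^2/3) = 0.50."""
        s = _samples(mode="basic", beta=1.0, V_A=0.0, V_C=0.0)
        m = CovariateMoments(mu=0.0, V_x=4.29)
        props = link_scale_proportions(s, m, mode="basic")
        expected = 4.29 / (4.29 + 1.0 + DISTRIBUTION_VARIANCE)
        assert expected == pytest.approx(0.50, abs=0.005)
        np.testing.assert_allclose(props["prop_fixed"], expected, atol=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_proportions_sum_to_one_per_draw(self, seed):
        s = _samples(n=200, seed=seed)
        m = CovariateMoments(mu=-1.3, V_x=5.0)
        props = link_scale_proportions(s, m, mode="random_slope")
        total = (
            props["prop_fixed"] + props["prop_additive"] + props["prop_cage"]
            + props["prop_residual"] + props["prop_distribution"]
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_mode_mismatch_rejected(self):
        s = _samples(mode="basic")
        m = CovariateMoments(mu=0.0, V_x=1.0)
        with pytest.raises(ValueError, match="random-slope"):
            link_scale_proportions(s, m, mode="random_slope")


class TestDataScale:
    def test_uniform_factor_preserves_ranking(self):
        s = _samples()
        m = CovariateMoments(mu=-1.3, V_x=5.0)
        link = summarize_components(
            link_scale_proportions(s, m)[
                ["prop_fixed", "prop_additive", "prop_cage"]
            ]
        )["median"]
        data = summarize_components(
            data_scale_proportions(s, m, P=0.5)[
                ["prop_fixed", "prop_additive", "prop_cage"]
            ]
        )["median"]
        assert list(link.sort_values().index) == list(data.sort_values().index)
        # derivative factor at P = 0.5 is (0.25)^2
        assert (0.5 * 0.5) ** 2 == pytest.approx(0.0625)

    def test_link_and_data_proportions_agree_closely(self):
        """The two scales give similar variance ratios (within 0.05)."""
        s = _samples(seed=5)
        m = CovariateMoments(mu=-1.29, V_x=5.06)
        link = link_scale_proportions(s, m)
        data = data_scale_proportions(s, m, P=0.544)
        for col in ("prop_fixed", "prop_additive", "prop_cage"):
            d = np.abs(np.median(link[col]) - np.median(data[col]))
            assert d < 0.05, col

    def test_degenerate_all_zero_variances(self):
        s = _samples(mode="basic", beta=0.0, V_A=0.0, V_C=0.0)
        m = CovariateMoments(mu=0.0, V_x=1.0)
        props = data_scale_proportions(s, m, P=0.5, mode="basic")
        np.testing.assert_allclose(props["prop_fixed"], 0.0, atol=1e-12)
        np.testing.assert_allclose(props["prop_additive"], 0.0, atol=1e-12)
        np.testing.assert_allclose(props["prop_observation"], 1.0 - props["prop_residual"], atol=1e-12)

    def test_invalid_P_rejected(self):
        s = _samples()
        m = CovariateMoments(mu=0.0, V_x=1.0)
        for P in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                data_scale_proportions(s, m, P=P)


class TestConditionalDecomposition:
    def test_centre_point_equals_intercept_variance(self):
        s = _samples(C_A_IS=0.0)
        cond = conditional_decomposition(s, grid=[6.5], centre=6.5)
        med_vai = np.median(s.pooled("V_A_I"))
        assert cond["V_A_conditional"].iloc[0] == pytest.approx(med_vai, rel=1e-9)

    def test_matches_monte_carlo_at_fixed_x(self):
        """V_A(x) equals the Monte-Carlo variance of a1 + a2 x at fixed x."""
        vi, vs, c = 1.485, 0.191, 0.183
        s = _samples(V_A_I=vi, V_A_S=vs, C_A_IS=c)
        x = -2.5  # density 4
        cond = conditional_decomposition(s, grid=[4.0], centre=6.5)
        rng = np.random.default_rng(2)
        G = np.array([[vi, c], [c, vs]])
        a = rng.multivariate_normal([0, 0], G, size=1_000_000)
        mc = np.var(a[:, 0] + a[:, 1] * x)
        assert cond["V_A_conditional"].iloc[0] == pytest.approx(mc, rel=0.01)

    def test_conditional_variance_nonnegative_when_G_psd(self):
        s = _samples(seed=9)
        cond = conditional_decomposition(s, grid=np.linspace(1, 12, 23))
        assert (cond["V_A_conditional"] >= 0).all()
        assert ((cond["prop_median"] >= 0) & (cond["prop_median"] <= 1)).all()

    def test_data_scale_maximized_at_interior_density(self):
        """With p(x) traversing near 0 to near 1 the data-scale conditional
        proportion peaks at an interior grid point."""
        s = _samples(alpha=1.146, beta=0.9, **TABLE_MEDIANS)
        cond = conditional_decomposition(
            s, grid=np.arange(1.0, 13.0), data_scale=True, P=0.544
        )
        peak = int(np.argmax(cond["prop_median"].to_numpy()))
        assert 0 < peak < len(cond) - 1

    def test_grid_outside_observed_range_warns(self):
        s = _samples()
        with pytest.warns(UserWarning, match="outside"):
            conditional_decomposition(s, grid=[0.5, 3.0], observed_range=(1, 12))

    def test_basic_samples_rejected(self):
        s = _samples(mode="basic")
        with pytest.raises(ValueError, match="random-slope"):
            conditional_decomposition(s)
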