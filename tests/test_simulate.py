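"""Hyperspherical correlation sampling, lognormal pools, stationary series
and gradient simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commstab import (
    CommunityMoments,
    CorrelationAngles,
    GradientSpec,
    LognormalPool,
    ScalingParams,
    angles_to_correlation,
    estimate_phi,
    evenness_evar,
    moments_from_timeseries,
    phi_closed_form,
    sample_correlation,
    sample_pool,
    simulate_gradient,
    simulate_timeseries,
    theoretical_moments,
    validate_moments,
)


class TestAnglesToCorrelation:
    def test_right_angle_gives_independence(self):
        R = angles_to_correlation(CorrelationAngles(n=2, theta=[math.pi / 2]))
        np.testing.assert_allclose(R, np.eye(2), atol=1e-15)

    def test_zero_angle_gives_perfect_correlation(self):
        R = angles_to_correlation(CorrelationAngles(n=2, theta=[0.0]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_three_species_hand_expansion(self):
        R = angles_to_correlation(CorrelationAngles(n=3, theta=[math.pi / 3] * 3))
        assert R[1, 0] == pytest.approx(0.5)
        assert R[2, 0] == pytest.approx(0.5)
        # cos(pi/3)^2 + sin(pi/3) * cos(pi/3) * sin(pi/3)
        assert R[2, 1] == pytest.approx(0.625)

    def test_angle_count_and_range_validated(self):
        with pytest.raises(ValueError, match="angles"):
            CorrelationAngles(n=3, theta=[0.1, 0.2])
        with pytest.raises(ValueError, match=r"\[0, pi\]"):
            CorrelationAngles(n=2, theta=[3.5])

    @settings(deadline=None, max_examples=80)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(2, 12),
    )
    def test_always_a_valid_correlation_matrix(self, seed, n):
        """Any in-range angles yield unit diagonal, symmetry, PSD and
        off-diagonals within [-1, 1]."""
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, math.pi, size=n * (n - 1) // 2)
        R = angles_to_correlation(CorrelationAngles(n=n, theta=theta))
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T)
        assert (np.abs(R) <= 1 + 1e-12).all()
        assert np.linalg.eigvalsh(R)[0] >= -1e-10


class TestSampleCorrelation:
    def test_deterministic_given_seed(self):
        R1 = sample_correlation(6, np.random.default_rng(42))
        R2 = sample_correlation(6, np.random.default_rng(42))
        np.testing.assert_array_equal(R1, R2)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_expected_mean_correlation_is_zero(self, n):
        """Uniform angles on [0, pi] give E[mean pairwise correlation] = 0
        at any richness: the grand mean over 2000 draws sits within 3
        standard errors of zero."""
        rng = np.random.default_rng(n)
        iu = np.triu_indices(n, k=1)
        means = np.empty(2000)
        for k in range(2000):
            means[k] = sample_correlation(n, rng)[iu].mean()
        se = means.std(ddof=1) / math.sqrt(means.size)
        assert abs(means.mean()) < 3 * se

    def test_requires_two_species(self):
        with pytest.raises(ValueError, match="n >= 2"):
            sample_correlation(1, np.random.default_rng(0))


class TestSamplePool:
    def test_sigma_zero_is_perfectly_even(self):
        vals = sample_pool(LognormalPool(mu=1.0, sigma=0.0, pool_size=8))
        np.testing.assert_allclose(vals, math.e)

    def test_seed_reproducibility(self):
        p = LognormalPool(mu=1.0, sigma=2.0, pool_size=16, seed=7)
        np.testing.assert_array_equal(sample_pool(p), sample_pool(p))

    def test_wider_sigma_lowers_evenness(self):
        rng = np.random.default_rng(0)
        e_narrow = np.mean(
            [
                evenness_evar(
                    sample_pool(LognormalPool(sigma=0.5, pool_size=20), rng)
                ).e_var
                for _ in range(50)
            ]
        )
        e_wide = np.mean(
            [
                evenness_evar(
                    sample_pool(LognormalPool(sigma=2.0, pool_size=20), rng)
                ).e_var
                for _ in range(50)
            ]
        )
        assert e_wide < e_narrow


class TestSimulateTimeseries:
    def test_zero_covariance_returns_means(self):
        mom = validate_moments(
            CommunityMoments(m=[2.0, 5.0], V=np.zeros((2, 2)))
        )
        ts = simulate_timeseries(mom, 10, np.random.default_rng(0))
        np.testing.assert_allclose(ts.values, np.tile([2.0, 5.0], (10, 1)))

    def test_sample_variances_concentrate(self):
        """Chi-square concentration: at T = 20000 each sample variance lies
        within 5% of its target."""
        target = np.array([1.0, 4.0, 0.25])
        mom = validate_moments(
            CommunityMoments(m=[10.0, 10.0, 10.0], V=np.diag(target))
        )
        ts = simulate_timeseries(mom, 20000, np.random.default_rng(5))
        sample_var = ts.values.var(axis=0, ddof=1)
        np.testing.assert_allclose(sample_var, target, rtol=0.05)

    def test_plug_in_phi_consistency(self):
        """The plug-in synchrony estimate converges on the population value
        as the series lengthens."""
        rng = np.random.default_rng(11)
        mom = theoretical_moments(
            5, ScalingParams(a=1, b=2, x=0), np.exp(rng.normal(1, 1, 5)), 0.3
        )
        phi_pop = estimate_phi(mom)
        errs = []
        for T in (50, 20000):
            draws = [
                abs(
                    estimate_phi(
                        moments_from_timeseries(simulate_timeseries(mom, T, rng))
                    )
                    - phi_pop
                )
                for _ in range(8)
            ]
            errs.append(np.mean(draws))
        assert errs[1] < errs[0]

    def test_clip_zero_truncates(self):
        mom = validate_moments(CommunityMoments(m=[0.5], V=[[4.0]]))
        ts = simulate_timeseries(mom, 200, np.random.default_rng(0), clip_zero=True)
        assert (ts.values >= 0).all()


class TestSimulateGradient:
    def test_even_pool_constant_rho_matches_closed_form(self):
        """With perfect evenness and a constant correlation, every replicate
        reproduces the equal-variance closed form exactly."""
        df = simulate_gradient(
            LognormalPool(mu=1.0, sigma=0.0, pool_size=64),
            GradientSpec(richness_grid=(1, 2, 4, 8, 16), rho_model=0.1),
            ScalingParams(a=1.0, b=2.0, x=0.0),
            replicates=3,
            seed=0,
        )
        for _, row in df.iterrows():
            assert row["phi"] == pytest.approx(
                phi_closed_form(int(row["n"]), 0.1), rel=1e-12
            )

    def test_deterministic_given_seed(self):
        args = (
            LognormalPool(sigma=1.0, pool_size=32),
            GradientSpec(richness_grid=(2, 4, 8)),
            ScalingParams(a=1, b=1.5, x=0.5),
        )
        df1 = simulate_gradient(*args, replicates=4, seed=9)
        df2 = simulate_gradient(*args, replicates=4, seed=9)
        assert df1.equals(df2)

    def test_unevenness_slows_synchrony_decline(self):
        """Higher lognormal sigma keeps phi higher at intermediate richness
        (synchrony declines more gradually with diversity when unevenness
        is higher)."""
        kw = dict(replicates=150, seed=4)
        spec = GradientSpec(richness_grid=(8,), rho_model="sampled")
        scaling = ScalingParams(a=1.0, b=2.0, x=0.0)
        phi_even = simulate_gradient(
            LognormalPool(sigma=0.0, pool_size=64), spec, scaling, **kw
        )["phi"].mean()
        phi_uneven = simulate_gradient(
            LognormalPool(sigma=2.0, pool_size=64), spec, scaling, **kw
        )["phi"].mean()
        assert phi_uneven > phi_even

    def test_unweighted_cv_flat_but_weighted_trends(self):
        """At x = 0 the unweighted mean species CV has no diversity trend,
        while the abundance-weighted version drifts when b != 2."""
        df = simulate_gradient(
            LognormalPool(sigma=2.0, pool_size=128),
            GradientSpec(richness_grid=(2, 4, 8, 16, 32), rho_model="sampled"),
            ScalingParams(a=1.0, b=1.5, x=0.0),
            replicates=150,
            seed=21,
        )
        agg = df.groupby("n")[["cv_weighted", "cv_unweighted"]].mean()
        weighted_drop = agg["cv_weighted"].iloc[0] - agg["cv_weighted"].iloc[-1]
        unweighted_drop = abs(
            agg["cv_unweighted"].iloc[0] - agg["cv_unweighted"].iloc[-1]
        )
        assert weighted_drop > 0
        assert unweighted_drop < 0.5 * weighted_drop

    @pytest.mark.parametrize(
        "b, decreasing", [(1.5, True), (2.5, False)]
    )
    def test_ordered_assembly_direction(self, b, decreasing):
        """Adding species in order of increasing abundance pushes weighted
        CV down with richness when b < 2 and up when b > 2."""
        df = simulate_gradient(
            LognormalPool(sigma=1.5, pool_size=64),
            GradientSpec(
                richness_grid=(2, 8, 32),
                assembly="ordered_increasing",
                rho_model=0.0,
            ),
            ScalingParams(a=1.0, b=b, x=0.0),
            replicates=60,
            seed=13,
        )
        agg = df.groupby("n")["cv_weighted"].mean()
        diff = agg.iloc[-1] - agg.iloc[0]
        assert diff < 0 if decreasing else diff > 0

    def test_richness_beyond_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            simulate_gradient(
                LognormalPool(pool_size=4),
                GradientSpec(richness_grid=(2, 8)),
                ScalingParams(),
                replicates=1,
                seed=0,
            )

    def test_finite_series_estimates_near_exact_moments(self):
        df = simulate_gradient(
            LognormalPool(sigma=0.0, pool_size=16),
            GradientSpec(richness_grid=(4,), rho_model=0.2),
            ScalingParams(a=1.0, b=2.0, x=0.0),
            replicates=5,
            seed=2,
            timeseries_length=4000,
        )
        assert df["phi"].mean() == pytest.approx(
            phi_closed_form(4, 0.2), abs=0.05
        )
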