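import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import popcode as pc
from popcode._linalg import NotPositiveDefiniteError, n_pairs


def two_neuron_stats(var1=1.0, var2=1.0):
    return pc.PopulationStats(
        sensitivities=[[1.0], [1.0]],
        cross_cov=[[1.0], [1.0]],
        mean_resp_cov=2 * np.eye(2),
        noise_vars=[var1, var2],
        stim_cov=[[1.0]],
    )


class TestNoiseCovFrom:
    def test_independent_identity(self):
        noise = pc.noise_cov_from([1.0, 1.0, 1.0], np.zeros(3))
        np.testing.assert_array_equal(noise.cov, np.eye(3))

    def test_offdiag_scaling(self):
        # 0.5 * sqrt(4 * 1) = 1.0
        noise = pc.noise_cov_from([4.0, 1.0], [0.5])
        assert noise.cov[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(noise.cov), [4.0, 1.0])

    def test_anticorrelated_pair(self):
        noise = pc.noise_cov_from([1.0, 1.0], [-1.0])
        np.testing.assert_allclose(noise.cov, [[1.0, -1.0], [-1.0, 1.0]])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pc.noise_cov_from([1.0, 1.0], [1.5])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pc.noise_cov_from([1.0, 1.0, 1.0], [0.1])

    def test_corr_roundtrip(self, rng):
        nv = rng.uniform(0.5, 3.0, 4)
        vals = pc.random_admissible(4, 4, rng).corr.values
        noise = pc.noise_cov_from(nv, vals)
        np.testing.assert_allclose(noise.corr_pairs().values, vals, atol=1e-12)


class TestLinearFisher:
    def test_unit_sensitivity_identity_noise(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0], [0.0], [0.0]],
            cross_cov=[[1.0], [0.0], [0.0]],
            mean_resp_cov=np.eye(3),
            noise_vars=[1.0, 1.0, 1.0],
            stim_cov=[[1.0]],
        )
        mat, scalar = pc.linear_fisher(stats, pc.independent_noise([1.0, 1.0, 1.0]))
        assert scalar == pytest.approx(1.0)
        assert mat.shape == (1, 1)

    @pytest.mark.parametrize("rho,expected", [(0.5, 4.0 / 3.0), (-0.5, 4.0)])
    def test_symmetric_pair_closed_form(self, rho, expected):
        stats = two_neuron_stats()
        noise = pc.noise_cov_from([1.0, 1.0], [rho])
        _, val = pc.linear_fisher(stats, noise)
        assert val == pytest.approx(expected, rel=1e-14)

    def test_sign_rule_instance(self):
        # negative correlation beats independence for positively signal-correlated pair
        stats = two_neuron_stats()
        indep = pc.linear_fisher(stats, pc.independent_noise([1.0, 1.0]))[1]
        anti = pc.linear_fisher(stats, pc.noise_cov_from([1, 1], [-0.5]))[1]
        assert anti > indep == pytest.approx(2.0)

    def test_singular_noise_raises(self):
        stats = two_neuron_stats()
        noise = pc.NoiseCov([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(NotPositiveDefiniteError):
            pc.linear_fisher(stats, noise)


class TestOLE:
    def test_noise_free_readout(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0], [0.0]],
            cross_cov=[[1.0], [0.0]],
            mean_resp_cov=np.eye(2),
            noise_vars=[1.0, 1.0],
            stim_cov=[[1.0]],
        )
        a = pc.ole_solution(stats, None)
        np.testing.assert_allclose(a.ravel(), [1.0, 0.0])

    def test_canceling_noise_keeps_noise_free_readout(self):
        # C^n annihilates A, so the readout equals the noise-free one and the
        # OLE information equals the noise-free bound (= 2 here), NOT 2/3:
        # (C^n + C_mu)^{-1} L = [[2,-1],[-1,2]]^{-1} (1,1)^T = (1,1)^T.
        stats = pc.PopulationStats(
            sensitivities=[[1.0], [1.0]],
            cross_cov=[[1.0], [1.0]],
            mean_resp_cov=np.eye(2),
            noise_vars=[1.0, 1.0],
            stim_cov=[[2.5]],
        )
        noise = pc.NoiseCov([[1.0, -1.0], [-1.0, 1.0]])
        a = pc.ole_solution(stats, noise)
        np.testing.assert_allclose(a.ravel(), [1.0, 1.0], atol=1e-12)
        a_free = pc.ole_solution(stats, None)
        np.testing.assert_allclose(a, a_free, atol=1e-12)
        _, val = pc.ole_info(stats, noise)
        assert val == pytest.approx(pc.noise_free_bound(stats), rel=1e-14)
        assert val == pytest.approx(2.0, rel=1e-14)

    def test_zero_cross_cov(self, rng, random_stats):
        base = random_stats(rng, 4)
        stats = pc.PopulationStats(
            sensitivities=base.sensitivities,
            cross_cov=np.zeros_like(base.cross_cov),
            mean_resp_cov=base.mean_resp_cov,
            noise_vars=base.noise_vars,
            stim_cov=base.stim_cov,
        )
        noise = pc.independent_noise(stats.noise_vars)
        np.testing.assert_array_equal(pc.ole_solution(stats, noise), 0.0)
        assert pc.ole_info(stats, noise)[1] == 0.0
        assert pc.ole_mse(stats, noise) == pytest.approx(float(np.trace(stats.stim_cov)))

    def test_zero_noise_matches_bound(self, rng, random_stats):
        stats = random_stats(rng, 5)
        zero_noise = pc.NoiseCov(np.eye(5) * 1e-14)
        val = pc.ole_info(stats, zero_noise)[1]
        assert val == pytest.approx(pc.noise_free_bound(stats), rel=1e-9)

    def test_perfect_linear_code_zero_mse(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0]], cross_cov=[[1.0]], mean_resp_cov=[[1.0]],
            noise_vars=[1e-12], stim_cov=[[1.0]],
        )
        assert pc.ole_mse(stats, None) == pytest.approx(0.0, abs=1e-12)

    def test_mse_matches_monte_carlo(self, rng):
        # simulation oracle: draw (s, x) from the generative linear-Gaussian
        # model implied by the statistics and score the OLE readout
        n, reps = 3, 200000
        l = rng.standard_normal((n, 1))
        cs = np.array([[1.3]])
        cmu = l @ np.linalg.solve(cs, l.T)  # exactly linear mean response
        nv = rng.uniform(0.5, 1.5, n)
        corr = pc.random_admissible(n, n, rng).corr.values * 0.5
        noise = pc.noise_cov_from(nv, corr)
        stats = pc.PopulationStats(
            sensitivities=l, cross_cov=l, mean_resp_cov=cmu, noise_vars=nv, stim_cov=cs
        )
        s = rng.normal(0.0, np.sqrt(cs[0, 0]), reps)
        slope = (l / cs[0, 0]).ravel()
        chol = np.linalg.cholesky(noise.cov + 1e-12 * np.eye(n))
        x = slope[None, :] * s[:, None] + rng.standard_normal((reps, n)) @ chol.T
        a = pc.ole_solution(stats, noise).ravel()
        b = -a @ x.mean(axis=0) + s.mean()
        mse_mc = np.mean((x @ a + b - s) ** 2)
        assert mse_mc == pytest.approx(pc.ole_mse(stats, noise), rel=0.02)


class TestMutualInfo:
    def test_independence_zero(self, rng, random_stats):
        base = random_stats(rng, 4)
        stats = pc.PopulationStats(
            sensitivities=base.sensitivities,
            cross_cov=np.zeros_like(base.cross_cov),
            mean_resp_cov=base.mean_resp_cov,
            noise_vars=base.noise_vars,
            stim_cov=base.stim_cov,
        )
        val = pc.mutual_info_gaussian(stats, pc.independent_noise(stats.noise_vars))
        assert val == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sig2,eta2", [(1.0, 1.0), (2.0, 0.5), (0.3, 1.7)])
    def test_single_neuron_channel(self, sig2, eta2):
        stats = pc.PopulationStats(
            sensitivities=[[1.0]], cross_cov=[[sig2]], mean_resp_cov=[[sig2]],
            noise_vars=[eta2], stim_cov=[[sig2]],
        )
        val = pc.mutual_info_gaussian(stats, pc.independent_noise([eta2]))
        assert val == pytest.approx(0.5 * np.log(1 + sig2 / eta2), rel=1e-12)

    def test_small_signal_limit_proportional_to_ole(self, rng):
        # leading Taylor term of the mutual information is I_OLE / (2 sigma_s^2)
        n = 4
        l = rng.standard_normal((n, 1)) * 1.0
        cs = np.array([[1.0]])
        cmu = l @ l.T + pc._linalg.random_pd(rng, n)
        nv = rng.uniform(0.5, 2.0, n)
        for eps in (1e-3, 1e-4):
            stats = pc.PopulationStats(
                sensitivities=l * eps, cross_cov=l * eps,
                mean_resp_cov=cmu * eps**2 + np.eye(n) * 1e-18,
                noise_vars=nv, stim_cov=cs,
            )
            noise = pc.independent_noise(nv)
            mi = pc.mutual_info_gaussian(stats, noise)
            ole = pc.ole_info(stats, noise)[1]
            assert mi == pytest.approx(0.5 * ole / cs[0, 0], rel=5e-2 * np.sqrt(eps) + 1e-4)

    def test_symmetry_in_blocks(self, rng, random_stats):
        # I computed from the (s, x) joint equals the symmetric determinant form
        stats = random_stats(rng, 5, stim_dim=2)
        corr = pc.random_admissible(5, 5, rng).corr.values * 0.4
        noise = pc.noise_cov_from(stats.noise_vars, corr)
        val = pc.mutual_info_gaussian(stats, noise)
        cx = noise.cov + stats.mean_resp_cov
        joint = np.block([[stats.stim_cov, stats.cross_cov.T], [stats.cross_cov, cx]])
        direct = 0.5 * (
            np.linalg.slogdet(stats.stim_cov)[1]
            + np.linalg.slogdet(cx)[1]
            - np.linalg.slogdet(joint)[1]
        )
        assert val == pytest.approx(direct, rel=1e-10)

    def test_inconsistent_joint_raises(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0], [1.0]],
            cross_cov=[[2.0], [2.0]],
            mean_resp_cov=np.eye(2),
            noise_vars=[0.1, 0.1],
            stim_cov=[[1.0]],
        )
        with pytest.raises(pc.InconsistentJointCovarianceError):
            pc.mutual_info_gaussian(stats, pc.independent_noise([0.1, 0.1]))

    def test_boundary_divergence_sentinel(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0]], cross_cov=[[1.0]], mean_resp_cov=[[1.0]],
            noise_vars=[1e-16], stim_cov=[[1.0]],
        )
        with pytest.warns(UserWarning):
            val = pc.mutual_info_gaussian(stats, pc.NoiseCov([[1e-16]]))
        assert np.isinf(val)


class TestSignalCorrelations:
    def test_orthogonal_sensitivities(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0, 0.0], [0.0, 1.0]],
            cross_cov=[[1.0, 0.0], [0.0, 1.0]],
            mean_resp_cov=np.eye(2) * 2,
            noise_vars=[1.0, 1.0],
            stim_cov=np.eye(2),
        )
        xi = pc.signal_correlations(stats, "fisher").values
        assert xi[0] == pytest.approx(0.0)

    def test_scalar_sign_product(self):
        stats = pc.PopulationStats(
            sensitivities=[[2.0], [-3.0]], cross_cov=[[2.0], [-3.0]],
            mean_resp_cov=np.eye(2) * 2, noise_vars=[1.0, 1.0], stim_cov=[[1.0]],
        )
        assert pc.signal_correlations(stats, "fisher").values[0] == pytest.approx(-1.0)

    def test_parallel_sensitivities(self):
        stats = pc.PopulationStats(
            sensitivities=[[1.0, 1.0], [1.0, 1.0]],
            cross_cov=[[1.0, 1.0], [1.0, 1.0]],
            mean_resp_cov=np.eye(2) * 3,
            noise_vars=[1.0, 1.0],
            stim_cov=np.eye(2),
        )
        assert pc.signal_correlations(stats, "fisher").values[0] == pytest.approx(1.0)

    def test_zero_norm_flagged(self):
        stats = pc.PopulationStats(
            sensitivities=[[0.0], [1.0]], cross_cov=[[1.0], [1.0]],
            mean_resp_cov=np.eye(2) * 2, noise_vars=[1.0, 1.0], stim_cov=[[1.0]],
        )
        with pytest.warns(UserWarning):
            xi = pc.signal_correlations(stats, "fisher").values
        assert np.isnan(xi[0])

    def test_bounded(self, rng, random_stats):
        for measure in pc.MEASURES:
            stats = random_stats(rng, 6, stim_dim=2)
            xi = pc.signal_correlations(stats, measure).values
            assert np.all(np.abs(xi[np.isfinite(xi)]) <= 1.0)


class TestGradients:
    def test_two_neuron_fisher_gradient(self):
        # d/d rho [2 / (1 + rho)] at rho = 0 is -2
        stats = two_neuron_stats()
        g = pc.info_gradient_at_independent(stats, "fisher").values
        assert g[0] == pytest.approx(-2.0, rel=1e-12)

    @pytest.mark.parametrize("measure", pc.MEASURES)
    def test_sign_opposite_to_signal_correlations(self, measure, rng, random_stats):
        for _ in range(10):
            stats = random_stats(rng, 5, stim_dim=2)
            xi = pc.signal_correlations(stats, measure).values
            g = pc.info_gradient_at_independent(stats, measure).values
            mask = np.abs(xi) > 1e-10
            assert np.all(np.sign(g[mask]) == -np.sign(xi[mask]))

    @pytest.mark.parametrize("measure", pc.MEASURES)
    def test_matches_finite_differences(self, measure, rng, random_stats):
        stats = random_stats(rng, 5)
        g = pc.info_gradient_at_independent(stats, measure).values
        h = 1e-5
        m = n_pairs(5)
        for p in range(m):
            e = np.zeros(m)
            e[p] = h
            up = pc.info(stats, pc.noise_cov_from(stats.noise_vars, e), measure)
            dn = pc.info(stats, pc.noise_cov_from(stats.noise_vars, -e), measure)
            fd = (up - dn) / (2 * h)
            assert g[p] == pytest.approx(fd, rel=1e-6, abs=1e-10)


class TestNoiseFreeBound:
    def test_identity_case(self):
        n = 4
        stats = pc.PopulationStats(
            sensitivities=np.eye(n), cross_cov=np.eye(n), mean_resp_cov=np.eye(n),
            noise_vars=np.ones(n), stim_cov=np.eye(n),
        )
        assert pc.noise_free_bound(stats) == pytest.approx(n)

    def test_zero_cross_cov(self, rng, random_stats):
        base = random_stats(rng, 3)
        stats = pc.PopulationStats(
            sensitivities=base.sensitivities, cross_cov=np.zeros_like(base.cross_cov),
            mean_resp_cov=base.mean_resp_cov, noise_vars=base.noise_vars,
            stim_cov=base.stim_cov,
        )
        assert pc.noise_free_bound(stats) == 0.0

    def test_dominates_ole_info(self, rng, random_stats):
        stats = random_stats(rng, 5)
        bound = pc.noise_free_bound(stats)
        for _ in range(100):
            d = int(rng.integers(1, 6))
            corr = pc.random_admissible(5, d, rng).corr
            noise = pc.noise_cov_from(stats.noise_vars, corr)
            assert pc.ole_info(stats, noise)[1] <= bound + 1e-9 * abs(bound)


class TestStrengthAndWeights:
    def test_strength_examples(self):
        assert pc.correlation_strength(np.zeros(3)) == 0.0
        assert pc.correlation_strength(np.array([-1.0])) == 1.0
        assert pc.correlation_strength(np.array([0.3, 0.4, 0.0])) == pytest.approx(0.5)

    def test_two_neuron_weight(self):
        # gradient -2, signal correlation +1: positive weight 2
        stats = two_neuron_stats()
        w = pc.rescaling_weights(stats, "fisher")
        assert w[0] == pytest.approx(2.0, rel=1e-12)

    def test_homogeneous_population_equal_weights(self):
        n = 4
        stats = pc.PopulationStats(
            sensitivities=np.ones((n, 1)), cross_cov=np.ones((n, 1)),
            mean_resp_cov=np.ones((n, n)) * 0.5 + np.eye(n) * 0.5,
            noise_vars=np.ones(n), stim_cov=[[2.0]],
        )
        for measure in pc.MEASURES:
            w = pc.rescaling_weights(stats, measure)
            np.testing.assert_allclose(w, w[0], rtol=1e-10)

    @pytest.mark.parametrize("measure", pc.MEASURES)
    def test_weights_reproduce_gradient(self, measure, rng, random_stats):
        stats = random_stats(rng, 6)
        w = pc.rescaling_weights(stats, measure)
        xi = pc.signal_correlations(stats, measure).values
        g = pc.info_gradient_at_independent(stats, measure).values
        ok = np.isfinite(w)
        assert np.all(w[ok] > 0)
        np.testing.assert_allclose(w[ok] * xi[ok], -g[ok], rtol=1e-10, atol=1e-12)


class TestPairVector:
    @given(st.integers(min_value=2, max_value=9))
    @settings(max_examples=20, deadline=None)
    def test_roundtrip_matrix(self, n):
        rng = np.random.default_rng(n)
        vals = rng.uniform(-1, 1, n_pairs(n))
        pv = pc.PairVector(vals, label="noise_corr")
        mat = pv.matrix(1.0)
        assert mat.shape == (n, n)
        np.testing.assert_array_equal(pc._linalg.matrix_to_pairs(mat), vals)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            pc.PairVector(np.zeros(4))

    def test_noise_corr_range_validated(self):
        with pytest.raises(ValueError):
            pc.PairVector([1.2], label="noise_corr")


class TestConvexityProperty:
    @pytest.mark.parametrize("measure", pc.MEASURES)
    def test_midpoint_convexity(self, measure, rng, random_stats):
        stats = random_stats(rng, 6)
        for _ in range(200):
            a = pc.random_admissible(6, int(rng.integers(2, 7)), rng).corr.values
            b = pc.random_admissible(6, int(rng.integers(2, 7)), rng).corr.values
            vals = []
            for v in (a, b, 0.5 * (a + b)):
                noise = pc.noise_cov_from(stats.noise_vars, v)
                try:
                    vals.append(pc.info(stats, noise, measure))
                except NotPositiveDefiniteError:
                    vals = None
                    break
            if vals is None or not all(np.isfinite(vals)):
                continue
            assert vals[2] <= 0.5 * (vals[0] + vals[1]) + 1e-8 * max(abs(vals[0]), abs(vals[1]), 1.0)
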