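import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traitscape import diversity as dv


def coverage_oracle(x):
    """Independent step-by-step implementation of the coverage estimator."""
    x = np.asarray([v for v in x if v > 0], dtype=int)
    n = x.sum()
    f1 = np.sum(x == 1)
    f2 = np.sum(x == 2)
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1) / ((n - 1) * f1 + 2 * f2)


def alpha_oracle(x, target=0.985):
    """Independent oracle for coverage-targeted richness.

    Solves the extrapolated-coverage equation numerically for m instead of
    using the closed-form log solution, then evaluates the richness
    extrapolation formula.
    """
    from scipy.optimize import brentq

    x = np.asarray([v for v in x if v > 0], dtype=int)
    n = int(x.sum())
    S_obs = len(x)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f1 == 0 or coverage_oracle(x) >= target:
        return float(S_obs)
    f0 = f1**2 / (2 * f2) if f2 > 0 else f1 * (f1 - 1) / 2
    if f0 == 0:
        return float(S_obs)
    A = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)

    def cov_at(m):
        return 1.0 - (f1 / n) * A ** (m + 1)

    if A >= 1.0 or cov_at(1e9) < target:
        m_star = np.inf
    else:
        m_star = brentq(lambda m: cov_at(m) - target, 0.0, 1e9)
    if np.isinf(m_star):
        return float(S_obs + f0)
    return float(S_obs + f0 * (1 - (1 - f1 / (n * f0 + f1)) ** m_star))


class TestDrawAbundance:
    def test_extremes(self):
        p = np.array([[1.0, 0.0]])
        a = dv.draw_abundance(p, K=20, seed=0)
        assert a[0, 0] == 20 and a[0, 1] == 0

    def test_binomial_expectation(self):
        p = np.full((100, 100), 0.5)
        a = dv.draw_abundance(p, K=20, seed=1)
        assert a.mean() == pytest.approx(10.0, abs=0.1)

    def test_seed_determinism_and_bounds(self):
        p = np.random.default_rng(0).random((10, 10))
        a = dv.draw_abundance(p, K=20, seed=5)
        b = dv.draw_abundance(p, K=20, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 20


class TestSampleCoverage:
    @pytest.mark.parametrize(
        "vec, expected",
        [([5, 3, 2], 1.0), ([1, 1, 1], 0.0), ([2, 1, 1], 0.625)],
    )
    def test_closed_forms(self, vec, expected):
        assert dv.sample_coverage(vec) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            dv.sample_coverage([0, 0])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.integers(0, 6, size=rng.integers(2, 15))
            if x.sum() == 0:
                continue
            assert dv.sample_coverage(x) == pytest.approx(coverage_oracle(x))


class TestAlphaCoverage:
    def test_complete_coverage_returns_observed_richness(self):
        assert dv.alpha_coverage([10, 10, 10], target=0.985) == 3.0
        assert dv.alpha_coverage([10, 10, 10], target=0.5) == 3.0

    def test_all_singletons_finite_extrapolation(self):
        # f2 = 0: f0 = f1(f1-1)/2 = 3, coverage never reaches the target,
        # so the asymptotic estimate S_obs + f0 applies
        assert dv.alpha_coverage([1, 1, 1], target=0.985) == pytest.approx(6.0)

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            x = rng.integers(0, 8, size=rng.integers(3, 25))
            if x.sum() < 2:
                continue
            got = dv.alpha_coverage(x)
            want = alpha_oracle(x)
            assert got == pytest.approx(want, rel=1e-6), x
            checked += 1

    def test_monotone_in_target(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.integers(0, 5, size=10)
            if x.sum() < 1:
                continue
            assert dv.alpha_coverage(x, 0.985) >= dv.alpha_coverage(x, 0.90) - 1e-12


class TestFunctionalThreshold:
    def test_two_species_closed_form(self):
        D = np.array([[0.0, 0.6], [0.6, 0.0]])
        assert dv.functional_threshold([5, 5], D) == pytest.approx(0.3)

    def test_equal_distance_closed_form(self):
        S, d = 7, 0.4
        D = np.full((S, S), d)
        np.fill_diagonal(D, 0.0)
        tau = dv.functional_threshold(np.ones(S), D)
        assert tau == pytest.approx(d * (S - 1) / S)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        x = rng.integers(1, 9, size=6)
        p = x / x.sum()
        want = sum(
            p[i] * p[j] * D[i, j] for i in range(6) for j in range(6)
        )
        assert dv.functional_threshold(x, D) == pytest.approx(want)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            dv.functional_threshold([5, 0, 0], np.zeros((3, 3)))


class TestTraitAlpha:
    def test_all_distant_species_equal_species_alpha(self):
        D = np.full((4, 4), 0.9)
        np.fill_diagonal(D, 0.0)
        x = [3, 4, 5, 6]
        assert dv.trait_alpha(x, D, tau=0.5) == dv.alpha_coverage(x)

    def test_all_close_species_single_entity(self):
        D = np.full((4, 4), 0.1)
        np.fill_diagonal(D, 0.0)
        assert dv.trait_alpha([10, 10, 10, 10], D, tau=0.5) == 1.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_trait_alpha_never_exceeds_species_alpha(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(3, 12))
        D = rng.random((S, S))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        x = rng.integers(0, 10, size=S)
        if x.sum() < 1:
            return
        tau = float(rng.uniform(0.05, 0.9))
        assert dv.trait_alpha(x, D, tau) <= dv.alpha_coverage(x) + 1e-9


class TestBetaDissimilarity:
    def test_identical_pair_species(self):
        X = np.array([[3, 3], [2, 2], [1, 1]])
        np.testing.assert_allclose(dv.beta_dissimilarity(X, "species"), 0.0)

    def test_disjoint_pair_species(self):
        X = np.array([[3, 0], [0, 2]])
        np.testing.assert_allclose(dv.beta_dissimilarity(X, "species"), 1.0)

    def test_trait_limits(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        ident = np.array([[3, 3], [2, 2]])
        np.testing.assert_allclose(
            dv.beta_dissimilarity(ident, "trait", gower=D, tau=1.0), 0.0, atol=1e-12
        )
        disjoint = np.array([[3, 0], [0, 2]])
        np.testing.assert_allclose(
            dv.beta_dissimilarity(disjoint, "trait", gower=D, tau=1.0), 1.0
        )

    def test_trait_pair_matches_brute_force(self):
        # 3 species, 2 units: recompute FD-gamma/alpha from explicit loops
        rng = np.random.default_rng(6)
        D = rng.random((3, 3)) * 0.8
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        tau = 0.5
        dtau = np.minimum(D, tau)
        xu = np.array([4.0, 1.0, 0.0])
        xw = np.array([0.0, 2.0, 3.0])
        pu, pw = xu / xu.sum(), xw / xw.sum()
        pp = (pu + pw) / 2
        Q = pp @ dtau @ pp
        fd_gamma = 1.0 / sum(
            dtau[i, j] * (pp[i] * pp[j] / Q) ** 2 for i in range(3) for j in range(3)
        )
        items = [(i, p / 2) for i, p in enumerate(pu)] + [
            (i, p / 2) for i, p in enumerate(pw)
        ]
        s = sum(
            dtau[i, j] * (a * b / Q) ** 2 for i, a in items for j, b in items
        )
        fd_alpha = 0.25 / s
        d_beta = fd_gamma / fd_alpha
        assert 1.0 <= d_beta <= 4.0
        want_u = (4.0 - d_beta) / 3.0
        got = dv._trait_beta_pair(xu, xw, dtau)
        assert got == pytest.approx(want_u, rel=1e-9)

    def test_empty_unit_excluded(self):
        X = np.array([[3, 0, 3], [2, 0, 2]])
        out = dv.beta_dissimilarity(X, "species")
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.0)

    def test_q0_replication_principle(self):
        # pooling two equally-sized compositionally disjoint assemblages
        # doubles richness-based gamma
        xu = np.array([2, 2, 2, 0, 0, 0])
        xw = np.array([0, 0, 0, 2, 2, 2])
        s_u = (xu > 0).sum()
        pooled = ((xu + xw) > 0).sum()
        assert pooled == 2 * s_u
        # and the pairwise similarity is zero
        assert dv._species_beta_pair(xu, xw) == pytest.approx(0.0)


class TestBuildLayers:
    def test_deterministic_per_seed(self, complete_traits):
        from traitscape import traits as tr

        gow = tr.gower_matrix(complete_traits)
        rng = np.random.default_rng(7)
        p = rng.random((12, 9))
        a = dv.build_layers(p, gow, seed=3)
        b = dv.build_layers(p, gow, seed=3)
        np.testing.assert_array_equal(a.species_alpha, b.species_alpha)
        np.testing.assert_array_equal(a.trait_beta, b.trait_beta)

    def test_uniform_landscape_beta_near_zero(self, complete_traits):
        from traitscape import traits as tr

        gow = tr.gower_matrix(complete_traits)
        p = np.tile(np.linspace(0.9, 1.0, 12)[:, None], (1, 6))
        layers = dv.build_layers(p, gow, K=50, seed=1)
        assert layers.species_beta.max() < 0.1

    def test_two_block_disjoint_floras_have_high_boundary_beta(self):
        # two disjoint floras occupying the left and right halves of a strip
        S, M = 10, 6
        p = np.zeros((S, M))
        p[:5, :3] = 1.0
        p[5:, 3:] = 1.0
        D = np.full((S, S), 0.8)
        np.fill_diagonal(D, 0.0)
        layers = dv.build_layers(p, D, K=20, seed=2)
        # each unit has 2 identical partners and 3 fully distinct ones
        np.testing.assert_allclose(layers.species_beta, 0.6, atol=1e-9)
        assert layers.provenance["tau"] > 0

    def test_invariants_on_random_layers(self, complete_traits):
        from traitscape import traits as tr

        gow = tr.gower_matrix(complete_traits)
        p = np.random.default_rng(8).random((12, 9)) * 0.8
        layers = dv.build_layers(p, gow, seed=4)
        assert (layers.trait_alpha <= layers.species_alpha + 1e-9).all()
        for arr in (layers.species_beta, layers.trait_beta):
            assert (arr >= 0).all() and (arr <= 1).all()
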