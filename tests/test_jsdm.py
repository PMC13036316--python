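import numpy as np
import pandas as pd
import pytest

from traitscape import jsdm
from traitscape import phylogeny as phy
from traitscape import synthetic_data as synth
from traitscape.occurrences import PlanningGrid


@pytest.fixture(scope="module")
def tiny_setup():
    """Small S x M problem with matching covariances and design."""
    S, M = 6, 6
    tree = synth.gen_phylogeny(S, seed=3)
    Sspp, labels = phy.phylo_covariance(tree)
    grid = PlanningGrid(3, 2)
    Sm = jsdm.spatial_covariance(grid)
    rng = np.random.default_rng(0)
    env = pd.DataFrame(
        rng.standard_normal((M, 3)),
        columns=["annual_mean_temp", "temp_seasonality", "soil_organic_carbon"],
    )
    traits = pd.DataFrame({"leaf_length": rng.standard_normal(S)},
                          index=pd.Index(labels, name="species"))
    return dict(S=S, M=M, Sspp=Sspp, Sm=Sm, env=env, traits=traits, grid=grid)


def dense_V(variances, Sspp, Sm, sp_idx, un_idx):
    S, M = Sspp.shape[0], Sm.shape[0]
    Ws = np.eye(S)[sp_idx]
    Wm = np.eye(M)[un_idx]
    va, vb, vc, vd, ve = variances
    return (
        ve * np.eye(len(sp_idx))
        + Ws @ (va * np.eye(S) + vb * Sspp) @ Ws.T
        + Wm @ (vc * np.eye(M) + vd * Sm) @ Wm.T
    )


class TestSpatialCovariance:
    def test_closed_forms(self):
        grid = PlanningGrid(3, 1)
        Sm = jsdm.spatial_covariance(grid)
        assert Sm[0, 0] == pytest.approx(1.0)  # d = 0
        assert Sm[0, 2] == pytest.approx(np.exp(-1.0))  # d = d_max

    def test_single_unit(self):
        assert jsdm.spatial_covariance(PlanningGrid(1, 1)).shape == (1, 1)

    def test_psd_on_50_unit_grid(self):
        Sm = jsdm.spatial_covariance(PlanningGrid(10, 5))
        assert np.linalg.eigvalsh(Sm).min() > -1e-10


class TestBuildDesign:
    def test_null_has_four_columns(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        assert d.X.shape[1] == 4

    def test_trait_model_has_eight_columns(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait="leaf_length"),
                              tiny_setup["traits"], tiny_setup["env"])
        assert d.X.shape[1] == 8

    def test_binary_trait_interaction_structure(self, tiny_setup):
        traits = tiny_setup["traits"].copy()
        traits["red"] = [1.0, 0, 1, 0, 1, 0]
        d = jsdm.build_design(jsdm.ModelSpec(trait="red"), traits, tiny_setup["env"])
        env_col = d.columns.index("annual_mean_temp")
        int_col = d.columns.index("red:annual_mean_temp")
        on = d.X[:, d.columns.index("red")] == 1.0
        np.testing.assert_allclose(d.X[on, int_col], d.X[on, env_col])
        np.testing.assert_allclose(d.X[~on, int_col], 0.0)

    def test_rows_species_major(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        assert (d.sp_idx[: tiny_setup["M"]] == 0).all()
        assert (d.un_idx[: tiny_setup["M"]] == np.arange(tiny_setup["M"])).all()

    def test_nonfinite_rejected(self, tiny_setup):
        env = tiny_setup["env"].copy()
        env.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"], env)


class TestWoodburyAgainstDense:
    def test_solve_logdet_diag(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait="leaf_length"),
                              tiny_setup["traits"], tiny_setup["env"])
        struct = jsdm._CovStructure(tiny_setup["Sspp"], tiny_setup["Sm"],
                                    d.sp_idx, d.un_idx)
        vs = (0.3, 0.2, 0.15, 0.25, 0.5)
        V = struct.V(vs)
        Vd = dense_V(vs, tiny_setup["Sspp"], tiny_setup["Sm"], d.sp_idx, d.un_idx)
        rng = np.random.default_rng(1)
        r = rng.standard_normal(d.n)
        np.testing.assert_allclose(V.solve(r), np.linalg.solve(Vd, r), atol=1e-9)
        assert V.logdet == pytest.approx(np.linalg.slogdet(Vd)[1])
        np.testing.assert_allclose(
            V.diag_inverse(), np.diag(np.linalg.inv(Vd)), atol=1e-9
        )


class TestFit:
    def test_ols_limit(self, tiny_setup):
        # residual-only truth: GLS fixed effects collapse to OLS
        rng = np.random.default_rng(2)
        d = jsdm.build_design(jsdm.ModelSpec(trait="leaf_length"),
                              tiny_setup["traits"], tiny_setup["env"])
        beta_true = rng.normal(size=d.X.shape[1]) * 0.2
        y = d.X @ beta_true + 0.05 * rng.standard_normal(d.n)
        f = jsdm.fit(y, d, tiny_setup["Sspp"], tiny_setup["Sm"])
        ols = np.linalg.lstsq(d.X, y, rcond=None)[0]
        np.testing.assert_allclose(f.beta, ols, atol=1e-4)

    def test_loglik_not_below_initialization(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        rng = np.random.default_rng(3)
        y = (rng.random(d.n) < 0.4).astype(float)
        struct = jsdm._CovStructure(tiny_setup["Sspp"], tiny_setup["Sm"],
                                    d.sp_idx, d.un_idx)
        v0 = max(float(np.var(y)), 1e-6) / 5.0
        nll0 = jsdm._profile_nll(np.log(np.full(5, v0)), struct, d.X, y)[0]
        f = jsdm.fit(y, d, tiny_setup["Sspp"], tiny_setup["Sm"])
        assert f.loglik >= -nll0 - 1e-9

    def test_species_permutation_equivariance(self, tiny_setup):
        rng = np.random.default_rng(4)
        d = jsdm.build_design(jsdm.ModelSpec(trait="leaf_length"),
                              tiny_setup["traits"], tiny_setup["env"])
        y = (rng.random(d.n) < 0.4).astype(float)
        f = jsdm.fit(y, d, tiny_setup["Sspp"], tiny_setup["Sm"])
        S, M = tiny_setup["S"], tiny_setup["M"]
        perm = rng.permutation(S)
        traits_p = tiny_setup["traits"].iloc[perm]
        d_p = jsdm.build_design(jsdm.ModelSpec(trait="leaf_length"), traits_p,
                                tiny_setup["env"])
        y_p = y.reshape(S, M)[perm].reshape(-1)
        Sspp_p = tiny_setup["Sspp"][np.ix_(perm, perm)]
        f_p = jsdm.fit(y_p, d_p, Sspp_p, tiny_setup["Sm"])
        np.testing.assert_allclose(f.beta, f_p.beta, atol=1e-5)
        np.testing.assert_allclose(
            f.latent.reshape(S, M)[perm], f_p.latent.reshape(S, M), atol=1e-6
        )


class TestPredict:
    def test_rescaled_to_unit_interval(self, tiny_setup):
        rng = np.random.default_rng(5)
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        y = (rng.random(d.n) < 0.4).astype(float)
        f = jsdm.fit(y, d, tiny_setup["Sspp"], tiny_setup["Sm"])
        p = jsdm.predict(f)
        assert p.min() == pytest.approx(0.0)
        assert p.max() == pytest.approx(1.0)
        # monotone transform preserves ranking
        order_latent = np.argsort(np.asarray(f.latent).ravel())
        order_p = np.argsort(p.ravel())
        np.testing.assert_array_equal(order_latent, order_p)

    def test_constant_surface_maps_to_half(self, tiny_setup):
        f = jsdm.FitResult(
            beta=np.zeros(1), beta_se=np.zeros(1), columns=["intercept"],
            variances={}, loglik=0.0, converged=True, n_eval=0,
            latent=np.full((3, 3), 0.7),
        )
        np.testing.assert_allclose(jsdm.predict(f), 0.5)


class TestAverageRuns:
    def test_mean_and_permutation_invariance(self):
        a = np.zeros((2, 2))
        b = np.ones((2, 2))
        np.testing.assert_allclose(jsdm.average_runs([a, b]), 0.5)
        c = np.full((2, 2), 0.25)
        np.testing.assert_allclose(
            jsdm.average_runs([a, b, c]), jsdm.average_runs([c, a, b])
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jsdm.average_runs([np.zeros((2, 2)), np.zeros((3, 2))])


class TestCrossValidate:
    def test_near_perfect_fit_gives_small_rmse(self, tiny_setup):
        rng = np.random.default_rng(6)
        d = jsdm.build_design(jsdm.ModelSpec(trait="leaf_length"),
                              tiny_setup["traits"], tiny_setup["env"])
        beta = rng.normal(size=d.X.shape[1])
        y = d.X @ beta + 1e-4 * rng.standard_normal(d.n)
        r = jsdm.cross_validate(y, d, tiny_setup["Sspp"], tiny_setup["Sm"],
                                k=3, seed=0)
        assert r.mean() < 0.01

    def test_every_species_in_every_training_fold(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        labels = jsdm._species_stratified_folds(d, k=3, seed=1)
        for fold in range(3):
            train_species = set(d.sp_idx[labels != fold])
            assert train_species == set(range(tiny_setup["S"]))

    def test_rejects_k_below_two(self, tiny_setup):
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        with pytest.raises(ValueError):
            jsdm.cross_validate(np.zeros(d.n), d, tiny_setup["Sspp"],
                                tiny_setup["Sm"], k=1)


class TestCPO:
    def test_iid_limit_matches_closed_form(self, tiny_setup):
        # all random-effect variances ~ 0: CPO is the Gaussian density under
        # the leave-one-out conditional of an (almost) iid model
        rng = np.random.default_rng(7)
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        y = d.X @ np.array([0.4, 0.1, -0.1, 0.05]) + 0.2 * rng.standard_normal(d.n)
        f = jsdm.fit(y, d, tiny_setup["Sspp"], tiny_setup["Sm"])
        c = jsdm.cpo(f)
        assert (c > 0).all()
        # brute-force conditioning oracle at the fitted covariance
        from scipy.stats import norm

        vs = [f.variances[k] for k in jsdm._VAR_NAMES]
        Vd = dense_V(vs, tiny_setup["Sspp"], tiny_setup["Sm"], d.sp_idx, d.un_idx)
        mu = d.X @ f.beta
        n = d.n
        oracle = np.empty(n)
        for i in range(n):
            o = np.delete(np.arange(n), i)
            cvec = Vd[i, o]
            sol = np.linalg.solve(Vd[np.ix_(o, o)], np.column_stack([y[o] - mu[o], cvec]))
            cm = mu[i] + cvec @ sol[:, 0]
            cv = Vd[i, i] - cvec @ sol[:, 1]
            oracle[i] = norm.pdf(y[i], cm, np.sqrt(cv))
        np.testing.assert_allclose(c, oracle, atol=1e-8)

    def test_outliers_get_lower_cpo(self, tiny_setup):
        rng = np.random.default_rng(8)
        d = jsdm.build_design(jsdm.ModelSpec(trait=None), tiny_setup["traits"],
                              tiny_setup["env"])
        y = 0.1 * rng.standard_normal(d.n)
        y[0] = 5.0  # gross outlier
        f = jsdm.fit(y, d, tiny_setup["Sspp"], tiny_setup["Sm"])
        c = jsdm.cpo(f)
        assert c[0] < np.median(c)


class TestDeltaMetrics:
    def test_identical_models_give_zero_delta(self):
        rmse = np.array([0.4, 0.5])
        quart = pd.Series([1, 2], index=["A", "B"])
        cpo_arr = np.ones((2, 3))
        ev = jsdm.delta_metrics(
            {("leaf_length", "points"): rmse},
            {"points": rmse.copy()},
            {("leaf_length", "points"): cpo_arr},
            {"points": cpo_arr.copy()},
            quart,
            ["A", "B"],
        )
        t = ev.rmse_table
        assert t.loc[t.model == "leaf_length", "delta_rmse"].iloc[0] == 0.0
        assert (ev.delta_cpo_species["delta_cpo"] == 0).all()

    def test_scaling_maps_best_to_zero_worst_to_one(self):
        quart = pd.Series([1], index=["A"])
        ev = jsdm.delta_metrics(
            {("t1", "points"): np.array([0.2]), ("t2", "points"): np.array([0.6])},
            {"points": np.array([0.4])},
            {}, {}, quart, ["A"],
        )
        t = ev.rmse_table.set_index("model")
        assert t.loc["t1", "rmse_scaled"] == 0.0
        assert t.loc["t2", "rmse_scaled"] == 1.0
        assert t.loc["t1", "delta_rmse"] == pytest.approx(-0.5)

    def test_rare_species_signal_shows_in_quartile_one(self):
        # trait CPO gains concentrated in quartile-1 species
        species = [f"S{i}" for i in range(8)]
        quart = pd.Series([1, 1, 2, 2, 3, 3, 4, 4], index=species)
        base = np.full((8, 5), 0.5)
        gain = base.copy()
        gain[:2] += 0.3  # rare species predicted much better
        ev = jsdm.delta_metrics(
            {("t", "points"): np.array([0.3])}, {"points": np.array([0.3])},
            {("t", "points"): gain}, {"points": base}, quart, species,
        )
        qs = ev.quartile_summary["overall"]
        assert qs.loc[1] > qs.loc[4]
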