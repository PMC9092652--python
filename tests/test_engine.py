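"""Likelihood engine: design coding, covariance assembly, fitting, BLUPs."""

import numpy as np
import pandas as pd
import pytest

import nestlmm as nl
from nestlmm import (LongitudinalDataset, ModelSpec, RandomEffectsLevel,
                     ResidualStructure, TrajectoryLMM, design_matrices,
                     marginal_covariance, refit_all_optimizers)
from nestlmm.model import LMMProblem, SpecError, embed_theta, pack_theta, unpack_theta

from conftest import dense_negloglik, random_small_instance


def _toy(times=(0.0, 1.0), groups=("a",)):
    rows = []
    for gi, g in enumerate(groups):
        for t in times:
            rows.append({"subject": f"m{gi}", "group": g, "time": t,
                         "response": float(t)})
    return LongitudinalDataset(pd.DataFrame(rows))


class TestDesignMatrices:
    def test_reference_group_coding(self):
        ds = _toy(groups=("a", "b"))
        spec = nl.make_model_spec("V").spec
        blocks = design_matrices(ds, spec)
        X0 = blocks["m0"]["X"]  # reference group, times 0 and 1
        np.testing.assert_allclose(X0, [[1, 0, 0, 0], [1, 0, 1, 0]])
        X1 = blocks["m1"]["X"]
        np.testing.assert_allclose(X1, [[1, 1, 0, 0], [1, 1, 1, 1]])

    def test_slope_only_z_is_time_column(self):
        ds = _toy(groups=("a", "b"), times=(0.0, 2.0, 5.0))
        spec = nl.make_model_spec("VI").spec  # mouse slope only + AR(1)
        blocks = design_matrices(ds, spec)
        z = blocks["m0"]["Z_subject"][0]
        np.testing.assert_allclose(z[:, 0], [0.0, 2.0, 5.0])
        assert z.shape[1] == 1

    def test_demo_design_dimensions(self):
        grid = nl.blanton_design_grid()
        ds = nl.build_design(grid).with_response(np.zeros(480))
        prob = LMMProblem(ds, nl.make_model_spec("I").spec)
        assert prob.X_all.shape == (480, 4)

    def test_single_group_is_rank_error(self):
        ds = _toy(groups=("a",))
        with pytest.raises(SpecError):
            LMMProblem(ds, nl.make_model_spec("V").spec)

    def test_cluster_spec_without_cluster_column(self):
        ds = _toy(groups=("a", "b"))
        with pytest.raises(SpecError):
            LMMProblem(ds, nl.make_model_spec("I").spec)


class TestMarginalCovariance:
    def test_intercept_only_two_obs(self):
        spec = nl.make_model_spec("IV").spec
        V = marginal_covariance(spec, {"g_subject": [[2.0]], "sigma2": 1.0},
                                times=[0.0, 1.0])
        np.testing.assert_allclose(V, [[3.0, 2.0], [2.0, 3.0]])

    def test_no_random_effects_identity(self):
        spec = nl.make_model_spec("V").spec
        V = marginal_covariance(spec, {"sigma2": 1.0}, times=[0.0, 1.0, 2.0])
        np.testing.assert_allclose(V, np.eye(3))

    def test_ar1_phi_zero_equals_independent(self):
        v_ind = marginal_covariance(nl.make_model_spec("VII").spec,
                                    {"g_subject": [[1.5]], "sigma2": 2.0,
                                     "phi": 0.0}, times=[0.0, 1.0, 3.0])
        v_iid = marginal_covariance(nl.make_model_spec("IV").spec,
                                    {"g_subject": [[1.5]], "sigma2": 2.0},
                                    times=[0.0, 1.0, 3.0])
        np.testing.assert_allclose(v_ind, v_iid)

    def test_ar1_decay_by_observation_order(self):
        spec = nl.make_model_spec("VIII").spec
        V = marginal_covariance(spec, {"sigma2": 1.0, "phi": 0.5},
                                times=[0.0, 1.0, 3.0])
        np.testing.assert_allclose(V, [[1.0, 0.5, 0.25],
                                       [0.5, 1.0, 0.5],
                                       [0.25, 0.5, 1.0]])

    def test_non_psd_g_rejected(self):
        spec = nl.make_model_spec("III").spec
        with pytest.raises(ValueError):
            marginal_covariance(spec, {"g_subject": [[1.0, 5.0], [5.0, 1.0]],
                                       "sigma2": 1.0}, times=[0.0, 1.0])


class TestLikelihood:
    @pytest.mark.parametrize("mid", ["I", "II", "III", "IV", "VI", "VII", "VIII"])
    def test_matches_dense_oracle(self, mid, small_nested_dataset):
        rng = np.random.default_rng(11)
        spec = nl.make_model_spec(mid).spec
        prob = LMMProblem(small_nested_dataset, spec)
        for reml in (True, False):
            theta = rng.normal(size=spec.n_theta) * 0.4
            a = prob.nll(theta, reml)
            b = dense_negloglik(small_nested_dataset, spec, theta, reml)
            assert a == pytest.approx(b, rel=1e-10)

    def test_zero_variance_reduces_to_ols_gaussian(self, intercept_only_dataset):
        ds = intercept_only_dataset
        spec = nl.make_model_spec("IV").spec
        sigma2 = 2.7
        theta = pack_theta(spec, [np.array([[1e-300]])], sigma2)
        theta[0] = -300.0  # log-chol floor: variance exp(-600) ~ 0
        prob = LMMProblem(ds, spec)
        # direct OLS Gaussian -loglik at same sigma2
        X, y = prob.X_all, prob.y_all
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        N = len(y)
        ols = 0.5 * (N * np.log(2 * np.pi * sigma2) + r @ r / sigma2)
        theta_v = np.array([np.log(sigma2)])
        assert prob.nll(theta, False) == pytest.approx(ols, rel=1e-10)
        prob_v = LMMProblem(ds, nl.make_model_spec("V").spec)
        assert prob_v.nll(theta_v, False) == pytest.approx(ols, rel=1e-10)

    def test_ar1_phi_zero_equals_independent_likelihood(self, small_nested_dataset):
        rng = np.random.default_rng(5)
        spec_ar = nl.make_model_spec("VII").spec
        spec_ind = nl.make_model_spec("IV").spec
        theta_ind = rng.normal(size=spec_ind.n_theta) * 0.5
        theta_ar = np.append(theta_ind, 0.0)  # atanh(0) = 0
        pa = LMMProblem(small_nested_dataset, spec_ar)
        pi = LMMProblem(small_nested_dataset, spec_ind)
        for reml in (True, False):
            assert pa.nll(theta_ar, reml) == pytest.approx(
                pi.nll(theta_ind, reml), rel=1e-12)

    def test_theta_round_trip(self):
        spec = nl.make_model_spec("I").spec
        g_c = np.array([[2.0, 0.3], [0.3, 0.5]])
        g_s = np.array([[1.0, -0.1], [-0.1, 0.2]])
        theta = pack_theta(spec, [g_c, g_s], 1.7)
        gs, s2, phi = unpack_theta(spec, theta)
        np.testing.assert_allclose(gs[0], g_c, atol=1e-9)
        np.testing.assert_allclose(gs[1], g_s, atol=1e-9)
        assert s2 == pytest.approx(1.7, rel=1e-9)
        assert phi is None


class TestFit:
    def test_model_v_equals_ols_exactly(self, intercept_only_dataset):
        ds = intercept_only_dataset
        res = TrajectoryLMM(ds, nl.make_model_spec("V").spec).fit(method="ml")
        X = LMMProblem(ds, nl.make_model_spec("V").spec).X_all
        y = ds.df["response"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-10)
        assert res.converged and not res.singular

    def test_statsmodels_cross_check(self, intercept_only_dataset):
        """Independent implementation agreement on Models III and IV.

        The REML optimum must match statsmodels MixedLM (best of its
        optimizers) or exceed it; estimates agree wherever the optima agree.
        """
        import warnings
        sm = pytest.importorskip("statsmodels.api")
        ds = intercept_only_dataset
        df = ds.df.copy()
        df["g"] = ds.group_indicator()
        df["gt"] = df["g"] * df["time"]
        for mid, re_formula in [("IV", "1"), ("III", "1 + time")]:
            res = TrajectoryLMM(ds, nl.make_model_spec(mid).spec).fit()
            m = sm.MixedLM.from_formula("response ~ g + time + gt",
                                        groups="subject",
                                        re_formula=re_formula, data=df)
            refs = []
            for meth in ("lbfgs", "powell"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    refs.append(m.fit(reml=True, method=meth))
            ref = max(refs, key=lambda r: r.llf)
            assert res.llf >= ref.llf - 1e-6
            assert res.llf == pytest.approx(ref.llf, abs=5e-3)
            np.testing.assert_allclose(res.params.to_numpy(),
                                       ref.fe_params.to_numpy(),
                                       rtol=1e-3, atol=1e-6)
            # the two optima differ at ~1e-3 in llf, so SEs agree to ~1%
            np.testing.assert_allclose(res.bse.to_numpy(),
                                       ref.bse_fe.to_numpy(), rtol=2e-2)

    def test_refit_from_solution_is_fixed_point(self, intercept_only_dataset):
        model = TrajectoryLMM(intercept_only_dataset,
                              nl.make_model_spec("IV").spec)
        res1 = model.fit()
        res2 = model.fit(start=res1.theta)
        assert res2.llf == pytest.approx(res1.llf, abs=1e-8)

    def test_intercept_variance_recovery(self):
        """Mean of g-hat over replicates within 3 MC SEs of the truth g=4."""
        sc = nl.SimulationScenario("intercept_only", effect_fraction=0.0,
                                   g=[[4.0]], sigma2=1.0)
        grid = nl.make_independent_design(200, timepoints=tuple(range(6)))
        spec = nl.make_model_spec("IV").spec
        ghats = []
        for seed in range(30):
            ds = nl.simulate_dataset(sc, grid, seed=1000 + seed)
            res = TrajectoryLMM(ds, spec).fit()
            ghats.append(res.vc.g["subject"].values[0, 0])
        ghats = np.asarray(ghats)
        mc_se = ghats.std(ddof=1) / np.sqrt(len(ghats))
        assert abs(ghats.mean() - 4.0) < 3 * mc_se + 1e-9

    def test_singular_flag_on_overspecified_model(self):
        """Fitting a random intercept to independent data flags the boundary."""
        sc = nl.SimulationScenario("none", effect_fraction=0.0, sigma2=1.0)
        flags = []
        for seed in range(5):
            ds = nl.simulate_dataset(sc, nl.make_independent_design(30), seed=seed)
            res = TrajectoryLMM(ds, nl.make_model_spec("IV").spec).fit()
            flags.append(res.singular)
        assert any(flags)

    def test_embed_theta_preserves_likelihood(self, small_nested_dataset):
        spec_small = nl.make_model_spec("IV").spec
        spec_big = nl.make_model_spec("II").spec
        res = TrajectoryLMM(small_nested_dataset, spec_small).fit(method="ml")
        theta_big = embed_theta(spec_small, res.theta, spec_big)
        prob = LMMProblem(small_nested_dataset, spec_big)
        assert -prob.nll(theta_big, False) == pytest.approx(res.llf, abs=1e-5)


class TestStability:
    def test_well_conditioned_fit_is_stable(self, intercept_only_dataset):
        rep = refit_all_optimizers(nl.make_model_spec("IV").spec,
                                   intercept_only_dataset,
                                   optimizers=("lbfgsb", "powell"))
        assert rep.stable
        assert rep.n_converged == 2

    def test_duplicate_optimizer_zero_discrepancy(self, intercept_only_dataset):
        rep = refit_all_optimizers(nl.make_model_spec("IV").spec,
                                   intercept_only_dataset,
                                   optimizers=("lbfgsb", "lbfgsb"))
        assert rep.max_rel_discrepancy == pytest.approx(0.0, abs=1e-12)

    def test_overspecified_model_flags_singular_somewhere(self):
        """Donor-level model on donor-free data: boundary/singular fits show up."""
        sc = nl.SimulationScenario("intercept_only", effect_fraction=0.0)
        ds = nl.simulate_dataset(sc, nl.default_nested_grid(2, 3), seed=3)
        rep = refit_all_optimizers(nl.make_model_spec("II").spec, ds,
                                   optimizers=("lbfgsb", "powell"))
        frame = rep.to_frame()
        assert (frame["singular"] | ~frame["converged"]).any()


class TestBlups:
    def test_near_zero_variance_gives_population_lines(self):
        sc = nl.SimulationScenario("none", effect_fraction=1.0, sigma2=1.0)
        ds = nl.simulate_dataset(sc, nl.make_independent_design(20), seed=0)
        res = TrajectoryLMM(ds, nl.make_model_spec("IV").spec).fit()
        if res.vc.g["subject"].values[0, 0] < 1e-6:
            gammas = np.concatenate(list(res.random_effects["subject"].values()))
            assert np.abs(gammas).max() < 1e-3

    def test_conditional_residual_decomposition(self, intercept_only_dataset):
        res = TrajectoryLMM(intercept_only_dataset,
                            nl.make_model_spec("IV").spec).fit()
        y = intercept_only_dataset.df["response"].to_numpy()
        np.testing.assert_allclose(y - res.fittedvalues, res.resid, atol=1e-12)

    def test_blups_track_true_intercepts_when_noise_small(self):
        sc = nl.SimulationScenario("intercept_only", effect_fraction=0.0,
                                   g=[[9.0]], sigma2=0.01)
        grid = nl.make_independent_design(40, timepoints=(0.0, 1.0, 2.0, 3.0))
        ds = nl.simulate_dataset(sc, grid, seed=8)
        res = TrajectoryLMM(ds, nl.make_model_spec("IV").spec).fit()
        # per-subject day-0-ish mean deviation approximates the true intercept
        df = ds.df.copy()
        prob = res.model.problem
        Xd = np.empty_like(prob.X_all)
        Xd[prob.row_order] = prob.X_all
        df["mean_dev"] = df["response"].to_numpy() - Xd @ res.params.to_numpy()
        truth = df.groupby("subject", observed=True)["mean_dev"].mean()
        blup = pd.Series({k: v[0] for k, v in res.random_effects["subject"].items()})
        corr = np.corrcoef(truth.loc[blup.index], blup)[0, 1]
        assert corr > 0.9

    def test_blup_count_matches_units(self, small_nested_dataset):
        res = TrajectoryLMM(small_nested_dataset,
                            nl.make_model_spec("III").spec).fit()
        assert len(res.random_effects["subject"]) == small_nested_dataset.n_subjects


class TestProperties:
    def test_oracle_equivalence_random_instances(self):
        """Engine (restricted) loglik matches the dense oracle, 10 instances."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            ds = random_small_instance(rng)
            mid = rng.choice(["I", "II", "III", "IV", "VI", "VII", "VIII"])
            spec = nl.make_model_spec(str(mid)).spec
            theta = rng.normal(size=spec.n_theta) * 0.5
            reml = bool(rng.integers(2))
            a = LMMProblem(ds, spec).nll(theta, reml)
            b = dense_negloglik(ds, spec, theta, reml)
            assert a == pytest.approx(b, rel=1e-8)

    def test_v_positive_definite_over_parameter_samples(self):
        rng = np.random.default_rng(99)
        spec = nl.make_model_spec("I").spec
        times = np.array([0.0, 1.0, 3.0, 7.0])
        for _ in range(50):
            gs, s2, phi = nl.model.unpack_theta(spec, rng.normal(size=spec.n_theta))
            V = marginal_covariance(
                spec, {"g_cluster": gs[0], "g_subject": gs[1], "sigma2": s2},
                times=np.tile(times, 2), subject_sizes=[4, 4])
            np.linalg.cholesky(V)  # raises if not PD
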