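import numpy as np
import pandas as pd
import pytest

import splitcar as sc
from splitcar.infer import (
    GaussianSystem,
    _solve_point,
    assemble_system,
    constrain,
    fit_model,
    fit_system,
    mixture_quantile,
    sample_constrained,
)
from splitcar.models import Priors, make_model

from conftest import dense_constrained_moments, random_two_region_problem


class TestConstrain:
    def test_matches_dense_conditioning(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(8, 8))
        Q = M @ M.T + 8 * np.eye(8)
        b = rng.normal(size=8)
        A = rng.normal(size=(2, 8))
        mean_c, h = constrain(Q, b, A)
        mu_d, Sig_d = dense_constrained_moments(Q, b, A)
        assert np.allclose(mean_c, mu_d, atol=1e-10)
        assert np.allclose(h.covariance(), Sig_d, atol=1e-10)

    def test_mean_already_in_constraint_space_unchanged(self):
        Q = np.diag([2.0, 3.0, 4.0])
        A = np.array([[1.0, 1.0, 1.0]])
        x = np.array([1.0, 1.0, -2.0])   # satisfies A x = 0
        mean_c, _ = constrain(Q, Q @ x, A)
        assert np.allclose(mean_c, x, atol=1e-12)

    def test_rank_deficient_constraints_rejected(self):
        Q = np.eye(4)
        A = np.array([[1.0, 0, 0, 0], [2.0, 0, 0, 0]])
        with pytest.raises(ValueError, match="rank deficient"):
            constrain(Q, np.zeros(4), A)

    def test_constrained_draws_satisfy_constraint(self):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(6, 6))
        Q = M @ M.T + 6 * np.eye(6)
        A = np.array([[1.0] * 6, [1, -1, 1, -1, 1, -1.0]])
        draws = sample_constrained(Q, rng.normal(size=6), A, rng, 200)
        assert np.abs(draws @ A.T).max() < 1e-8


class TestDenseOracleEquivalence:
    def test_sparse_path_matches_dense_linear_algebra(self):
        rng = np.random.default_rng(77)
        for rep in range(8):
            g, summ = random_two_region_problem(rng)
            variant = ["I", "II", "III", "IVb"][rep % 4]
            system = assemble_system(make_model(variant, g), g, summ)
            for _ in range(2):
                th = rng.normal(2.5, 1.0, system.n_theta)
                gp = _solve_point(system, th, marginals=True, latent_sd=True)
                mu_d, Sig_d = dense_constrained_moments(
                    system.posterior_precision(th), system._b, system._At.T
                )
                assert np.abs(gp.mean - mu_d).max() < 1e-8
                assert np.abs(gp.latent_sd**2 - np.diag(Sig_d)).max() < 1e-8

    def test_marginal_likelihood_differences_match_dense_marginalization(self):
        # proper toy (no intrinsic block): lml can be computed by integrating
        # the latent field out exactly with dense linear algebra
        rng = np.random.default_rng(13)
        n = 6
        y = rng.normal(size=n)
        var = rng.uniform(0.2, 0.8, n)
        X = np.ones((n, 1))
        sys_ = GaussianSystem(
            area_ids=tuple(range(n)),
            X=X,
            fixed_names=["intercept"],
            fixed_prec=np.array([0.5]),
            v_blocks=[("all", np.arange(n))],
            u_blocks=[],
            A_u=np.zeros((0, n)),
            y=y,
            obs_var=var,
            priors=Priors(),
        )

        def dense_lml(tau):
            C = X @ X.T / 0.5 + np.eye(n) / tau + np.diag(var)
            sign, ld = np.linalg.slogdet(C)
            return -0.5 * (n * np.log(2 * np.pi) + ld + y @ np.linalg.solve(C, y))

        l1 = _solve_point(sys_, [np.log(4.0)]).log_marginal
        l2 = _solve_point(sys_, [np.log(9.0)]).log_marginal
        assert (l1 - l2) == pytest.approx(dense_lml(4.0) - dense_lml(9.0), abs=1e-8)


class TestHyperGrid:
    def test_weights_normalize(self, small_bundle, small_summaries):
        g = small_bundle.truth.graph
        fit = fit_model(make_model("II", g), g, small_summaries)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert (fit.weights > 0).all()

    def test_conjugate_toy_posterior_mean(self):
        # v_j observed almost exactly: tau | y ~ Gamma(0.5 + n/2, 0.005 + ss/2)
        rng = np.random.default_rng(7)
        n = 30
        y = rng.standard_normal(n) / 5.0
        sys_ = GaussianSystem(
            area_ids=tuple(range(n)),
            X=np.zeros((n, 0)),
            fixed_names=[],
            fixed_prec=np.zeros(0),
            v_blocks=[("all", np.arange(n))],
            u_blocks=[],
            A_u=np.zeros((0, n)),
            y=y,
            obs_var=np.full(n, 1e-6),
            priors=Priors(),
        )
        summ = pd.DataFrame(
            {"n": 1, "p_hat": 0.5, "var_p": 0.01, "y_logit": y, "var_logit": 1e-6,
             "status": "observed"},
            index=list(range(n)),
        )
        fit = fit_system(sys_, summ)
        e_tau = fit.weights @ np.exp(fit.grid_theta[:, 0])
        exact = (0.5 + n / 2) / (0.005 + 0.5 * np.sum(y**2))
        assert e_tau == pytest.approx(exact, rel=0.01)

    def test_grid_refinement_changes_prevalence_below_1e3(self, small_bundle, small_summaries):
        g = small_bundle.truth.graph
        spec = make_model("II", g)
        coarse = fit_model(spec, g, small_summaries, step=0.5)
        fine = fit_model(spec, g, small_summaries, step=0.25)
        p1 = coarse.fitted_prevalence(method="ghq")
        p2 = fine.fitted_prevalence(method="ghq")
        assert np.abs(p1 - p2).max() < 1e-3


class TestMixtureMarginals:
    def test_single_point_grid_is_exact_conditional(self, small_bundle, small_summaries):
        g = small_bundle.truth.graph
        spec = make_model("II", g)
        fit = fit_model(spec, g, small_summaries, grid=np.array([[2.0, 3.0]]))
        assert len(fit.weights) == 1 and fit.weights[0] == 1.0
        assert np.allclose(fit.eta_mean, fit.point_eta_mean[0])
        assert np.allclose(fit.eta_sd, fit.point_eta_sd[0])

    def test_mixture_mean_is_weighted_component_mean(self, small_bundle, small_summaries):
        g = small_bundle.truth.graph
        fit = fit_model(make_model("II", g), g, small_summaries)
        assert np.allclose(fit.eta_mean, fit.weights @ fit.point_eta_mean, atol=1e-12)

    def test_fitted_prevalence_between_3sd_expit_bounds(self, small_bundle, small_summaries):
        from scipy.special import expit

        g = small_bundle.truth.graph
        fit = fit_model(make_model("II", g), g, small_summaries)
        p = fit.fitted_prevalence()
        lo = expit(fit.eta_mean - 3.5 * fit.eta_sd)
        hi = expit(fit.eta_mean + 3.5 * fit.eta_sd)
        assert ((p > lo) & (p < hi)).all()
        assert ((p > 0) & (p < 1)).all()

    def test_mixture_quantile_brackets_cdf(self):
        m = np.array([-1.0, 2.0])
        s = np.array([0.5, 1.0])
        w = np.array([0.3, 0.7])
        q50 = mixture_quantile(m, s, w, 0.5)
        from scipy.stats import norm

        cdf = np.sum(w * norm.cdf((q50 - m) / s))
        assert cdf == pytest.approx(0.5, abs=1e-8)


class TestPrediction:
    def path_fit(self, y_vals, unsampled, var=0.05, grid=None):
        """Fit variant II on a 6-node path with chosen observations."""
        g = sc.AdjacencyGraph.from_edges(list("abcdef"), [(i, i + 1) for i in range(5)])
        y = np.array(y_vals, dtype=float)
        status = np.array(["observed"] * 6, dtype=object)
        vl = np.full(6, var)
        for a in unsampled:
            i = g.index(a)
            y[i] = np.nan
            vl[i] = np.nan
            status[i] = "unsampled"
        summ = pd.DataFrame(
            {"n": 10, "p_hat": 0.3, "var_p": 0.01, "y_logit": y, "var_logit": vl,
             "status": status},
            index=list(g.area_ids),
        )
        grid = np.array([[2.0, 2.0]]) if grid is None else grid
        return fit_model(make_model("II", g), g, summ, grid=grid), summ

    def test_zero_observations_gives_constrained_prior(self):
        g = sc.AdjacencyGraph.from_edges(list("abcd"), [(0, 1), (1, 2), (2, 3)])
        summ = pd.DataFrame(
            {"n": 0, "p_hat": np.nan, "var_p": np.nan, "y_logit": np.nan,
             "var_logit": np.nan, "status": "unsampled"},
            index=list(g.area_ids),
        )
        system = assemble_system(make_model("II", g), g, summ)
        th = np.array([1.5, 2.0])
        gp = _solve_point(system, th, marginals=True, latent_sd=True)
        mu_d, Sig_d = dense_constrained_moments(
            system.prior_precision(th), np.zeros(system.dim), system._At.T
        )
        assert np.abs(gp.mean - mu_d).max() < 1e-8
        assert np.abs(gp.latent_sd**2 - np.diag(Sig_d)).max() < 1e-8

    def test_unsampled_area_pulled_toward_high_neighbours(self):
        # unsampled node 'c' sits between high-valued neighbours; the rest low
        fit, _ = self.path_fit([1.0, 1.0, 0.0, 1.0, -2.0, -2.0], unsampled=["c"])
        i = list(fit.area_ids).index("c")
        baseline = fit.latent_mean[0]  # common intercept
        assert fit.eta_mean[i] > baseline

    def test_unsampled_sd_exceeds_sampled_twin(self):
        # symmetric path: b and e see the same neighbour values, e observed
        fit, _ = self.path_fit([0.5, np.nan, -0.5, -0.5, 0.0, 0.5][::-1],
                               unsampled=["e"])
        ids = list(fit.area_ids)
        assert fit.eta_sd[ids.index("e")] > fit.eta_sd[ids.index("b")]

    def test_predict_unsampled_returns_flagged_rows(self, small_bundle, small_summaries):
        g = small_bundle.truth.graph
        fit = fit_model(make_model("II", g), g, small_summaries)
        tab = fit.predict_unsampled(method="ghq")
        n_unsampled = (small_summaries["status"] == "unsampled").sum()
        assert len(tab) == n_unsampled
        samp = fit.prevalence_summary(method="ghq")
        samp = samp[samp.status == "observed"]
        assert tab["sd"].mean() > samp["sd"].mean()

    def test_growing_var_logit_moves_area_toward_neighbour_mean(self):
        ys = [0.0, 2.0, 0.0, 0.0, 0.0, 0.0]
        etas = []
        for var1 in (0.05, 0.5, 5.0):
            g = sc.AdjacencyGraph.from_edges(list("abcdef"), [(i, i + 1) for i in range(5)])
            vl = np.full(6, 0.05)
            vl[1] = var1
            summ = pd.DataFrame(
                {"n": 10, "p_hat": 0.3, "var_p": 0.01, "y_logit": ys, "var_logit": vl,
                 "status": "observed"},
                index=list(g.area_ids),
            )
            fit = fit_model(make_model("II", g), g, summ, grid=np.array([[2.0, 2.0]]))
            etas.append(fit.eta_mean[1])
        # direct estimate 2.0 pulled monotonically down toward the ~0 neighbours
        assert etas[0] > etas[1] > etas[2]


class TestShrinkage:
    def test_fit_shrinks_toward_region_mean_or_reduces_sd(self, small_bundle, small_summaries):
        g = small_bundle.truth.graph
        fit = fit_model(make_model("II", g), g, small_summaries)
        tab = fit.prevalence_summary(method="ghq")
        labels = np.asarray(g.component_labels)
        summ = small_summaries
        ok = 0
        total = 0
        for c in range(2):
            areas = [a for a, l in zip(g.area_ids, labels) if l == c]
            sub = summ.loc[areas]
            obs = sub[sub.status != "unsampled"]
            wts = obs["n"]
            region_mean = float((obs["p_hat"] * wts).sum() / wts.sum())
            for a in obs.index:
                direct = obs.loc[a, "p_hat"]
                fitted = tab.loc[a, "fitted_mean"]
                lo, hi = sorted((direct, region_mean))
                between = lo - 1e-9 <= fitted <= hi + 1e-9
                direct_sd = np.sqrt(obs.loc[a, "var_p"])
                smaller_sd = tab.loc[a, "sd"] < direct_sd
                ok += between or smaller_sd
                total += 1
        assert ok / total >= 0.95
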