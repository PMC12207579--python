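"""AI-REML engine tests against independent likelihood and BLUP oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize

from diallelgp.reml import RandomTerm, REMLProblem, ResidualSpec


def direct_neg2loglik(y, X, Vparts, theta):
    """REML -2logL computed through the n x n covariance matrix V.

    Independent of the mixed-model-equations code path: builds
    ``V = sum_i theta_i * Vparts_i`` explicitly and evaluates
    ``log|V| + log|X'V^-1 X| + y'Py``.
    """
    V = sum(t * Vp for t, Vp in zip(theta, Vparts))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    s1, ld1 = np.linalg.slogdet(V)
    s2, ld2 = np.linalg.slogdet(XVX)
    return ld1 + ld2 + float(y @ P @ y)


@pytest.fixture()
def balanced_oneway():
    """10 groups x 3 replicates with a random group effect."""
    rng = np.random.default_rng(5)
    b, r = 10, 3
    u = rng.normal(0, np.sqrt(4.0), b)
    y = 2.0 + np.repeat(u, r) + rng.normal(0, 1.0, b * r)
    groups = np.repeat(np.arange(b), r)
    Z = sp.csr_matrix((np.ones(b * r), (np.arange(b * r), groups)),
                      shape=(b * r, b))
    X = np.ones((b * r, 1))
    return y, X, Z, groups, b, r


class TestLikelihoodAndEstimates:
    def test_engine_likelihood_equals_direct_V_form(self, balanced_oneway):
        y, X, Z, groups, b, r = balanced_oneway
        problem = REMLProblem(y, X, [RandomTerm("g", Z, q=b)])
        comps = {"g": 3.0, "resid": 1.2}
        state = problem._assemble(comps)
        Vparts = [(Z @ Z.T).toarray(), np.eye(len(y))]
        direct = direct_neg2loglik(y, X, Vparts, [3.0, 1.2])
        assert state["neg2ll"] == pytest.approx(direct, abs=1e-8)

    def test_estimates_match_direct_numerical_maximization(self, balanced_oneway):
        """Two-component model: engine vs Nelder-Mead on the explicit REML
        likelihood (V-inverse form), agreeing within 1e-4."""
        y, X, Z, groups, b, r = balanced_oneway
        problem = REMLProblem(y, X, [RandomTerm("g", Z, q=b)])
        res = problem.fit()
        Vparts = [(Z @ Z.T).toarray(), np.eye(len(y))]

        def f(logtheta):
            return direct_neg2loglik(y, X, Vparts, np.exp(logtheta))

        opt = minimize(f, np.log([1.0, 1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 2000})
        theta_opt = np.exp(opt.x)
        assert res.neg2loglik == pytest.approx(opt.fun, abs=1e-4)
        assert res.components["g"][0, 0] == pytest.approx(theta_opt[0],
                                                          abs=1e-4)
        assert res.components["resid"][0, 0] == pytest.approx(theta_opt[1],
                                                              abs=1e-4)

    def test_balanced_anova_closed_form(self, balanced_oneway):
        """On balanced one-way data REML equals the ANOVA estimators
        sigma_e^2 = MSE and sigma_g^2 = (MSB - MSE)/r."""
        y, X, Z, groups, b, r = balanced_oneway
        res = REMLProblem(y, X, [RandomTerm("g", Z, q=b)]).fit()
        ybar_g = np.array([y[groups == g].mean() for g in range(b)])
        mse = sum(((y[groups == g] - ybar_g[g]) ** 2).sum()
                  for g in range(b)) / (b * (r - 1))
        msb = r * ((ybar_g - y.mean()) ** 2).sum() / (b - 1)
        assert res.components["resid"][0, 0] == pytest.approx(mse, rel=1e-6)
        assert res.components["g"][0, 0] == pytest.approx((msb - mse) / r,
                                                          rel=1e-6)

    def test_matches_statsmodels_on_unbalanced_data(self):
        """Random-intercept model cross-checked against statsmodels MixedLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        groups = np.repeat(np.arange(12), rng.integers(2, 6, 12))
        n = groups.size
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1.3, 12)[groups] \
            + rng.normal(0, 0.8, n)
        X = np.column_stack([np.ones(n), x])
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), groups)),
                          shape=(n, 12))
        res = REMLProblem(y, X, [RandomTerm("g", Z, q=12)]).fit()
        sm_fit = sm.MixedLM(y, X, groups).fit(reml=True)
        assert res.components["g"][0, 0] == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3)
        assert res.components["resid"][0, 0] == pytest.approx(
            float(sm_fit.scale), rel=1e-3)

    def test_null_variance_lands_at_floor(self):
        """Pure-noise data: the group variance collapses to the floor."""
        at_floor = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            b, r = 100, 2
            y = rng.normal(0, 1.0, b * r)
            groups = np.repeat(np.arange(b), r)
            Z = sp.csr_matrix((np.ones(b * r), (np.arange(b * r), groups)),
                              shape=(b * r, b))
            res = REMLProblem(y, np.ones((b * r, 1)),
                              [RandomTerm("g", Z, q=b)]).fit()
            if res.components["g"][0, 0] < 0.05 * res.components["resid"][0, 0]:
                at_floor += 1
        assert at_floor >= 10


class TestMMESolutions:
    def _toy(self, seed=0, n_groups=4, reps=2):
        rng = np.random.default_rng(seed)
        n = n_groups * reps
        groups = np.repeat(np.arange(n_groups), reps)
        B = rng.standard_normal((n_groups, n_groups))
        K = B @ B.T / n_groups + np.eye(n_groups)
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = rng.standard_normal(n) * 2 + x
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), groups)),
                          shape=(n, n_groups))
        return y, X, Z, K, groups

    def test_blup_matches_direct_gls(self):
        """MME solutions equal brute-force GLS/BLUP through V-inverse."""
        y, X, Z, K, groups = self._toy()
        s_u, s_e = 1.7, 0.9
        problem = REMLProblem(y, X, [RandomTerm("u", Z, q=K.shape[0], K=K)])
        sol = problem.solve({"u": s_u, "resid": s_e})
        V = s_u * (Z @ (K @ Z.T.toarray())) + s_e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u_hat = s_u * K @ Z.T.toarray() @ Vi @ (y - X @ beta)
        assert np.allclose(sol.fixed, beta, atol=1e-6)
        assert np.allclose(sol.random["u"], u_hat, atol=1e-6)

    def test_isolated_level_shrinks_to_prior(self):
        """A level with no records and no covariance links keeps EBV 0 and
        PEV equal to its prior variance."""
        y, X, Z, K, groups = self._toy()
        K2 = np.block([[K, np.zeros((4, 1))],
                       [np.zeros((1, 4)), np.array([[1.3]])]])
        Z2 = sp.hstack([Z, sp.csr_matrix((len(y), 1))]).tocsr()
        problem = REMLProblem(y, X, [RandomTerm("u", Z2, q=5, K=K2)])
        sol = problem.solve({"u": 2.0, "resid": 1.0})
        assert sol.random["u"][-1] == pytest.approx(0.0, abs=1e-10)
        assert sol.pev["u"][-1] == pytest.approx(2.0 * 1.3)

    def test_duplicating_records_preserves_blue_and_shrinks_pev(self):
        """With a balanced, exchangeable design (intercept + iid group
        effects), doubling every record leaves the BLUE unchanged while
        every PEV strictly decreases (information monotonicity)."""
        y, X, Z, _K, groups = self._toy(3)
        X = X[:, :1]  # intercept only: GLS reweighting cannot move the BLUE
        problem = REMLProblem(y, X, [RandomTerm("u", Z, q=4)])
        sol1 = problem.solve({"u": 1.5, "resid": 1.0})
        y2 = np.concatenate([y, y])
        X2 = np.vstack([X, X])
        Z2 = sp.vstack([Z, Z]).tocsr()
        problem2 = REMLProblem(y2, X2, [RandomTerm("u", Z2, q=4)])
        sol2 = problem2.solve({"u": 1.5, "resid": 1.0})
        assert np.allclose(sol1.fixed, sol2.fixed, atol=1e-8)
        assert np.all(sol2.pev["u"] < sol1.pev["u"] - 1e-12)

    def test_rank_deficient_fixed_design_pruned(self):
        y, X, Z, K, groups = self._toy(4)
        X_bad = np.column_stack([X, X[:, 0] + X[:, 1]])
        problem = REMLProblem(y, X_bad, [RandomTerm("u", Z, q=4, K=K)])
        assert problem.p == 2 and len(problem.dropped_cols) == 1


class TestInvariances:
    def _sim(self, seed=0, shift=0.0, permute=False):
        rng = np.random.default_rng(42)
        b, r = 30, 3
        u = rng.normal(0, 1.5, b)
        y = 5.0 + np.repeat(u, r) + rng.normal(0, 1.0, b * r) + shift
        groups = np.repeat(np.arange(b), r)
        if permute:
            perm = np.random.default_rng(seed).permutation(b * r)
            y, groups = y[perm], groups[perm]
        Z = sp.csr_matrix((np.ones(b * r), (np.arange(b * r), groups)),
                          shape=(b * r, b))
        return REMLProblem(y, np.ones((b * r, 1)),
                           [RandomTerm("g", Z, q=b)]).fit()

    def test_translation_invariance(self):
        r1, r2 = self._sim(), self._sim(shift=123.4)
        assert r1.components["g"][0, 0] == pytest.approx(
            r2.components["g"][0, 0], rel=1e-6)
        assert r1.components["resid"][0, 0] == pytest.approx(
            r2.components["resid"][0, 0], rel=1e-6)

    def test_record_order_invariance(self):
        r1, r2 = self._sim(), self._sim(seed=9, permute=True)
        assert r1.neg2loglik == pytest.approx(r2.neg2loglik, abs=1e-6)
        assert r1.components["g"][0, 0] == pytest.approx(
            r2.components["g"][0, 0], rel=1e-6)


class TestBivariateEngine:
    def test_scores_match_brute_force(self):
        """Analytic score vector for a two-trait model equals the brute-force
        derivative of the V-form likelihood for every parameter."""
        rng = np.random.default_rng(17)
        q, n_per = 8, 2
        n1 = n2 = q * n_per
        B = rng.standard_normal((q, q))
        K = B @ B.T / q + np.eye(q)
        lev = np.tile(np.arange(q), n_per)
        rows = np.arange(n1)
        Za1 = sp.csr_matrix((np.ones(n1), (rows, lev)), shape=(n1, 2 * q))
        Za2 = sp.csr_matrix((np.ones(n2), (rows, q + lev)), shape=(n2, 2 * q))
        Z = sp.vstack([Za1, Za2]).tocsr()
        y = rng.standard_normal(n1 + n2)
        X = np.zeros((n1 + n2, 2))
        X[:n1, 0] = 1
        X[n1:, 1] = 1
        trait = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])
        unit = np.concatenate([np.arange(n1), np.arange(n2)])
        resid = ResidualSpec(trait=trait, unit=unit, d=2)
        problem = REMLProblem(y, X, [RandomTerm("a", Z, q=q, d=2, K=K)],
                              resid=resid)
        comps = {"a": np.array([[2.0, 0.6], [0.6, 1.5]]),
                 "resid": np.array([[1.0, 0.3], [0.3, 1.4]])}
        state = problem._assemble(comps)
        params = problem._param_list()
        score, ai, Py, Cinv = problem._score_and_ai(state, params)

        # brute force V and derivatives
        n = n1 + n2
        Zd = Z.toarray()
        Vparts = {}
        for s in range(2):
            for t in range(s, 2):
                E = np.zeros((2, 2))
                E[s, t] = E[t, s] = 1
                Vparts[("a", s, t)] = Zd @ np.kron(E, K) @ Zd.T
                D = np.zeros((n, n))
                if s == t:
                    D[trait == s, trait == s] = 0.0
                    for i in np.flatnonzero(trait == s):
                        D[i, i] = 1.0
                else:
                    for i, j in problem.resid.pairs:
                        D[i, j] = D[j, i] = 1.0
                Vparts[("resid", s, t)] = D
        V = sum(np.atleast_2d(comps[k])[s, t] * Vp
                for (k, s, t), Vp in Vparts.items())
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
        Pyb = P @ y
        for i, key in enumerate(params):
            Vd = Vparts[key]
            brute = 0.5 * (Pyb @ Vd @ Pyb - np.trace(P @ Vd))
            assert score[i] == pytest.approx(brute, abs=1e-6), key

    def test_duplicate_trait_recovers_unit_correlation(self):
        """Fitting a trait against an exact copy of itself drives the
        additive cross-covariance to the correlation cap."""
        rng = np.random.default_rng(23)
        q = 30
        B = rng.standard_normal((q, q))
        K = B @ B.T / q + np.eye(q)
        L = np.linalg.cholesky(K)
        a = L @ rng.standard_normal(q) * 1.5
        reps = 2
        lev = np.tile(np.arange(q), reps)
        n1 = q * reps
        y1 = a[lev] + rng.normal(0, 0.5, n1)
        y = np.concatenate([y1, y1])
        rows = np.arange(n1)
        Za1 = sp.csr_matrix((np.ones(n1), (rows, lev)), shape=(n1, 2 * q))
        Za2 = sp.csr_matrix((np.ones(n1), (rows, q + lev)), shape=(n1, 2 * q))
        Z = sp.vstack([Za1, Za2]).tocsr()
        X = np.zeros((2 * n1, 2))
        X[:n1, 0] = 1
        X[n1:, 1] = 1
        trait = np.concatenate([np.zeros(n1, int), np.ones(n1, int)])
        unit = np.concatenate([np.arange(n1), np.arange(n1)])
        resid = ResidualSpec(trait=trait, unit=unit, d=2)
        res = REMLProblem(y, X, [RandomTerm("a", Z, q=q, d=2, K=K)],
                          resid=resid).fit()
        C = res.components["a"]
        r_g = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
        assert r_g > 0.99
        R = res.components["resid"]
        assert R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]) > 0.99
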