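"""EM-REML engine: GLS/dense oracles, monotonicity, backend agreement."""

import numpy as np
import pytest
from scipy import sparse

from cattlernm.reml import (EMControls, MMEProblem, RandomTerm, em_reml_fit,
                            nearest_psd, restricted_loglik, solve_mme)


def dense_gls(problem: MMEProblem, comps: dict):
    """Textbook GLS/BLUP on the stacked observed rows (dense V path):
    beta = (X'Vi X)^-1 X'Vi y, u = G Z'Vi (y - X beta), and the REML
    log-likelihood from log|V|, log|X'Vi X| and the residual form."""
    rows = []
    for i in range(problem.n_records):
        for t in range(problem.n_traits):
            if not np.isnan(problem.y[i, t]):
                rows.append((i, t))
    n = len(rows)
    h = np.vstack([problem.h_by_trait[t][i].toarray() for i, t in rows])
    y = np.array([problem.y[i, t] for i, t in rows])
    x = h[:, :problem.p_fixed]
    z = h[:, problem.p_fixed:]
    r = comps["residual"]
    rs = np.zeros((n, n))
    for a, (i, t) in enumerate(rows):
        for b, (j, s) in enumerate(rows):
            if i == j:
                rs[a, b] = r[t, s]
    gblocks = []
    for tm in problem.terms:
        k = (np.eye(tm.n_levels) if tm.k_inverse is None
             else np.linalg.inv(tm.k_inverse.toarray()))
        gblocks.append(np.kron(k, comps[tm.label]))
    if gblocks:
        from scipy.linalg import block_diag
        g = block_diag(*gblocks)
        v = z @ g @ z.T + rs
    else:
        v = rs
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    resid = y - x @ beta
    u = (g @ z.T @ vi @ resid) if gblocks else np.zeros(z.shape[1])
    ll = -0.5 * (np.linalg.slogdet(v)[1] + np.linalg.slogdet(xvx)[1]
                 + resid @ vi @ resid + (n - x.shape[1]) * np.log(2 * np.pi))
    return beta, u, ll


def random_problem(seed, n=40, n_traits=2, missing=0.25, with_pedigree=False):
    """Small random mixed-model problem with 1-2 traits and two terms."""
    rng = np.random.default_rng(seed)
    p_per = 2
    p = p_per * n_traits
    x_by = []
    for t in range(n_traits):
        block = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = np.zeros((n, p))
        x[:, t * p_per:(t + 1) * p_per] = block
        x_by.append(sparse.csr_matrix(x))
    q1 = 6
    lev = rng.integers(q1, size=n)
    z_by = []
    for t in range(n_traits):
        z = sparse.csr_matrix((np.ones(n), (np.arange(n), lev * n_traits + t)),
                              shape=(n, q1 * n_traits))
        z_by.append(z)
    terms = [RandomTerm("grp", n_traits, q1, z_by)]
    if with_pedigree:
        from cattlernm.pedigree import build_a_inverse, validate_and_sort
        import pandas as pd
        q2 = n
        raw = pd.DataFrame({
            "animal": [f"a{i}" for i in range(q2)],
            "sire": [None if i < 4 else f"a{rng.integers(max(0, i - 8), i)}"
                     for i in range(q2)],
            "dam": [None] * q2})
        ped = validate_and_sort(raw)
        ainv, _, logdet_a = build_a_inverse(ped)
        za = []
        d = 2 * n_traits
        for t in range(n_traits):
            rowsl, cols, vals = [], [], []
            phi = rng.uniform(-1, 1, n)
            for i in range(n):
                rowsl += [i, i]
                cols += [i * d + 2 * t, i * d + 2 * t + 1]
                vals += [1.0, phi[i]]
            za.append(sparse.csr_matrix((vals, (rowsl, cols)), shape=(n, q2 * d)))
        terms.append(RandomTerm("anim", d, q2, za, k_inverse=ainv,
                                logdet_k=logdet_a))
    y = rng.normal(30, 4, (n, n_traits))
    if n_traits > 1:
        miss = rng.random(n) < missing
        y[miss, 1] = np.nan
    problem = MMEProblem(y, x_by, terms)
    comps = {"grp": np.eye(n_traits) * 2.0 + 0.5,
             "residual": np.eye(n_traits) * 4.0 + 1.0}
    if with_pedigree:
        base = np.eye(2 * n_traits)
        comps["anim"] = 1.5 * base + 0.3 * (np.ones_like(base) - base)
    return problem, comps


class TestMMEOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_solutions_match_dense_gls(self, seed):
        problem, comps = random_problem(seed, with_pedigree=(seed % 2 == 0))
        theta, _ = solve_mme(problem, comps,
                             EMControls(backend="dense", dense_cap=10**6))
        beta, u, _ = dense_gls(problem, comps)
        assert np.allclose(theta[:problem.p_fixed], beta, atol=1e-8)
        assert np.allclose(theta[problem.p_fixed:], u, atol=1e-8)

    def test_no_random_terms_reduces_to_weighted_ls(self):
        rng = np.random.default_rng(3)
        n = 30
        x = sparse.csr_matrix(np.column_stack([np.ones(n), rng.standard_normal(n)]))
        y = rng.normal(0, 1, (n, 1))
        problem = MMEProblem(y, [x], [])
        theta, _ = solve_mme(problem, {"residual": np.array([[2.5]])},
                             EMControls(backend="dense", dense_cap=10**6))
        beta = np.linalg.lstsq(x.toarray(), y[:, 0], rcond=None)[0]
        assert np.allclose(theta, beta, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_restricted_loglik_matches_dense(self, seed):
        problem, comps = random_problem(seed + 10, with_pedigree=True)
        got = restricted_loglik(problem, comps)
        _, _, expected = dense_gls(problem, comps)
        assert got == pytest.approx(expected, abs=1e-8)


class TestBackends:
    def test_sparse_equals_dense_throughout(self):
        problem, comps = random_problem(21, n=60, with_pedigree=True)
        fits = {}
        for backend in ("dense", "sparse"):
            fits[backend] = em_reml_fit(
                problem, comps, EMControls(max_iter=8, backend=backend,
                                           dense_cap=10**6, accelerate=False))
        for k in fits["dense"].components:
            assert np.allclose(fits["dense"].components[k],
                               fits["sparse"].components[k], rtol=1e-7, atol=1e-9)
        assert np.allclose(fits["dense"].trace["loglik"],
                           fits["sparse"].trace["loglik"], rtol=1e-9)


class TestEMProperties:
    @pytest.mark.parametrize("accelerate", [False, True])
    def test_loglik_monotone(self, accelerate):
        problem, comps = random_problem(5, n=50, with_pedigree=True)
        fit = em_reml_fit(problem, comps,
                          EMControls(max_iter=30, backend="dense",
                                     dense_cap=10**6, accelerate=accelerate))
        ll = fit.trace["loglik"].to_numpy()
        assert np.all(np.diff(ll) > -1e-6)

    def test_fixed_point_matches_generic_optimizer(self):
        """EM and a direct optimizer of the dense REML likelihood agree."""
        from scipy.optimize import minimize
        rng = np.random.default_rng(8)
        n, q = 120, 15
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        lev = rng.integers(q, size=n)
        z = sparse.csr_matrix((np.ones(n), (np.arange(n), lev)), shape=(n, q))
        u = rng.standard_normal(q) * 1.5
        y = (x @ [3.0, 1.0] + z @ u + rng.standard_normal(n) * 2.0)[:, None]
        problem = MMEProblem(y, [sparse.csr_matrix(x)],
                             [RandomTerm("u", 1, q, [z])])
        fit = em_reml_fit(problem,
                          {"u": [[1.0]], "residual": [[1.0]]},
                          EMControls(max_iter=500, tol=1e-10, loglik_tol=1e-12,
                                     backend="dense", dense_cap=10**6))
        zd = z.toarray()

        def negll(p):
            s2u, s2e = np.exp(p)
            v = s2u * zd @ zd.T + s2e * np.eye(n)
            vi = np.linalg.inv(v)
            xvx = x.T @ vi @ x
            beta = np.linalg.solve(xvx, x.T @ vi @ y[:, 0])
            r = y[:, 0] - x @ beta
            return 0.5 * (np.linalg.slogdet(v)[1] + np.linalg.slogdet(xvx)[1]
                          + r @ vi @ r)

        res = minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                       options=dict(xatol=1e-12, fatol=1e-14))
        opt = np.exp(res.x)
        assert fit.components["u"][0, 0] == pytest.approx(opt[0], rel=0.02)
        assert fit.components["residual"][0, 0] == pytest.approx(opt[1], rel=0.02)

    def test_zero_truth_shrinks_to_floor(self):
        """With no group effect in the data the variance hits the floor
        and the residual absorbs the total variance."""
        rng = np.random.default_rng(12)
        n, q = 400, 20
        x = sparse.csr_matrix(np.ones((n, 1)))
        z = sparse.csr_matrix((np.ones(n), (np.arange(n),
                                            rng.integers(q, size=n))),
                              shape=(n, q))
        y = rng.normal(0, 2.0, (n, 1))
        problem = MMEProblem(y, [x], [RandomTerm("u", 1, q, [z])])
        fit = em_reml_fit(problem, {"u": [[1.0]], "residual": [[1.0]]},
                          EMControls(max_iter=400, backend="dense",
                                     dense_cap=10**6))
        assert fit.components["u"][0, 0] < 0.2
        assert fit.components["residual"][0, 0] == pytest.approx(4.0, rel=0.15)

    def test_scale_equivariance(self):
        """Scaling y by c scales every component estimate by c^2."""
        problem, comps = random_problem(31, n=50, n_traits=1)
        fit1 = em_reml_fit(problem, comps, EMControls(
            max_iter=60, backend="dense", dense_cap=10**6))
        y2 = problem.y * 3.0
        problem2 = MMEProblem(y2, [problem.h_by_trait[0][:, :problem.p_fixed]],
                              problem.terms)
        fit2 = em_reml_fit(problem2, comps, EMControls(
            max_iter=60, backend="dense", dense_cap=10**6))
        for k in fit1.components:
            assert np.allclose(fit2.components[k], 9.0 * fit1.components[k],
                               rtol=0.05)


class TestNearestPSD:
    def test_passthrough_when_psd(self):
        b = np.array([[2.0, 0.5], [0.5, 1.0]])
        out, clamped = nearest_psd(b)
        assert not clamped and np.allclose(out, b)

    def test_indefinite_gets_floored(self):
        b = np.array([[1.0, 2.0], [2.0, 1.0]])
        out, clamped = nearest_psd(b)
        assert clamped
        assert np.linalg.eigvalsh(out).min() >= 0
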