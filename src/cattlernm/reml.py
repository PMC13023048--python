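"""EM-REML on Henderson's mixed-model equations, missing traits allowed.

The engine is generic over random terms.  A term contributes a block of
``n_levels * dim`` equations whose prior covariance is ``K (x) B`` with
``K`` a known structure matrix (pedigree relationship matrix via its
sparse inverse, or identity) and ``B`` an unknown ``dim x dim``
(co)variance matrix estimated by EM.  Records carry up to T traits with
an unknown T x T residual covariance ``R``; partially observed records
contribute through the inverse of the residual sub-block of their
observed traits, and the EM update of ``R`` uses the expected
complete-data residual cross-products (standard missing-data E-step).

EM updates (per iteration, with C the inverse of the MME matrix):

    B_k  <-  ( U_k' Kinv U_k  +  tr-block(Kinv C_kk) ) / n_levels
    R    <-  mean over records of E[e e' | y]

Both require only *selected* entries of C — prediction-error covariance
blocks on the pattern of Kinv and record-level quadratic forms — which
the sparse backend reads off a Takahashi selected inverse; a dense
LAPACK backend (cho_factor/dpotri) serves small problems and acts as the
cross-check oracle in the test-suite.

The restricted log-likelihood is evaluated every iteration from the same
factorization via the identity

    -2 lR = log|R*| + log|G| + log|M| + y'Py + (n - p) log 2pi

and is non-decreasing across EM iterations, which the fitter verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.linalg.lapack import dpotri

from .sparse_ldl import SparseLDL

__all__ = [
    "RandomTerm", "MMEProblem", "EMControls", "REMLResult",
    "assemble_mme", "solve_mme", "em_reml_fit", "restricted_loglik",
    "nearest_psd",
]


@dataclass
class RandomTerm:
    """One random effect: ``n_levels`` levels with ``dim`` correlated
    coefficients each, prior covariance K (x) B."""

    label: str
    dim: int
    n_levels: int
    z_by_trait: list  # per trait: csr (n_records, n_levels * dim)
    k_inverse: sparse.spmatrix | None = None  # None = identity
    logdet_k: float = 0.0

    @property
    def n_cols(self) -> int:
        return self.n_levels * self.dim


class MMEProblem:
    """Design structure of a (possibly multi-trait) mixed model.

    ``y``: (n_records, T) with NaN for a missing trait; ``x_by_trait``:
    per-trait sparse fixed design, all sharing one global fixed column
    space of width p (a trait's rows are zero outside its own columns).
    """

    def __init__(self, y: np.ndarray, x_by_trait: list, terms: list[RandomTerm]):
        self.y = np.atleast_2d(np.asarray(y, dtype=float))
        if self.y.shape[0] == 1 and self.y.shape[1] > 1 and len(x_by_trait) == 1:
            self.y = self.y.T
        self.n_records, self.n_traits = self.y.shape
        self.terms = terms
        self.p_fixed = x_by_trait[0].shape[1]
        self.h_by_trait = [
            sparse.hstack([x_by_trait[t]] + [tm.z_by_trait[t] for tm in terms],
                          format="csr")
            for t in range(self.n_traits)
        ]
        self.n_cols = self.p_fixed + sum(tm.n_cols for tm in terms)
        self.offsets = {}
        off = self.p_fixed
        for tm in terms:
            self.offsets[tm.label] = off
            off += tm.n_cols

        obs = ~np.isnan(self.y)
        if np.any(~obs.any(axis=1)):
            raise ValueError("records with no observed trait are not allowed")
        self.n_obs_total = int(obs.sum())
        # observation classes: one per distinct missingness pattern
        self.classes = []
        patterns = {}
        for i, row in enumerate(map(tuple, obs)):
            patterns.setdefault(row, []).append(i)
        for pat, rows in sorted(patterns.items(), reverse=True):
            self.classes.append((np.array([t for t, o in enumerate(pat) if o]),
                                 np.asarray(rows, dtype=np.int64)))
        # cached cross-products per class
        self._xp = []
        for tr, rows in self.classes:
            hs = {t: self.h_by_trait[t][rows] for t in tr}
            ys = {t: self.y[rows, t] for t in tr}
            gg = {}
            hy = {}
            yy = {}
            for a in tr:
                for b in tr:
                    if a <= b:
                        gg[(a, b)] = (hs[a].T @ hs[b]).tocsr()
                    hy[(a, b)] = hs[a].T @ ys[b]
                    yy[(a, b)] = float(ys[a] @ ys[b])
            self._xp.append({"rows": rows, "traits": tr, "h": hs, "y": ys,
                             "gg": gg, "hy": hy, "yy": yy})
        self._pattern = self._build_pattern()

    def _build_pattern(self) -> sparse.csr_matrix:
        """Symbolic pattern every factorization must cover: all data
        cross-product positions plus structurally-full prior blocks.
        Scipy arithmetic prunes explicit zeros, so this pattern is
        re-injected before sparse factorization to guarantee that every
        PEV entry the EM updates query lies on the factor."""
        rows_all, cols_all = [], []
        for xp in self._xp:
            for (a, b), g in xp["gg"].items():
                coo = g.tocoo()
                rows_all += [coo.row, coo.col]
                cols_all += [coo.col, coo.row]
        off = self.p_fixed
        for tm in self.terms:
            d = tm.dim
            if tm.k_inverse is None:
                ki_r = ki_c = np.arange(tm.n_levels)
            else:
                coo = sparse.coo_matrix(tm.k_inverse)
                ki_r, ki_c = coo.row, coo.col
            a = np.arange(d)
            r = np.broadcast_to(off + (ki_r[:, None, None] * d + a[None, :, None]),
                                (len(ki_r), d, d)).ravel()
            c = np.broadcast_to(off + (ki_c[:, None, None] * d + a[None, None, :]),
                                (len(ki_c), d, d)).ravel()
            rows_all += [r, c]
            cols_all += [c, r]
            off += tm.n_cols
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        pat = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                                shape=(self.n_cols, self.n_cols)).tocsr()
        pat.data[:] = 0.0
        return pat

    def prior_matrix(self, components: dict) -> sparse.spmatrix:
        """Block-diagonal Kinv (x) Binv prior precision.

        Built coordinate-wise with *structurally full* dim x dim blocks
        (explicit zeros kept), so the factor pattern always covers every
        PEV entry the EM trace terms will query."""
        blocks = [sparse.csr_matrix((self.p_fixed, self.p_fixed))]
        for tm in self.terms:
            b_inv = np.linalg.inv(components[tm.label])
            d = tm.dim
            if tm.k_inverse is None:
                ki = sparse.eye(tm.n_levels, format="coo")
            else:
                ki = sparse.coo_matrix(tm.k_inverse)
            a = np.arange(d)
            rows, cols = np.broadcast_to(
                ki.row[:, None, None] * d + a[None, :, None], (len(ki.row), d, d)
            ).ravel(), np.broadcast_to(
                ki.col[:, None, None] * d + a[None, None, :], (len(ki.col), d, d)
            ).ravel()
            data = (ki.data[:, None, None] * b_inv[None, :, :]).ravel()
            blk = sparse.coo_matrix((data, (rows, cols)),
                                    shape=(tm.n_cols, tm.n_cols))
            blocks.append(blk.tocsr())
        return sparse.block_diag(blocks, format="csr")


@dataclass
class EMControls:
    max_iter: int = 500
    tol: float = 1e-6          # max relative change in any component
    loglik_tol: float = 1e-8
    psd_floor: float = 1e-8    # eigenvalue floor, scaled by trace/dim
    backend: str = "auto"      # "dense" | "sparse" | "auto"
    dense_cap: int = 2500
    monotone_tol: float = 1e-6
    accelerate: bool = True    # safeguarded squared-extrapolation cycles
    max_step: float = 32.0     # cap on the extrapolation factor
    #: optional ECME-style moves: per (term label, coordinate subset),
    #: line-search a multiplicative scale on those coordinates against the
    #: restricted likelihood.  EM contracts extremely slowly along weakly
    #: informed variance directions (random-regression slope blocks); a
    #: direct scale search breaks those modes while every accepted move
    #: still increases the likelihood.
    scale_search: tuple = ()
    scale_grid: tuple = (0.1, 0.3, 0.6, 0.85, 1.2, 2.0)


@dataclass
class REMLResult:
    components: dict
    solutions: np.ndarray
    fixed_effects: np.ndarray
    fixed_se: np.ndarray
    trace: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    n_clamped: int = 0
    term_solutions: dict = field(default_factory=dict)


def _residual_weights(components, traits):
    r = components["residual"]
    sub = r[np.ix_(traits, traits)]
    return np.linalg.inv(sub), float(np.linalg.slogdet(sub)[1])


def assemble_mme(problem: MMEProblem, components: dict):
    """Coefficient matrix and right-hand side of the MME at the given
    components.  Returns (M csr, rhs, aux) with aux carrying log|R*| and
    y'Rinv y for the likelihood."""
    n = problem.n_cols
    m_data = sparse.csr_matrix((n, n))
    rhs = np.zeros(n)
    logdet_r = 0.0
    yry = 0.0
    for xp in problem._xp:
        tr = xp["traits"]
        w, ld = _residual_weights(components, tr)
        logdet_r += ld * len(xp["rows"])
        for ia, a in enumerate(tr):
            for ib, b in enumerate(tr):
                wab = w[ia, ib]
                if a <= b:
                    g = xp["gg"][(a, b)]
                    m_data = m_data + wab * (g if a == b else (g + g.T))
                rhs += wab * xp["hy"][(a, b)]
                yry += wab * xp["yy"][(a, b)]
    m = m_data + problem.prior_matrix(components) if problem.terms else m_data
    return m.tocsr(), rhs, {"logdet_r": logdet_r, "yry": yry}


class _DenseFactor:
    def __init__(self, m: sparse.spmatrix):
        md = np.asarray(m.todense())
        self._c, _ = cho_factor(md, lower=True)
        self._ld = 2.0 * float(np.sum(np.log(np.diag(self._c))))
        inv, info = dpotri(self._c, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError(f"dpotri failed (info={info})")
        lo = np.tril(inv)  # dpotri fills the lower triangle only
        self._inv = lo + np.tril(lo, -1).T

    def solve(self, b):
        return cho_solve((self._c, True), b)

    def logdet(self):
        return self._ld

    def inv_entries(self, rows, cols):
        return self._inv[np.asarray(rows, dtype=np.int64),
                         np.asarray(cols, dtype=np.int64)]


def _augment(m, pattern):
    mc = m.tocoo()
    pc = pattern.tocoo()
    out = sparse.coo_matrix(
        (np.concatenate([mc.data, np.zeros(pc.nnz)]),
         (np.concatenate([mc.row, pc.row]),
          np.concatenate([mc.col, pc.col]))), shape=m.shape).tocsc()
    out.sum_duplicates()
    return out


def _factorize(m, controls: EMControls, pattern: sparse.spmatrix | None = None,
               problem: "MMEProblem | None" = None):
    """Factor the MME matrix, reusing per-problem symbolic work.

    The assembled matrix has an identical sparsity structure every
    iteration (same cross-product and prior patterns), so the ordering,
    the permuted upper-triangular structure, the fill-in analysis and
    the index maps from the assembled data array into the factor input
    are all computed once and cached on the problem; subsequent calls
    only refill a data vector and run the numeric factorization.
    """
    n = m.shape[0]
    use_sparse = (controls.backend == "sparse"
                  or (controls.backend == "auto" and n > controls.dense_cap))
    if not use_sparse:
        return _DenseFactor(m)
    cache = getattr(problem, "_solver_cache", None) if problem is not None else None
    m = m.tocsr()
    if cache is not None and cache.get("m_nnz") == m.nnz:
        aug_data = np.zeros(cache["aug_nnz"])
        aug_data[cache["pos_m"]] = m.data
        return cache["factor"].refactor(aug_data[cache["up_gather"]])

    m_aug = _augment(m, pattern) if pattern is not None else sparse.csc_matrix(m)
    fac = SparseLDL(m_aug)
    if problem is not None:
        # index maps: (i) each entry of the assembled csr into the
        # augmented csc, via an index-valued structural sum; (ii) each
        # augmented entry into the permuted upper triangle.
        probe = m.copy()
        probe.data = np.arange(1, m.nnz + 1, dtype=np.float64)
        probe_aug = _augment(probe, pattern) if pattern is not None \
            else sparse.csc_matrix(probe)
        pos_m = np.empty(m.nnz, dtype=np.int64)
        nz = probe_aug.data > 0
        pos_m[probe_aug.data[nz].astype(np.int64) - 1] = np.where(nz)[0]
        idx = m_aug.copy()
        idx.data = np.arange(1, m_aug.nnz + 1, dtype=np.float64)
        idx_p = idx[fac.perm][:, fac.perm]
        up = sparse.triu(idx_p, format="csc")
        up.sort_indices()
        problem._solver_cache = {
            "m_nnz": m.nnz, "aug_nnz": m_aug.nnz, "pos_m": pos_m,
            "up_gather": up.data.astype(np.int64) - 1, "factor": fac,
        }
    return fac


@njit(cache=True)
def _expand_pairs(aip, aii, aix, bip, bii, bix):
    """All (col_a, col_b, val_a*val_b, record) tuples of two row-aligned
    CSR matrices — the index/weight lists for record-level quadratic
    forms h_a' C h_b."""
    n = aip.shape[0] - 1
    total = 0
    for i in range(n):
        total += (aip[i + 1] - aip[i]) * (bip[i + 1] - bip[i])
    ra = np.empty(total, dtype=np.int64)
    ca = np.empty(total, dtype=np.int64)
    w = np.empty(total)
    seg = np.empty(total, dtype=np.int64)
    k = 0
    for i in range(n):
        for pa in range(aip[i], aip[i + 1]):
            for pb in range(bip[i], bip[i + 1]):
                ra[k] = aii[pa]
                ca[k] = bii[pb]
                w[k] = aix[pa] * bix[pb]
                seg[k] = i
                k += 1
    return ra, ca, w, seg


def _record_quadforms(fac, ha, hb):
    """Per-record h_a C h_b' for row-aligned sparse designs."""
    ra, ca, w, seg = _expand_pairs(
        ha.indptr.astype(np.int64), ha.indices.astype(np.int64), ha.data,
        hb.indptr.astype(np.int64), hb.indices.astype(np.int64), hb.data)
    cv = fac.inv_entries(ra, ca)
    if np.any(np.isnan(cv)):
        raise RuntimeError("requested inverse entry off the factor pattern")
    return np.bincount(seg, weights=w * cv, minlength=ha.shape[0])


def _term_trace(fac, problem: MMEProblem, term: RandomTerm):
    """tr-block(Kinv C_kk): the dim x dim sum over Kinv's pattern of the
    corresponding PEV blocks."""
    off = problem.offsets[term.label]
    d = term.dim
    if term.k_inverse is None:
        i = np.arange(term.n_levels, dtype=np.int64)
        j = i
        v = np.ones(term.n_levels)
    else:
        coo = sparse.coo_matrix(term.k_inverse)
        i, j, v = coo.row.astype(np.int64), coo.col.astype(np.int64), coo.data
    a = np.arange(d, dtype=np.int64)
    rows = off + (i[:, None, None] * d + a[None, :, None])
    cols = off + (j[:, None, None] * d + a[None, None, :])
    rows, cols = np.broadcast_arrays(rows, cols)
    cv = fac.inv_entries(rows.ravel(), cols.ravel()).reshape(len(i), d, d)
    if np.any(np.isnan(cv)):
        raise RuntimeError("PEV block off the factor pattern")
    return np.einsum("n,nab->ab", v, cv)


def nearest_psd(b: np.ndarray, floor_scale: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Symmetrise and floor eigenvalues at floor_scale * trace/dim."""
    b = 0.5 * (b + b.T)
    w, q = eigh(b)
    floor = floor_scale * max(np.trace(b) / b.shape[0], 1e-12)
    if np.all(w >= floor):
        return b, False
    w = np.maximum(w, floor)
    return (q * w) @ q.T, True


def _loglik_from_parts(problem, components, aux, fac, theta, rhs):
    logdet_g = 0.0
    for tm in problem.terms:
        sign, ld = np.linalg.slogdet(components[tm.label])
        if sign <= 0:
            return -np.inf
        logdet_g += tm.dim * tm.logdet_k + tm.n_levels * ld
    ypy = aux["yry"] - float(theta @ rhs)
    const = (problem.n_obs_total - problem.p_fixed) * np.log(2.0 * np.pi)
    return -0.5 * (aux["logdet_r"] + logdet_g + fac.logdet() + ypy + const)


def restricted_loglik(problem: MMEProblem, components: dict,
                      controls: EMControls | None = None) -> float:
    """REML log-likelihood (including constants) at the given components."""
    controls = controls or EMControls()
    m, rhs, aux = assemble_mme(problem, components)
    fac = _factorize(m, controls, problem._pattern, problem)
    theta = fac.solve(rhs)
    return _loglik_from_parts(problem, components, aux, fac, theta, rhs)


def solve_mme(problem: MMEProblem, components: dict,
              controls: EMControls | None = None):
    """BLUE/BLUP solutions at fixed components (one factorization)."""
    controls = controls or EMControls()
    m, rhs, aux = assemble_mme(problem, components)
    fac = _factorize(m, controls, problem._pattern, problem)
    theta = fac.solve(rhs)
    return theta, fac


def _residual_update(problem: MMEProblem, components, fac, theta):
    """Expected complete-data residual cross-products, averaged."""
    t_all = problem.n_traits
    r = components["residual"]
    total = np.zeros((t_all, t_all))
    for xp in problem._xp:
        tr = xp["traits"]
        rows = xp["rows"]
        k = len(tr)
        ehat = np.column_stack([xp["y"][t] - xp["h"][t] @ theta for t in tr])
        eoo = np.einsum("ia,ib->ab", ehat, ehat)
        for ia in range(k):
            for ib in range(ia, k):
                q = _record_quadforms(fac, xp["h"][tr[ia]], xp["h"][tr[ib]]).sum()
                eoo[ia, ib] += q
                if ib != ia:
                    eoo[ib, ia] += q
        mis = np.array([t for t in range(t_all) if t not in tr], dtype=np.int64)
        n_c = len(rows)
        total[np.ix_(tr, tr)] += eoo
        if len(mis):
            roo = r[np.ix_(tr, tr)]
            rmo = r[np.ix_(mis, tr)]
            rmm = r[np.ix_(mis, mis)]
            bmat = rmo @ np.linalg.inv(roo)
            emo = bmat @ eoo
            emm = n_c * (rmm - bmat @ rmo.T) + bmat @ eoo @ bmat.T
            total[np.ix_(mis, tr)] += emo
            total[np.ix_(tr, mis)] += emo.T
            total[np.ix_(mis, mis)] += emm
    return total / problem.n_records


def _rel_change(old: np.ndarray, new: np.ndarray) -> float:
    scale = max(np.abs(np.diag(old)).max(), 1e-10)
    return float(np.abs(new - old).max() / scale)


def _max_change(old: dict, new: dict) -> float:
    return max(_rel_change(old[k], new[k]) for k in old)


def _em_step(problem, comps, controls):
    """One exact EM update; returns (new comps, loglik at comps, clamps)."""
    m, rhs, aux = assemble_mme(problem, comps)
    fac = _factorize(m, controls, problem._pattern, problem)
    theta = fac.solve(rhs)
    ll = _loglik_from_parts(problem, comps, aux, fac, theta, rhs)
    new = {}
    n_clamped = 0
    for tm in problem.terms:
        off = problem.offsets[tm.label]
        u = theta[off:off + tm.n_cols].reshape(tm.n_levels, tm.dim)
        quad = u.T @ u if tm.k_inverse is None else u.T @ (tm.k_inverse @ u)
        b_new = (quad + _term_trace(fac, problem, tm)) / tm.n_levels
        b_new, clamped = nearest_psd(b_new, controls.psd_floor)
        n_clamped += clamped
        new[tm.label] = b_new
    r_new = _residual_update(problem, comps, fac, theta)
    r_new, clamped = nearest_psd(r_new, controls.psd_floor)
    n_clamped += clamped
    new["residual"] = r_new
    return new, ll, n_clamped


def _loglik_cheap(problem, comps, controls):
    """Restricted log-likelihood without the selected inverse; -inf for
    numerically singular proposals (they are simply rejected)."""
    try:
        m, rhs, aux = assemble_mme(problem, comps)
        fac = _factorize(m, controls, problem._pattern, problem)
        theta = fac.solve(rhs)
        return _loglik_from_parts(problem, comps, aux, fac, theta, rhs)
    except (np.linalg.LinAlgError, ZeroDivisionError, FloatingPointError):
        return -np.inf


def _vec(comps, order):
    return np.concatenate([comps[k].ravel() for k in order])


def _unvec(v, template, order, floor):
    out = {}
    pos = 0
    for k in order:
        shp = template[k].shape
        m = v[pos:pos + shp[0] * shp[1]].reshape(shp)
        out[k], _ = nearest_psd(m, floor)
        pos += shp[0] * shp[1]
    return out


def _scale_search_moves(problem, comps, controls, ll_current, state):
    """Multiplicative line searches on selected coordinate subsets.

    A group is searched every cycle until the unit scale wins twice in a
    row, then only every fifth call (cheap re-checks).  Accepted moves
    strictly increase the restricted likelihood."""
    for group in controls.scale_search:
        label, idx = group
        state.setdefault("_calls", 0)
        if state[group] >= 2 and state["_calls"] % 5 != 0:
            continue
        if ll_current is None:
            ll_current = _loglik_cheap(problem, comps, controls)
        d = comps[label].shape[0]
        best_s, best_ll = 1.0, ll_current
        for s in controls.scale_grid:
            scale = np.ones(d)
            scale[list(idx)] = np.sqrt(s)
            cand = dict(comps)
            cand[label] = comps[label] * np.outer(scale, scale)
            ll = _loglik_cheap(problem, cand, controls)
            if np.isfinite(ll) and ll > best_ll:
                best_s, best_ll = s, ll
        if best_s != 1.0:
            scale = np.ones(d)
            scale[list(idx)] = np.sqrt(best_s)
            comps = dict(comps)
            comps[label] = comps[label] * np.outer(scale, scale)
            ll_current = best_ll
            state[group] = 0
        else:
            state[group] += 1
    state["_calls"] += 1
    return comps, ll_current


def em_reml_fit(problem: MMEProblem, start: dict,
                controls: EMControls | None = None) -> REMLResult:
    """Estimate all (co)variance components by EM-REML.

    ``start`` maps each term label (and ``"residual"``) to a symmetric
    positive-definite start matrix.  Returns the converged components,
    the BLUP solutions at those components, and a per-iteration trace of
    the components and the restricted log-likelihood (non-decreasing).

    By default each cycle takes two exact EM steps and attempts a
    squared-extrapolation (SQUAREM-style) jump along the EM trajectory;
    the jump is kept only if it does not lower the restricted likelihood,
    so the accepted sequence stays monotone while escaping the slow
    geometric crawl EM exhibits near flat ridges.  ``accelerate=False``
    gives plain EM.
    """
    controls = controls or EMControls()
    comps = {k: np.array(v, dtype=float, copy=True) for k, v in start.items()}
    order = sorted(comps)
    rows = []
    n_clamped = 0
    converged = False
    search_state = {g: 0 for g in controls.scale_search}  # settled counters
    it = 0
    while it < controls.max_iter:
        c1, ll0, nc = _em_step(problem, comps, controls)
        it += 1
        n_clamped += nc
        rows.append({"iteration": it, "loglik": ll0,
                     "max_rel_change": _max_change(comps, c1),
                     **{k: v.copy() for k, v in comps.items()}})
        if not controls.accelerate or it >= controls.max_iter:
            change = _max_change(comps, c1)
            ll_prev = rows[-2]["loglik"] if len(rows) > 1 else -np.inf
            comps = c1
            if change < controls.tol or abs(ll0 - ll_prev) < controls.loglik_tol:
                converged = True
                break
            continue

        c2, ll1, nc = _em_step(problem, c1, controls)
        it += 1
        n_clamped += nc
        rows.append({"iteration": it, "loglik": ll1,
                     "max_rel_change": _max_change(c1, c2),
                     **{k: v.copy() for k, v in c1.items()}})
        # extrapolate each component block along its own EM trajectory;
        # blocks converge at very different geometric rates (genetic
        # slope blocks are the slowest), so per-block step lengths beat
        # one global factor
        cand = {}
        for k in order:
            r = c1[k] - comps[k]
            v = c2[k] - c1[k] - r
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha = -np.abs(r) / np.abs(v)
            alpha = np.clip(np.nan_to_num(alpha, nan=-1.0,
                                          neginf=-controls.max_step),
                            -controls.max_step, -1.0)
            step = comps[k] - 2.0 * alpha * r + alpha * alpha * v
            cand[k], _ = nearest_psd(step, controls.psd_floor)
        accepted = c2
        ll_accept = None
        ll_cand = _loglik_cheap(problem, cand, controls)
        # accept only if at least as good as the pre-jump state; the
        # plain double-EM step c2 is >= ll1 by EM monotonicity, so the
        # accepted sequence never decreases either way
        if np.isfinite(ll_cand) and ll_cand >= ll1:
            accepted = cand
            ll_accept = ll_cand
        if controls.scale_search:
            accepted, ll_accept = _scale_search_moves(
                problem, accepted, controls, ll_accept, search_state)
        change = _max_change(comps, accepted)
        comps = accepted
        if change < controls.tol or (
                ll_accept is not None and abs(ll_accept - ll1) < controls.loglik_tol):
            converged = True
            break

    # final solve at the converged components
    m, rhs, aux = assemble_mme(problem, comps)
    fac = _factorize(m, controls, problem._pattern, problem)
    theta = fac.solve(rhs)
    ll = _loglik_from_parts(problem, comps, aux, fac, theta, rhs)
    fixed = theta[:problem.p_fixed]
    idx = np.arange(problem.p_fixed, dtype=np.int64)
    fixed_var = fac.inv_entries(idx, idx)
    term_solutions = {
        tm.label: theta[problem.offsets[tm.label]:
                        problem.offsets[tm.label] + tm.n_cols].reshape(tm.n_levels, tm.dim)
        for tm in problem.terms
    }
    trace = pd.DataFrame(rows)
    return REMLResult(components=comps, solutions=theta, fixed_effects=fixed,
                      fixed_se=np.sqrt(np.maximum(fixed_var, 0.0)), trace=trace,
                      loglik=ll, converged=converged, n_iter=it,
                      n_clamped=n_clamped, term_solutions=term_solutions)
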