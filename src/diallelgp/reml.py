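"""Average-information REML for multi-term Gaussian mixed models.

Solves models of the form ``y = X b + sum_r Z_r u_r + e`` where each random
term ``u_r ~ N(0, C_r (x) K_r)`` couples a (possibly multi-trait) covariance
matrix ``C_r`` with a known structure ``K_r`` (a relationship matrix, or the
identity), and the residual is either iid (univariate) or has a per-plot
trait covariance ``R`` (bivariate).  Estimation maximises the restricted
likelihood by average-information (AI) updates computed through the mixed
model equations, with step halving and EM-REML fallback whenever an AI step
would leave the parameter space.  Standard errors come from the inverse AI
matrix at convergence.

All likelihood quantities use the mixed-model-equations identities

    -2 log L = log|R| + sum_r (q_r log|C_r| + d_r log|K_r|)
             + log|C| + y' P y            (constants dropped)

with ``C`` the coefficient matrix of the MME and ``P`` the REML projection;
traces needed for the score vector come from blocks of ``C^-1``, so no n x n
inverse is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

__all__ = ["RandomTerm", "ResidualSpec", "REMLResult", "MMESolution",
           "REMLProblem", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class RandomTerm:
    """One random effect: u ~ N(0, C (x) K), Z maps observations to levels.

    ``Z`` has ``d * q`` columns in trait-major order (all ``q`` levels of
    trait 1, then trait 2, ...).  ``K=None`` means the identity structure.
    """

    name: str
    Z: sp.csr_matrix
    q: int
    d: int = 1
    K: np.ndarray | None = None
    K_inv: np.ndarray | None = None
    logdet_K: float = 0.0
    labels: list | None = None

    def __post_init__(self):
        self.Z = sp.csr_matrix(self.Z)
        if self.Z.shape[1] != self.d * self.q:
            raise ValueError(f"term {self.name}: Z has {self.Z.shape[1]} "
                             f"columns, expected d*q = {self.d * self.q}")
        if self.K is not None and self.K_inv is None:
            cf = cho_factor(_jittered(self.K), lower=True)
            self.logdet_K = 2.0 * np.sum(np.log(np.diag(cf[0])))
            inv, _ = dpotri(cf[0], lower=1)
            self.K_inv = np.tril(inv) + np.tril(inv, -1).T


def _jittered(K: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    return K + eps * np.mean(np.diag(K)) * np.eye(K.shape[0])


@dataclass
class ResidualSpec:
    """Residual structure: trait index per observation and plot unit index.

    Observations sharing a unit (same plot, different traits) get the
    cross-trait residual covariance; the covariance is estimable only if at
    least one unit carries two traits.
    """

    trait: np.ndarray          # (n,) int trait index of each observation
    unit: np.ndarray           # (n,) int plot/unit index
    d: int = 1

    pairs: np.ndarray = field(init=False)   # (n_pairs, 2) obs index pairs

    def __post_init__(self):
        self.trait = np.asarray(self.trait, dtype=int)
        self.unit = np.asarray(self.unit, dtype=int)
        if self.d == 1:
            self.pairs = np.empty((0, 2), dtype=int)
            return
        order = np.argsort(self.unit, kind="stable")
        pairs = []
        i = 0
        u = self.unit[order]
        while i < len(order):
            j = i
            while j + 1 < len(order) and u[j + 1] == u[i]:
                j += 1
            if j > i:
                members = order[i:j + 1]
                if len(members) != 2:
                    raise ValueError("a residual unit may hold at most one "
                                     "observation per trait")
                pairs.append(sorted(members, key=lambda k: self.trait[k]))
            i = j + 1
        self.pairs = (np.asarray(pairs, dtype=int) if pairs
                      else np.empty((0, 2), dtype=int))

    @property
    def cross_estimable(self) -> bool:
        return self.d > 1 and len(self.pairs) > 0


@dataclass
class REMLResult:
    components: dict              # term name -> C_r (d x d array), "resid" -> R
    se: dict                      # same keys, elementwise SEs (NaN if fixed)
    param_cov: np.ndarray         # covariance of free parameters (AI^-1)
    param_index: list             # [(key, s, t), ...] order of free params
    neg2loglik: float
    n_iter: int
    converged: bool
    boundary: list                # [(key, s, t), ...] at the variance floor
    trace: list                   # per-iteration (-2logL, params snapshot)
    cross_resid_estimable: bool = True

    def variance(self, key: str, s: int = 0, t: int = 0) -> float:
        return float(np.atleast_2d(self.components[key])[s, t])


@dataclass
class MMESolution:
    fixed: np.ndarray
    fixed_se: np.ndarray | None
    fixed_cov: np.ndarray | None
    random: dict                  # term name -> (d*q,) solution vector
    pev: dict                     # term name -> (d*q,) PEV, if requested
    neg2loglik: float


class REMLProblem:
    """A mixed model ready for REML estimation / MME solving.

    Parameters
    ----------
    y : (n,) response vector (traits stacked for bivariate models).
    X : (n, p) dense fixed-effect design; rank-deficient columns are dropped
        automatically (QR with pivoting).
    terms : list of RandomTerm.
    resid : ResidualSpec or None (None = iid univariate residual).
    """

    def __init__(self, y, X, terms, resid: ResidualSpec | None = None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        self.X, self.dropped_cols = _full_rank(X)
        self.p = self.X.shape[1]
        self.terms = list(terms)
        self.resid = resid if resid is not None else ResidualSpec(
            trait=np.zeros(n, dtype=int), unit=np.arange(n), d=1)
        self.n = n
        self.d_resid = self.resid.d
        self.W = sp.hstack([sp.csr_matrix(self.X)]
                           + [t.Z for t in self.terms]).tocsr()
        self.m = self.W.shape[1]
        # block offsets inside the MME
        self.offsets = {}
        off = self.p
        for t in self.terms:
            self.offsets[t.name] = (off, off + t.d * t.q)
            off += t.d * t.q

    # -- residual helpers ---------------------------------------------------

    def _r_inverse(self, R: np.ndarray):
        """Sparse R^-1, log|R| and y-independent residual bookkeeping."""
        tr_idx = self.resid.trait
        if self.d_resid == 1:
            s2 = float(R[0, 0])
            rinv = sp.identity(self.n, format="csr") / s2
            return rinv, self.n * np.log(s2)
        diag = np.array([1.0 / R[t, t] for t in tr_idx])
        rows, cols, vals = [], [], []
        logdet = 0.0
        paired = np.zeros(self.n, dtype=bool)
        for i, j in self.resid.pairs:
            sub = R[np.ix_([self.resid.trait[i], self.resid.trait[j]],
                           [self.resid.trait[i], self.resid.trait[j]])]
            det = sub[0, 0] * sub[1, 1] - sub[0, 1] ** 2
            logdet += np.log(det)
            inv = np.array([[sub[1, 1], -sub[0, 1]],
                            [-sub[0, 1], sub[0, 0]]]) / det
            for a, oa in enumerate((i, j)):
                for b, ob in enumerate((i, j)):
                    rows.append(oa); cols.append(ob); vals.append(inv[a, b])
            paired[i] = paired[j] = True
        single = ~paired
        logdet += float(np.sum(np.log(np.array(
            [R[t, t] for t in tr_idx[single]])))) if single.any() else 0.0
        rows.extend(np.flatnonzero(single))
        cols.extend(np.flatnonzero(single))
        vals.extend(diag[single])
        rinv = sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        return rinv, logdet

    # -- assembly -----------------------------------------------------------

    def _assemble(self, comps: dict):
        R = np.atleast_2d(np.asarray(comps["resid"], dtype=float))
        rinv, logdet_R = self._r_inverse(R)
        WtRi = (self.W.T @ rinv).tocsr()
        Cmat = (WtRi @ self.W).toarray()
        rhs = WtRi @ self.y
        logdet_G = 0.0
        ginv_blocks = {}
        for t in self.terms:
            Cr = np.atleast_2d(np.asarray(comps[t.name], dtype=float))
            Cr_inv = np.linalg.inv(Cr)
            sign, ld = np.linalg.slogdet(Cr)
            if sign <= 0:
                raise np.linalg.LinAlgError(f"{t.name}: C_r not PD")
            logdet_G += t.q * ld + t.d * t.logdet_K
            Kinv = t.K_inv if t.K_inv is not None else None
            if t.d == 1:
                block = (Kinv / Cr[0, 0] if Kinv is not None
                         else sp.identity(t.q).toarray() / Cr[0, 0])
            else:
                base = Kinv if Kinv is not None else np.eye(t.q)
                block = np.kron(Cr_inv, base)
            lo, hi = self.offsets[t.name]
            Cmat[lo:hi, lo:hi] += block
            ginv_blocks[t.name] = (Cr, Cr_inv)
        cf = cho_factor(Cmat, lower=True)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
        soln = cho_solve(cf, rhs)
        ytRiy = float(self.y @ (rinv @ self.y))
        yPy = ytRiy - float(soln @ rhs)
        neg2ll = logdet_R + logdet_G + logdet_C + yPy
        return {
            "R": R, "rinv": rinv, "WtRi": WtRi, "cf": cf, "soln": soln,
            "rhs": rhs, "yPy": yPy, "neg2ll": neg2ll, "ginv": ginv_blocks,
            "logdet_C": logdet_C,
        }

    def _c_inverse(self, cf):
        inv, info = dpotri(cf[0], lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        return np.tril(inv) + np.tril(inv, -1).T

    # -- parameter bookkeeping ---------------------------------------------

    def _param_list(self):
        params = []
        for t in self.terms:
            for s in range(t.d):
                for u in range(s, t.d):
                    params.append((t.name, s, u))
        for s in range(self.d_resid):
            for u in range(s, self.d_resid):
                if s != u and not self.resid.cross_estimable:
                    continue
                params.append(("resid", s, u))
        return params

    def _pack(self, comps, params):
        return np.array([np.atleast_2d(comps[k])[s, t] for k, s, t in params])

    def _unpack(self, vec, comps, params):
        out = {k: np.atleast_2d(np.asarray(v, dtype=float)).copy()
               for k, v in comps.items()}
        for val, (k, s, t) in zip(vec, params):
            out[k][s, t] = val
            out[k][t, s] = val
        return out

    def _valid(self, comps, floors):
        for key, mat in comps.items():
            mat = np.atleast_2d(mat)
            if np.any(np.diag(mat) < floors[key] * (1.0 - 1e-12)):
                return False
            if mat.shape[0] > 1:
                try:
                    np.linalg.cholesky(mat)
                except np.linalg.LinAlgError:
                    return False
        return True

    # -- score and AI -------------------------------------------------------

    def _score_and_ai(self, state, params):
        """Score vector (of log L) and AI matrix at the current state."""
        cf, soln = state["cf"], state["soln"]
        rinv = state["rinv"]
        Py = rinv @ (self.y - self.W @ soln)
        Cinv = self._c_inverse(cf)

        quads, traces, xis = [], [], []
        v_cache = {}
        for key, s, t in params:
            if key == "resid":
                quad, trace, xi = self._resid_derivs(state, Cinv, Py, s, t)
            else:
                term = next(tt for tt in self.terms if tt.name == key)
                if key not in v_cache:
                    v_cache[key] = term.Z.T @ Py
                v = v_cache[key]
                quad, trace, xi = self._term_derivs(term, state, Cinv, v, s, t)
            quads.append(quad)
            traces.append(trace)
            xis.append(xi)

        score = 0.5 * (np.array(quads) - np.array(traces))
        npar = len(params)
        AI = np.zeros((npar, npar))
        Pxis = []
        for xi in xis:
            wx = state["WtRi"] @ xi
            Pxi = rinv @ (xi - self.W @ cho_solve(cf, wx))
            Pxis.append(Pxi)
        for a in range(npar):
            for b in range(a, npar):
                AI[a, b] = AI[b, a] = 0.5 * float(xis[a] @ Pxis[b])
        return score, AI, Py, Cinv

    def _term_derivs(self, term, state, Cinv, v, s, t):
        q, d = term.q, term.d
        lo, hi = self.offsets[term.name]
        Crr = Cinv[lo:hi, lo:hi]
        Cr, Cr_inv = state["ginv"][term.name]
        Kinv = term.K_inv
        K = term.K

        def vblock(i):
            return v[i * q:(i + 1) * q]

        Kv_t = K @ vblock(t) if K is not None else vblock(t)
        quad = float(vblock(s) @ Kv_t)

        # t_uv = tr(C^{rr}[u,v] K^-1)
        tmat = np.zeros((d, d))
        for u in range(d):
            for w in range(u, d):
                blk = Crr[u * q:(u + 1) * q, w * q:(w + 1) * q]
                val = (float(np.sum(blk * Kinv)) if Kinv is not None
                       else float(np.trace(blk)))
                tmat[u, w] = tmat[w, u] = val
        trace = Cr_inv[t, s] * q - float(Cr_inv[t] @ tmat @ Cr_inv[:, s])

        # xi = Z (E_st (x) K) v   (symmetrised for s != t)
        u_vec = np.zeros(d * q)
        u_vec[s * q:(s + 1) * q] += Kv_t
        if s != t:
            Kv_s = K @ vblock(s) if K is not None else vblock(s)
            u_vec[t * q:(t + 1) * q] += Kv_s
            quad *= 2.0
            trace *= 2.0
        xi = term.Z @ u_vec
        return quad, trace, xi

    def _resid_derivs(self, state, Cinv, Py, s, t):
        tr_idx = self.resid.trait
        rinv = state["rinv"]
        if s == t:
            mask = tr_idx == s
            quad = float(np.sum(Py[mask] ** 2))
            tr_rinv = float(rinv.diagonal()[mask].sum())
            D = sp.diags(mask.astype(float), format="csr")
            xi = np.where(mask, Py, 0.0)
        else:
            pairs = self.resid.pairs
            i, j = pairs[:, 0], pairs[:, 1]
            quad = 2.0 * float(np.sum(Py[i] * Py[j]))
            rinv_csr = rinv.tocsr()
            tr_rinv = 2.0 * float(np.sum(np.array(
                [rinv_csr[a, b] for a, b in pairs])))
            rows = np.concatenate([i, j])
            cols = np.concatenate([j, i])
            D = sp.csr_matrix((np.ones(rows.size), (rows, cols)),
                              shape=(self.n, self.n))
            xi = np.zeros(self.n)
            xi[i] = Py[j]
            xi[j] = Py[i]
        U = state["WtRi"]           # m x n  (W' R^-1)
        UD = (U @ D) @ U.T          # m x m sparse
        UD = UD.tocoo()
        tr_corr = float(np.sum(Cinv[UD.row, UD.col] * UD.data))
        trace = tr_rinv - tr_corr
        return quad, trace, xi

    # -- EM fallback ---------------------------------------------------------

    def _em_step(self, state, comps, Cinv):
        new = {k: np.atleast_2d(np.asarray(v, dtype=float)).copy()
               for k, v in comps.items()}
        soln = state["soln"]
        for term in self.terms:
            lo, hi = self.offsets[term.name]
            u = soln[lo:hi]
            Crr = Cinv[lo:hi, lo:hi]
            q, d = term.q, term.d
            Kinv = term.K_inv
            Cr = np.zeros((d, d))
            for s in range(d):
                for t in range(s, d):
                    us, ut = u[s * q:(s + 1) * q], u[t * q:(t + 1) * q]
                    blk = Crr[s * q:(s + 1) * q, t * q:(t + 1) * q]
                    if Kinv is not None:
                        val = float(us @ (Kinv @ ut)) + float(np.sum(blk * Kinv))
                    else:
                        val = float(us @ ut) + float(np.trace(blk))
                    Cr[s, t] = Cr[t, s] = val / q
            new[term.name] = Cr
        if self.d_resid == 1:
            # Henderson residual update  (y'y - soln' W' y) / (n - p)
            wy = self.W.T @ self.y
            s2 = (float(self.y @ self.y) - float(state["soln"] @ wy)) \
                / (self.n - self.p)
            new["resid"] = np.array([[max(s2, 1e-12)]])
        return new

    # -- public API ----------------------------------------------------------

    def default_start(self):
        """Equal split of the per-trait phenotypic variance over components."""
        nt = max([t.d for t in self.terms] + [self.d_resid])
        var_t = np.zeros(nt)
        for tr in range(nt):
            mask = self.resid.trait == tr
            var_t[tr] = np.var(self.y[mask], ddof=1) if mask.sum() > 1 else 1.0
        k = len(self.terms) + 1
        comps = {}
        for t in self.terms:
            sub = var_t[:t.d]
            comps[t.name] = np.diag(sub / k) + 1e-12 * np.eye(t.d)
        comps["resid"] = np.diag(var_t[:self.d_resid] / k)
        return comps

    def fit(self, start: dict | None = None, max_iter: int = 100,
            tol: float = 1e-8, floor_frac: float = 1e-6) -> REMLResult:
        comps = start if start is not None else self.default_start()
        comps = {k: np.atleast_2d(np.asarray(v, dtype=float)).copy()
                 for k, v in comps.items()}
        params = self._param_list()
        nt = max([t.d for t in self.terms] + [self.d_resid])
        var_t = np.array([np.var(self.y[self.resid.trait == tr], ddof=1)
                          if (self.resid.trait == tr).sum() > 1 else 1.0
                          for tr in range(nt)])
        floors = {t.name: floor_frac * float(var_t[:t.d].mean())
                  for t in self.terms}
        floors["resid"] = floor_frac * float(var_t[:self.d_resid].mean())

        floor_vec = np.array([floors[k] if s == t else -np.inf
                              for k, s, t in params])
        diag_mask = np.array([s == t for _k, s, t in params])

        trace_log = []
        state = self._assemble(comps)
        prev = state["neg2ll"]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            score, ai, Py, Cinv = self._score_and_ai(state, params)
            theta = self._pack(comps, params)
            # covariances pinned on the correlation cap are held so the
            # reduced AI step can move along the constraint surface
            hold = np.zeros(len(params), dtype=bool)
            for i, (k, s, t) in enumerate(params):
                if s != t:
                    mat = np.atleast_2d(comps[k])
                    cap = 0.999 * np.sqrt(mat[s, s] * mat[t, t])
                    if abs(mat[s, t]) >= 0.98 * cap:
                        hold[i] = True
            target = _constrained_ai_step(theta, score, ai, floor_vec,
                                          diag_mask, hold)

            # try the AI target with step halving, guarded by the likelihood
            new_comps = new_state = None
            if target is not None:
                step = 1.0
                for _ in range(10):
                    cand = self._unpack(theta + step * (target - theta),
                                        comps, params)
                    cand = _apply_floors(cand, floors)
                    if self._valid(cand, floors):
                        try:
                            cand_state = self._assemble(cand)
                        except np.linalg.LinAlgError:
                            cand_state = None
                        if cand_state is not None and (
                                cand_state["neg2ll"]
                                <= state["neg2ll"] + 1e-8):
                            new_comps, new_state = cand, cand_state
                            break
                    step *= 0.5
            if new_comps is None:
                # EM-REML fallback: monotone, always inside the space
                new_comps = _apply_floors(self._em_step(state, comps, Cinv),
                                          floors)
                new_state = self._assemble(new_comps)

            comps, state = new_comps, new_state
            trace_log.append((state["neg2ll"],
                              {k: np.atleast_2d(v).tolist()
                               for k, v in comps.items()}))
            if abs(prev - state["neg2ll"]) < tol * (abs(state["neg2ll"]) + 1.0):
                converged = True
                prev = state["neg2ll"]
                break
            prev = state["neg2ll"]

        if not converged and max_iter > 1:
            raise ConvergenceError(
                f"REML did not converge in {max_iter} iterations "
                f"(-2logL trace tail: {[t[0] for t in trace_log[-5:]]})",
                trace_log)

        score, ai, Py, Cinv = self._score_and_ai(state, params)
        try:
            pcov = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            pcov = np.full((len(params), len(params)), np.nan)
        se = {k: np.full_like(np.atleast_2d(comps[k]), np.nan, dtype=float)
              for k in comps}
        for idx, (k, s, t) in enumerate(params):
            val = pcov[idx, idx]
            se[k][s, t] = se[k][t, s] = np.sqrt(val) if val >= 0 else np.nan

        boundary = [(k, s, t) for (k, s, t) in params
                    if s == t and np.atleast_2d(comps[k])[s, t]
                    <= floors[k] * 1.001]
        return REMLResult(
            components={k: np.atleast_2d(v) for k, v in comps.items()},
            se=se, param_cov=pcov, param_index=params,
            neg2loglik=state["neg2ll"], n_iter=n_iter, converged=converged,
            boundary=boundary, trace=trace_log,
            cross_resid_estimable=(self.d_resid == 1
                                   or self.resid.cross_estimable))

    def solve(self, comps: dict, compute_pev: bool = True,
              pev_terms=None) -> MMESolution:
        """Solve the MME at fixed variance components (BLUE + BLUP).

        PEV of a random level is the corresponding diagonal of the inverse
        coefficient matrix (already on the variance scale, since the MME are
        assembled with R^-1 absorbed).
        """
        comps = {k: np.atleast_2d(np.asarray(v, dtype=float))
                 for k, v in comps.items()}
        state = self._assemble(comps)
        soln = state["soln"]
        random = {}
        for t in self.terms:
            lo, hi = self.offsets[t.name]
            random[t.name] = soln[lo:hi]
        pev = {}
        fixed_se = fixed_cov = None
        if compute_pev:
            Cinv = self._c_inverse(state["cf"])
            fixed_cov = Cinv[:self.p, :self.p]
            fixed_se = np.sqrt(np.diag(fixed_cov))
            wanted = pev_terms if pev_terms is not None \
                else [t.name for t in self.terms]
            for t in self.terms:
                if t.name in wanted:
                    lo, hi = self.offsets[t.name]
                    pev[t.name] = np.diag(Cinv)[lo:hi].copy()
        return MMESolution(fixed=soln[:self.p], fixed_se=fixed_se,
                           fixed_cov=fixed_cov, random=random, pev=pev,
                           neg2loglik=state["neg2ll"])


def _constrained_ai_step(theta, score, ai, floor_vec, diag_mask,
                         hold_mask=None):
    """Newton/AI target with variance floors handled by an active set.

    Parameters proposed below their floor are pinned there and the AI system
    is re-solved for the remaining free parameters, so a component heading
    for the boundary does not stall the others.  ``hold_mask`` marks
    covariance parameters sitting on the correlation cap; they stay at their
    current value (the cap itself is re-applied after the step).
    """
    npar = len(theta)
    ridge = 1e-10 * max(np.trace(ai), 1.0)
    active = (hold_mask.copy() if hold_mask is not None
              else np.zeros(npar, dtype=bool))
    pin_vec = np.where(diag_mask, floor_vec, theta)
    cand = None
    for _ in range(npar + 1):
        free = ~active
        if not free.any():
            break
        delta = np.zeros(npar)
        delta[active] = pin_vec[active] - theta[active]
        try:
            rhs = score[free] - ai[np.ix_(free, active)] @ delta[active]
            delta[free] = np.linalg.solve(
                ai[np.ix_(free, free)] + ridge * np.eye(int(free.sum())), rhs)
        except np.linalg.LinAlgError:
            return None
        cand = theta + delta
        newly = diag_mask & (cand < floor_vec) & ~active
        if not newly.any():
            return cand
        active |= newly
    return cand


def _apply_floors(comps: dict, floors: dict) -> dict:
    out = {}
    for k, mat in comps.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float)).copy()
        d = mat.shape[0]
        for s in range(d):
            if mat[s, s] < floors[k]:
                mat[s, s] = floors[k]
        for s in range(d):
            for t in range(s + 1, d):
                cap = 0.999 * np.sqrt(mat[s, s] * mat[t, t])
                mat[s, t] = mat[t, s] = np.clip(mat[s, t], -cap, cap)
        out[k] = mat
    return out


def _full_rank(X: np.ndarray):
    """Drop linearly dependent columns (QR with column pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return X, []
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    dropped = sorted(set(range(X.shape[1])) - set(keep))
    return X[:, keep], dropped
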