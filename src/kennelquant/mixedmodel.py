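"""Generic REML engine for Gaussian mixed models with structured random effects.

The model is

    y = X beta + sum_B Z_B u_B + e,   u_B ~ N(0, Theta_B (x) K_B),

where each random factor B spans one or more traits (Theta_B is the
free (co)variance matrix across those traits, trait-major column
layout) and K_B is a known level-covariance (the numerator relationship
matrix for the additive factor, identity otherwise; only K^-1 and
log|K| are needed). Residuals are block-diagonal by *event*: the
observations belonging to one event (one test occasion) share the
residual covariance R restricted to the traits observed in that event,
which handles trait-wise missing records exactly.

Estimation is average-information (AI) REML: the AI matrix is built
from working variates (one extra mixed-model-equation solve per
parameter), the gradient from exact trace terms evaluated through the
inverse coefficient matrix, and each Newton step is safeguarded by
step-halving with an expectation-maximization fallback that guarantees
ascent. Variance matrices are kept positive (semi-)definite by
eigenvalue bending at a floor of 1e-8 times the phenotypic variance.

Everything downstream (univariate animal model, multivariate fits,
BLUP solutions, prediction error variances) is a thin layer over this
engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.linalg import eigh, lapack

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class FactorBlock:
    """One random factor: incidence, level covariance and trait span."""

    name: str
    Z: sparse.spmatrix  # n_obs x (n_traits * n_levels), trait-major columns
    n_levels: int
    n_traits: int = 1
    K_inv: sparse.spmatrix | None = None  # None -> identity levels
    K_logdet: float = 0.0

    def __post_init__(self):
        self.Z = sparse.csr_matrix(self.Z)
        if self.K_inv is not None:
            self.K_inv = sparse.csr_matrix(self.K_inv)

    @property
    def width(self) -> int:
        return self.n_traits * self.n_levels


@dataclass
class FitResult:
    """Converged (or flagged) REML fit."""

    theta: dict  # factor name -> Theta matrix; "residual" -> R matrix
    se: dict  # same keys, elementwise SEs (NaN where not estimated)
    param_names: list
    param_values: np.ndarray
    param_cov: np.ndarray  # inverse AI matrix at convergence
    loglik: float  # REML log-likelihood
    loglik_ml: float  # ML log-likelihood at the same parameter values
    beta: np.ndarray
    beta_se: np.ndarray
    u: dict  # factor name -> BLUP solution vector
    converged: bool
    iterations: int
    trace: list = field(default_factory=list)  # (iter, loglik, step kind)
    n_obs: int = 0
    n_fixed: int = 0

    def param_se(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.clip(np.diag(self.param_cov), 0.0, None))


def _sym_inv(Mx: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a small symmetric PD matrix."""
    w, V = eigh(Mx)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    return (V / w) @ V.T, float(np.sum(np.log(w)))


def _bend(Mx: np.ndarray, floor: float) -> np.ndarray:
    """Project a symmetric matrix to eigenvalues >= floor."""
    Mx = 0.5 * (Mx + Mx.T)
    w, V = eigh(Mx)
    if w.min() < floor:
        w = np.clip(w, floor, None)
        Mx = (V * w) @ V.T
    return Mx


class _State:
    """All quantities derived from one parameter value."""

    __slots__ = (
        "thetas",
        "R",
        "loglik",
        "loglik_ml",
        "chol",
        "sol",
        "Rinv",
        "resid",
        "Py",
        "yPy",
        "Rinv_pat",
        "Minv",
    )


class MixedModel:
    """Assembled design for one data set; fit repeatedly with different starts
    or at fixed parameter values."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        factors: Sequence[FactorBlock],
        obs_trait: np.ndarray | None = None,
        event_id: np.ndarray | None = None,
        n_traits: int = 1,
    ):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n, self.p = self.X.shape
        if self.y.shape[0] != self.n:
            raise ValueError("y and X row counts differ")
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effect design is rank deficient")
        self.factors = list(factors)
        self.n_traits = n_traits
        self.obs_trait = (
            np.zeros(self.n, dtype=int) if obs_trait is None else np.asarray(obs_trait, dtype=int)
        )
        self.event_id = (
            np.arange(self.n) if event_id is None else np.asarray(event_id, dtype=int)
        )

        # column layout
        off = self.p
        self.offsets: list[int] = []
        for f in self.factors:
            self.offsets.append(off)
            off += f.width
        self.m = off
        self.W = sparse.hstack(
            [sparse.csr_matrix(self.X)] + [f.Z for f in self.factors], format="csr"
        )
        self.WtW = (self.W.T @ self.W).tocsr()

        # residual event patterns: group events by the set of observed traits
        self.patterns: dict[tuple, np.ndarray] = {}
        by_event: dict[int, list[int]] = {}
        for i, e in enumerate(self.event_id):
            by_event.setdefault(int(e), []).append(i)
        tmp: dict[tuple, list[list[int]]] = {}
        for obs in by_event.values():
            traits = tuple(int(self.obs_trait[i]) for i in obs)
            if len(set(traits)) != len(traits):
                raise ValueError("an event contains two observations of the same trait")
            order = np.argsort(traits)
            key = tuple(sorted(traits))
            tmp.setdefault(key, []).append([obs[k] for k in order])
        for key, rows in tmp.items():
            self.patterns[key] = np.array(rows, dtype=int)  # (n_events, k)

        # which trait pairs are ever co-observed (residual covariances
        # outside this set are not identified and are fixed at zero)
        self.co_observed = np.zeros((n_traits, n_traits), dtype=bool)
        for key in self.patterns:
            for a in key:
                for b in key:
                    self.co_observed[a, b] = True

        # per-trait phenotypic scale for floors and starting values
        self.var_y = np.array(
            [
                np.var(self.y[self.obs_trait == t]) if np.any(self.obs_trait == t) else 1.0
                for t in range(n_traits)
            ]
        )
        self.var_y = np.where(self.var_y > 0, self.var_y, 1.0)

        # parameter index: factor (co)variances then residual (co)variances
        self.param_index: list[tuple] = []
        for fi, f in enumerate(self.factors):
            for a in range(f.n_traits):
                for b in range(a, f.n_traits):
                    self.param_index.append(("f", fi, a, b))
        for a in range(n_traits):
            for b in range(a, n_traits):
                if self.co_observed[a, b]:
                    self.param_index.append(("r", a, b))
        self.n_params = len(self.param_index)
        # lower bounds: variance (diagonal) parameters are floored, covariances
        # are controlled by eigenvalue bending instead
        self._param_floor = np.full(self.n_params, -np.inf)
        for pi, (kind, *idx) in enumerate(self.param_index):
            if kind == "f":
                fi, a, b = idx
                if a == b:
                    self._param_floor[pi] = 1e-8 * float(
                        np.mean(self.var_y[: self.factors[fi].n_traits])
                    )
            else:
                a, b = idx
                if a == b:
                    self._param_floor[pi] = 1e-8 * float(np.mean(self.var_y))

        # cross-products used by the residual EM update: B_ab = sum over
        # co-observed events of W_a' W_b (parameter independent)
        self._em_B: dict[tuple, sparse.spmatrix] = {}
        self._em_rows: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        for a in range(n_traits):
            for b in range(a, n_traits):
                rows_a, rows_b = [], []
                for key, obs_mat in self.patterns.items():
                    if a in key and b in key:
                        ia, ib = key.index(a), key.index(b)
                        rows_a.append(obs_mat[:, ia])
                        rows_b.append(obs_mat[:, ib])
                if rows_a:
                    ra = np.concatenate(rows_a)
                    rb = np.concatenate(rows_b)
                    self._em_rows[(a, b)] = (ra, rb)
                    self._em_B[(a, b)] = (self.W[ra].T @ self.W[rb]).tocsr()

    # -- parameter plumbing -------------------------------------------------

    def start_values(self) -> tuple[list[np.ndarray], np.ndarray]:
        per_trait_nf = np.zeros(self.n_traits)
        for f in self.factors:
            per_trait_nf[: f.n_traits] += 1  # factors span leading traits
        per_trait_nf = np.maximum(per_trait_nf, 1)
        thetas = []
        for f in self.factors:
            th = np.diag(
                [0.4 * self.var_y[t] / per_trait_nf[t] for t in range(f.n_traits)]
            )
            thetas.append(th)
        R = np.diag(0.5 * self.var_y)
        return thetas, R

    def _pack(self, thetas: list[np.ndarray], R: np.ndarray) -> np.ndarray:
        vals = []
        for kind, *idx in self.param_index:
            if kind == "f":
                fi, a, b = idx
                vals.append(thetas[fi][a, b])
            else:
                a, b = idx
                vals.append(R[a, b])
        return np.array(vals)

    def _unpack_delta(
        self, thetas: list[np.ndarray], R: np.ndarray, delta: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray]:
        new_t = [t.copy() for t in thetas]
        new_R = R.copy()
        for val, (kind, *idx) in zip(delta, self.param_index):
            if kind == "f":
                fi, a, b = idx
                new_t[fi][a, b] += val
                if a != b:
                    new_t[fi][b, a] += val
            else:
                a, b = idx
                new_R[a, b] += val
                if a != b:
                    new_R[b, a] += val
        return new_t, new_R

    def _apply_floors(
        self, thetas: list[np.ndarray], R: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray]:
        out_t = []
        for f, th in zip(self.factors, thetas):
            floor = 1e-8 * float(np.mean(self.var_y[: f.n_traits]))
            out_t.append(_bend(th, floor))
        floor_r = 1e-8 * float(np.mean(self.var_y))
        R = _bend(R, floor_r)
        return out_t, R

    # -- likelihood ---------------------------------------------------------

    def _assemble(self, thetas: list[np.ndarray], R: np.ndarray) -> _State:
        n, p = self.n, self.p
        # residual inverse, block-diagonal by event pattern
        logdetR = 0.0
        rows, cols, vals = [], [], []
        Rinv_pat: dict[tuple, np.ndarray] = {}
        for key, obs_mat in self.patterns.items():
            sub = R[np.ix_(key, key)]
            inv, ld = _sym_inv(sub)
            Rinv_pat[key] = inv
            logdetR += ld * obs_mat.shape[0]
            k = len(key)
            rows.append(np.repeat(obs_mat, k, axis=1).ravel())
            cols.append(np.tile(obs_mat, (1, k)).ravel())
            vals.append(np.tile(inv.ravel(), obs_mat.shape[0]))
        Rinv = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()

        # G_u^-1 blocks
        logdetGu = 0.0
        gi_blocks = [sparse.csr_matrix((p, p))]
        for f, th in zip(self.factors, thetas):
            Ti, ld_t = _sym_inv(th)
            Ki = f.K_inv if f.K_inv is not None else sparse.eye(f.n_levels, format="csr")
            gi_blocks.append(sparse.kron(sparse.csr_matrix(Ti), Ki, format="csr"))
            logdetGu += f.n_levels * ld_t + f.n_traits * f.K_logdet
        Gstar = sparse.block_diag(gi_blocks, format="csr")

        M = (self.W.T @ Rinv @ self.W + Gstar).toarray()
        Rinv_y = Rinv @ self.y
        rhs = self.W.T @ Rinv_y

        c, info = lapack.dpotrf(M, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("coefficient matrix not positive definite")
        sol, info = lapack.dpotrs(c, rhs, lower=1)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(c))))
        yPy = float(self.y @ Rinv_y - rhs @ sol)

        st = _State()
        st.thetas = [t.copy() for t in thetas]
        st.R = R.copy()
        st.chol = c
        st.sol = sol
        st.Rinv = Rinv
        st.Rinv_pat = Rinv_pat
        st.resid = self.y - self.W @ sol
        st.Py = Rinv @ st.resid
        st.yPy = yPy
        st.loglik = -0.5 * (logdetR + logdetGu + logdetM + yPy + (n - p) * LOG2PI)
        # ML log-likelihood at the same parameters (beta profiled out):
        # log|V| = log|R| + log|G_u| + log|Z'R^-1 Z + G_u^-1|
        if self.m > p:
            Czz = M[p:, p:]
            cz, info = lapack.dpotrf(Czz, lower=1)
            logdetCzz = 2.0 * float(np.sum(np.log(np.diag(cz)))) if info == 0 else np.nan
        else:
            logdetCzz = 0.0
        st.loglik_ml = -0.5 * (logdetR + logdetGu + logdetCzz + yPy + n * LOG2PI)
        st.Minv = None
        return st

    def _minv(self, st: _State) -> np.ndarray:
        if st.Minv is None:
            invm, info = lapack.dpotri(st.chol, lower=1)
            if info != 0:
                raise np.linalg.LinAlgError("dpotri failed")
            st.Minv = invm + np.tril(invm, -1).T
        return st.Minv

    def _solve(self, st: _State, B: np.ndarray) -> np.ndarray:
        out, info = lapack.dpotrs(st.chol, B, lower=1)
        return out

    # -- derivatives --------------------------------------------------------

    def _derivatives(self, st: _State) -> tuple[np.ndarray, np.ndarray]:
        """Score vector and average-information matrix at ``st``."""
        Minv = self._minv(st)
        n_par = self.n_params
        grads = np.zeros(n_par)
        Wvar = np.zeros((self.n, n_par))  # working variates V_dot P y

        # cached per-factor pieces
        fac_cache = {}
        for fi, (f, th) in enumerate(zip(self.factors, st.thetas)):
            off = self.offsets[fi]
            Ti, _ = _sym_inv(th)
            Ki = f.K_inv if f.K_inv is not None else sparse.eye(f.n_levels, format="csr")
            Gi = sparse.kron(sparse.csr_matrix(Ti), Ki, format="csr")
            Cbb = Minv[off : off + f.width, off : off + f.width]
            Dmat = (Gi @ Cbb).T  # = Cbb @ Gi (both symmetric)
            q0 = f.n_levels
            # block traces tr(D[b,a])
            btr = np.empty((f.n_traits, f.n_traits))
            for a in range(f.n_traits):
                for b in range(f.n_traits):
                    btr[b, a] = np.trace(
                        Dmat[b * q0 : (b + 1) * q0, a * q0 : (a + 1) * q0]
                    )
            u_b = st.sol[off : off + f.width].reshape(f.n_traits, q0)
            fac_cache[fi] = (Ti, btr, u_b, q0)

        for pi, (kind, *idx) in enumerate(self.param_index):
            if kind == "f":
                fi, a, b = idx
                f = self.factors[fi]
                Ti, btr, u_b, q0 = fac_cache[fi]
                E = np.zeros((f.n_traits, f.n_traits))
                E[a, b] += 1.0
                E[b, a] += 1.0
                if a == b:
                    E[a, b] = 1.0
                    E = np.zeros_like(E)
                    E[a, a] = 1.0
                ETi = E @ Ti
                tr_term = np.trace(ETi) * q0 - float(np.sum(ETi * btr.T))
                w_levels = ETi @ u_b  # (t_B, q0)
                w = self.factors[fi].Z @ w_levels.ravel()
            else:
                a, b = idx
                E = np.zeros((self.n_traits, self.n_traits))
                E[a, b] += 1.0
                E[b, a] += 1.0
                if a == b:
                    E = np.zeros_like(E)
                    E[a, a] = 1.0
                # tr(R^-1 Rdot) - tr(M^-1 W' Rinv Rdot Rinv W)
                tr1 = 0.0
                rows, cols, vals = [], [], []
                w = np.zeros(self.n)
                for key, obs_mat in self.patterns.items():
                    Eoo = E[np.ix_(key, key)]
                    if not Eoo.any():
                        continue
                    Rinv_oo = st.Rinv_pat[key]
                    tr1 += np.trace(Rinv_oo @ Eoo) * obs_mat.shape[0]
                    S = Rinv_oo @ Eoo @ Rinv_oo
                    k = len(key)
                    rows.append(np.repeat(obs_mat, k, axis=1).ravel())
                    cols.append(np.tile(obs_mat, (1, k)).ravel())
                    vals.append(np.tile(S.ravel(), obs_mat.shape[0]))
                    # working variate contribution: Rdot @ Py on these rows
                    Py_blocks = st.Py[obs_mat]  # (n_e, k)
                    w_blocks = Py_blocks @ Eoo.T
                    np.add.at(w, obs_mat.ravel(), w_blocks.ravel())
                if rows:
                    Smat = sparse.coo_matrix(
                        (
                            np.concatenate(vals),
                            (np.concatenate(rows), np.concatenate(cols)),
                        ),
                        shape=(self.n, self.n),
                    ).tocsr()
                    Bm = (self.W.T @ Smat @ self.W).tocsr()
                    tr2 = float(Bm.multiply(Minv).sum())
                else:
                    tr2 = 0.0
                tr_term = tr1 - tr2
            quad = float(st.Py @ w)
            grads[pi] = -0.5 * (tr_term - quad)
            Wvar[:, pi] = w

        # AI matrix: 0.5 * Wvar' P Wvar
        V = st.Rinv @ Wvar
        T = self.W.T @ V
        U = self._solve(st, T)
        PW = V - st.Rinv @ (self.W @ U)
        AI = 0.5 * (Wvar.T @ PW)
        AI = 0.5 * (AI + AI.T)
        return grads, AI

    # -- EM fallback --------------------------------------------------------

    def _em_update(self, st: _State) -> tuple[list[np.ndarray], np.ndarray]:
        Minv = self._minv(st)
        new_t = []
        for fi, (f, th) in enumerate(zip(self.factors, st.thetas)):
            off = self.offsets[fi]
            q0 = f.n_levels
            U = st.sol[off : off + f.width].reshape(f.n_traits, q0).T  # (q0, t_B)
            Ki = f.K_inv if f.K_inv is not None else sparse.eye(q0, format="csr")
            quad = U.T @ (Ki @ U)
            Kcoo = Ki.tocoo()
            TrM = np.empty((f.n_traits, f.n_traits))
            for a in range(f.n_traits):
                for b in range(f.n_traits):
                    sub = Minv[off + a * q0 : off + (a + 1) * q0, off + b * q0 : off + (b + 1) * q0]
                    TrM[a, b] = float(np.sum(Kcoo.data * sub[Kcoo.row, Kcoo.col]))
            new_t.append((quad + TrM) / q0)
        # residual: pairwise over co-observed events
        R_new = st.R.copy()
        for (a, b), (ra, rb) in self._em_rows.items():
            n_ab = len(ra)
            cross = float(st.resid[ra] @ st.resid[rb])
            tr = float(self._em_B[(a, b)].multiply(Minv).sum())
            R_new[a, b] = R_new[b, a] = (cross + tr) / n_ab
        return new_t, R_new

    # -- main fitting loop --------------------------------------------------

    def _apply_pins(
        self, thetas: list[np.ndarray], R: np.ndarray, pinned: dict[int, float]
    ) -> tuple[list[np.ndarray], np.ndarray]:
        for pi, val in pinned.items():
            kind, *idx = self.param_index[pi]
            if kind == "f":
                fi, a, b = idx
                thetas[fi][a, b] = thetas[fi][b, a] = val
            else:
                a, b = idx
                R[a, b] = R[b, a] = val
        return thetas, R

    def fit_reml(
        self,
        start: tuple[list[np.ndarray], np.ndarray] | None = None,
        max_iter: int = 100,
        tol_loglik: float = 1e-8,
        tol_param: float = 1e-6,
        pinned: dict[int, float] | None = None,
    ) -> FitResult:
        """Maximize the REML log-likelihood.

        ``pinned`` fixes selected (co)variance parameters (by position
        in ``param_index``) at given values, e.g. a genetic covariance
        at 0 for a boundary likelihood-ratio test.
        """
        pinned = pinned or {}
        thetas, R = start if start is not None else self.start_values()
        thetas, R = self._apply_pins(*self._apply_floors(thetas, R), pinned)
        st = self._assemble(thetas, R)
        trace = [(0, st.loglik, "start")]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            grads, AI = self._derivatives(st)
            prev_vec = self._pack(st.thetas, st.R)
            prev_ll = st.loglik
            accepted = None
            # active set: variance parameters held at the floor with a
            # negative score are excluded from the Newton step, otherwise
            # their unbounded update dominates the direction
            at_floor = (prev_vec <= 4.0 * self._param_floor) & (grads < 0)
            free = [i for i in range(self.n_params) if i not in pinned and not at_floor[i]]
            # Newton step with average information, safeguarded
            delta = np.zeros(self.n_params)
            try:
                AIf = AI[np.ix_(free, free)]
                ridge = 1e-8 * max(np.trace(AIf) / max(len(free), 1), 1e-12)
                delta[free] = np.linalg.solve(
                    AIf + ridge * np.eye(len(free)), grads[free]
                )
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    cand = self._unpack_delta(st.thetas, st.R, step * delta)
                    cand = self._apply_pins(*self._apply_floors(*cand), pinned)
                    try:
                        cst = self._assemble(*cand)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if cst.loglik >= prev_ll - 1e-10:
                        accepted = (cst, "ai" if step == 1.0 else "ai-halved")
                        break
                    step *= 0.5
            if accepted is None:
                cand = self._apply_pins(*self._apply_floors(*self._em_update(st)), pinned)
                cst = self._assemble(*cand)
                if cst.loglik >= prev_ll - 1e-8:
                    accepted = (cst, "em")
            if accepted is None:
                break  # cannot improve: treat current point as final
            st, kind = accepted
            trace.append((it, st.loglik, kind))
            new_vec = self._pack(st.thetas, st.R)
            scale = np.maximum(np.abs(prev_vec), 1e-3 * float(np.mean(self.var_y)))
            if (
                abs(st.loglik - prev_ll) < tol_loglik
                and np.max(np.abs(new_vec - prev_vec) / scale) < tol_param
            ):
                converged = True
                break

        grads, AI = self._derivatives(st)
        try:
            param_cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            param_cov = np.linalg.pinv(AI)
        return self._result(st, param_cov, converged, it, trace)

    def _result(self, st: _State, param_cov, converged, iterations, trace) -> FitResult:
        Minv = self._minv(st)
        names = []
        for kind, *idx in self.param_index:
            if kind == "f":
                fi, a, b = idx
                names.append(f"{self.factors[fi].name}[{a},{b}]")
            else:
                a, b = idx
                names.append(f"residual[{a},{b}]")
        theta = {f.name: th.copy() for f, th in zip(self.factors, st.thetas)}
        theta["residual"] = st.R.copy()
        se_map = {k: np.full_like(v, np.nan) for k, v in theta.items()}
        ses = np.sqrt(np.clip(np.diag(param_cov), 0.0, None))
        for val, (kind, *idx) in zip(ses, self.param_index):
            if kind == "f":
                fi, a, b = idx
                se_map[self.factors[fi].name][a, b] = val
                se_map[self.factors[fi].name][b, a] = val
            else:
                a, b = idx
                se_map["residual"][a, b] = val
                se_map["residual"][b, a] = val
        u = {}
        for f, off in zip(self.factors, self.offsets):
            u[f.name] = st.sol[off : off + f.width].copy()
        return FitResult(
            theta=theta,
            se=se_map,
            param_names=names,
            param_values=self._pack(st.thetas, st.R),
            param_cov=param_cov,
            loglik=st.loglik,
            loglik_ml=st.loglik_ml,
            beta=st.sol[: self.p].copy(),
            beta_se=np.sqrt(np.clip(np.diag(Minv)[: self.p], 0.0, None)),
            u=u,
            converged=converged,
            iterations=iterations,
            trace=trace,
            n_obs=self.n,
            n_fixed=self.p,
        )

    # -- fixed-parameter solve and ML fit ------------------------------------

    def solve_at(self, thetas: list[np.ndarray], R: np.ndarray) -> tuple[np.ndarray, _State]:
        """Solve the mixed-model equations at fixed (co)variances."""
        st = self._assemble(thetas, R)
        return st.sol, st

    def pev(self, st: _State, factor_name: str, dense_cutoff: int = 2000) -> np.ndarray:
        """Prediction error variances: diagonal of the inverse coefficient
        matrix block for ``factor_name``.

        Dense inversion below ``dense_cutoff`` equations, batched sparse
        solves above.
        """
        fi = [f.name for f in self.factors].index(factor_name)
        off = self.offsets[fi]
        width = self.factors[fi].width
        if self.m <= dense_cutoff:
            Minv = self._minv(st)
            return np.diag(Minv)[off : off + width].copy()
        out = np.empty(width)
        batch = 256
        for s0 in range(0, width, batch):
            k = min(batch, width - s0)
            E = np.zeros((self.m, k))
            for j in range(k):
                E[off + s0 + j, j] = 1.0
            sol = self._solve(st, E)
            for j in range(k):
                out[s0 + j] = sol[off + s0 + j, j]
        return out

    def ml_loglik(self, thetas: list[np.ndarray], R: np.ndarray) -> float:
        return self._assemble(thetas, R).loglik_ml

    def fit_ml_univariate(self, max_iter: int = 200) -> tuple[float, list[np.ndarray], np.ndarray]:
        """Maximize the ML log-likelihood for a single-trait model.

        All (co)variance matrices are 1x1, so the optimization runs over
        log-variances with a derivative-free safeguarded optimizer. Used
        for information-criterion comparisons across fixed-effect sets,
        where REML likelihoods are not comparable.
        """
        from scipy.optimize import minimize

        if self.n_traits != 1 or any(f.n_traits != 1 for f in self.factors):
            raise ValueError("ML fit implemented for univariate models only")
        t0, R0 = self.fit_reml().theta, None  # warm start from REML
        x0 = np.log(
            np.concatenate(
                [
                    [max(t0[f.name][0, 0], 1e-8 * self.var_y[0]) for f in self.factors],
                    [max(t0["residual"][0, 0], 1e-8 * self.var_y[0])],
                ]
            )
        )

        def unpack(x):
            vs = np.exp(x)
            thetas = [np.array([[v]]) for v in vs[:-1]]
            R = np.array([[vs[-1]]])
            return thetas, R

        def negll(x):
            try:
                return -self.ml_loglik(*unpack(x))
            except np.linalg.LinAlgError:
                return 1e12

        res = minimize(negll, x0, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        thetas, R = unpack(res.x)
        return -res.fun, thetas, R
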