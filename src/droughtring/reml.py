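"""Restricted maximum likelihood engine for individual-tree mixed models.

The model handled here is

    y_t = X b_t + u_a,t + sum_j Z_j u_j,t + e_t        (traits t = 1..T)

where ``u_a`` is an additive genetic effect with covariance ``G_a ⊗ K`` for a
supplied relationship kernel ``K`` (pedigree A or genomic G among the
phenotyped individuals), the ``u_j`` are design random intercepts (block, set
within block, ...) with trait-specific variances, and the residual has
covariance ``R ⊗ I``.  ``G_a`` and ``R`` are full T×T covariance matrices so
bivariate fits yield additive covariances directly.

Numerics
--------
The kernel is eigendecomposed once (``K = U Λ U'``); rotating the data by
``U'`` makes the genetic-plus-residual part of ``V`` block diagonal in T×T
blocks, and the low-rank design factors are folded in with a Woodbury
identity.  Every EM or AI iteration is then O(n·q²) for q design levels
instead of O(n³), and the decomposition can be reused across traits and
simulation replicates that share a pedigree.

Variance components are updated with the expectation–maximization REML
recursions written in terms of the projection matrix P (monotone in the
restricted log-likelihood), optionally followed by average-information (AI)
Newton steps; the inverse AI matrix supplies standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.linalg import LinAlgError
from scipy.linalg import cho_factor, cho_solve

__all__ = ["REMLProblem", "REMLResult"]

_EINS = dict(optimize=True)


def _as_2d(Y):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


@dataclass
class REMLResult:
    """Converged variance components and derived quantities.

    Attributes
    ----------
    G_a : (T, T) additive (co)variance matrix, or None if no kernel.
    R : (T, T) residual (co)variance matrix.
    factor_variances : dict name -> (T,) array of design variances.
    se : dict parameter label -> standard error (from the AI matrix).
    cov_params : covariance matrix of the parameter vector (AI inverse).
    param_labels : labels matching ``cov_params`` rows.
    beta : fixed-effect estimates, trait-major.
    cov_beta : covariance of the fixed effects.
    loglik_path : restricted log-likelihood at each EM/AI iteration.
    Py : (n, T) projection P·y in the original data order (for BLUP).
    """

    G_a: np.ndarray | None
    R: np.ndarray
    factor_variances: dict
    se: dict
    cov_params: np.ndarray
    param_labels: list
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    Py: np.ndarray
    converged: bool
    n_iter: int

    @property
    def variances(self):
        """Flat dict of variance components (univariate convenience)."""
        out = {}
        if self.G_a is not None:
            out["additive"] = float(self.G_a[0, 0]) if self.G_a.shape[0] == 1 else self.G_a
        for name, v in self.factor_variances.items():
            out[name] = float(v[0]) if len(v) == 1 else v
        out["residual"] = float(self.R[0, 0]) if self.R.shape[0] == 1 else self.R
        return out


class REMLProblem:
    """One dataset prepared for REML fitting.

    Parameters
    ----------
    Y : (n,) or (n, T) response(s); complete cases only.
    X : (n, p) fixed-effect design, full column rank.
    kernel : optional (n, n) PSD relationship kernel among the observations
        (Z_a·A·Z_a' for an animal model where every tree has a record).
    factors : sequence of (name, Z) with Z an (n, q_j) 0/1 incidence matrix.
    decomposition : optional (eigenvalues, eigenvectors) of the kernel,
        reusable across fits sharing a pedigree (skips the O(n^3) eigh).
    """

    def __init__(self, Y, X, kernel=None, factors=(), decomposition=None):
        Y = _as_2d(Y)
        self.n, self.T = Y.shape
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise ValueError("X and Y row counts differ")
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            raise ValueError(
                f"fixed-effects design is rank deficient (rank {r} < {X.shape[1]} columns); "
                "remove aliased columns"
            )
        self.p = X.shape[1]
        if self.n <= self.p:
            raise ValueError("need more observations than fixed effects")
        self.factor_names = [name for name, _ in factors]
        Zs = [np.asarray(Z, dtype=float) for _, Z in factors]
        for Z in Zs:
            if Z.shape[0] != self.n:
                raise ValueError("factor incidence rows must match observations")

        self.has_kernel = kernel is not None or decomposition is not None
        if self.has_kernel:
            if decomposition is not None:
                lam, U = decomposition
                lam = np.asarray(lam, dtype=float)
                U = np.asarray(U, dtype=float)
            else:
                K = np.asarray(kernel, dtype=float)
                if K.shape != (self.n, self.n):
                    raise ValueError("kernel must be n x n over the observations")
                lam, U = np.linalg.eigh((K + K.T) / 2.0)
            self.lam = np.clip(lam, 0.0, None)
            self.U = U
            self.Y = U.T @ Y
            self.Xmat = U.T @ X
            self.Z = [U.T @ Z for Z in Zs]
        else:
            self.lam = None
            self.U = None
            self.Y = Y
            self.Xmat = X
            self.Z = Zs

        self.qs_list = [Z.shape[1] for Z in self.Z]
        self.qs = int(sum(self.qs_list))
        self.Zall = np.hstack(self.Z) if self.Z else np.zeros((self.n, 0))
        self.col_of = {}
        off = 0
        for name, q in zip(self.factor_names, self.qs_list):
            self.col_of[name] = slice(off, off + q)
            off += q
        # trait-major fixed design (n, T, T*p): trait t uses columns t*p..(t+1)*p
        pt = self.T * self.p
        Xarr = np.zeros((self.n, self.T, pt))
        for t in range(self.T):
            Xarr[:, t, t * self.p : (t + 1) * self.p] = self.Xmat
        self.Xarr = Xarr
        self.vary = Y.var(axis=0, ddof=1)
        self.floor = 1e-10 * self.vary

    # ------------------------------------------------------------------ state

    def _state(self, Ga, Fv, R):
        """Factorize V for the current parameters; return working dict."""
        n, T, qs = self.n, self.T, self.qs
        if self.has_kernel:
            B = self.lam[:, None, None] * Ga[None, :, :] + R[None, :, :]
        else:
            B = np.broadcast_to(R, (n, T, T)).copy()
        Bi = np.linalg.inv(B)
        sign, logdetB = np.linalg.slogdet(B)
        if np.any(sign <= 0):
            raise LinAlgError("V core not positive definite")
        st = {"Ga": Ga, "Fv": Fv, "R": R, "B": B, "Bi": Bi, "logdetB": float(logdetB.sum())}

        if qs:
            Zall = self.Zall
            gdiag = np.concatenate(
                [np.repeat(Fv[name][t], q) for t in range(T) for name, q in zip(self.factor_names, self.qs_list)]
            )
            # order: trait-major, factor, level  -> index (t, c) with c over qs
            TQ = T * qs
            M = np.zeros((TQ, TQ))
            for t in range(T):
                for s in range(T):
                    blk = (Zall * Bi[:, t, s][:, None]).T @ Zall
                    M[t * qs : (t + 1) * qs, s * qs : (s + 1) * qs] = blk
            M[np.arange(TQ), np.arange(TQ)] += 1.0 / gdiag
            cho = cho_factor(M, lower=True)
            logdetM = 2.0 * np.log(np.diag(cho[0])).sum()
            st.update(gdiag=gdiag, cho=cho, logdetM=float(logdetM), logdetG=float(np.log(gdiag).sum()))
        else:
            st.update(gdiag=None, cho=None, logdetM=0.0, logdetG=0.0)
        return st

    def _apply_Vinv(self, st, A):
        """V^{-1} A for A of shape (n, T, m)."""
        Bi = st["Bi"]
        u = np.einsum("kts,ksm->ktm", Bi, A, **_EINS)
        if self.qs:
            Zall = self.Zall
            s = np.einsum("kc,ktm->tcm", Zall, u, **_EINS)
            m = A.shape[2]
            w = cho_solve(st["cho"], s.reshape(self.T * self.qs, m)).reshape(self.T, self.qs, m)
            corr = np.einsum("kc,scm->ksm", Zall, w, **_EINS)
            u = u - np.einsum("kts,ksm->ktm", Bi, corr, **_EINS)
        return u

    def _fixed(self, st):
        VinvX = self._apply_Vinv(st, self.Xarr)
        XtVX = np.einsum("ktm,ktl->ml", self.Xarr, VinvX, **_EINS)
        choX = cho_factor((XtVX + XtVX.T) / 2.0, lower=True)
        logdetXVX = 2.0 * np.log(np.diag(choX[0])).sum()
        VinvY = self._apply_Vinv(st, self.Y[:, :, None])[:, :, 0]
        rhs = np.einsum("ktm,kt->m", self.Xarr, VinvY, **_EINS)
        beta = cho_solve(choX, rhs)
        v = VinvY - np.einsum("ktm,m->kt", VinvX, beta, **_EINS)  # P y
        yPy = float(np.einsum("kt,kt->", self.Y, v, **_EINS))
        ll = -0.5 * (st["logdetB"] + st["logdetM"] + st["logdetG"] + float(logdetXVX) + yPy)
        st.update(VinvX=VinvX, choX=choX, beta=beta, v=v, yPy=yPy, ll=ll)
        return st

    def _apply_P(self, st, A):
        u = self._apply_Vinv(st, A)
        XtVA = np.einsum("ktm,ktl->ml", self.Xarr, u, **_EINS)
        u = u - np.einsum("ktm,ml->ktl", st["VinvX"], cho_solve(st["choX"], XtVA), **_EINS)
        return u

    def _pblocks(self, st):
        """Observation-diagonal T×T blocks of P."""
        Bi = st["Bi"]
        D2 = np.zeros((self.n, self.T, self.T))
        if self.qs:
            TQ = self.T * self.qs
            # F[k, t, (a,c)] = Bi[k,t,a] * Zall[k,c]
            F = np.einsum("kta,kc->ktac", Bi, self.Zall, **_EINS).reshape(self.n, self.T, TQ)
            S = cho_solve(st["cho"], F.reshape(self.n * self.T, TQ).T).T.reshape(self.n, self.T, TQ)
            D2 = np.einsum("ktq,ksq->kts", F, S, **_EINS)
        Cx = cho_solve(st["choX"], np.eye(self.T * self.p))
        XC = np.einsum("ktm,ml,ksl->kts", st["VinvX"], Cx, st["VinvX"], **_EINS)
        return Bi - D2 - XC

    def _design_traces(self, st):
        """tr(P H) and y'PHPy for every (factor, trait) scalar variance."""
        v = st["v"]
        trF = {}
        quadF = {}
        if not self.qs:
            return trF, quadF
        # all design columns embedded trait-by-trait
        ncols = self.T * self.qs
        Warr = np.zeros((self.n, self.T, ncols))
        for t in range(self.T):
            Warr[:, t, t * self.qs : (t + 1) * self.qs] = self.Zall
        PW = self._apply_P(st, Warr)
        vW = self.Zall.T @ v  # (qs, T)
        for name in self.factor_names:
            sl = self.col_of[name]
            for t in range(self.T):
                cols = np.arange(sl.start, sl.stop) + t * self.qs
                tr = float(np.einsum("kc,kc->", self.Zall[:, sl], PW[:, t, cols], **_EINS))
                trF[(name, t)] = tr
                quadF[(name, t)] = float((vW[sl.start : sl.stop, t] ** 2).sum())
        return trF, quadF

    # ------------------------------------------------------------------ EM

    def _em_step(self, st):
        Ga, Fv, R = st["Ga"], st["Fv"], st["R"]
        v = st["v"]
        Pb = self._pblocks(st)
        trF, quadF = self._design_traces(st)
        n = self.n

        TrR = Pb.sum(axis=0)
        QuadR = np.einsum("ka,kb->ab", v, v, **_EINS)
        R_new = R + (R @ (QuadR - TrR) @ R) / n
        if self.has_kernel:
            TrG = np.einsum("k,kab->ab", self.lam, Pb, **_EINS)
            QuadG = np.einsum("k,ka,kb->ab", self.lam, v, v, **_EINS)
            Ga_new = Ga + (Ga @ (QuadG - TrG) @ Ga) / n
        else:
            Ga_new = Ga
        Fv_new = {}
        for name in self.factor_names:
            q = self.qs_list[self.factor_names.index(name)]
            vals = np.empty(self.T)
            for t in range(self.T):
                s2 = Fv[name][t]
                vals[t] = s2 + (s2 * s2 / q) * (quadF[(name, t)] - trF[(name, t)])
            Fv_new[name] = vals
        return self._floor_params(Ga_new, Fv_new, R_new)

    def _floor_params(self, Ga, Fv, R):
        def fix_mat(M):
            M = (M + M.T) / 2.0
            w, Q = np.linalg.eigh(M)
            w = np.maximum(w, self.floor.max())
            return (Q * w) @ Q.T

        if self.has_kernel:
            Ga = fix_mat(Ga)
        R = fix_mat(R)
        Fv = {k: np.maximum(v, self.floor.max()) for k, v in Fv.items()}
        return Ga, Fv, R

    # ------------------------------------------------------------------ AI

    def _param_layout(self):
        labels = []
        if self.has_kernel:
            for a in range(self.T):
                for b in range(a, self.T):
                    labels.append(("Ga", a, b))
        for name in self.factor_names:
            for t in range(self.T):
                labels.append(("F", name, t))
        for a in range(self.T):
            for b in range(a, self.T):
                labels.append(("R", a, b))
        return labels

    def _pack(self, Ga, Fv, R):
        out = []
        for lab in self._param_layout():
            if lab[0] == "Ga":
                out.append(Ga[lab[1], lab[2]])
            elif lab[0] == "F":
                out.append(Fv[lab[1]][lab[2]])
            else:
                out.append(R[lab[1], lab[2]])
        return np.array(out)

    def _unpack(self, theta):
        T = self.T
        Ga = np.zeros((T, T))
        R = np.zeros((T, T))
        Fv = {name: np.zeros(T) for name in self.factor_names}
        for val, lab in zip(theta, self._param_layout()):
            if lab[0] == "Ga":
                Ga[lab[1], lab[2]] = Ga[lab[2], lab[1]] = val
            elif lab[0] == "F":
                Fv[lab[1]][lab[2]] = val
            else:
                R[lab[1], lab[2]] = R[lab[2], lab[1]] = val
        return Ga, Fv, R

    def _Hv(self, lab, v, vW):
        """H_m · v for parameter with label ``lab``; v is (n, T)."""
        out = np.zeros_like(v)
        kind = lab[0]
        if kind in ("Ga", "R"):
            _, a, b = lab
            w = self.lam if kind == "Ga" else np.ones(self.n)
            if a == b:
                out[:, a] = w * v[:, a]
            else:
                out[:, a] = w * v[:, b]
                out[:, b] += w * v[:, a]
        else:
            _, name, t = lab
            sl = self.col_of[name]
            out[:, t] = self.Zall[:, sl] @ vW[sl.start : sl.stop, t]
        return out

    def _score_and_ai(self, st):
        """REML score vector and average-information matrix."""
        labels = self._param_layout()
        v = st["v"]
        vW = self.Zall.T @ v if self.qs else np.zeros((0, self.T))
        Pb = self._pblocks(st)
        trF, quadF = self._design_traces(st)
        TrR = Pb.sum(axis=0)
        QuadR = np.einsum("ka,kb->ab", v, v, **_EINS)
        if self.has_kernel:
            TrG = np.einsum("k,kab->ab", self.lam, Pb, **_EINS)
            QuadG = np.einsum("k,ka,kb->ab", self.lam, v, v, **_EINS)

        score = np.empty(len(labels))
        Hvs = np.empty((self.n, self.T, len(labels)))
        for i, lab in enumerate(labels):
            Hvs[:, :, i] = self._Hv(lab, v, vW)
            kind = lab[0]
            if kind == "Ga":
                _, a, b = lab
                mult = 1.0 if a == b else 2.0
                score[i] = 0.5 * mult * (QuadG[a, b] - TrG[a, b])
            elif kind == "R":
                _, a, b = lab
                mult = 1.0 if a == b else 2.0
                score[i] = 0.5 * mult * (QuadR[a, b] - TrR[a, b])
            else:
                score[i] = 0.5 * (quadF[(lab[1], lab[2])] - trF[(lab[1], lab[2])])
        PHv = self._apply_P(st, Hvs)
        AI = 0.5 * np.einsum("kti,ktj->ij", Hvs, PHv, **_EINS)
        return score, AI

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        Ga0=None,
        Fv0=None,
        R0=None,
        method="em",
        tol=1e-8,
        max_iter=1000,
        ai_rounds=1,
    ):
        """Estimate variance components.

        method : "em" — EM-REML to convergence, then ``ai_rounds`` AI rounds
            that compute standard errors without moving the estimates
            (the classic EM-then-AI recipe); "ai" — a few EM warm-up steps
            followed by AI Newton iterations (fast; falls back to EM when a
            step leaves the parameter space).
        """
        T = self.T
        Sp = np.cov(self.Y.T).reshape(T, T) if self.has_kernel or True else None
        Sp = np.atleast_2d(np.cov(self.Y.T)).reshape(T, T)
        if Ga0 is None:
            Ga0 = 0.4 * Sp if self.has_kernel else None
        if R0 is None:
            R0 = (0.5 if self.has_kernel else 0.8) * Sp
        if Fv0 is None:
            Fv0 = {name: 0.05 * np.diag(Sp).copy() for name in self.factor_names}
        Ga = Ga0 if self.has_kernel else np.zeros((T, T))
        Fv = {k: np.asarray(val, dtype=float).reshape(T).copy() for k, val in Fv0.items()}
        R = np.asarray(R0, dtype=float).reshape(T, T).copy()
        Ga, Fv, R = self._floor_params(Ga, Fv, R)

        scale = float(self.vary.max())
        path = []
        st = self._fixed(self._state(Ga, Fv, R))
        path.append(st["ll"])
        converged = False
        n_em_warm = 3 if method == "ai" else max_iter
        it = 0
        while it < max_iter:
            it += 1
            theta_old = self._pack(Ga, Fv, R)
            if method == "ai" and it > n_em_warm:
                score, AI = self._score_and_ai(st)
                labels = self._param_layout()
                # parameters pinned at the boundary with an inward-pointing
                # gradient are excluded from the Newton update
                at_floor = np.array([
                    (lab[0] == "F" or lab[1] == lab[2])
                    and theta_old[i] <= 2.0 * self.floor.max() and score[i] < 0
                    for i, lab in enumerate(labels)
                ])
                free = ~at_floor
                ok = False
                try:
                    step = np.zeros_like(score)
                    sub = AI[np.ix_(free, free)]
                    sub = sub + 1e-10 * scale * np.eye(free.sum())
                    step[free] = np.linalg.solve(sub, score[free])
                    frac = 1.0
                    for _ in range(8):
                        cand = theta_old + frac * step
                        Ga_c, Fv_c, R_c = self._unpack(cand)
                        try:
                            Ga_c, Fv_c, R_c = self._floor_params(Ga_c, Fv_c, R_c)
                            st_c = self._fixed(self._state(Ga_c, Fv_c, R_c))
                        except LinAlgError:
                            frac *= 0.5
                            continue
                        if st_c["ll"] >= st["ll"] - 1e-10 * (1 + abs(st["ll"])):
                            Ga, Fv, R, st = Ga_c, Fv_c, R_c, st_c
                            ok = True
                            break
                        frac *= 0.5
                except LinAlgError:
                    ok = False
                if not ok:
                    Ga, Fv, R = self._em_step(st)
                    st = self._fixed(self._state(Ga, Fv, R))
            else:
                Ga, Fv, R = self._em_step(st)
                st = self._fixed(self._state(Ga, Fv, R))
            path.append(st["ll"])
            dll = abs(path[-1] - path[-2]) / (1.0 + abs(path[-1]))
            dtheta = np.max(np.abs(self._pack(Ga, Fv, R) - theta_old)) / scale
            if dll < tol and dtheta < np.sqrt(tol):
                converged = True
                break

        # final AI round(s): refine the EM solution and provide the
        # information matrix for standard errors
        if method == "em":
            for _ in range(ai_rounds):
                score, AI = self._score_and_ai(st)
                try:
                    step = np.linalg.solve(AI + 1e-12 * np.eye(len(score)) * scale, score)
                except LinAlgError:
                    break
                frac = 1.0
                for _ in range(6):
                    cand = self._pack(Ga, Fv, R) + frac * step
                    Ga_c, Fv_c, R_c = self._unpack(cand)
                    try:
                        Ga_c, Fv_c, R_c = self._floor_params(Ga_c, Fv_c, R_c)
                        st_c = self._fixed(self._state(Ga_c, Fv_c, R_c))
                    except LinAlgError:
                        frac *= 0.5
                        continue
                    if st_c["ll"] >= st["ll"] - 1e-10 * (1 + abs(st["ll"])):
                        Ga, Fv, R, st = Ga_c, Fv_c, R_c, st_c
                        path.append(st["ll"])
                        break
                    frac *= 0.5
        score, AI = self._score_and_ai(st)
        labels = self._param_layout()
        try:
            cov = np.linalg.inv(AI)
        except LinAlgError:
            cov = np.linalg.pinv(AI)
        se = {lab: float(np.sqrt(max(cov[i, i], 0.0))) for i, lab in enumerate(labels)}

        Cx = cho_solve(st["choX"], np.eye(self.T * self.p))
        Py = st["v"]
        if self.has_kernel:
            Py = self.U @ Py
        return REMLResult(
            G_a=Ga.copy() if self.has_kernel else None,
            R=R.copy(),
            factor_variances={k: val.copy() for k, val in Fv.items()},
            se=se,
            cov_params=cov,
            param_labels=labels,
            beta=st["beta"].copy(),
            cov_beta=Cx,
            loglik=float(st["ll"]),
            loglik_path=np.array(path),
            Py=Py,
            converged=converged,
            n_iter=it,
        )
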