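"""Penalized least-squares solvers for rare-variant effect estimation.

Four penalty families on the linear model, all solved on column-centered
data with an unpenalized intercept (``b0 = ybar - xbar' beta``):

* ``lasso``        : L1 selection, ``lam * sum |b_j|``.
* ``gflasso``      : L1 selection plus graph-fused grouping
  ``lam2 * sum_{j<j'} |b_j - r(j,j') b_j'|`` over the complete pair graph,
  with ``r`` either +1 or the sign of the inter-variant correlation.
* ``tlp_s``        : truncated-L1 selection ``lam1 * sum J_tau(|b_j|)`` with
  ``J_tau(x) = min(x / tau, 1)`` — coefficients beyond ``tau`` carry no
  shrinkage, approximating best-subset selection as ``tau -> 0+``.
* ``tlp_sg``       : TLP selection plus TLP grouping of the *absolute*
  coefficients, ``lam2 * sum_{j<j'} J_tau(||b_j| - |b_j'||)``, so variants
  may share an effect size while differing in direction.

Convex problems (lasso, DC surrogates with separable penalties) are solved
by cyclic coordinate descent; fused surrogates by ADMM with residual
balancing.  The non-convex TLP objectives use a difference-of-convex (DC)
outer loop: the concave part of the penalty is linearized at the current
iterate, giving a convex majorizer whose minimizer cannot increase the true
objective.  TLP-S runs the DC loop from two deterministic warm starts —
the convex surrogate Lasso(lam1/tau) and Lasso(lam1) — keeping the better
attained objective (the surrogate start alone collapses to zero at small
tau); TLP-SG starts at the TLP-S solution.  Convergence is to a local
minimizer.

Solvers natively handle batches of problems (shared or per-problem design
matrices); the public single-fit functions are thin wrappers over the
batched kernels, which the permutation engine reuses across permuted
traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "CoefEstimate",
    "tlp_value",
    "objective_value",
    "lasso_fit",
    "gflasso_fit",
    "tlp_s_fit",
    "tlp_sg_fit",
    "correlation_signs",
]

FAMILIES = ("lasso", "gflasso_r1", "gflasso_rcor", "tlp_s", "tlp_sg")


@dataclass
class PenaltySpec:
    """Penalty family plus its tuning parameters."""

    family: str
    lambda_: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    tau: float = 0.5
    r_signs: np.ndarray | None = None  # (k, k) in {-1, +1}; gflasso only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for name in ("lambda_", "lambda1", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.family in ("tlp_s", "tlp_sg") and self.tau <= 0:
            raise ValueError("tau must be > 0 for TLP families")


@dataclass
class CoefEstimate:
    """A fitted coefficient vector with its attained objective."""

    beta: np.ndarray
    intercept: float
    objective: float
    converged: bool = True
    iterations: int = 0


def tlp_value(x, tau: float):
    """Truncated L1 penalty J_tau(x) = min(x / tau, 1) for x >= 0."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("tlp_value expects non-negative arguments")
    out = np.minimum(x / tau, 1.0)
    return float(out) if out.ndim == 0 else out


def correlation_signs(X: np.ndarray) -> np.ndarray:
    """Sign of the pairwise column correlations; +1 where undefined."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    bad = sd == 0
    if bad.any():
        logger.debug("correlation_signs: %d zero-variance columns default to +1",
                     bad.sum())
    denom = np.where(bad, 1.0, sd)
    C = (Xc / denom).T @ (Xc / denom)
    R = np.where(C < 0, -1.0, 1.0)
    R[bad, :] = 1.0
    R[:, bad] = 1.0
    np.fill_diagonal(R, 1.0)
    return R


def _centered(geno, trait):
    X = geno.dosages if hasattr(geno, "dosages") else np.asarray(geno, dtype=float)
    y = np.asarray(trait, dtype=float)
    xbar = X.mean(axis=0)
    ybar = y.mean()
    return X - xbar, y - ybar, xbar, ybar


def _pair_index(k: int) -> tuple[np.ndarray, np.ndarray]:
    jj, jp = np.triu_indices(k, 1)
    return jj, jp


def _penalty_term(beta: np.ndarray, spec: PenaltySpec, X: np.ndarray | None) -> np.ndarray:
    """Penalty value per problem; beta has shape (R, k)."""
    beta = np.atleast_2d(beta)
    k = beta.shape[1]
    fam = spec.family
    if fam == "lasso":
        return spec.lambda_ * np.abs(beta).sum(axis=1)
    if fam == "tlp_s":
        return spec.lambda1 * tlp_value(np.abs(beta), spec.tau).sum(axis=1)
    jj, jp = _pair_index(k)
    if fam in ("gflasso_r1", "gflasso_rcor"):
        if fam == "gflasso_r1":
            r = np.ones(jj.size)
        else:
            R = spec.r_signs if spec.r_signs is not None else correlation_signs(X)
            r = R[jj, jp]
        pen = spec.lambda1 * np.abs(beta).sum(axis=1)
        pen = pen + spec.lambda2 * np.abs(beta[:, jj] - r * beta[:, jp]).sum(axis=1)
        return pen
    # tlp_sg
    pen = spec.lambda1 * tlp_value(np.abs(beta), spec.tau).sum(axis=1)
    diffs = np.abs(np.abs(beta[:, jj]) - np.abs(beta[:, jp]))
    pen = pen + spec.lambda2 * tlp_value(diffs, spec.tau).sum(axis=1)
    return pen


def objective_value(geno, trait, beta, spec: PenaltySpec) -> float:
    """Exact penalized objective on centered data (the solver oracle)."""
    Xc, yc, _, _ = _centered(geno, trait)
    beta = np.asarray(beta, dtype=float)
    resid = yc - Xc @ beta
    loss = 0.5 * float(resid @ resid)
    return loss + float(_penalty_term(beta[None, :], spec, Xc)[0])


def _soft(x: np.ndarray, thr) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


# ---------------------------------------------------------------------------
# batched coordinate descent for separable penalties  a_j|b_j| + q_j b_j
# ---------------------------------------------------------------------------

def _gram(X, Y):
    """Gram matrix G = X'X and correlation b = X'y per batch row."""
    Y = np.atleast_2d(Y)
    if X.ndim == 2:
        return X.T @ X, Y @ X
    return np.einsum("rnj,rnk->rjk", X, X), np.einsum("rnk,rn->rk", X, Y)


def _cd_solve(X, Y, a, q, beta0, tol: float = 1e-8, max_sweeps: int = 2000,
              gram=None):
    """Minimize 0.5||y - X b||^2 + sum_j a_j|b_j| + q_j b_j per batch row.

    ``X`` is (n, k) shared across the batch or (R, n, k); ``Y`` is (R, n);
    ``a``/``q``/``beta0`` broadcast to (R, k).  Works on the Gram matrices
    (precomputable via ``gram=(G, b)``), so a sweep costs O(k^2) per
    problem regardless of n.  Returns (beta, converged, sweeps).
    Zero-variance columns are frozen at their starting value.
    """
    Y = np.atleast_2d(Y)
    R = Y.shape[0]
    k = X.shape[-1]
    G, b = _gram(X, Y) if gram is None else gram
    sharedG = G.ndim == 2
    c = np.diagonal(G, axis1=-2, axis2=-1)  # (k,) or (R, k)
    c = np.broadcast_to(c, (R, k))
    ok = c > 0
    csafe = np.where(ok, c, 1.0)
    a = np.broadcast_to(np.asarray(a, dtype=float), (R, k))
    q = np.broadcast_to(np.asarray(q, dtype=float), (R, k))
    beta = np.array(np.broadcast_to(np.asarray(beta0, dtype=float), (R, k)))
    # gb[:, l] = sum_m G[l, m] beta[m], maintained incrementally
    gb = beta @ G.T if sharedG else np.einsum("rlm,rm->rl", G, beta)
    sweeps = 0
    dmax = 0.0
    for sweeps in range(1, max_sweeps + 1):
        dmax = 0.0
        for j in range(k):
            g = b[:, j] - gb[:, j] + c[:, j] * beta[:, j]
            num = _soft(g - q[:, j], a[:, j])
            bnew = np.where(ok[:, j], num / csafe[:, j], beta[:, j])
            d = bnew - beta[:, j]
            if np.any(d != 0.0):
                gb += (np.outer(d, G[j]) if sharedG
                       else G[:, :, j] * d[:, None])
                beta[:, j] = bnew
                dmax = max(dmax, float(np.abs(d).max()))
        if dmax < tol:
            break
    return beta, sweeps < max_sweeps or dmax < tol, sweeps


# ---------------------------------------------------------------------------
# batched ADMM for generalized-lasso surrogates  sum_m a_m|(D b)_m| + q' b
# ---------------------------------------------------------------------------

def _admm_solve(X, Y, D, a, q, beta0, rho: float = 1.0, tol: float = 1e-8,
                max_iter: int = 8000, check_every: int = 25,
                objective=None):
    """Minimize 0.5||y - X b||^2 + q'b + sum_m a_m |(D b)_m| per batch row.

    ``D`` is (m, k) shared or (R, m, k); ``a`` broadcasts to (R, m) and
    ``q`` to (R, k).  When an ``objective`` callable (beta -> (R,) values)
    is given, the best iterate visited at the check points is returned, so
    the reported solution never has a worse exact objective than the final
    ADMM iterate.
    """
    sharedX = X.ndim == 2
    sharedD = D.ndim == 2
    Y = np.atleast_2d(Y)
    R, n = Y.shape
    k = X.shape[-1]
    m = D.shape[-2]
    a = np.broadcast_to(np.asarray(a, dtype=float), (R, m))
    q = np.broadcast_to(np.asarray(q, dtype=float), (R, k))
    beta = np.array(np.broadcast_to(np.asarray(beta0, dtype=float), (R, k)))

    def factor(rho_):
        if sharedX:
            XtX = X.T @ X
        else:
            XtX = np.einsum("rnj,rnk->rjk", X, X)
        if sharedD:
            DtD = D.T @ D
        else:
            DtD = np.einsum("rmj,rmk->rjk", D, D)
        M = XtX + rho_ * DtD
        if M.ndim == 2:
            M = np.broadcast_to(M, (R, k, k))
        return np.linalg.inv(M + 1e-12 * np.eye(k))

    Minv = factor(rho)
    Xty = Y @ X if sharedX else np.einsum("rnk,rn->rk", X, Y)

    def Dmul(b):
        return b @ D.T if sharedD else np.einsum("rmk,rk->rm", D, b)

    def Dtmul(z):
        return z @ D if sharedD else np.einsum("rmk,rm->rk", D, z)

    z = Dmul(beta)
    u = np.zeros_like(z)
    best_beta, best_obj = None, None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rhs = Xty - q + rho * Dtmul(z - u)
        beta = np.einsum("rjk,rk->rj", Minv, rhs)
        Db = Dmul(beta)
        z_old = z
        z = _soft(Db + u, a / rho)
        u = u + Db - z
        if it % check_every == 0 or it == max_iter:
            primal = float(np.abs(Db - z).max(initial=0.0))
            dual = float(rho * np.abs(Dtmul(z - z_old)).max(initial=0.0))
            if objective is not None:
                # evaluate at the feasible-ish iterate
                obj = objective(beta)
                if best_obj is None:
                    best_obj, best_beta = obj, beta.copy()
                else:
                    better = obj < best_obj
                    if np.any(better):
                        best_beta[better] = beta[better]
                        best_obj = np.minimum(best_obj, obj)
            if primal < tol and dual < tol:
                converged = True
                break
            # residual balancing
            if primal > 10 * dual and rho < 1e6:
                rho *= 2.0
                u /= 2.0
                Minv = factor(rho)
            elif dual > 10 * primal and rho > 1e-6:
                rho /= 2.0
                u *= 2.0
                Minv = factor(rho)
    if objective is not None and best_beta is not None:
        obj = objective(beta)
        better = obj < best_obj
        best_beta[better] = beta[better]
        return best_beta, converged, it
    return beta, converged, it


# ---------------------------------------------------------------------------
# public single-problem fits
# ---------------------------------------------------------------------------

def _finish(beta: np.ndarray, xbar: np.ndarray, ybar: float, obj: float,
            converged: bool, iters: int) -> CoefEstimate:
    beta = np.asarray(beta, dtype=float).ravel()
    return CoefEstimate(beta=beta, intercept=float(ybar - xbar @ beta),
                        objective=float(obj), converged=bool(converged),
                        iterations=int(iters))


def lasso_fit(geno, trait, lambda_: float, tol: float = 1e-8,
              max_sweeps: int = 5000) -> CoefEstimate:
    """L1-penalized least squares by cyclic coordinate descent."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    Xc, yc, xbar, ybar = _centered(geno, trait)
    k = Xc.shape[1]
    if lambda_ == 0.0:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        beta = beta[None, :]
        conv, sweeps = True, 0
    else:
        beta, conv, sweeps = _cd_solve(Xc, yc[None, :], lambda_, 0.0,
                                       np.zeros((1, k)), tol, max_sweeps)
    if not conv:
        logger.warning("lasso_fit did not converge in %d sweeps", max_sweeps)
    spec = PenaltySpec("lasso", lambda_=lambda_)
    obj = 0.5 * float(np.sum((yc - Xc @ beta[0]) ** 2)) + \
        float(_penalty_term(beta, spec, Xc)[0])
    return _finish(beta[0], xbar, ybar, obj, conv, sweeps)


def _gflasso_D(k: int, r: np.ndarray) -> np.ndarray:
    jj, jp = _pair_index(k)
    m = jj.size
    D = np.zeros((k + m, k))
    D[:k, :] = np.eye(k)
    D[np.arange(k, k + m), jj] = 1.0
    D[np.arange(k, k + m), jp] = -r
    return D


def gflasso_fit(geno, trait, lambda1: float, lambda2: float,
                r_mode: str = "one", tol: float = 1e-8,
                max_iter: int = 8000) -> CoefEstimate:
    """Graph-fused Lasso over the complete pair graph, solved by ADMM."""
    if r_mode not in ("one", "cor"):
        raise ValueError("r_mode must be 'one' or 'cor'")
    Xc, yc, xbar, ybar = _centered(geno, trait)
    k = Xc.shape[1]
    family = "gflasso_r1" if r_mode == "one" else "gflasso_rcor"
    R = np.ones((k, k)) if r_mode == "one" else correlation_signs(Xc)
    spec = PenaltySpec(family, lambda1=lambda1, lambda2=lambda2, r_signs=R)
    jj, jp = _pair_index(k)
    D = _gflasso_D(k, R[jj, jp])
    a = np.concatenate([np.full(k, lambda1), np.full(jj.size, lambda2)])

    def obj(B):
        resid = yc[None, :] - B @ Xc.T
        return 0.5 * np.einsum("rn,rn->r", resid, resid) + _penalty_term(B, spec, Xc)

    beta, conv, iters = _admm_solve(Xc, yc[None, :], D, a, 0.0,
                                    np.zeros((1, k)), tol=tol,
                                    max_iter=max_iter, objective=obj)
    if not conv:
        logger.warning("gflasso_fit reached max_iter=%d", max_iter)
    return _finish(beta[0], xbar, ybar, obj(beta)[0], conv, iters)


def _tlp_s_batched(Xc, Yc, lambda1: float, tau: float, tol_outer: float = 1e-6,
                   tol_inner: float = 1e-8, max_outer: int = 100,
                   max_sweeps: int = 2000, beta0=None, gram=None):
    """DC loop for TLP-S on a batch; returns (beta, objective, converged, iters).

    Surrogate at iterate b^m: J_tau(|x|) = |x|/tau - h(x) with
    h(x) = max(|x| - tau, 0)/tau convex; linearizing h from below gives the
    weighted-lasso problem with a_j = lam1/tau and linear term
    q_j = -(lam1/tau) sign(b^m_j) I(|b^m_j| > tau) — large coefficients see
    no net shrinkage.  Majorization makes the true objective monotone.
    """
    Yc = np.atleast_2d(Yc)
    R = Yc.shape[0]
    k = Xc.shape[-1]
    spec = PenaltySpec("tlp_s", lambda1=lambda1, tau=tau)
    if gram is None:
        gram = _gram(Xc, Yc)

    def obj(B):
        if Xc.ndim == 2:
            resid = Yc - B @ Xc.T
        else:
            resid = Yc - np.einsum("rnk,rk->rn", Xc, B)
        return 0.5 * np.einsum("rn,rn->r", resid, resid) + _penalty_term(B, spec, None)

    def dc_loop(beta):
        beta = np.array(np.broadcast_to(np.asarray(beta, dtype=float), (R, k)))
        cur = obj(beta)
        conv = False
        it = 0
        for it in range(1, max_outer + 1):
            s = np.where(beta >= 0, 1.0, -1.0)
            q = -(lambda1 / tau) * s * (np.abs(beta) > tau)
            beta, _, _ = _cd_solve(Xc, Yc, lambda1 / tau, q, beta,
                                   tol_inner, max_sweeps, gram=gram)
            new = obj(beta)
            if float((cur - new).max(initial=0.0)) < tol_outer:
                cur = np.minimum(cur, new)
                conv = True
                break
            cur = np.minimum(cur, new)
        return beta, cur, conv, it

    if beta0 is not None:
        return dc_loop(beta0)
    # dual warm start: the convex surrogate Lasso(lam1/tau), and Lasso(lam1)
    # itself — at small tau the former collapses to the zero local minimum.
    starts = []
    for lam in {lambda1 / tau, lambda1}:
        w, _, _ = _cd_solve(Xc, Yc, lam, 0.0, np.zeros((R, k)),
                            tol_inner, max_sweeps, gram=gram)
        starts.append(dc_loop(w))
    beta, cur, conv, it = starts[0]
    for beta2, cur2, conv2, it2 in starts[1:]:
        better = cur2 < cur
        beta = np.where(better[:, None], beta2, beta)
        cur = np.minimum(cur, cur2)
        conv = conv and conv2
        it = max(it, it2)
    return beta, cur, conv, it


def tlp_s_fit(geno, trait, lambda1: float, tau: float,
              tol: float = 1e-6) -> CoefEstimate:
    """Truncated-L1 selection fit via DC iterations from a Lasso warm start."""
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    Xc, yc, xbar, ybar = _centered(geno, trait)
    beta, objv, conv, iters = _tlp_s_batched(Xc, yc[None, :], lambda1, tau,
                                             tol_outer=tol)
    if not conv:
        logger.warning("tlp_s_fit: DC loop hit max iterations")
    return _finish(beta[0], xbar, ybar, objv[0], conv, iters)


def _tlp_sg_batched(Xc, Yc, lambda1: float, lambda2: float, tau: float,
                    tol_outer: float = 1e-6, tol_inner: float = 1e-7,
                    max_outer: int = 50, max_admm: int = 4000, beta0=None):
    """DC loop for TLP-SG on a batch with an accept-if-better safeguard.

    At iterate b^m the signs s_j = sign(b^m_j) linearize |b_j| ~ s_j b_j, and
    the concave parts of both TLP terms are linearized, leaving a
    generalized-lasso surrogate solved by ADMM.  Because the sign
    linearization is only local, each candidate is accepted per problem only
    if it lowers the exact objective; the warm start is never worsened.
    """
    Yc = np.atleast_2d(Yc)
    R = Yc.shape[0]
    k = Xc.shape[-1]
    spec = PenaltySpec("tlp_sg", lambda1=lambda1, lambda2=lambda2, tau=tau)
    jj, jp = _pair_index(k)
    m = jj.size

    def obj(B):
        if Xc.ndim == 2:
            resid = Yc - B @ Xc.T
        else:
            resid = Yc - np.einsum("rnk,rk->rn", Xc, B)
        return 0.5 * np.einsum("rn,rn->r", resid, resid) + _penalty_term(B, spec, None)

    if beta0 is None:
        beta0, _, _, _ = _tlp_s_batched(Xc, Yc, lambda1, tau)
    beta = np.array(np.broadcast_to(np.asarray(beta0, dtype=float), (R, k)))
    cur = obj(beta)
    a = np.concatenate([np.full(k, lambda1 / tau), np.full(m, lambda2 / tau)])
    conv = False
    it = 0
    for it in range(1, max_outer + 1):
        s = np.where(beta >= 0, 1.0, -1.0)  # (R, k)
        D = np.zeros((R, k + m, k))
        D[:, :k, :] = np.eye(k)
        rr = np.arange(R)[:, None]
        D[rr, k + np.arange(m)[None, :], jj[None, :]] = s[:, jj]
        D[rr, k + np.arange(m)[None, :], jp[None, :]] = -s[:, jp]
        q = -(lambda1 / tau) * s * (np.abs(beta) > tau)  # selection part
        dm = np.abs(beta[:, jj]) - np.abs(beta[:, jp])  # (R, m)
        w = -(lambda2 / tau) * np.sign(dm) * (np.abs(dm) > tau)
        # fold pair linear terms into q: w_p * (s_j e_j - s_j' e_j')
        for col, sign_ in ((jj, 1.0), (jp, -1.0)):
            contrib = np.zeros_like(q)
            np.add.at(contrib, (rr.repeat(m, 1), np.broadcast_to(col, (R, m))),
                      sign_ * w * s[:, col])
            q += contrib
        cand, _, _ = _admm_solve(Xc, Yc, D, a, q, beta, tol=tol_inner,
                                 max_iter=max_admm, objective=obj)
        new = obj(cand)
        better = new < cur - 1e-12
        improved = float((cur - new)[better].max(initial=0.0))
        beta[better] = cand[better]
        cur = np.minimum(cur, new)
        if improved < tol_outer:
            conv = True
            break
    return beta, cur, conv, it


def tlp_sg_fit(geno, trait, lambda1: float, lambda2: float, tau: float,
               tol: float = 1e-6) -> CoefEstimate:
    """TLP selection-plus-grouping fit (DC outer loop, ADMM inner solver)."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda parameters must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    Xc, yc, xbar, ybar = _centered(geno, trait)
    beta, objv, conv, iters = _tlp_sg_batched(Xc, yc[None, :], lambda1,
                                              lambda2, tau, tol_outer=tol)
    if not conv:
        logger.warning("tlp_sg_fit: DC loop hit max iterations")
    return _finish(beta[0], xbar, ybar, objv[0], conv, iters)
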