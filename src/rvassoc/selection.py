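"""AIC-based tuning-parameter selection for the penalized fits.

The tuning parameters are chosen by exhaustive grid search minimizing

    AIC = -2 log L + 2 p,   log L = (-n log(s^2) - n - p - 1) / 2,
    s^2 = sum_i (Y_i - b0 - X_i b)^2 / (n - p - 1),

where the effective parameter count ``p`` depends on the penalty family:
the number of non-zero coefficients for Lasso and TLP-S, the number of
non-zero *unique* coefficients for gflasso with r = 1, and the number of
non-zero unique *absolute* coefficients for gflasso with r = cor and
TLP-SG (fused groups count once).  "Non-zero" means ``|b_j| > 1e-3``
(the same threshold used for post-selection testing) and "unique" means
distinct beyond an absolute tolerance of 1e-4; both are configurable.

Default grids: 50 equally spaced lambda values on [0.001, 10] for the
Lasso; five equally spaced points on [0.001, 1] for lambda1, [0.001, 0.5]
for lambda2 and [0.001, 0.5] for tau elsewhere.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .penalties import (CoefEstimate, PenaltySpec, _admm_solve, _cd_solve,
                        _gflasso_D, _gram, _pair_index, _penalty_term,
                        _tlp_s_batched, _tlp_sg_batched, correlation_signs)

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "ModelSelectionRecord",
    "default_grid",
    "effective_params",
    "aic",
    "grid_search",
]

ZERO_TOL = 1e-3  # |beta| above this counts as selected
UNIQUE_TOL = 1e-4  # values closer than this are one fused group


@dataclass
class GridSpec:
    """Per-parameter grids; iterated in lexicographic parameter order."""

    grids: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, vals in self.grids.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size == 0:
                raise ValueError(f"empty grid for {name}")
            if np.any(vals < 0):
                raise ValueError(f"negative grid value for {name}")
            self.grids[name] = vals

    def points(self):
        names = list(self.grids)
        for combo in itertools.product(*(self.grids[n] for n in names)):
            yield dict(zip(names, combo))

    def __len__(self) -> int:
        out = 1
        for v in self.grids.values():
            out *= len(v)
        return out


@dataclass
class ModelSelectionRecord:
    params: dict
    p_eff: int
    sigma_sq_hat: float
    log_lik: float
    aic: float


def default_grid(family: str) -> GridSpec:
    lam1 = np.linspace(0.001, 1.0, 5)
    lam2 = np.linspace(0.001, 0.5, 5)
    tau = np.linspace(0.001, 0.5, 5)
    if family == "lasso":
        return GridSpec({"lambda_": np.linspace(0.001, 10.0, 50)})
    if family in ("gflasso_r1", "gflasso_rcor"):
        return GridSpec({"lambda1": lam1, "lambda2": lam2})
    if family == "tlp_s":
        return GridSpec({"lambda1": lam1, "tau": tau})
    if family == "tlp_sg":
        return GridSpec({"lambda1": lam1, "lambda2": lam2, "tau": tau})
    raise ValueError(f"no default grid for family {family!r}")


def _count_unique(vals: np.ndarray, tol: float) -> int:
    if vals.size == 0:
        return 0
    v = np.sort(vals)
    return 1 + int(np.sum(np.diff(v) > tol))


def effective_params(beta, family: str, zero_tol: float = ZERO_TOL,
                     unique_tol: float = UNIQUE_TOL) -> int:
    """Effective number of parameters of a fitted coefficient vector."""
    b = beta.beta if isinstance(beta, CoefEstimate) else np.asarray(beta, dtype=float)
    nz = b[np.abs(b) > zero_tol]
    if family in ("lasso", "tlp_s", "ols"):
        return int(nz.size)
    if family == "gflasso_r1":
        return _count_unique(nz, unique_tol)
    if family in ("gflasso_rcor", "tlp_sg"):
        return _count_unique(np.abs(nz), unique_tol)
    raise ValueError(f"unknown family {family!r}")


def _aic_terms(n: int, rss: np.ndarray, p: np.ndarray):
    """Vectorized AIC pieces; +inf where the residual df is exhausted."""
    dof = n - p - 1
    ok = dof >= 1
    sigma = np.where(ok, rss / np.where(ok, dof, 1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = (-n * np.log(np.maximum(sigma, 1e-300)) - n - p - 1) / 2.0
    aic_ = np.where(ok, -2.0 * loglik + 2.0 * p, np.inf)
    return sigma, loglik, aic_


def aic(geno, trait, est: CoefEstimate, family: str,
        zero_tol: float = ZERO_TOL, unique_tol: float = UNIQUE_TOL,
        params: dict | None = None) -> ModelSelectionRecord:
    """Evaluate the AIC of a fitted estimate on its data."""
    X = geno.dosages if hasattr(geno, "dosages") else np.asarray(geno, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = X.shape[0]
    resid = y - est.intercept - X @ est.beta
    rss = float(resid @ resid)
    p = effective_params(est, family, zero_tol, unique_tol)
    sigma, loglik, aic_ = _aic_terms(n, np.array([rss]), np.array([p]))
    return ModelSelectionRecord(params=dict(params or {}), p_eff=int(p),
                                sigma_sq_hat=float(sigma[0]),
                                log_lik=float(loglik[0]), aic=float(aic_[0]))


# ---------------------------------------------------------------------------
# batched grid search (shared by the public API and the permutation engine)
# ---------------------------------------------------------------------------

def _fit_grid_point(Xc, Yc, family, params, beta_init, fast: bool, gram=None):
    """One batched penalized fit on centered data; returns beta (R, k)."""
    R = Yc.shape[0]
    k = Xc.shape[-1]
    tol_in = 1e-6 if fast else 1e-8
    if family == "lasso":
        beta, _, _ = _cd_solve(Xc, Yc, params["lambda_"], 0.0, beta_init,
                               tol=tol_in, max_sweeps=2000, gram=gram)
        return beta
    if family in ("gflasso_r1", "gflasso_rcor"):
        lam1, lam2 = params["lambda1"], params["lambda2"]
        if Xc.ndim == 2:
            Rsign = np.ones((k, k)) if family == "gflasso_r1" else correlation_signs(Xc)
            jj, jp = _pair_index(k)
            D = _gflasso_D(k, Rsign[jj, jp])
        else:
            jj, jp = _pair_index(k)
            Ds = []
            for r in range(Xc.shape[0]):
                Rsign = (np.ones((k, k)) if family == "gflasso_r1"
                         else correlation_signs(Xc[r]))
                Ds.append(_gflasso_D(k, Rsign[jj, jp]))
            D = np.stack(Ds)
        m = jj.size
        a = np.concatenate([np.full(k, lam1), np.full(m, lam2)])
        beta, _, _ = _admm_solve(Xc, Yc, D, a, 0.0, beta_init,
                                 tol=1e-6 if fast else 1e-8,
                                 max_iter=1500 if fast else 8000)
        return beta
    if family == "tlp_s":
        beta, _, _, _ = _tlp_s_batched(Xc, Yc, params["lambda1"], params["tau"],
                                       tol_inner=tol_in,
                                       max_sweeps=600 if fast else 2000,
                                       gram=gram)
        return beta
    if family == "tlp_sg":
        beta, _, _, _ = _tlp_sg_batched(Xc, Yc, params["lambda1"],
                                        params["lambda2"], params["tau"],
                                        tol_inner=1e-5 if fast else 1e-7,
                                        max_admm=800 if fast else 4000,
                                        beta0=beta_init)
        return beta
    raise ValueError(f"unknown family {family!r}")


def grid_search_batched(X, Y, family: str, grid: GridSpec | None = None,
                        zero_tol: float = ZERO_TOL, unique_tol: float = UNIQUE_TOL,
                        fast: bool = False, collect_audit: bool = False):
    """AIC grid search over a batch of problems sharing the grid.

    ``X`` is (n, k) shared or (R, n, k); ``Y`` is (R, n).  Returns a dict
    with best ``beta`` (R, k), ``aic`` (R,), ``p_eff`` (R,), ``params``
    (list of R dicts) and optionally the full audit of candidate AICs.
    """
    grid = grid or default_grid(family)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    R, n = Y.shape
    k = X.shape[-1]
    Xc = X - X.mean(axis=-2, keepdims=True)
    if X.ndim == 2:
        Xc = Xc.reshape(n, k)
    Yc = Y - Y.mean(axis=1, keepdims=True)

    best_aic = np.full(R, np.inf)
    best_beta = np.zeros((R, k))
    best_p = np.zeros(R, dtype=int)
    best_params = [dict() for _ in range(R)]
    audit = []
    beta_warm = np.zeros((R, k))
    convex = family in ("lasso", "gflasso_r1", "gflasso_rcor")
    gram = _gram(Xc, Yc) if family in ("lasso", "tlp_s", "tlp_sg") else None
    warm_cache: dict[tuple, np.ndarray] = {}
    for params in grid.points():
        if family == "tlp_sg":
            # TLP-S warm start depends only on (lambda1, tau); cache it
            key = (params["lambda1"], params["tau"])
            if key not in warm_cache:
                warm_cache[key], _, _, _ = _tlp_s_batched(
                    Xc, Yc, key[0], key[1], tol_inner=1e-6 if fast else 1e-8,
                    max_sweeps=600 if fast else 2000, gram=gram)
            init = warm_cache[key]
        else:
            init = beta_warm if convex else np.zeros((R, k))
        beta = _fit_grid_point(Xc, Yc, family, params, init, fast, gram=gram)
        if convex:
            beta_warm = beta
        if Xc.ndim == 2:
            resid = Yc - beta @ Xc.T
        else:
            resid = Yc - np.einsum("rnk,rk->rn", Xc, beta)
        rss = np.einsum("rn,rn->r", resid, resid)
        p = np.array([effective_params(beta[r], family, zero_tol, unique_tol)
                      for r in range(R)])
        _, _, aic_ = _aic_terms(n, rss, p)
        if collect_audit:
            audit.append((dict(params), aic_.copy()))
        better = aic_ < best_aic  # strict: lexicographically first wins ties
        if np.any(better):
            best_aic[better] = aic_[better]
            best_beta[better] = beta[better]
            best_p[better] = p[better]
            for r in np.nonzero(better)[0]:
                best_params[r] = dict(params)
    bad = ~np.isfinite(best_aic)
    if np.any(bad):
        logger.warning("grid_search: all candidates degenerate for %d problems; "
                       "returning the null fit", int(bad.sum()))
        best_beta[bad] = 0.0
    out = {"beta": best_beta, "aic": best_aic, "p_eff": best_p,
           "params": best_params}
    if collect_audit:
        out["audit"] = audit
    return out


def grid_search(geno, trait, family: str, grid: GridSpec | None = None,
                zero_tol: float = ZERO_TOL, unique_tol: float = UNIQUE_TOL):
    """Fit every grid point and return the minimal-AIC candidate.

    Returns ``(params, CoefEstimate, ModelSelectionRecord)``; ties are
    broken toward the lexicographically smallest parameter tuple.
    """
    X = geno.dosages if hasattr(geno, "dosages") else np.asarray(geno, dtype=float)
    y = np.asarray(trait, dtype=float)
    res = grid_search_batched(X, y[None, :], family, grid,
                              zero_tol, unique_tol, fast=False)
    beta = res["beta"][0]
    params = res["params"][0]
    xbar, ybar = X.mean(axis=0), y.mean()
    spec_kwargs = dict(params)
    if family == "lasso":
        spec = PenaltySpec("lasso", lambda_=spec_kwargs["lambda_"])
    elif family in ("gflasso_r1", "gflasso_rcor"):
        spec = PenaltySpec(family, lambda1=spec_kwargs.get("lambda1", 0.0),
                           lambda2=spec_kwargs.get("lambda2", 0.0))
    else:
        spec = PenaltySpec(family, lambda1=spec_kwargs.get("lambda1", 0.0),
                           lambda2=spec_kwargs.get("lambda2", 0.0),
                           tau=spec_kwargs.get("tau", 0.5))
    Xc = X - xbar
    yc = y - ybar
    obj = 0.5 * float(np.sum((yc - Xc @ beta) ** 2)) + \
        float(_penalty_term(beta[None, :], spec, Xc)[0])
    est = CoefEstimate(beta=beta, intercept=float(ybar - xbar @ beta),
                       objective=obj, converged=True, iterations=0)
    record = aic(X, y, est, family, zero_tol, unique_tol, params=params)
    return params, est, record
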