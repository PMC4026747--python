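"""Global association tests for a quantitative trait against a variant group.

All tests target the linear model ``Y_i = b0 + sum_j X_ij b_j + e_i`` with
``e_i ~ N(0, s^2)`` and the global null ``H0: b = 0``.  Five of them are
built on the null score vector and its covariance,

    U = sum_i (Y_i - Ybar) X_i,
    V = Cov(U | H0) = s0^2 * sum_i (X_i - Xbar)(X_i - Xbar)',

with ``s0^2`` the null variance estimate.  The F-test fits the full model;
the Sum (burden) test pools all variants into one covariate; the adaptive
Sum (aSum) test first flips variants with nominally significant negative
marginal effects and is calibrated by permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreComponents",
    "TestResult",
    "AsumCoding",
    "compute_score_components",
    "score_test",
    "ssu_test",
    "ssuw_test",
    "uminp_test",
    "f_test",
    "sum_test",
    "asum_coding",
    "asum_test",
    "mixture_chisq_pvalue",
]

_EIG_RTOL = 1e-10  # relative eigenvalue cutoff for singular V
_MVN_SEED = 20140513  # fixed sub-seed for the UminP rectangle integral


@dataclass
class ScoreComponents:
    """Score vector, its null covariance and the null variance estimate."""

    U: np.ndarray
    V: np.ndarray
    sigma0_sq: float
    n: int
    degenerate: bool = False  # constant trait

    @property
    def diag_V(self) -> np.ndarray:
        return np.diag(self.V)


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df_or_weights: object = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class AsumCoding:
    """Per-variant recoding decision for the adaptive Sum test."""

    flip_mask: np.ndarray
    marginal_beta: np.ndarray
    marginal_p: np.ndarray
    alpha0: float = 0.1

    def recode(self, X: np.ndarray) -> np.ndarray:
        Xs = X.copy()
        Xs[:, self.flip_mask] = 2.0 - Xs[:, self.flip_mask]
        return Xs


def _as_matrix(geno) -> np.ndarray:
    return geno.dosages if hasattr(geno, "dosages") else np.asarray(geno, dtype=float)


def compute_score_components(geno, trait) -> ScoreComponents:
    """Score vector U, covariance V and null variance for the group test."""
    X = _as_matrix(geno)
    y = np.asarray(trait, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("trait length does not match genotype rows")
    if k == 0:
        raise ValueError("no variants")
    yc = y - y.mean()
    sigma0_sq = float(yc @ yc) / (n - 1)
    Xc = X - X.mean(axis=0)
    U = Xc.T @ yc
    V = sigma0_sq * (Xc.T @ Xc)
    return ScoreComponents(U=U, V=V, sigma0_sq=sigma0_sq, n=n,
                           degenerate=sigma0_sq == 0.0)


def _positive_eigs(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, Q = np.linalg.eigh((M + M.T) / 2.0)
    cut = _EIG_RTOL * max(w.max(initial=0.0), 0.0)
    keep = w > cut
    return w[keep], Q[:, keep]


def score_test(sc: ScoreComponents) -> TestResult:
    """T = U' V^- U with a chi-squared null on df = rank(V)."""
    w, Q = _positive_eigs(sc.V)
    if w.size == 0:
        return TestResult("Score", 0.0, 1.0, 0, degenerate=True)
    proj = Q.T @ sc.U
    stat = float(np.sum(proj**2 / w))
    df = int(w.size)
    return TestResult("Score", stat, float(stats.chi2.sf(stat, df)), df)


def ssu_test(sc: ScoreComponents) -> TestResult:
    """T = U'U; the null is a mixture of chi-squared(1) with weights eig(V)."""
    w, _ = _positive_eigs(sc.V)
    if w.size == 0:
        return TestResult("SSU", 0.0, 1.0, [], degenerate=True)
    stat = float(sc.U @ sc.U)
    return TestResult("SSU", stat, mixture_chisq_pvalue(w, stat), w)


def ssuw_test(sc: ScoreComponents) -> TestResult:
    """T = U' diag(V)^-1 U; mixture weights from the scaled covariance."""
    d = sc.diag_V
    keep = d > 0
    if not keep.any():
        return TestResult("SSUw", 0.0, 1.0, [], degenerate=True)
    if not keep.all():
        logger.debug("SSUw: dropping %d zero-variance variants", (~keep).sum())
    U = sc.U[keep]
    Vs = sc.V[np.ix_(keep, keep)]
    dhalf = 1.0 / np.sqrt(d[keep])
    C = Vs * np.outer(dhalf, dhalf)
    stat = float(np.sum(U**2 / d[keep]))
    w, _ = _positive_eigs(C)
    if w.size == 0:
        return TestResult("SSUw", stat, 1.0, [], degenerate=True)
    return TestResult("SSUw", stat, mixture_chisq_pvalue(w, stat), w)


def _mvn_rectangle(C: np.ndarray, c: float) -> float:
    """Pr(|Z_j| <= c for all j) for Z ~ MVN(0, C), C a correlation matrix."""
    k = C.shape[0]
    if k == 1:
        return float(stats.chi2.cdf(c * c, 1))
    # guard against tiny negative eigenvalues from rounding
    w, Q = np.linalg.eigh((C + C.T) / 2.0)
    C = (Q * np.maximum(w, 1e-12)) @ Q.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    frozen = stats.multivariate_normal(mean=np.zeros(k), cov=C, seed=_MVN_SEED,
                                       allow_singular=True,
                                       maxpts=1_000_000 * k, abseps=1e-5)
    val = float(frozen.cdf(np.full(k, c), lower_limit=np.full(k, -c)))
    return min(max(val, 0.0), 1.0)


def uminp_test(sc: ScoreComponents) -> TestResult:
    """T = max_j U_j^2 / v_j; p via a multivariate-normal rectangle probability.

    Perfectly (anti)correlated duplicate variants are collapsed before the
    numerical integration — the event {|Z_j| <= c} is identical for them.
    """
    d = sc.diag_V
    keep = d > 0
    if not keep.any():
        return TestResult("UminP", 0.0, 1.0, None, degenerate=True)
    if not keep.all():
        logger.debug("UminP: dropping %d zero-variance variants", (~keep).sum())
    U = sc.U[keep]
    v = d[keep]
    stat = float(np.max(U**2 / v))
    Vs = sc.V[np.ix_(keep, keep)]
    dhalf = 1.0 / np.sqrt(v)
    C = Vs * np.outer(dhalf, dhalf)
    # collapse |corr| ~ 1 duplicates
    reps: list[int] = []
    for j in range(C.shape[0]):
        if not any(abs(C[j, i]) >= 1.0 - 1e-8 for i in reps):
            reps.append(j)
    Cr = C[np.ix_(reps, reps)]
    p = 1.0 - _mvn_rectangle(Cr, np.sqrt(stat))
    return TestResult("UminP", stat, min(max(p, 0.0), 1.0), Cr)


def f_test(geno, trait) -> TestResult:
    """Overall F-test of H0: b = 0 in the full linear model."""
    X = _as_matrix(geno)
    y = np.asarray(trait, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    df1 = int(np.linalg.matrix_rank(Xc))
    if df1 == 0:
        return TestResult("F", 0.0, 1.0, (0, n - 1), degenerate=True)
    df2 = n - df1 - 1
    if df2 <= 0:
        raise ValueError("saturated fit: no residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    rss1 = float(resid @ resid)
    if rss1 <= 1e-12 * max(rss0, 1.0):
        return TestResult("F", np.inf, 0.0, (df1, df2), degenerate=True)
    fstat = ((rss0 - rss1) / df1) / (rss1 / df2)
    fstat = max(fstat, 0.0)
    return TestResult("F", float(fstat), float(stats.f.sf(fstat, df1, df2)), (df1, df2))


def sum_test(geno, trait) -> TestResult:
    """Burden test: regress Y on the genotype row sum, test the common slope."""
    X = _as_matrix(geno)
    y = np.asarray(trait, dtype=float)
    n = X.shape[0]
    s = X.sum(axis=1)
    sc_ = s - s.mean()
    sss = float(sc_ @ sc_)
    if sss <= 0:
        return TestResult("Sum", 0.0, 1.0, n - 2, degenerate=True)
    yc = y - y.mean()
    syy = float(yc @ yc)
    ssy = float(sc_ @ yc)
    b = ssy / sss
    rss = max(syy - ssy**2 / sss, 0.0)
    if rss <= 1e-12 * max(syy, 1.0):
        return TestResult("Sum", np.inf, 0.0, n - 2, degenerate=True)
    se = np.sqrt(rss / (n - 2) / sss)
    t = b / se
    return TestResult("Sum", float(t), float(2 * stats.t.sf(abs(t), n - 2)), n - 2)


def _marginal_stats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Marginal simple-regression slopes and two-sided p-values.

    ``Y`` has shape (B, n) — one row per (permuted) trait; returns (B, k)
    slope and p-value arrays.  Monomorphic columns get slope 0, p 1.
    """
    n, k = X.shape
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("nk,nk->k", Xc, Xc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("bn,bn->b", Yc, Yc)
    sxy = Yc @ Xc  # (B, k)
    ok = sxx > 0
    beta = np.zeros_like(sxy)
    beta[:, ok] = sxy[:, ok] / sxx[ok]
    rss = np.maximum(syy[:, None] - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / np.where(ok, sxx, np.nan))
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.ones_like(beta)
    finite = np.isfinite(t) & ok
    p[finite] = 2 * stats.t.sf(np.abs(t[finite]), n - 2)
    p[~ok[None, :].repeat(Y.shape[0], axis=0)] = 1.0
    p[ok[None, :].repeat(Y.shape[0], axis=0) & ~np.isfinite(t)] = 0.0
    return beta, p


def _asum_lrt(X: np.ndarray, Y: np.ndarray, alpha0: float) -> np.ndarray:
    """Vectorized aSum log-likelihood-ratio statistic for each trait row."""
    n = X.shape[0]
    beta, p = _marginal_stats(X, Y)
    flip = (beta < 0) & (p <= alpha0)  # (B, k)
    s = X.sum(axis=1)  # (n,)
    # recoded row sum: flip variant j contributes 2 - X_.j instead of X_.j
    sstar = s[None, :] + 2.0 * flip.sum(axis=1, keepdims=True) - 2.0 * (flip @ X.T)
    sc_ = sstar - sstar.mean(axis=1, keepdims=True)
    sss = np.einsum("bn,bn->b", sc_, sc_)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("bn,bn->b", Yc, Yc)
    ssy = np.einsum("bn,bn->b", sc_, Yc)
    ok = (sss > 0) & (syy > 0)
    rss = np.where(ok, np.maximum(syy - np.where(ok, ssy**2 / np.where(ok, sss, 1.0), 0.0), 1e-300), syy)
    T = np.zeros(Y.shape[0])
    T[ok] = n * np.log(syy[ok] / rss[ok])
    return T


def asum_coding(geno, trait, alpha0: float = 0.1) -> AsumCoding:
    """Marginal fits and the flip decision of the adaptive Sum test."""
    X = _as_matrix(geno)
    y = np.asarray(trait, dtype=float)
    beta, p = _marginal_stats(X, y[None, :])
    flip = (beta[0] < 0) & (p[0] <= alpha0)
    return AsumCoding(flip_mask=flip, marginal_beta=beta[0], marginal_p=p[0], alpha0=alpha0)


def asum_test(geno, trait, alpha0: float = 0.1, B: int = 100,
              seed: int | np.random.Generator = 0) -> TestResult:
    """Adaptive Sum test with a permutation-calibrated LRT.

    The whole procedure — marginal fits, coding flips, burden LRT — is
    recomputed on each of ``B`` permutations of the trait; the p-value is
    the strict-inequality permutation fraction ``sum_b I(T < T0_b) / B``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = _as_matrix(geno)
    y = np.asarray(trait, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(B)])
    T = float(_asum_lrt(X, y[None, :], alpha0)[0])
    T0 = _asum_lrt(X, perms, alpha0)
    p = float(np.mean(T < T0))
    return TestResult("aSum", T, p, B)


def _imhof_integrand(u: np.ndarray, w: np.ndarray, t: float) -> np.ndarray:
    theta = 0.5 * np.sum(np.arctan(np.outer(w, u)), axis=0) - 0.5 * t * u
    lrho = 0.25 * np.sum(np.log1p(np.outer(w**2, u**2)), axis=0)
    return np.sin(theta) / (u * np.exp(lrho))


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _imhof_integral(w: np.ndarray, t: float) -> float:
    """Integral of the inversion integrand on (0, inf) by panelled quadrature.

    Panel width tracks the oscillation frequency (the integrand phase slope
    is about -t/2 for large u); panels are summed until their contribution
    is negligible.
    """
    freq = 0.5 * (t + w.sum())
    width = max(min(4.0, 2.0 * np.pi / max(freq, 1e-3)), 1e-3) * 4.0
    block = 64
    total = 0.0
    lo = 0.0
    for _ in range(60):  # up to 3840 panels
        starts = lo + width * np.arange(block)
        u = (starts[:, None] + 0.5 * width * (_GL_NODES + 1.0)[None, :]).ravel()
        vals = _imhof_integrand(u, w, t).reshape(block, -1)
        parts = 0.5 * width * (vals @ _GL_WEIGHTS)
        small = np.abs(parts) < 1e-11
        run = 0
        stop = None
        for i, s in enumerate(small):
            run = run + 1 if s else 0
            if run >= 2:
                stop = i + 1
                break
        if stop is not None:
            total += float(parts[:stop].sum())
            return total
        total += float(parts.sum())
        lo += width * block
    return total


def _satterthwaite_pvalue(w: np.ndarray, t: float) -> float:
    mu, var = w.sum(), 2.0 * np.sum(w**2)
    scale = var / (2.0 * mu)
    df = 2.0 * mu**2 / var
    return float(stats.chi2.sf(t / scale, df))


def mixture_chisq_pvalue(weights, t: float) -> float:
    """Upper-tail probability of a weighted sum of chi-squared(1) variables.

    ``Pr(sum_j w_j chi2_1j >= t)`` by Imhof's characteristic-function
    inversion (numerical quadrature), falling back to Satterthwaite
    moment matching when the quadrature misbehaves.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < -1e-8 * max(abs(w).max(initial=0.0), 1.0)):
        raise ValueError("negative mixture weight")
    w = w[w > 0]
    if w.size == 0:
        return 1.0
    if t <= 0:
        return 1.0
    scale = w.max()
    w = w / scale
    t = t / scale
    if w.size == 1:
        return float(stats.chi2.sf(t / w[0], 1))
    try:
        p = 0.5 + _imhof_integral(w, t) / np.pi
        if not np.isfinite(p) or p < -1e-4 or p > 1 + 1e-4:
            raise FloatingPointError
    except Exception:
        return _satterthwaite_pvalue(w, t)
    return min(max(p, 0.0), 1.0)
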