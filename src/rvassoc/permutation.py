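"""Permutation-calibrated association tests built on penalized fits.

The null distribution of a statistic computed from a penalized estimate is
intractable, so the whole pipeline is calibrated by permuting the trait:

1. grid-search the tuning parameters by AIC on the observed data and fit;
2. compute the test statistic T from the fitted coefficients;
3. for each of B permutations of Y, repeat steps 1-2 *including the
   per-permutation grid search*, giving null statistics T0(b);
4. p = sum_b I(T < T0(b)) / B  (strict inequality, no +1 correction, so
   p = 0 is attainable at finite B; an optional (sum+1)/(B+1) mode is
   provided for users needing strictly valid p-values).

Statistics: a 1-df F statistic from regressing Y on the fitted linear
predictor Z = X beta-hat (any family), and post-selection SSU / SSUw
statistics restricted to variants with |beta-hat_j| > 0.001 (used with
TLP-SG in the source method; available for other families behind a flag).
The ``ols`` family (unpenalized least-squares fit, no grid) is provided to
cross-check the permutation machinery against the asymptotic tests.

All B+1 problems share the design matrix, so the grid search runs as one
batched solve across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .penalties import CoefEstimate
from .selection import GridSpec, ZERO_TOL, grid_search_batched
from .scoretests import compute_score_components

__all__ = [
    "PermutationResult",
    "one_df_statistic",
    "selected_score_statistic",
    "permutation_test",
]

STATISTICS = ("one_df", "ssu", "ssuw")


@dataclass
class PermutationResult:
    """Observed statistic, permutation nulls and the resulting p-value."""

    method: str
    statistic_kind: str
    observed_T: float
    null_T: np.ndarray
    B: int
    p_value: float
    params: dict = field(default_factory=dict)
    per_perm_params: list | None = None


def _one_df_f(Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Batched 1-df F statistic of Y on Z (rows paired); 0 if Z constant."""
    Zc = Z - Z.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    szz = np.einsum("bn,bn->b", Zc, Zc)
    syy = np.einsum("bn,bn->b", Yc, Yc)
    szy = np.einsum("bn,bn->b", Zc, Yc)
    n = Z.shape[1]
    ok = szz > 0
    expl = np.where(ok, szy**2 / np.where(ok, szz, 1.0), 0.0)
    rss = np.maximum(syy - expl, 1e-300)
    F = np.where(ok, expl / (rss / (n - 2)), 0.0)
    return F


def one_df_statistic(geno, trait, est: CoefEstimate) -> float:
    """F statistic (1, n-2 df) from regressing Y on Z = X beta-hat."""
    X = geno.dosages if hasattr(geno, "dosages") else np.asarray(geno, dtype=float)
    y = np.asarray(trait, dtype=float)
    Z = X @ est.beta
    return float(_one_df_f(Z[None, :], y[None, :])[0])


def selected_score_statistic(sc, est: CoefEstimate, kind: str,
                             threshold: float = ZERO_TOL) -> float:
    """Post-selection SSU or SSUw statistic on variants with |b_j| > 0.001."""
    if kind not in ("ssu", "ssuw"):
        raise ValueError("kind must be 'ssu' or 'ssuw'")
    sel = np.abs(est.beta) > threshold
    if not sel.any():
        return 0.0
    U = sc.U[sel]
    if kind == "ssu":
        return float(U @ U)
    d = sc.diag_V[sel]
    ok = d > 0
    if not ok.any():
        return 0.0
    return float(np.sum(U[ok] ** 2 / d[ok]))


def _batched_statistics(X, Y, beta, kind: str, threshold: float) -> np.ndarray:
    """Statistic for each (trait row, fitted beta row) pair."""
    if kind == "one_df":
        Z = beta @ X.T
        return _one_df_f(Z, Y)
    # post-selection score statistics: V is permutation-invariant up to
    # sigma0^2, which is itself invariant, so compute U per row directly.
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U = Yc @ Xc  # (B, k)
    sel = np.abs(beta) > threshold
    if kind == "ssu":
        return np.einsum("bk,bk->b", U * sel, U)
    n = Y.shape[1]
    syy = np.einsum("bn,bn->b", Yc, Yc)
    sigma0 = syy / (n - 1)
    d_base = np.einsum("nk,nk->k", Xc, Xc)  # diag(V)/sigma0^2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d_base > 0, 1.0 / d_base, 0.0)
    num = np.einsum("bk,bk->b", U**2 * sel, np.broadcast_to(w, U.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sigma0 > 0, num / sigma0, 0.0)


def _permute_rows(y: np.ndarray, B: int, seed: int) -> np.ndarray:
    """Deterministic trait permutations keyed by (seed, b)."""
    rows = np.empty((B, y.size))
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b + 1]))
        rows[b] = y[rng.permutation(y.size)]
    return rows


def permutation_test(geno, trait, family: str,
                     statistic_kind: str | tuple[str, ...] = "one_df",
                     grid: GridSpec | None = None, B: int = 100,
                     seed: int = 0, allow_any_statistic: bool = False,
                     plus_one: bool = False, fast: bool = True,
                     threshold: float = ZERO_TOL):
    """Permutation-calibrated test(s) for one penalized-fit family.

    ``statistic_kind`` may be a single kind or a tuple; all requested
    statistics share the same fits (one grid search per permutation).
    Post-selection ``ssu``/``ssuw`` are reserved for ``tlp_sg`` (and the
    ``ols`` cross-check) unless ``allow_any_statistic`` is set.  Returns a
    ``PermutationResult`` (or dict of them, keyed by kind, when a tuple is
    given).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    kinds = (statistic_kind,) if isinstance(statistic_kind, str) else tuple(statistic_kind)
    for kind in kinds:
        if kind not in STATISTICS:
            raise ValueError(f"unknown statistic {kind!r}")
        if kind in ("ssu", "ssuw") and family not in ("tlp_sg", "ols") \
                and not allow_any_statistic:
            raise ValueError(
                f"post-selection {kind} is reserved for tlp_sg; "
                "pass allow_any_statistic=True to override")
    X = geno.dosages if hasattr(geno, "dosages") else np.asarray(geno, dtype=float)
    y = np.asarray(trait, dtype=float)
    Y = np.vstack([y[None, :], _permute_rows(y, B, seed)])

    if family == "ols":
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        beta, *_ = np.linalg.lstsq(Xc, Yc.T, rcond=None)
        beta = beta.T
        params = [dict()] * (B + 1)
    else:
        res = grid_search_batched(X, Y, family, grid, fast=fast)
        beta = res["beta"]
        params = res["params"]

    out = {}
    for kind in kinds:
        T = _batched_statistics(X, Y, beta, kind, threshold)
        obs, null = float(T[0]), T[1:]
        hits = int(np.sum(obs < null))
        p = (hits + 1) / (B + 1) if plus_one else hits / B
        out[kind] = PermutationResult(
            method=family, statistic_kind=kind, observed_T=obs,
            null_T=null.copy(), B=B, p_value=float(p), params=dict(params[0]),
            per_perm_params=[dict(pp) for pp in params[1:]])
    return out[kinds[0]] if isinstance(statistic_kind, str) else out
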