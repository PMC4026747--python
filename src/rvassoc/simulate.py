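"""Synthetic genotype/trait generator for rare-variant power studies.

Haplotypes are produced by dichotomizing a latent multivariate-normal
vector with first-order autoregressive correlation (``R[j,j'] = rho^|j-j|'``,
``rho = 0.8``), which induces linkage disequilibrium between neighbouring
variants; the per-variant cut point ``Phi^{-1}(1 - f_j)`` fixes the allele
frequency ``f_j``.  A genotype is the sum of two independent haplotypes.
Rare-variant frequencies are drawn uniformly on [0.005, 0.01] per variant
and replicate.  In the mixed scheme, two of the ``k`` variant positions
are common variants: the same latent block is thresholded at an allele
frequency drawn uniformly on [0.2, 0.7], so common variants are in LD
with the surrounding rare variants, as within a real gene.

Traits follow ``Y_i = 0.3 + X_i beta + e_i`` with ``e_i ~ N(0, sd=2)``.
Six causal variants are placed at uniformly random positions each
replicate, and the six case-specific effect values (see
:func:`case_effects`) are assigned to those positions in random order; a
common variant drawn as causal has its effect divided by 10 so it does
not dominate the trait.  ``case=0`` is the global null (``beta = 0``)
used for type-I error studies.  Monomorphic simulated columns are kept —
downstream tests must tolerate them, as with real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "case_effects",
    "make_case_config",
    "simulate_haplotypes",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_replicate",
    "replicate_rng",
]

_EFFECTS = {
    ("rv_only", 1): [0.9, 0.9, 0.9, 0.9, 0.9, 0.9],
    ("rv_only", 2): [1.2, 1.2, 1.2, -1.2, -1.2, -1.2],
    ("rv_only", 3): [1.4, 1.3, -1.2, 1.2, -1.3, 1.4],
    ("rv_cv", 1): [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    ("rv_cv", 2): [1.5, 1.5, 1.5, -1.5, -1.5, -1.5],
    ("rv_cv", 3): [1.1, 1.3, -1.2, 1.2, -1.3, 1.1],
}

N_CAUSAL = 6


def case_effects(scheme: str, case: int) -> np.ndarray:
    """The six causal effect sizes for a scheme/case combination."""
    if case == 0:
        return np.zeros(N_CAUSAL)
    try:
        return np.asarray(_EFFECTS[(scheme, case)], dtype=float)
    except KeyError:
        raise ValueError(f"unknown scheme/case {(scheme, case)!r}") from None


@dataclass
class SimulationConfig:
    """A fully resolved replicate configuration (positions and MAFs drawn).

    ``noise_sd`` is the residual standard deviation of the trait model
    (default 2) and ``beta0`` the intercept (default 0.3).
    """

    scheme: str
    case: int
    n: int = 400
    k: int = N_CAUSAL
    beta: np.ndarray = field(default=None)  # type: ignore[assignment]
    causal_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    cv_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    freq: np.ndarray = field(default=None)  # type: ignore[assignment]
    beta0: float = 0.3
    noise_sd: float = 2.0
    rho: float = 0.8

    def __post_init__(self) -> None:
        if self.scheme not in ("rv_only", "rv_cv"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.k < N_CAUSAL:
            raise ValueError("k must be at least 6")
        if self.noise_sd < 0 or not (-1 < self.rho < 1):
            raise ValueError("need noise_sd >= 0 and |rho| < 1")


def make_case_config(scheme: str, case: int, n_noncausal: int = 0,
                     n: int = 400, rng: np.random.Generator | int = 0,
                     rv_maf_range=(0.005, 0.01),
                     cv_freq_range=(0.2, 0.7)) -> SimulationConfig:
    """Draw one replicate's configuration for a scheme/case set-up.

    ``k = 6 + n_noncausal`` variants total; in the mixed scheme two of the
    positions (chosen at random) are common variants.  Causal positions
    are a uniformly random size-6 subset; the six case effect values are
    assigned to them in random order, and a causal common variant has its
    effect divided by 10.
    """
    if n_noncausal < 0:
        raise ValueError("n_noncausal must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k = N_CAUSAL + n_noncausal
    effects = case_effects(scheme, case)
    causal_idx = rng.choice(k, size=N_CAUSAL, replace=False)  # random order
    beta = np.zeros(k)
    beta[causal_idx] = effects
    causal_idx = np.sort(causal_idx)
    n_cv = 2 if scheme == "rv_cv" else 0
    cv_idx = (np.sort(rng.choice(k, size=n_cv, replace=False))
              if n_cv else np.empty(0, dtype=int))
    freq = rng.uniform(*rv_maf_range, size=k)
    freq[cv_idx] = rng.uniform(*cv_freq_range, size=n_cv)
    if case != 0:
        on_cv = np.isin(causal_idx, cv_idx)
        beta[causal_idx[on_cv]] /= 10.0
    return SimulationConfig(scheme=scheme, case=case, n=n, k=k, beta=beta,
                            causal_idx=causal_idx, cv_idx=cv_idx, freq=freq)


def _ar1_cholesky(k: int, rho: float) -> np.ndarray:
    lags = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    return np.linalg.cholesky(rho ** lags)


def simulate_haplotypes(freq: np.ndarray, rho: float,
                        rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw ``size`` haplotypes: latent MVN(0, AR1(rho)), dichotomized.

    Allele j is present iff the latent coordinate exceeds
    ``Phi^{-1}(1 - freq_j)``, so its marginal frequency is ``freq_j``.
    """
    freq = np.asarray(freq, dtype=float)
    k = freq.size
    thresh = stats.norm.ppf(1.0 - freq)
    Z = rng.standard_normal((size, k)) @ _ar1_cholesky(k, rho).T
    return (Z > thresh).astype(np.int8)


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Genotypes = sum of two haplotypes from one shared AR1 latent block."""
    n, k = config.n, config.k
    H = simulate_haplotypes(config.freq, config.rho, rng, size=2 * n)
    X = (H[:n] + H[n:]).astype(float)
    mask = np.zeros(k, dtype=bool)
    mask[config.causal_idx] = config.beta[config.causal_idx] != 0
    return GenotypeMatrix(X, causal_mask=mask)


def simulate_trait(geno: GenotypeMatrix, config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Y = beta0 + X beta + N(0, noise_sd^2) noise."""
    eps = rng.normal(0.0, config.noise_sd, size=config.n)
    return config.beta0 + geno.dosages @ config.beta + eps


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for a (seed, replicate) pair."""
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


def simulate_replicate(scheme: str, case: int, n_noncausal: int = 0,
                       n: int = 400, seed: int = 0, replicate: int = 0):
    """One (genotypes, trait, config) draw with its own seeded stream."""
    rng = replicate_rng(seed, replicate)
    config = make_case_config(scheme, case, n_noncausal, n, rng)
    geno = simulate_genotypes(config, rng)
    y = simulate_trait(geno, config, rng)
    return geno, y, config
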