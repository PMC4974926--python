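"""Cross-species synthesis of path coefficients.

A path coefficient estimated per bee species is combined across species
by fixed-effect inverse-variance weighting on the Fisher z scale: each
r is transformed with z = 0.5 ln[(1 + r) / (1 - r)], weighted by
w = N - 3 (the reciprocal of var(z) for a correlation estimated from N
sites), and averaged.  Uncertainty comes from a percentile bootstrap
over species: resample the (z, w) pairs with replacement, recompute the
weighted mean, and take the 2.5th / 97.5th percentiles.

The module also provides the Spearman rank correlation (with an exact
permutation p-value for small samples) used to relate species-level
diversity effects to diet generalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError

DEFAULT_BOOTSTRAP_REPS = 100_000

#: largest N for which the exact permutation Spearman p-value is the default
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class MetaInput:
    """One species' contribution: coefficient r estimated from N sites."""

    species: str
    r: float
    N: int

    def __post_init__(self):
        if not -1.0 < self.r < 1.0:
            raise DomainError(f"{self.species}: |r| must be < 1 for the z transform")
        if self.N <= 3:
            raise DomainError(f"{self.species}: need N > 3 sites (weight = N - 3)")

    @property
    def z(self) -> float:
        return fisher_z(self.r)

    @property
    def weight(self) -> float:
        return float(self.N - 3)


@dataclass(frozen=True)
class MetaResult:
    z_mean: float
    ci_lower: float
    ci_upper: float
    B: int
    seed: int
    n_species: int

    @property
    def r_mean(self) -> float:
        """Back-transform of the weighted mean z to the correlation scale."""
        return math.tanh(self.z_mean)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = 0.5 ln[(1 + r)/(1 - r)] = atanh(r)."""
    if not -1.0 < r < 1.0:
        raise DomainError("|r| must be < 1")
    return float(math.atanh(r))


def weighted_mean_z(inputs: list[MetaInput]) -> float:
    """Inverse-variance weighted mean of the species' z values."""
    if not inputs:
        raise DomainError("need at least one species")
    w = np.array([i.weight for i in inputs])
    z = np.array([i.z for i in inputs])
    return float((w * z).sum() / w.sum())


def bootstrap_ci(inputs: list[MetaInput], B: int = DEFAULT_BOOTSTRAP_REPS,
                 seed: int = 0) -> MetaResult:
    """Percentile bootstrap over species of the weighted mean z.

    Species (z, w) pairs are resampled with replacement B times; the
    95% interval is the 2.5th / 97.5th percentile of the resampled
    weighted means.  Fully reproducible given ``seed``.
    """
    if B < 1:
        raise DomainError("B must be >= 1")
    if not inputs:
        raise DomainError("need at least one species")
    k = len(inputs)
    w = np.array([i.weight for i in inputs])
    z = np.array([i.z for i in inputs])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, k, size=(B, k))
    wz = (w * z)[idx].sum(axis=1) / w[idx].sum(axis=1)
    lo, hi = np.percentile(wz, [2.5, 97.5])
    return MetaResult(z_mean=weighted_mean_z(inputs), ci_lower=float(lo),
                      ci_upper=float(hi), B=B, seed=seed, n_species=k)


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman_correlation(x, y, method: str = "auto") -> tuple[float, float, int]:
    """Spearman rank correlation with a small-sample exact p-value.

    ``method``: "exact" enumerates every permutation of one variable's
    ranks (feasible for N <= 9 and the default there), "approx" uses the
    two-sided t approximation, "auto" picks exact for N <= 9.

    Returns ``(rho, p, N)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise DomainError("x and y must share a length")
    if n < 3:
        raise DomainError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateInputError("constant vector: Spearman rho undefined")
    rho, p_approx = stats.spearmanr(x, y)
    rho = float(rho)
    if method == "auto":
        method = "exact" if n <= EXACT_SPEARMAN_MAX_N else "approx"
    if method == "approx":
        return rho, float(p_approx), n
    if method != "exact":
        raise DomainError(f"unknown method {method!r}")
    rx = _rank(x)
    ry = _rank(y)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(float(rx_c @ rx_c))
    ry_c = ry - ry.mean()
    perms = np.array(list(permutations(ry_c)))
    denom_y = math.sqrt(float(ry_c @ ry_c))
    rhos = perms @ rx_c / (denom_x * denom_y)
    p_exact = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p_exact, n
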