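"""Zero-truncated count distributions and half-normal detection kernels.

These are the primitives shared by the survey simulator and the
hierarchical model: group sizes follow a zero-truncated Poisson (a group
contains at least one animal), observer counts of a detected group follow
a zero-truncated binomial (a detecting observer counts at least one
animal), and detection probability decays with perpendicular distance
through a half-normal kernel ``exp(-d^2 / (2 scale^2))``.

All probability mass functions are computed in log space internally and
returned on the linear scale.  Every sampling routine takes an explicit
:class:`numpy.random.Generator`; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "ZTPoissonParams",
    "ZTBinomialParams",
    "ztpois_pmf",
    "ztpois_logpmf",
    "ztpois_mean",
    "ztpois_support",
    "ztpois_sample",
    "ztbinom_pmf",
    "ztbinom_logpmf",
    "ztbinom_mean",
    "ztbinom_sample",
    "halfnormal_kernel",
]

#: Mass allowed beyond the truncated support used for inverse-CDF sampling.
_TAIL_EPS = 1e-12


@dataclass(frozen=True)
class ZTPoissonParams:
    """Mean ``lam`` of the untruncated Poisson; the zero class is removed."""

    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise ValueError(f"lam must be a positive real, got {self.lam!r}")


@dataclass(frozen=True)
class ZTBinomialParams:
    """Per-individual detection probability ``r`` and group size ``n``."""

    r: float
    n: int

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError(f"r must be in (0, 1], got {self.r!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")


def _check_positive_int(k, upper: int | None = None):
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        if not np.all(np.equal(np.mod(k, 1), 0)):
            raise ValueError("k must be integer-valued")
        k = k.astype(np.int64)
    if np.any(k < 1):
        raise ValueError("k must be >= 1 (zero-truncated support)")
    if upper is not None and np.any(k > upper):
        raise ValueError(f"k must be <= {upper}")
    return k


def ztpois_logpmf(k, params: ZTPoissonParams):
    """Log pmf of the zero-truncated Poisson at ``k >= 1``."""
    k = _check_positive_int(k)
    lam = params.lam
    # log [ e^-lam lam^k / (k! (1 - e^-lam)) ]; -expm1 avoids cancellation
    # in the normalising constant at small lam
    return k * np.log(lam) - lam - special.gammaln(k + 1.0) - np.log(-np.expm1(-lam))


def ztpois_pmf(k, params: ZTPoissonParams):
    """Pmf of the zero-truncated Poisson: ``e^-lam lam^k / (k! (1-e^-lam))``."""
    return np.exp(ztpois_logpmf(k, params))


def ztpois_mean(params: ZTPoissonParams) -> float:
    """Mean ``lam / (1 - e^-lam)`` of the zero-truncated Poisson."""
    return params.lam / -np.expm1(-params.lam)


def ztpois_support(params: ZTPoissonParams, tail: float = _TAIL_EPS) -> np.ndarray:
    """Support ``1..k_max`` with at most ``tail`` mass beyond ``k_max``."""
    # Untruncated quantile bounds the truncated one since truncation only
    # shifts mass toward small k.
    k_max = int(stats.poisson.ppf(1.0 - tail, params.lam)) + 1
    return np.arange(1, max(k_max, 1) + 1)


def ztpois_sample(params: ZTPoissonParams, rng: np.random.Generator, size=None):
    """Draw zero-truncated Poisson variates by inverse CDF.

    The support is truncated at the 1 - 1e-12 quantile, which avoids the
    unbounded rejection loops a naive resample-zeros scheme hits at small
    ``lam``.
    """
    support = ztpois_support(params)
    cdf = np.cumsum(ztpois_pmf(support, params))
    cdf /= cdf[-1]
    u = rng.random(size)
    out = support[np.searchsorted(cdf, u, side="left")]
    return out if size is not None else int(out)


def ztbinom_logpmf(k, params: ZTBinomialParams):
    """Log pmf of the zero-truncated binomial at ``1 <= k <= n``."""
    k = _check_positive_int(k, upper=params.n)
    r, n = params.r, params.n
    if r >= 1.0:
        return np.where(k == n, 0.0, -np.inf)
    log_norm = np.log1p(-np.exp(n * np.log1p(-r)))  # log(1 - (1-r)^n)
    return stats.binom.logpmf(k, n, r) - log_norm


def ztbinom_pmf(k, params: ZTBinomialParams):
    """Pmf ``C(n,k) r^k (1-r)^(n-k) / (1 - (1-r)^n)`` on ``1..n``."""
    return np.exp(ztbinom_logpmf(k, params))


def ztbinom_mean(params: ZTBinomialParams) -> float:
    """Mean ``n r / (1 - (1-r)^n)`` of the zero-truncated binomial."""
    r, n = params.r, params.n
    if r >= 1.0:
        return float(n)
    return n * r / -np.expm1(n * np.log1p(-r))


def ztbinom_sample(params: ZTBinomialParams, rng: np.random.Generator, size=None):
    """Draw zero-truncated binomial variates by inverse CDF on ``1..n``."""
    support = np.arange(1, params.n + 1)
    cdf = np.cumsum(ztbinom_pmf(support, params))
    cdf /= cdf[-1]
    u = rng.random(size)
    out = support[np.searchsorted(cdf, u, side="left")]
    return out if size is not None else int(out)


def halfnormal_kernel(d, scale):
    """Half-normal detection kernel ``exp(-d^2 / (2 scale^2))``.

    Equals 1 at ``d = 0`` and decreases monotonically with distance;
    ``scale`` is the half-normal shape parameter in the same units as ``d``.
    """
    d = np.asarray(d, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    out = np.exp(-(d**2) / (2.0 * scale**2))
    return out if out.ndim else float(out)
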