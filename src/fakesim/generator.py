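"""Synthetic 'true' ordinal data with a single-factor latent structure.

The generator draws rows from a latent one-factor Gaussian model with
equicorrelated unit-variance margins and discretizes each column through
thresholds chosen so that the observed item marginals follow a shifted
binomial distribution on ``{1, ..., q}``.  Because discretization attenuates
correlation, the latent equicorrelation is calibrated so that the
*observed-scale* pairwise Pearson correlation hits the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .matrix import OrdinalMatrix

__all__ = [
    "GenerativeParams",
    "binomial_thresholds",
    "discretized_pair_correlation",
    "calibrate_latent_correlation",
    "generate_true_data",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the single-factor ordinal generative model.

    Parameters
    ----------
    n, m : int
        Respondents and items.
    q : int
        Ordinal categories; item marginals are ``Binomial(q - 1, p_binom)``
        shifted to ``{1, ..., q}``.
    p_binom : float
        Binomial marginal parameter, strictly inside ``(0, 1)``.
    rho_target : float
        Target pairwise Pearson correlation on the observed ordinal scale.
    seed : int
        Seed for the latent draws.
    """

    n: int
    m: int
    q: int
    p_binom: float = 0.5
    rho_target: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive")
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if not (0.0 < self.p_binom < 1.0):
            raise ValueError(f"p_binom must be in (0, 1), got {self.p_binom}")
        if not (0.0 <= self.rho_target < 0.95):
            raise ValueError(f"rho_target must be in [0, 0.95), got {self.rho_target}")


def binomial_thresholds(p_binom: float, q: int) -> np.ndarray:
    """Standard-normal cut points reproducing shifted-binomial marginals.

    Cut point ``c_v = Phi^-1(F_B(v - 1))`` for ``v = 1..q-1`` where ``F_B``
    is the ``Binomial(q - 1, p_binom)`` CDF, so a standard normal variate
    discretized by these thresholds takes value ``v`` with probability
    ``Binomial(q - 1, p_binom).pmf(v - 1)``.

    Returns
    -------
    numpy.ndarray
        ``q - 1`` strictly increasing thresholds.
    """
    if not (0.0 < p_binom < 1.0):
        raise ValueError(f"degenerate p_binom={p_binom}")
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    cdf = stats.binom.cdf(np.arange(q - 1), q - 1, p_binom)
    return stats.norm.ppf(cdf)


def _binomial_marginal(p_binom: float, q: int) -> np.ndarray:
    return stats.binom.pmf(np.arange(q), q - 1, p_binom)


def discretized_pair_correlation(
    rho_latent: float, p_binom: float, q: int
) -> float:
    """Pearson correlation of a discretized bivariate-normal pair.

    Evaluates exactly, via bivariate-normal rectangle probabilities, the
    observed-scale Pearson correlation of two standard normal variables with
    correlation ``rho_latent`` after each is discretized through
    :func:`binomial_thresholds`.
    """
    if rho_latent == 0.0:
        return 0.0
    c = binomial_thresholds(p_binom, q)
    # joint CDF at every finite cut-point pair
    grid = np.array([(x, y) for x in c for y in c])
    mvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho_latent], [rho_latent, 1.0]]
    )
    cdf = np.empty((q + 1, q + 1))
    cdf[0, :] = 0.0
    cdf[:, 0] = 0.0
    cdf[1:q, 1:q] = mvn.cdf(grid).reshape(q - 1, q - 1)
    cdf[q, 1:q] = stats.norm.cdf(c)  # x -> +inf
    cdf[1:q, q] = stats.norm.cdf(c)
    cdf[q, q] = 1.0
    cell = np.diff(np.diff(cdf, axis=0), axis=1)  # P(X = u, Y = v), q x q
    v = np.arange(1, q + 1, dtype=float)
    exy = v @ cell @ v
    p = _binomial_marginal(p_binom, q)
    mu = v @ p
    var = v**2 @ p - mu**2
    return float((exy - mu**2) / var)


@lru_cache(maxsize=64)
def calibrate_latent_correlation(
    rho_target: float, p_binom: float, q: int, tol: float = 0.005
) -> float:
    """Latent correlation whose discretized observed correlation hits target.

    Monotone bisection on :func:`discretized_pair_correlation`.  Returns a
    latent correlation in ``[0, 1)`` such that the observed-scale Pearson
    correlation is within ``tol`` of ``rho_target``.

    Raises
    ------
    ValueError
        If the target exceeds the discretization ceiling.
    """
    if not (0.0 <= rho_target < 0.95):
        raise ValueError(f"rho_target must be in [0, 0.95), got {rho_target}")
    if rho_target == 0.0:
        return 0.0
    lo, hi = rho_target, 0.999  # attenuation: latent >= observed
    f_hi = discretized_pair_correlation(hi, p_binom, q)
    if f_hi < rho_target - tol:
        raise ValueError(
            f"rho_target={rho_target} unreachable: discretization ceiling "
            f"{f_hi:.4f} at latent correlation {hi}"
        )
    f_lo = discretized_pair_correlation(lo, p_binom, q)
    if f_lo >= rho_target:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = discretized_pair_correlation(mid, p_binom, q)
        if abs(f_mid - rho_target) <= 0.2 * tol:
            return mid
        if f_mid < rho_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_true_data(params: GenerativeParams) -> OrdinalMatrix:
    """Draw a synthetic honest-response matrix under the one-factor model.

    Each latent item score is ``sqrt(rho_latent) * factor +
    sqrt(1 - rho_latent) * noise`` with a common standard-normal factor per
    respondent, giving unit variances and latent equicorrelation
    ``rho_latent`` (calibrated from ``params.rho_target``).  Columns are
    discretized through :func:`binomial_thresholds` and shifted to
    ``{1, ..., q}``.  Deterministic under a fixed seed.
    """
    rho_latent = calibrate_latent_correlation(
        params.rho_target, params.p_binom, params.q
    )
    rng = np.random.default_rng(params.seed)
    factor = rng.standard_normal((params.n, 1))
    noise = rng.standard_normal((params.n, params.m))
    z = np.sqrt(rho_latent) * factor + np.sqrt(1.0 - rho_latent) * noise
    c = binomial_thresholds(params.p_binom, params.q)
    values = np.digitize(z, c) + 1
    return OrdinalMatrix(values, params.q)
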