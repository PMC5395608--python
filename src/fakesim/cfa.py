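"""One-factor confirmatory factor analysis by normal-theory ML.

Fits ``Sigma(theta) = lambda lambda' + diag(psi)`` to a sample covariance by
minimizing the maximum-likelihood discrepancy, and computes the incremental
and absolute fit indices (NFI, CFI, NNFI, RMSEA) against an independence
baseline.  Uniquenesses are deliberately left unconstrained so that improper
(Heywood) solutions can occur and be flagged rather than masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .matrix import OrdinalMatrix

__all__ = [
    "CFAResult",
    "fit_one_factor",
    "baseline_chi_square",
    "compute_fit_indices",
    "flag_improper",
]

#: Propriety limits: a solution is improper when any uniqueness is negative
#: or any loading exceeds this bound in absolute value.
LOADING_BOUND = 10.0


@dataclass
class CFAResult:
    """Estimates, chi-squares, fit indices, and propriety flags."""

    loadings: np.ndarray
    uniquenesses: np.ndarray
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    nfi: float
    cfi: float
    nnfi: float
    rmsea: float
    converged: bool
    proper: bool
    improper_reasons: list[str] = field(default_factory=list)
    n: int = 0

    @property
    def usable(self) -> bool:
        """Converged and proper — eligible for summary statistics."""
        return self.converged and self.proper


def _ml_discrepancy(S: np.ndarray, lam: np.ndarray, psi: np.ndarray):
    """ML discrepancy F and its gradient wrt (lam, psi).

    F = log|Sigma| - log|S| + tr(S Sigma^-1) - m with
    Sigma = lam lam' + diag(psi).  Returns (inf, zeros) when Sigma is not
    positive definite so the optimizer backtracks.
    """
    m = len(lam)
    sigma = np.outer(lam, lam)
    sigma[np.diag_indices(m)] += psi
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(2 * m)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sigma_inv = np.linalg.inv(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    f = logdet - logdet_s + float(np.trace(S @ sigma_inv)) - m
    # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
    G = sigma_inv @ (sigma - S) @ sigma_inv
    grad = np.concatenate([2.0 * G @ lam, np.diag(G)])
    return f, grad


def _start_values(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-principal-component start: lam = sqrt(e1) * u1, psi = residual."""
    evals, evecs = np.linalg.eigh(S)
    e1, u1 = evals[-1], evecs[:, -1]
    lam = np.sqrt(max(e1, 1e-8)) * u1
    if lam.mean() < 0:
        lam = -lam
    psi = np.maximum(np.diag(S) - lam**2, 0.05 * np.diag(S))
    return lam, psi


def fit_one_factor(
    data: OrdinalMatrix | np.ndarray,
    n: int | None = None,
    max_iter: int = 500,
    gtol: float = 1e-7,
    ftol: float = 1e-10,
) -> CFAResult:
    """Fit the one-factor model to a response matrix or covariance.

    Parameters
    ----------
    data : OrdinalMatrix or ndarray
        Either a response matrix (its Pearson sample covariance is used) or
        an ``m x m`` covariance matrix, in which case ``n`` is required.
    n : int, optional
        Sample size when a covariance is passed directly.
    max_iter, gtol, ftol :
        Optimizer controls (L-BFGS-B on the stacked ``(lam, psi)`` vector).

    Returns
    -------
    CFAResult
        Non-convergence is reported via the ``converged`` flag, never as an
        exception.  The loading sign is fixed so the mean loading is >= 0.
    """
    if isinstance(data, OrdinalMatrix):
        S = np.cov(data.values, rowvar=False, ddof=1)
        n = data.n
    else:
        S = np.asarray(data, dtype=float)
        if n is None:
            raise ValueError("sample size n is required with a covariance input")
    m = S.shape[0]
    if S.shape != (m, m):
        raise ValueError(f"covariance must be square, got {S.shape}")
    if m < 3:
        raise ValueError(f"one-factor model needs m >= 3 items, got {m}")
    if np.any(np.diag(S) <= 0):
        raise ValueError("covariance has a non-positive diagonal entry")
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")

    lam0, psi0 = _start_values(S)

    def objective(x):
        return _ml_discrepancy(S, x[:m], x[m:])

    def solve(lam_s, psi_s):
        return optimize.minimize(
            objective,
            np.concatenate([lam_s, psi_s]),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol, "ftol": ftol},
        )

    res = solve(lam0, psi0)
    if (not res.success or res.nit <= 5) and res.fun > 1e-10:
        # the PC start can stall in nearly unidentified (e.g. near-diagonal)
        # problems; retry from a weak-loading start and keep the better fit
        alt = solve(0.1 * np.sqrt(np.diag(S)), 0.9 * np.diag(S))
        if alt.fun < res.fun:
            res = alt
    lam, psi = res.x[:m], res.x[m:]
    if lam.mean() < 0:
        lam = -lam
    f_min = float(res.fun)
    converged = bool(res.success) and np.isfinite(f_min)

    chi2_model = max((n - 1) * f_min, 0.0) if np.isfinite(f_min) else np.nan
    df_model = m * (m + 1) // 2 - 2 * m
    chi2_baseline, df_baseline = baseline_chi_square(S, n)
    nfi, cfi, nnfi, rmsea = compute_fit_indices(
        chi2_model, df_model, chi2_baseline, df_baseline, n
    )
    if chi2_baseline <= 1e-10 or not np.isfinite(nfi):
        # degenerate baseline: indices undefined, exclude replicate
        converged = False
    proper, reasons = flag_improper(lam, psi)
    return CFAResult(
        loadings=lam,
        uniquenesses=psi,
        chi2_model=chi2_model,
        df_model=df_model,
        chi2_baseline=chi2_baseline,
        df_baseline=df_baseline,
        nfi=nfi,
        cfi=cfi,
        nnfi=nnfi,
        rmsea=rmsea,
        converged=converged,
        proper=proper,
        improper_reasons=reasons,
        n=n,
    )


def baseline_chi_square(S: np.ndarray, n: int) -> tuple[float, int]:
    """Chi-square of the independence model ``Sigma_b = diag(S)``.

    For the ML discrepancy this reduces to ``-(n - 1) * log|R|`` with ``R``
    the sample correlation matrix; degrees of freedom are ``m(m-1)/2``.
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("covariance has a non-positive diagonal entry")
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("singular correlation matrix")
    chi2 = max(-(n - 1) * logdet, 0.0)
    return chi2, m * (m - 1) // 2


def compute_fit_indices(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int, n: int
) -> tuple[float, float, float, float]:
    """Standard NFI / CFI / NNFI / RMSEA from model and baseline chi-squares.

    Returns NaN for all indices when the baseline chi-square is zero (the
    independence model already fits, so incremental indices are undefined).
    """
    if chi2_b <= 1e-10 or df_m <= 0 or not np.isfinite(chi2_m):
        return (np.nan, np.nan, np.nan, np.nan)
    nfi = (chi2_b - chi2_m) / chi2_b
    denom = chi2_b / df_b - 1.0
    nnfi = (chi2_b / df_b - chi2_m / df_m) / denom if denom != 0 else np.nan
    excess_m = max(chi2_m - df_m, 0.0)
    excess_b = max(chi2_b - df_b, excess_m, 0.0)
    cfi = 1.0 - excess_m / excess_b if excess_b > 0 else 1.0
    rmsea = np.sqrt(excess_m / (df_m * (n - 1)))
    return (float(nfi), float(cfi), float(nnfi), float(rmsea))


def flag_improper(
    loadings: "np.ndarray | CFAResult", uniquenesses: np.ndarray | None = None
) -> tuple[bool, list[str]]:
    """Propriety check: no negative uniqueness, no loading beyond +/-10.

    Accepts either a fitted :class:`CFAResult` or explicit loading and
    uniqueness vectors.
    """
    if isinstance(loadings, CFAResult):
        loadings, uniquenesses = loadings.loadings, loadings.uniquenesses
    reasons = []
    for j, psi_j in enumerate(uniquenesses):
        if psi_j < 0:
            reasons.append(f"negative variance: psi[{j}] = {psi_j:.4g}")
    for j, lam_j in enumerate(loadings):
        if abs(lam_j) > LOADING_BOUND:
            reasons.append(f"loading > {LOADING_BOUND:g}: lambda[{j}] = {lam_j:.4g}")
    return (len(reasons) == 0, reasons)
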