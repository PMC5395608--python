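"""Conditional replacement distributions for ordinal responses.

The core primitive is a two-shape-parameter discrete beta-like family
(:func:`dg_pmf`) on a bounded integer support.  Conditioned on an observed
value ``k``, a replacement distribution either *reverses* suspected fake-good
responses (values can only be lowered) or applies a *forward* fake-good
corruption (values can only be raised).  With per-entry replacement
probability ``pi``, the observed value is retained with probability
``1 - pi`` and otherwise replaced by a draw from the shape family over the
admissible values.

Three named scenarios fix the shape pair: ``uninformative`` (uniform over
admissible values), ``slight`` (replacement values concentrate adjacent to
the observed value), and ``extreme`` (replacement values concentrate far
from the observed value).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .matrix import OrdinalMatrix

__all__ = [
    "Direction",
    "ReplacementParams",
    "Scenario",
    "SCENARIOS",
    "dg_pmf",
    "replacement_pmf",
    "replacement_table",
    "perturb_matrix",
    "scenario_params",
]


class Direction(str, enum.Enum):
    """Direction of the replacement process.

    ``REVERSE`` reconstructs hypothetical honest data from suspected
    fake-good data: entries may only decrease.  ``FORWARD`` corrupts honest
    data with a fake-good process: entries may only increase.
    """

    REVERSE = "reverse"
    FORWARD = "forward"


@dataclass(frozen=True)
class ReplacementParams:
    """Parameters of the conditional replacement distribution.

    Parameters
    ----------
    gamma, delta : float
        Strictly positive shape parameters of the discrete beta family.
    pi : float
        Per-entry replacement probability in ``[0, 1]``.
    direction : Direction
        ``REVERSE`` (lower values) or ``FORWARD`` (raise values).
    """

    gamma: float
    delta: float
    pi: float
    direction: Direction = Direction.REVERSE

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.delta > 0):
            raise ValueError(
                f"shape parameters must be positive, got gamma={self.gamma}, "
                f"delta={self.delta}"
            )
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class Scenario:
    """A named canonical shape configuration (reverse-direction convention)."""

    name: str
    gamma: float
    delta: float


#: Canonical scenarios.  Shapes are quoted in the reverse-direction
#: convention; the forward direction swaps them so that "slight" means a
#: small shift either way.
SCENARIOS: dict[str, Scenario] = {
    "uninformative": Scenario("uninformative", 1.0, 1.0),
    "slight": Scenario("slight", 4.0, 1.5),
    "extreme": Scenario("extreme", 1.5, 4.0),
}


def dg_pmf(a: int, b: int, gamma: float, delta: float) -> np.ndarray:
    """Discrete generalized beta probability mass over ``{a, ..., b}``.

    Mass at ``h`` is proportional to
    ``(h - a + 1)**(gamma - 1) * (b - h + 1)**(delta - 1)``,
    normalized to sum to one over the integer support.

    Parameters
    ----------
    a, b : int
        Integer support bounds, ``a <= b``.
    gamma, delta : float
        Strictly positive shape parameters.  ``gamma = delta = 1`` gives the
        uniform distribution; ``gamma > delta`` skews mass toward ``b``,
        ``gamma < delta`` toward ``a``.

    Returns
    -------
    numpy.ndarray
        Probability vector of length ``b - a + 1``.
    """
    if a > b:
        raise ValueError(f"empty support: a={a} > b={b}")
    if not (gamma > 0 and delta > 0):
        raise ValueError(
            f"shape parameters must be positive, got gamma={gamma}, delta={delta}"
        )
    h = np.arange(a, b + 1, dtype=float)
    # log-space for numerical robustness at large shapes
    logw = (gamma - 1.0) * np.log(h - a + 1.0) + (delta - 1.0) * np.log(b - h + 1.0)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def replacement_pmf(k: int, params: ReplacementParams, q: int) -> np.ndarray:
    """Conditional distribution of the replacement value given observed ``k``.

    Parameters
    ----------
    k : int
        Observed value in ``{1, ..., q}``.
    params : ReplacementParams
        Shapes, replacement probability, and direction.
    q : int
        Number of ordinal categories.

    Returns
    -------
    numpy.ndarray
        Probability vector of length ``q`` over values ``1..q``.

    Notes
    -----
    Reverse direction: ``k = 1`` is absorbing (point mass at 1); for
    ``k > 1`` the observed value is kept with mass ``1 - pi`` and each lower
    value ``h < k`` receives ``pi * DG(h; 1, k - 1, gamma, delta)``.  The
    forward direction is the mirror image on the reflected scale with the
    shape parameters swapped.
    """
    k = int(k)
    if not (1 <= k <= q):
        raise ValueError(f"observed value {k} outside 1..{q}")
    p = np.zeros(q)
    direction = Direction(params.direction)
    if direction is Direction.REVERSE:
        if k == 1:
            p[0] = 1.0
            return p
        p[k - 1] = 1.0 - params.pi
        p[: k - 1] = params.pi * dg_pmf(1, k - 1, params.gamma, params.delta)
    else:
        if k == q:
            p[q - 1] = 1.0
            return p
        p[k - 1] = 1.0 - params.pi
        p[k:] = params.pi * dg_pmf(k + 1, q, params.delta, params.gamma)
    return p


def replacement_table(params: ReplacementParams, q: int) -> np.ndarray:
    """Stack :func:`replacement_pmf` for every observed value.

    Returns
    -------
    numpy.ndarray of shape (q, q)
        Row ``k - 1`` is the replacement pmf conditional on observing ``k``.
    """
    return np.stack([replacement_pmf(k, params, q) for k in range(1, q + 1)])


def perturb_matrix(
    data: OrdinalMatrix,
    params: ReplacementParams,
    seed: int | np.random.Generator,
) -> OrdinalMatrix:
    """Apply the replacement distribution independently to every entry.

    Each entry is replaced by an independent draw from its conditional
    replacement pmf, consuming a single uniform stream in row-major order.
    The reverse direction never increases an entry; the forward direction
    never decreases one.  Identical seed and inputs give identical output.

    Parameters
    ----------
    data : OrdinalMatrix
        Input matrix.
    params : ReplacementParams
        Replacement distribution parameters.
    seed : int or numpy.random.Generator
        Seed or generator for the uniform draws.

    Returns
    -------
    OrdinalMatrix
        Perturbed matrix with the same shape and scale.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = replacement_table(params, data.q)
    cdf = np.cumsum(table, axis=1)
    cdf[:, -1] = 1.0  # guard against round-off at the top bin
    u = rng.random(data.values.shape)
    rows = cdf[data.values - 1]  # (n, m, q)
    out = (u[..., None] >= rows).sum(axis=-1) + 1
    return OrdinalMatrix(out, data.q)


def scenario_params(
    name: str, pi: float, direction: Direction | str = Direction.REVERSE
) -> ReplacementParams:
    """Build :class:`ReplacementParams` from a canonical scenario name.

    Raises
    ------
    KeyError
        If ``name`` is not one of ``uninformative``, ``slight``, ``extreme``.
    """
    try:
        sc = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None
    return ReplacementParams(sc.gamma, sc.delta, pi, Direction(direction))
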