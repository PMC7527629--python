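"""Exact quantities of the Moran chain with directional selection and recurrent mutation.

The model is a constant-size population of ``N`` hematopoietic stem cells carrying
either the wildtype or a mutant (truncated) G-CSF receptor.  At each event one cell
dies uniformly at random and one cell proliferates; the wildtype is chosen to
proliferate with weight ``1 - s``, so ``s`` is the per-generation selective advantage
of the mutant clone.  Recurrent mutation converts each wildtype cell to mutant at
rate ``mu`` per cell per generation, which keeps the all-wildtype state live: an
extinct mutant lineage can be re-seeded.

Time is measured in generations (one expected division per cell).  Conversion to
calendar years via the division rate ``lambda`` happens only in the estimator layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InvalidParameterError",
    "ModelParams",
    "ChainState",
    "discrete_transition_probs",
    "continuous_rates",
    "fixation_probability",
    "expected_fixation_time_asymptotic",
]


class InvalidParameterError(ValueError):
    """A model parameter or state is outside its admissible range."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the Moran chain.

    Parameters
    ----------
    N : int
        Population size (number of HSCs), at least 2.
    s : float
        Selection coefficient of the mutant, ``0 <= s < 1``.
    mu : float
        Mutation rate per wildtype cell per generation, nonnegative.
    """

    N: int
    s: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int,)) and self.N >= 2):
            raise InvalidParameterError(f"N must be an integer >= 2, got {self.N!r}")
        if not (0.0 <= self.s < 1.0):
            raise InvalidParameterError(f"s must satisfy 0 <= s < 1, got {self.s!r}")
        if self.mu < 0.0:
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu!r}")


@dataclass(frozen=True)
class ChainState:
    """A point of a sample path: mutant count ``i`` at time ``t`` (generations)."""

    i: int
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.i < 0:
            raise InvalidParameterError(f"mutant count must be >= 0, got {self.i}")
        if self.t < 0.0:
            raise InvalidParameterError(f"time must be >= 0, got {self.t}")


def _check_count(i: int, N: int) -> None:
    if not 0 <= i <= N:
        raise InvalidParameterError(f"mutant count i={i} outside [0, N={N}]")


def discrete_transition_probs(i: int, N: int, s: float) -> tuple[float, float]:
    """One-step transition probabilities of the discrete-time chain (no mutation).

    Returns ``(p_up, p_down)`` where ``p_up`` is the probability of ``i -> i+1``
    (a wildtype dies and a mutant proliferates) and ``p_down`` of ``i -> i-1``.
    The remainder ``1 - p_up - p_down`` is the self-transition.
    """
    _check_count(i, N)
    if not (0.0 <= s < 1.0):
        raise InvalidParameterError(f"s must satisfy 0 <= s < 1, got {s!r}")
    denom = (1.0 - s) * (N - i) + i
    if denom == 0.0:  # only possible if i == 0 and s == 1, excluded above
        return 0.0, 0.0
    p_up = ((N - i) / N) * (i / denom)
    p_down = (i / N) * ((1.0 - s) * (N - i) / denom)
    return p_up, p_down


def continuous_rates(i: int, params: ModelParams) -> tuple[float, float]:
    """Transition intensities of the time-continuous chain with recurrent mutation.

    ``q_up = (N-i) * i / N + mu * (N-i)`` and ``q_down = i * (1-s) * (N-i) / N``,
    both per generation.  Both vanish at ``i = N`` (fixation is absorbing); with
    ``mu > 0`` the state ``i = 0`` is live with ``q_up = mu * N``.
    """
    N, s, mu = params.N, params.s, params.mu
    _check_count(i, N)
    q_up = (N - i) * i / N + mu * (N - i)
    q_down = i * (1.0 - s) * (N - i) / N
    return q_up, q_down


def fixation_probability(i: int, N: int, s: float) -> float:
    """Probability that the mutation-free chain hits ``N`` before ``0`` from ``i``.

    Equals ``(1 - (1-s)^i) / (1 - (1-s)^N)`` for ``s > 0`` and the neutral limit
    ``i / N`` at ``s = 0``; the two connect continuously, and the same expression
    holds for the discrete- and continuous-time versions of the chain.
    """
    _check_count(i, N)
    if not (0.0 <= s < 1.0):
        raise InvalidParameterError(f"s must satisfy 0 <= s < 1, got {s!r}")
    if s == 0.0:
        return i / N
    # expm1/log1p keep full precision as s -> 0, where the naive ratio loses
    # ~half the significant digits.
    num = -math.expm1(i * math.log1p(-s))
    den = -math.expm1(N * math.log1p(-s))
    return num / den


def expected_fixation_time_asymptotic(N: int, s: float) -> float:
    """Large-``N`` asymptotic of the expected fixation time, ``(2/s) * ln(N)``.

    Exposed for reference only; it is a coarse approximation at moderate ``N``
    and is never used inside estimation.
    """
    if s <= 0.0:
        raise InvalidParameterError(f"s must be > 0, got {s!r}")
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N!r}")
    return (2.0 / s) * math.log(N)
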