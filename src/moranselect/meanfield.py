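"""Deterministic (mean-field) approximation of the expected mutant frequency.

Replacing the mutant count by its expectation in the one-step conditional mean of
the chain gives, after rescaling ``y = x / N``, the ODE

    dy/dt = s * y * (1 - y) + mu * (1 - y)

— logistic growth driven by selection plus an influx from recurrent mutation.
The population size drops out entirely.  With ``alpha0 = (1 - y0) / (y0 + u)``
and ``u = mu / s`` the solution is explicit:

    y(t) = [1 - u * alpha0 * e^{-(mu+s)(t-t0)}] / [1 + alpha0 * e^{-(mu+s)(t-t0)}]

reducing to the plain logistic curve when ``mu = 0``.  This is an approximation
of the mean, not the exact expectation; tests compare it to simulation averages
within Monte-Carlo error only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .moran import InvalidParameterError

__all__ = ["MeanCurveParams", "ode_rhs", "mean_frequency"]


@dataclass(frozen=True)
class MeanCurveParams:
    """Parameters of the closed-form mean-frequency curve.

    ``u = mu/s`` and ``alpha0 = (1 - y0)/(y0 + u)`` are derived; ``s = 0`` is
    allowed (pure-mutation dynamics) and handled by an exact special case in
    :func:`mean_frequency`.
    """

    y0: float
    s: float
    mu: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.y0 < 1.0:
            raise InvalidParameterError(f"y0 must be in (0, 1), got {self.y0!r}")
        if self.s < 0.0:
            raise InvalidParameterError(f"s must be >= 0, got {self.s!r}")
        if self.mu < 0.0:
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu!r}")

    @property
    def u(self) -> float:
        if self.s == 0.0:
            raise InvalidParameterError("u = mu/s is undefined at s = 0")
        return self.mu / self.s

    @property
    def alpha0(self) -> float:
        return (1.0 - self.y0) / (self.y0 + self.u)


def ode_rhs(y: float, s: float, mu: float = 0.0) -> float:
    """Right-hand side ``s*y*(1-y) + mu*(1-y)`` of the mean-field ODE."""
    if np.any(np.asarray(y) < 0.0) or np.any(np.asarray(y) > 1.0):
        raise InvalidParameterError(f"y must be in [0, 1], got {y!r}")
    return (1.0 - y) * y * s + mu * (1.0 - y)


def mean_frequency(t, params: MeanCurveParams):
    """Closed-form mean mutant frequency at time(s) ``t`` (generations).

    Equals ``y0`` at ``t = t0``, is nondecreasing, tends to 1, and does not
    depend on the population size.  Scalar in, scalar out; array in, array out.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < params.t0):
        raise InvalidParameterError("t must be >= t0")
    dt = t_arr - params.t0
    if params.s == 0.0:
        # exact solution of dy/dt = mu*(1-y): exponential relaxation to 1
        y = 1.0 - (1.0 - params.y0) * np.exp(-params.mu * dt)
    else:
        u = params.u
        a0 = params.alpha0
        decay = a0 * np.exp(-(params.mu + params.s) * dt)
        y = (1.0 - u * decay) / (1.0 + decay)
    return y if isinstance(y, np.ndarray) and np.ndim(t) else float(y)
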