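"""Selection-coefficient estimation from two-time-point clone frequencies.

Given the mutant frequency ``y0`` at a first sampling and ``y1`` at a second one
``dt_years`` later, and the HSC division rate ``lam`` (divisions per year,
default 24, i.e. a 15-day interdivision time), the mean-field curve can be
inverted in closed form.  With ``alpha_i = (1 - y_i) / (y_i + u)`` and
``u = mu / s``:

    s_hat = ln(alpha0 / alpha1) / ((1 + u) * lam * dt_years)

At ``u = 0`` this is the per-generation change in log-odds,
``ln[(y1/(1-y1)) / (y0/(1-y0))] / (lam * dt_years)``.

A single pair of frequencies does not identify ``(s, mu)`` jointly — it pins
down a one-parameter trade-off curve indexed by ``u``; :func:`tradeoff_curve`
traces it.  The estimate never involves the population size ``N``.

Note on signs: the alpha ratio is written ``alpha0 / alpha1`` so that a growing
clone (``y1 > y0``, hence ``alpha1 < alpha0``) yields a positive ``s_hat``,
consistent with ``alpha1 = alpha0 * exp(-(mu+s) * dt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .moran import InvalidParameterError

__all__ = [
    "TwoPointObservation",
    "EstimateResult",
    "alpha_of",
    "odds",
    "estimate_s_given_u",
    "tradeoff_curve",
    "sensitivity_to_lambda",
    "read_observations",
    "estimates_to_frame",
]

DEFAULT_LAMBDA = 24.0  # HSC divisions per year (15-day interdivision time)

_CSV_REQUIRED = ("case_id", "y0", "y1", "dt_years", "lambda")
_CSV_OPTIONAL = ("phase", "mutation", "source")


@dataclass(frozen=True)
class TwoPointObservation:
    """One patient's mutant-receptor frequency at two sampling times.

    ``y0`` and ``y1`` are variant-allele-style frequencies in the open interval
    (0, 1); ``dt_years`` is the calendar time between samplings; ``lam``
    converts it to generations.
    """

    y0: float
    y1: float
    dt_years: float
    lam: float = DEFAULT_LAMBDA
    case_id: str = ""
    phase: str = "unclassified"
    mutation: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        for name, y in (("y0", self.y0), ("y1", self.y1)):
            if not 0.0 < y < 1.0:
                raise InvalidParameterError(
                    f"{name} must be strictly inside (0, 1), got {y!r}"
                )
        if not self.dt_years > 0:
            raise InvalidParameterError(f"dt_years must be > 0, got {self.dt_years!r}")
        if not self.lam > 0:
            raise InvalidParameterError(f"lambda must be > 0, got {self.lam!r}")

    @property
    def dt_generations(self) -> float:
        return self.lam * self.dt_years


@dataclass(frozen=True)
class EstimateResult:
    """Selection-coefficient estimate under an assumed mutation-selection ratio.

    ``alpha0``/``alpha1`` follow the ``(1-y)/(y+u)`` convention; ``odds0``/
    ``odds1`` are the plain odds ``y/(1-y)`` (the convention printed in the
    clinical summary table).  At ``u = 0`` the two are reciprocal.
    ``mu_implied = u * s_hat`` is the mutation rate this point of the trade-off
    curve corresponds to.
    """

    s_hat: float
    u: float
    mu_implied: float
    alpha0: float
    alpha1: float
    odds0: float
    odds1: float
    dt_generations: float
    case_id: str = ""


def odds(y: float) -> float:
    """The odds transform ``y / (1 - y)``."""
    if not 0.0 < y < 1.0:
        raise InvalidParameterError(f"y must be in (0, 1), got {y!r}")
    return y / (1.0 - y)


def alpha_of(y: float, u: float) -> float:
    """``(1 - y) / (y + u)``: strictly decreasing in both ``y`` and ``u``."""
    if not 0.0 < y < 1.0:
        raise InvalidParameterError(f"y must be in (0, 1), got {y!r}")
    if u < 0.0:
        raise InvalidParameterError(f"u must be >= 0, got {u!r}")
    return (1.0 - y) / (y + u)


def estimate_s_given_u(obs: TwoPointObservation, u: float = 0.0) -> EstimateResult:
    """Invert the mean-field curve for ``s`` at an assumed ``u = mu/s``.

    Positive for a growing clone, negative for a shrinking one, zero when the
    frequency did not change.
    """
    if u < 0.0:
        raise InvalidParameterError(f"u must be >= 0, got {u!r}")
    a0 = alpha_of(obs.y0, u)
    a1 = alpha_of(obs.y1, u)
    dt_gen = obs.dt_generations
    s_hat = math.log(a0 / a1) / ((1.0 + u) * dt_gen)
    return EstimateResult(
        s_hat=s_hat,
        u=u,
        mu_implied=u * s_hat,
        alpha0=a0,
        alpha1=a1,
        odds0=odds(obs.y0),
        odds1=odds(obs.y1),
        dt_generations=dt_gen,
        case_id=obs.case_id,
    )


def tradeoff_curve(
    obs: TwoPointObservation, u_grid: Sequence[float]
) -> list[EstimateResult]:
    """The mutation-selection trade-off: one estimate per assumed ``u``.

    For a growing clone ``s_hat(u)`` is continuous and nonincreasing in ``u``;
    each point carries its implied mutation rate ``u * s_hat(u)``.
    """
    return [estimate_s_given_u(obs, u) for u in u_grid]


def sensitivity_to_lambda(
    obs: TwoPointObservation, lambda_values: Sequence[float], u: float = 0.0
) -> list[EstimateResult]:
    """Re-estimate under alternative division rates; ``s_hat`` scales as 1/lambda."""
    out = []
    for lam in lambda_values:
        if lam <= 0:
            raise InvalidParameterError(f"lambda must be > 0, got {lam!r}")
        out.append(estimate_s_given_u(replace(obs, lam=lam), u))
    return out


def read_observations(path) -> list[TwoPointObservation]:
    """Load observations from a CSV with columns (case_id, y0, y1, dt_years, lambda
    [, phase, mutation, source])."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"input CSV is missing columns: {missing}")
    obs = []
    for _, row in df.iterrows():
        kwargs = {opt: str(row[opt]) for opt in _CSV_OPTIONAL if opt in df.columns}
        obs.append(
            TwoPointObservation(
                y0=float(row["y0"]),
                y1=float(row["y1"]),
                dt_years=float(row["dt_years"]),
                lam=float(row["lambda"]),
                case_id=str(row["case_id"]),
                **kwargs,
            )
        )
    return obs


def estimates_to_frame(
    observations: Sequence[TwoPointObservation],
    results: Sequence[EstimateResult],
) -> pd.DataFrame:
    """Tabulate observations with their appended estimate columns."""
    rows = []
    for o, r in zip(observations, results):
        rows.append(
            {
                "case_id": o.case_id,
                "y0": o.y0,
                "y1": o.y1,
                "dt_years": o.dt_years,
                "lambda": o.lam,
                "phase": o.phase,
                "mutation": o.mutation,
                "source": o.source,
                "odds0": r.odds0,
                "odds1": r.odds1,
                "dt_generations": r.dt_generations,
                "s_hat": r.s_hat,
                "mu_implied": r.mu_implied,
            }
        )
    return pd.DataFrame(rows)
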