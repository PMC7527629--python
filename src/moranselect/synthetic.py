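"""Synthetic two-time-point observations with known ground truth.

The generator reproduces the statistical structure the estimator assumes: a
Moran trajectory with known ``(N, s, mu)`` started at a target frequency,
sampled at two times ``lam * dt_years`` generations apart.  Optionally the two
frequencies are observed through binomial sampling at a finite read depth — a
simple stand-in for sequencing-based variant-allele-frequency calls (the
clinical sources report no noise model, so this stand-in is the package's own
addition; the default depth is infinite, i.e. noise-free).

Observed frequencies exactly at 0 or 1 are outside the estimator's open domain;
finite-depth draws that land there are redrawn (and counted), while a
trajectory truly absorbed at 0 (possible when ``mu = 0``) or at ``N`` is
signalled as unusable rather than clamped, since clamping would bias recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import TwoPointObservation, estimate_s_given_u
from .moran import InvalidParameterError, ModelParams
from .simulate import initial_count_from_frequency, simulate_counts_on_grid

__all__ = [
    "BoundaryObservationError",
    "SyntheticScenario",
    "generate_observation",
    "recovery_experiment",
]

_MAX_REDRAWS = 1000


class BoundaryObservationError(RuntimeError):
    """The trajectory hit an absorbing boundary; no usable two-point observation."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth conditions for one batch of synthetic observations.

    ``read_depth=None`` means noise-free observation of the true frequencies.
    """

    true_params: ModelParams
    y0_target: float = 0.2
    dt_years: float = 1.0
    lam: float = 24.0
    read_depth: int | None = None
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.y0_target < 1.0:
            raise InvalidParameterError(
                f"y0_target must be in (0, 1), got {self.y0_target!r}"
            )
        if self.read_depth is not None and self.read_depth < 1:
            raise InvalidParameterError("read_depth must be >= 1 or None")
        if self.dt_years <= 0 or self.lam <= 0:
            raise InvalidParameterError("dt_years and lam must be > 0")
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")


def _observe(rng: np.random.Generator, true_y: float, depth: int | None) -> tuple[float, int]:
    """Observed frequency and number of boundary redraws."""
    if depth is None:
        return true_y, 0
    for attempt in range(_MAX_REDRAWS):
        y = rng.binomial(depth, true_y) / depth
        if 0.0 < y < 1.0:
            return y, attempt
    raise BoundaryObservationError(
        f"could not draw an interior frequency at depth {depth} for y={true_y}"
    )


def generate_observation(
    scn: SyntheticScenario, rep_index: int
) -> TwoPointObservation:
    """One synthetic observation: simulate, sample at both times, observe.

    Reproducible: the replicate's RNG stream is derived from ``(scn.seed,
    rep_index)`` only.
    """
    params = scn.true_params
    N = params.N
    i0 = initial_count_from_frequency(scn.y0_target, N)
    ss = np.random.SeedSequence((scn.seed, rep_index))
    sim_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
    rng = np.random.default_rng(ss.spawn(1)[0])

    dt_gen = scn.lam * scn.dt_years
    i1 = int(simulate_counts_on_grid(params, i0, [dt_gen], sim_seed)[0])
    true_y0, true_y1 = i0 / N, i1 / N

    if scn.read_depth is None:
        if true_y1 <= 0.0:
            raise BoundaryObservationError(
                "trajectory went extinct before the second sampling (mu = 0)"
            )
        if true_y1 >= 1.0 or true_y0 >= 1.0 or true_y0 <= 0.0:
            raise BoundaryObservationError(
                "trajectory at an absorbing boundary; observation unusable"
            )
        y0_obs, y1_obs = true_y0, true_y1
    else:
        if not (0.0 < true_y0 < 1.0) or not (0.0 < true_y1 < 1.0):
            raise BoundaryObservationError(
                "true frequency at a boundary; finite-depth redraws cannot fix it"
            )
        y0_obs, _ = _observe(rng, true_y0, scn.read_depth)
        y1_obs, _ = _observe(rng, true_y1, scn.read_depth)

    return TwoPointObservation(
        y0=y0_obs,
        y1=y1_obs,
        dt_years=scn.dt_years,
        lam=scn.lam,
        case_id=f"synthetic-{rep_index}",
        phase="unclassified",
        mutation="synthetic",
        source="synthetic",
    )


def recovery_experiment(
    s_values, scn_template: SyntheticScenario, u: float = 0.0
) -> pd.DataFrame:
    """Bias/RMSE of the estimator across replicates, per true ``s``.

    For each true ``s`` the template scenario is rerun with that selection
    coefficient; every replicate goes through generate -> estimate at the given
    ``u``.  Replicates lost to absorbing boundaries are counted, not imputed.
    """
    rows = []
    for s_true in s_values:
        params = ModelParams(
            N=scn_template.true_params.N, s=s_true, mu=scn_template.true_params.mu
        )
        scn = SyntheticScenario(
            true_params=params,
            y0_target=scn_template.y0_target,
            dt_years=scn_template.dt_years,
            lam=scn_template.lam,
            read_depth=scn_template.read_depth,
            n_reps=scn_template.n_reps,
            seed=scn_template.seed,
        )
        estimates = []
        n_unusable = 0
        for rep in range(scn.n_reps):
            try:
                obs = generate_observation(scn, rep)
            except BoundaryObservationError:
                n_unusable += 1
                continue
            estimates.append(estimate_s_given_u(obs, u).s_hat)
        est = np.asarray(estimates)
        rows.append(
            {
                "s_true": s_true,
                "n_used": est.size,
                "n_unusable": n_unusable,
                "mean_s_hat": est.mean() if est.size else math.nan,
                "median_s_hat": float(np.median(est)) if est.size else math.nan,
                "bias": est.mean() - s_true if est.size else math.nan,
                "rmse": float(np.sqrt(np.mean((est - s_true) ** 2)))
                if est.size
                else math.nan,
                "sd": est.std(ddof=1) if est.size > 1 else math.nan,
                "q05": float(np.quantile(est, 0.05)) if est.size else math.nan,
                "q95": float(np.quantile(est, 0.95)) if est.size else math.nan,
            }
        )
    return pd.DataFrame(rows)
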