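"""Exact stochastic simulation of the time-continuous Moran chain.

The sampler is the classical exact algorithm for finite-state Markov jump
processes: from state ``i`` draw an exponential holding time with rate
``q_up + q_down`` (see :func:`moranselect.moran.continuous_rates`), then jump up
with probability ``q_up / (q_up + q_down)``.

Two execution paths are provided:

* :func:`simulate_trajectory` records every jump (sparse jump times + states) and
  is meant for small problems and for inspecting individual sample paths;
* :func:`simulate_counts_on_grid` / :func:`ensemble_summary` evaluate the chain on
  a fixed time grid inside a compiled (numba) loop without storing jumps, which is
  the only practical route for ensembles at ``N ~ 10^4`` over hundreds of
  generations (~10^6 jumps per replicate).

Replicate seeds are spawned deterministically from one master seed, so ensembles
are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .moran import InvalidParameterError, ModelParams, continuous_rates

__all__ = [
    "RunawaySimulationError",
    "Trajectory",
    "EnsembleSummary",
    "initial_count_from_frequency",
    "simulate_trajectory",
    "sample_at_times",
    "simulate_counts_on_grid",
    "ensemble_summary",
]


class RunawaySimulationError(RuntimeError):
    """The event-count cap was exceeded; parameters are probably off scale."""


@dataclass(frozen=True)
class Trajectory:
    """One realized sample path, stored sparsely.

    ``states[k]`` is the mutant count immediately after the jump at
    ``jump_times[k]``; the count before the first jump is ``initial_count``.
    The path is defined (piecewise constant, right-continuous) on
    ``[0, horizon]`` where ``horizon`` is ``t_max``, or infinity if the chain
    was absorbed before ``t_max``.
    """

    jump_times: np.ndarray
    states: np.ndarray
    params: ModelParams
    initial_count: int
    t_max: float
    seed: int | None = None
    absorbed: bool = field(default=False)

    @property
    def horizon(self) -> float:
        return math.inf if self.absorbed else self.t_max

    def frequencies(self) -> np.ndarray:
        return self.states / self.params.N


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean and standard deviation of the mutant frequency across replicates."""

    t_grid: np.ndarray
    mean_freq: np.ndarray
    sd_freq: np.ndarray
    n_reps: int


def initial_count_from_frequency(y0: float, N: int) -> int:
    """Nearest-integer mutant count for a target initial frequency."""
    if not 0.0 <= y0 <= 1.0:
        raise InvalidParameterError(f"y0 must be in [0, 1], got {y0!r}")
    return int(round(y0 * N))


def _default_event_cap(N: int, t_max: float) -> int:
    # ~N/2 events per generation is the worst-case jump rate scale; 10*N*t_max
    # is a generous ceiling.  For open-ended (absorption) runs fall back to a
    # fixed large cap.
    if math.isfinite(t_max):
        return max(1000, int(10 * N * t_max))
    return 100_000_000


def simulate_trajectory(
    params: ModelParams,
    i0: int,
    t_max: float,
    seed: int | None = None,
    max_events: int | None = None,
) -> Trajectory:
    """Simulate one sample path, recording every jump.

    Stops at ``t_max``, or earlier when the total jump rate vanishes
    (absorption at ``N``; or at ``0`` when ``mu = 0``).  Identical seeds give
    identical trajectories.
    """
    N = params.N
    if not 0 <= i0 <= N:
        raise InvalidParameterError(f"i0={i0} outside [0, N={N}]")
    if not t_max > 0:
        raise InvalidParameterError(f"t_max must be > 0, got {t_max!r}")
    cap = _default_event_cap(N, t_max) if max_events is None else max_events

    rng = np.random.default_rng(seed)
    times: list[float] = []
    states: list[int] = []
    t, i = 0.0, i0
    absorbed = False
    while True:
        q_up, q_down = continuous_rates(i, params)
        total = q_up + q_down
        if total <= 0.0:
            absorbed = True
            break
        t = t + rng.exponential(1.0 / total)
        if t > t_max:
            break
        i = i + 1 if rng.random() * total < q_up else i - 1
        times.append(t)
        states.append(i)
        if len(times) > cap:
            raise RunawaySimulationError(
                f"more than {cap} events before t_max={t_max}; "
                "raise max_events if the parameters are intentional"
            )
    return Trajectory(
        jump_times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=np.int64),
        params=params,
        initial_count=i0,
        t_max=t_max,
        seed=seed,
        absorbed=absorbed,
    )


def sample_at_times(traj: Trajectory, t_grid) -> np.ndarray:
    """Mutant counts at each grid time (right-continuous step interpolation)."""
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t < 0) or np.any(t > traj.horizon):
        raise InvalidParameterError(
            f"sampling times must lie in [0, {traj.horizon}]"
        )
    # index 0 -> before first jump
    idx = np.searchsorted(traj.jump_times, t, side="right")
    path = np.concatenate(([traj.initial_count], traj.states))
    return path[idx]


@njit(cache=True)
def _grid_kernel(N, s, mu, i0, t_grid, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    n = t_grid.shape[0]
    out = np.empty(n, dtype=np.int64)
    t = 0.0
    i = i0
    k = 0
    while k < n:
        q_up = (N - i) * i / N + mu * (N - i)
        q_down = i * (1.0 - s) * (N - i) / N
        total = q_up + q_down
        if total <= 0.0:
            break
        t_next = t + np.random.exponential(1.0 / total)
        while k < n and t_grid[k] < t_next:
            out[k] = i
            k += 1
        t = t_next
        if np.random.random() * total < q_up:
            i += 1
        else:
            i -= 1
    while k < n:
        out[k] = i
        k += 1
    return out


def _spawn_seeds(master_seed: int | None, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)


def simulate_counts_on_grid(
    params: ModelParams, i0: int, t_grid, seed: int
) -> np.ndarray:
    """Mutant counts of one replicate evaluated on ``t_grid`` (compiled path).

    Equivalent in law to ``sample_at_times(simulate_trajectory(...), t_grid)``
    but never materializes the jump sequence.
    """
    N = params.N
    if not 0 <= i0 <= N:
        raise InvalidParameterError(f"i0={i0} outside [0, N={N}]")
    t = np.ascontiguousarray(np.asarray(t_grid, dtype=float))
    if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
        raise InvalidParameterError("t_grid must be nondecreasing and >= 0")
    return _grid_kernel(N, params.s, params.mu, i0, t, np.uint32(seed))


def ensemble_summary(
    params: ModelParams,
    i0: int,
    t_grid,
    n_reps: int,
    seed: int | None = None,
) -> EnsembleSummary:
    """Mean and SD of the mutant frequency over ``n_reps`` replicates.

    Per-replicate seeds are spawned from the master seed; the SD is the
    population standard deviation across replicates at each grid point (zero
    when ``n_reps == 1``).
    """
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1, got {n_reps!r}")
    t = np.asarray(t_grid, dtype=float)
    seeds = _spawn_seeds(seed, n_reps)
    freqs = np.empty((n_reps, t.size), dtype=float)
    for r in range(n_reps):
        freqs[r] = simulate_counts_on_grid(params, i0, t, int(seeds[r])) / params.N
    return EnsembleSummary(
        t_grid=t,
        mean_freq=freqs.mean(axis=0),
        sd_freq=freqs.std(axis=0, ddof=0),
        n_reps=n_reps,
    )
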