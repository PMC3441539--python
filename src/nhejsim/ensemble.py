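"""Replicate ensembles: rejoining-time statistics, parameter sweeps, kinetics.

Reproduces the model's ensemble experiments:

* rejoining-time statistics with min/max fluctuation bars over replicate
  stochastic runs;
* sweeps of the mean rejoining time over nuclear volume, residue release
  rate, initial fragment number and fixed fragment length;
* the mean-of-means rejoining-time surface over the two short-fragment
  fractions (q1, q2);
* mean fraction-remaining kinetics P(t), the quantity compared with
  repair-foci time courses, including the biphasic low/high-LET presets.

Every ensemble is fully determined by its master seed: replicate ``i`` of
an experiment uses an RNG seeded from ``SeedSequence((master_seed..., i))``,
so tables are reproducible run to run and independent of execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .distributions import FragmentDistribution, fixed_length, fraction_pair
from .gillespie import rejoining_time, simulate
from .state_model import SimParams

__all__ = [
    "EnsembleSummary",
    "KineticsCurve",
    "SWEEPABLE",
    "fraction_surface",
    "mean_kinetics",
    "parameter_sweep",
    "replicate_times",
]

logger = logging.getLogger(__name__)

SeedLike = Union[int, Tuple[int, ...]]


def _seed_tuple(master_seed: SeedLike) -> Tuple[int, ...]:
    if isinstance(master_seed, tuple):
        return master_seed
    return (int(master_seed),)


def replicate_rng(master_seed: SeedLike, i: int) -> np.random.Generator:
    """RNG for replicate ``i``: seeded from ``(master_seed, i)``."""
    return np.random.default_rng(np.random.SeedSequence(_seed_tuple(master_seed) + (i,)))


@dataclass(frozen=True)
class EnsembleSummary:
    """Rejoining-time statistics at one parameter point."""

    parameter: Optional[str]
    value: Optional[float]
    n_samples: int
    times: np.ndarray
    mean: float
    min: float
    max: float
    se: float

    @classmethod
    def from_times(
        cls, times: np.ndarray, parameter: Optional[str] = None, value=None
    ) -> "EnsembleSummary":
        times = np.asarray(times, dtype=float)
        n = times.size
        se = float(times.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return cls(
            parameter=parameter,
            value=value,
            n_samples=n,
            times=times,
            mean=float(times.mean()),
            min=float(times.min()),
            max=float(times.max()),
            se=se,
        )


@dataclass(frozen=True)
class KineticsCurve:
    """Mean fraction of remaining fragments P(t) on a time grid."""

    times: np.ndarray
    p_mean: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "P_mean": self.p_mean})


def replicate_times(
    dist: FragmentDistribution,
    params: SimParams,
    n_samples: int,
    master_seed: SeedLike,
    parameter: Optional[str] = None,
    value=None,
) -> EnsembleSummary:
    """Rejoining times over ``n_samples`` independent SSA runs.

    Every replicate must complete; a stall in default mode signals an
    engine bug and is raised, not swallowed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if params.t_max is not None:
        params = params.with_(t_max=None)  # rejoining times need completion
    times = np.empty(n_samples)
    for i in range(n_samples):
        traj = simulate(dist, params, replicate_rng(master_seed, i))
        times[i] = rejoining_time(traj)
    return EnsembleSummary.from_times(times, parameter=parameter, value=value)


def mean_kinetics(
    dist: FragmentDistribution,
    params: SimParams,
    n_samples: int,
    time_grid: Sequence[float],
    master_seed: SeedLike,
) -> KineticsCurve:
    """Mean fraction-remaining curve P(t) = <count(t)> / count(0).

    Each replicate's fragment count is sampled by the last event at or
    before each grid point; irreparable fragments never join, so with them
    included P(t) plateaus at or above the irreparable fraction.
    """
    grid = np.asarray(list(time_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(np.diff(grid) < 0) or grid[0] < 0:
        raise ValueError("time grid must be non-negative and sorted")
    horizon = float(grid[-1])
    if params.t_max is None or params.t_max < horizon:
        params = params.with_(t_max=horizon)
    acc = np.zeros(grid.size)
    for i in range(n_samples):
        traj = simulate(dist, params, replicate_rng(master_seed, i))
        acc += traj.counts_at(grid) / traj.m0_total
    return KineticsCurve(times=grid, p_mean=acc / n_samples, n_samples=n_samples)


#: Sweepable parameters: nuclear volume, release rate, fragment number,
#: fixed fragment length.
SWEEPABLE = ("V", "k_r", "M0", "fixed_length_n")


def parameter_sweep(
    params: SimParams,
    m0: int,
    length_n: int,
    parameter: str,
    values: Sequence[float],
    n_samples: int,
    master_seed: SeedLike,
) -> pd.DataFrame:
    """Mean rejoining time vs one parameter, all else fixed.

    The baseline is a fixed-length population of ``m0`` fragments of
    ``length_n`` bp. ``parameter`` is one of :data:`SWEEPABLE`. Returns a
    table sorted by value with columns
    (parameter, value, n_samples, mean, min, max, se).
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {SWEEPABLE}")
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    rows = []
    base_seed = _seed_tuple(master_seed)
    for k, value in enumerate(sorted(values)):
        point_params, point_m0, point_n = params, m0, length_n
        if parameter == "V":
            point_params = params.with_(V=float(value))
        elif parameter == "k_r":
            point_params = params.with_(k_r=float(value))
        elif parameter == "M0":
            point_m0 = int(value)
        else:
            point_n = int(value)
        dist = fixed_length(point_m0, point_n, point_params)
        summary = replicate_times(
            dist, point_params, n_samples, base_seed + (k,),
            parameter=parameter, value=value,
        )
        logger.info(
            "sweep %s=%g: mean=%.4g se=%.3g (n=%d)",
            parameter, value, summary.mean, summary.se, n_samples,
        )
        rows.append(
            (parameter, value, n_samples, summary.mean, summary.min,
             summary.max, summary.se)
        )
    return pd.DataFrame(
        rows, columns=["parameter", "value", "n_samples", "mean", "min", "max", "se"]
    )


def fraction_surface(
    params: SimParams,
    m0: int,
    q1_grid: Sequence[float],
    q2_grid: Sequence[float],
    n_distributions: int,
    n_samples: int,
    master_seed: SeedLike,
    long_max: int = 3000,
) -> pd.DataFrame:
    """Mean-of-means rejoining time T(q1, q2) over the short-fraction simplex.

    For each feasible grid point, ``n_distributions`` distributions are
    sampled with :func:`~nhejsim.distributions.fraction_pair`, each
    summarised by ``n_samples`` replicates, and the per-distribution means
    averaged. Infeasible points (q1 + q2 > 1) are skipped with a warning.
    """
    rows = []
    base_seed = _seed_tuple(master_seed)
    point = 0
    for q1 in q1_grid:
        for q2 in q2_grid:
            if q1 + q2 > 1 + 1e-12:
                logger.warning("skipping infeasible fraction pair (%g, %g)", q1, q2)
                continue
            means = np.empty(n_distributions)
            for d in range(n_distributions):
                dist = fraction_pair(
                    m0, q1, q2,
                    seed=np.random.SeedSequence(base_seed + (point, d)),
                    params=params, long_max=long_max,
                )
                means[d] = replicate_times(
                    dist, params, n_samples, base_seed + (point, d, 1)
                ).mean
            rows.append((q1, q2, float(means.mean()), n_distributions, n_samples))
            point += 1
    return pd.DataFrame(
        rows, columns=["q1", "q2", "mean_time", "n_distributions", "n_samples"]
    )
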