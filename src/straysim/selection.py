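"""Fitness landscapes, Gaussian stabilizing selection, and Ricker density
dependence.

Each generation draws a fresh bivariate optimum (return day, RLS) around the
fixed long-run means -- independent draws, not a random walk, so distinct
demes keep distinct long-run optima.  Expected reproductive success is a
diagonal bivariate Gaussian in the distance from the optimum, scaled by
``w_max``; it is then down-weighted by a Ricker factor ``exp(beta * N_day)``
where ``N_day`` is the number of fish present in the stream on the day the
individual returns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import as_seed_sequence, child_seed
from .params import SimulationParams
from .population import Cohort

__all__ = [
    "FitnessLandscape",
    "draw_optima",
    "expected_rs",
    "daily_abundance",
    "density_day",
    "density_adjust",
    "calibrate_wmax",
    "CalibrationResult",
]


@dataclass(frozen=True)
class FitnessLandscape:
    """One generation's selection surface: optima, widths, and height."""

    theta_return: float
    theta_rls: float
    sel_sd_return: float
    sel_sd_rls: float
    w_max: float

    def __post_init__(self) -> None:
        if not (self.sel_sd_return > 0 and self.sel_sd_rls > 0):
            raise ValueError("selection SDs must be > 0")
        if not self.w_max > 0:
            raise ValueError("w_max must be > 0")


def draw_optima(
    params: SimulationParams,
    rng: np.random.Generator,
    theta: tuple[float, float] | None = None,
) -> FitnessLandscape:
    """Draw this generation's optima around the long-run means.

    theta_return ~ N(mu_return_natural, env_var_return) and
    theta_rls ~ N(mu_rls, env_var_rls), independently each generation.
    Pass ``theta`` to pin the optima instead (used for synchronous
    environments and analytic limits).
    """
    if theta is None:
        theta_return = params.mu_return_natural + rng.standard_normal() * np.sqrt(
            params.env_var_return
        )
        theta_rls = params.mu_rls + rng.standard_normal() * np.sqrt(
            params.env_var_rls
        )
    else:
        theta_return, theta_rls = theta
    return FitnessLandscape(
        theta_return=float(theta_return),
        theta_rls=float(theta_rls),
        sel_sd_return=float(np.sqrt(params.selection_var_return)),
        sel_sd_rls=float(np.sqrt(params.selection_var_rls)),
        w_max=params.w_max,
    )


def expected_rs(cohort: Cohort, landscape: FitnessLandscape) -> np.ndarray:
    """Expected reproductive success of every individual under the Gaussian
    landscape.  Selection reads only the two phenotypes -- never origin -- so
    strays and wild fish face the identical regime."""
    zd = (cohort.return_day - landscape.theta_return) / landscape.sel_sd_return
    zl = (cohort.rls - landscape.theta_rls) / landscape.sel_sd_rls
    return landscape.w_max * np.exp(-0.5 * (zd * zd + zl * zl))


def _presence_window(
    return_day: np.ndarray, rls: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First and last integer day of the half-open presence interval
    [return_day, return_day + rls)."""
    first = np.ceil(return_day).astype(np.int64)
    last = np.ceil(return_day + rls).astype(np.int64) - 1
    return first, last


def daily_abundance(cohort: Cohort, season_length: float) -> np.ndarray:
    """Number of fish present in the stream on each integer day.

    Returns an array indexable by day: ``counts[t]`` for t = 1..season_length
    (``counts[0]`` is unused and zero).  A fish is present from its return
    day through the end of its reproductive lifespan, half-open.
    """
    n_days = int(season_length)
    counts = np.zeros(n_days + 2, dtype=np.int64)
    if len(cohort) == 0:
        return counts[: n_days + 1]
    first, last = _presence_window(cohort.return_day, cohort.rls)
    first = np.clip(first, 1, n_days + 1)
    stop = np.clip(last, 0, n_days) + 1
    np.add.at(counts, first, 1)
    np.add.at(counts, stop, -1)
    return np.cumsum(counts)[: n_days + 1]


def density_day(cohort: Cohort, season_length: float) -> np.ndarray:
    """Integer census day assigned to each fish for the Ricker term: the
    first integer day of its presence window (its arrival day)."""
    first, _ = _presence_window(cohort.return_day, cohort.rls)
    return np.clip(first, 1, int(season_length))


def density_adjust(
    expected: np.ndarray,
    cohort: Cohort,
    abundance: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Ricker adjustment: RS'_i = RS_i * exp(beta * N_day_i).

    ``abundance`` must come from the same merged (natural + stray) cohort, so
    strays both compete and are competed against.  With beta <= 0 the factor
    never exceeds 1.
    """
    if beta > 0:
        warnings.warn(
            "beta > 0 amplifies reproductive success with density and can "
            "produce runaway growth",
            stacklevel=2,
        )
    if len(cohort) == 0:
        return expected.copy()
    season_length = len(abundance) - 1
    day = density_day(cohort, season_length)
    return expected * np.exp(beta * abundance[day])


@dataclass(frozen=True)
class CalibrationResult:
    w_max: float
    mean_final_nc: float
    target_nc: float
    n_pilot: int
    trajectory_mean: np.ndarray  # mean census per generation at the returned w_max
    history: tuple  # (w_max, mean_final_nc) per bisection step


def _pilot_mean_trajectory(
    params: SimulationParams, w_max: float, n_pilot: int, ss: np.random.SeedSequence
) -> np.ndarray:
    """Mean natural census per generation over pilot replicates at a given
    w_max (pHOS = 0, hatchery influx off)."""
    from . import simulate  # deferred: simulate imports this module
    from .params import replace

    pilot = replace(
        params,
        phos=0.0,
        w_max=w_max,
        n_generations_total=params.n_generations_hatchery,
    )
    n_gen = pilot.n_generations_total
    total = np.zeros(n_gen + 1)
    for r in range(n_pilot):
        summaries = simulate.run_replicate(pilot, child_seed(ss, r))
        total += np.array([s.nc_natural for s in summaries])
    return total / n_pilot


def calibrate_wmax(
    params: SimulationParams,
    target_nc: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    n_pilot: int = 50,
    bracket: tuple[float, float] = (1.5, 6.0),
    rel_tol: float = 0.10,
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisect w_max so that the mean final census of a no-hatchery pilot
    population sits within ``rel_tol`` of ``target_nc`` (default nc_initial).

    The same pilot seeds are reused at every candidate w_max (common random
    numbers), which makes the mean final census monotone in w_max and the
    whole procedure deterministic given ``seed``.
    """
    if target_nc is None:
        target_nc = params.nc_initial
    ss = as_seed_sequence(seed)
    lo, hi = bracket
    history = []

    def final_nc(w: float) -> float:
        traj = _pilot_mean_trajectory(params, w, n_pilot, ss)
        history.append((w, float(traj[-1])))
        return float(traj[-1])

    f_lo, f_hi = final_nc(lo), final_nc(hi)
    if not (f_lo < target_nc < f_hi):
        raise RuntimeError(
            "calibration bracket failure: mean final census "
            f"{f_lo:.1f} at w_max={lo} and {f_hi:.1f} at w_max={hi} do not "
            f"bracket the target {target_nc}; pilot history {history}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = final_nc(mid)
        if abs(f_mid - target_nc) <= rel_tol * target_nc:
            traj = _pilot_mean_trajectory(params, mid, n_pilot, ss)
            return CalibrationResult(
                w_max=mid,
                mean_final_nc=f_mid,
                target_nc=float(target_nc),
                n_pilot=n_pilot,
                trajectory_mean=traj,
                history=tuple(history),
            )
        if f_mid < target_nc:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge in {max_iter} bisection steps; "
        f"history {history}"
    )
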