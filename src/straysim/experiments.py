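"""Output metrics and the four preset experiment grids.

Experiment 1 sweeps hatchery return-timing mismatch and reads out the
relative reproductive success (RRS) of strays; Experiment 2 sweeps pHOS x
mismatch and tracks the natural-origin census; Experiment 3 tracks the mean
proportion of hatchery-origin ancestry (pHOA) carried by stream-born fish;
Experiment 4 runs six-deme metapopulations with a common hatchery return
day and reads out within-deme mean return days and the among-deme
coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import MetapopulationParams, SimulationParams, default_params, replace
from .simulate import (
    MetapopulationResult,
    ScenarioResult,
    cv_percent,
    run_metapopulation,
    run_scenario,
)

__all__ = [
    "ExperimentGrid",
    "build_grid",
    "rrs_summary",
    "trajectory_summary",
    "phoa_summary",
    "cv_among_demes",
    "cv_percent",
    "scenario_params",
    "analytic_limit_params",
    "run_experiment",
]

logger = logging.getLogger(__name__)

DEME_OPTIMA = (5.0, 10.0, 13.0, 15.0, 17.0, 20.0)
SHARED_HATCHERY_MEAN = 13.0


@dataclass(frozen=True)
class ExperimentGrid:
    experiment_id: int
    metric: str
    scenarios: tuple  # SimulationParams or MetapopulationParams per cell


def scenario_params(
    phos: float,
    hatchery_mean: float | None = None,
    *,
    n_generations: int | None = None,
    base: SimulationParams | None = None,
    **overrides,
) -> SimulationParams:
    """A single-stream scenario: defaults with pHOS and, optionally, the
    hatchery mean return day and total generation count overridden."""
    p = base if base is not None else default_params()
    fields = dict(phos=phos, **overrides)
    if hatchery_mean is not None:
        fields["mu_return_hatchery"] = float(hatchery_mean)
    if n_generations is not None:
        fields["n_generations_total"] = int(n_generations)
    return replace(p, **fields)


def analytic_limit_params(
    mismatch: float,
    *,
    phos: float = 0.2,
    nc_initial: int = 500,
) -> SimulationParams:
    """The zero-phenotypic-variance limit in which realized RRS equals the
    Gaussian fitness ratio exp(-mismatch^2 / (2 (omega sigma_return)^2)).

    Trait variances shrink to a point mass while the selection widths stay
    pinned at their default values (omega^2 * 20 and omega^2 * 10 days^2);
    environmental variance and density dependence are switched off; the
    reproductive lifespan is long enough that the wild and hatchery point
    masses always overlap in the stream; and the mate cap is effectively
    infinite, so the mating pool is complete bipartite and the expected
    realized-RS ratio reduces exactly to the pair-weight ratio.  One spawning
    event per replicate (no introgression feedback).
    """
    base = default_params()
    return replace(
        base,
        phos=phos,
        mu_return_natural=10.0,
        mu_return_hatchery=10.0 + mismatch,
        mu_rls=60.0,
        var_return=1e-6,
        var_rls=1e-6,
        env_var_return=0.0,
        env_var_rls=0.0,
        beta=0.0,
        lambda_mates=1e4,
        sel_var_return=base.omega**2 * base.var_return,
        sel_var_rls=base.omega**2 * base.var_rls,
        nc_initial=nc_initial,
        n_generations_total=1,
        n_generations_hatchery=1,
        burn_in=0,
    )


def build_grid(experiment_id: int) -> ExperimentGrid:
    """The exact scenario grid of one of the four experiments, everything
    else at defaults."""
    if experiment_id == 1:
        scenarios = tuple(
            scenario_params(0.2, mu_h) for mu_h in (10.0, 15.0, 20.0, 25.0)
        )
        return ExperimentGrid(1, "rrs", scenarios)
    if experiment_id == 2:
        scenarios = tuple(
            scenario_params(phos, mu_h)
            for phos in (0.0, 0.01, 0.1, 0.3)
            for mu_h in (15.0, 20.0, 25.0)
        )
        return ExperimentGrid(2, "nc_natural", scenarios)
    if experiment_id == 3:
        scenarios = tuple(
            scenario_params(phos, mu_h)
            for phos in (0.01, 0.1, 0.3)
            for mu_h in (15.0, 20.0, 25.0)
        )
        return ExperimentGrid(3, "phoa", scenarios)
    if experiment_id == 4:
        scenarios = tuple(
            MetapopulationParams.default(
                phos=phos,
                deme_optima=DEME_OPTIMA,
                hatchery_mean=SHARED_HATCHERY_MEAN,
            )
            for phos in (0.0, 0.1, 0.2, 0.3)
        )
        return ExperimentGrid(4, "mean_return_day", scenarios)
    raise ValueError(f"unknown experiment id {experiment_id!r} (expected 1-4)")


def _ci_mean(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, ci_low, ci_high) of a sample, normal approximation."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return float("nan"), float("nan"), float("nan")
    m = float(np.mean(finite))
    if finite.size < 2:
        return m, float("nan"), float("nan")
    half = 1.96 * float(np.std(finite, ddof=1)) / np.sqrt(finite.size)
    return m, m - half, m + half


def rrs_summary(
    result: ScenarioResult, burn_in: int | None = None
) -> tuple[float, float, float]:
    """Scenario-level RRS of hatchery strays: mean over post-burn-in hatchery
    generations within each replicate, then across replicates with a 95% CI.

    RRS uses realized (pedigree) offspring counts.  Generations with a zero
    natural mean RS are skipped (NaN) and logged.
    """
    params = result.params
    if params.phos <= 0:
        raise ValueError("RRS is undefined for a scenario without strays")
    if burn_in is None:
        burn_in = params.burn_in
    lo_g = burn_in + 1
    hi_g = params.n_generations_hatchery
    if lo_g > hi_g:
        raise ValueError("burn-in leaves no hatchery generations to average")
    rrs = result.fields["rrs"][:, lo_g : hi_g + 1]
    n_bad = int(np.sum(~np.isfinite(rrs)))
    if n_bad:
        logger.info("rrs_summary: skipped %d generation(s) with undefined RRS", n_bad)
    with np.errstate(invalid="ignore"):
        per_replicate = np.nanmean(rrs, axis=1)
    return _ci_mean(per_replicate)


def trajectory_summary(
    result: ScenarioResult, generation: int
) -> tuple[float, float, float]:
    """Across-replicate mean (with 95% CI) of the natural-origin census at
    one generation."""
    return _ci_mean(result.fields["nc_natural"][:, generation])


def phoa_summary(
    result: ScenarioResult, generation: int
) -> tuple[float, float, float]:
    """Across-replicate mean (with 95% CI) of the mean hatchery-origin
    ancestry of stream-born fish at one generation."""
    return _ci_mean(result.fields["phoa"][:, generation])


def cv_among_demes(
    mp_result: MetapopulationResult, generation: int
) -> tuple[float, float, float]:
    """Across-replicate mean (with 95% CI) of the among-deme coefficient of
    variation (percent, sample-SD convention) of deme mean return days."""
    return _ci_mean(mp_result.cv_return_day[:, generation])


def run_experiment(
    experiment_id: int,
    replicates: int = 200,
    base_seed: int = 0,
    workers: int = 1,
) -> pd.DataFrame:
    """Run a full experiment grid and return one tidy summary row per cell
    (per deme for Experiment 4), evaluated at the last hatchery generation
    and the final generation."""
    grid = build_grid(experiment_id)
    rows = []
    for cell, scen in enumerate(grid.scenarios):
        if isinstance(scen, MetapopulationParams):
            res = run_metapopulation(scen, replicates, base_seed + cell, workers=workers)
            p0 = scen.deme_params[0]
            gens = (p0.n_generations_hatchery, p0.n_generations_total)
            for g in gens:
                m, lo, hi = cv_among_demes(res, g)
                rows.append(
                    dict(
                        experiment=4,
                        phos=p0.phos,
                        mu_return_hatchery=p0.mu_return_hatchery,
                        deme_optimum=np.nan,
                        generation=g,
                        metric="cv_return_day",
                        mean=m,
                        ci_low=lo,
                        ci_high=hi,
                        n_replicates=replicates,
                        extinction_fraction=float(
                            res.any_deme_extinct[:, g].mean()
                        ),
                    )
                )
                for d, deme_res in enumerate(res.deme_results):
                    dm, dlo, dhi = _ci_mean(
                        deme_res.fields["mean_return_natural"][:, g]
                    )
                    rows.append(
                        dict(
                            experiment=4,
                            phos=p0.phos,
                            mu_return_hatchery=p0.mu_return_hatchery,
                            deme_optimum=scen.deme_optima[d],
                            generation=g,
                            metric="mean_return_day",
                            mean=dm,
                            ci_low=dlo,
                            ci_high=dhi,
                            n_replicates=replicates,
                            extinction_fraction=float(
                                deme_res.extinction_fraction()[g]
                            ),
                        )
                    )
            continue
        res = run_scenario(scen, replicates, base_seed + cell, workers=workers)
        gens = (scen.n_generations_hatchery, scen.n_generations_total)
        if grid.metric == "rrs" and scen.phos > 0:
            m, lo, hi = rrs_summary(res)
            rows.append(
                dict(
                    experiment=experiment_id,
                    phos=scen.phos,
                    mu_return_hatchery=scen.mu_return_hatchery,
                    deme_optimum=np.nan,
                    generation=np.nan,
                    metric="rrs",
                    mean=m,
                    ci_low=lo,
                    ci_high=hi,
                    n_replicates=replicates,
                    extinction_fraction=float(res.extinction_fraction()[-1]),
                )
            )
        for g in gens:
            if grid.metric == "phoa":
                m, lo, hi = phoa_summary(res, g)
                metric = "phoa"
            else:
                m, lo, hi = trajectory_summary(res, g)
                metric = "nc_natural"
            rows.append(
                dict(
                    experiment=experiment_id,
                    phos=scen.phos,
                    mu_return_hatchery=scen.mu_return_hatchery,
                    deme_optimum=np.nan,
                    generation=g,
                    metric=metric,
                    mean=m,
                    ci_low=lo,
                    ci_high=hi,
                    n_replicates=replicates,
                    extinction_fraction=float(res.extinction_fraction()[g]),
                )
            )
    return pd.DataFrame(rows)
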