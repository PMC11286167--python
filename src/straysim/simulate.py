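"""Generation loop for single streams and metapopulations.

One spawning event: stray influx (rounded pHOS product of the returning
natural census), merge, draw this generation's optima, Gaussian selection,
Ricker density adjustment on the merged cohort, temporal mating-pool
construction, recruit count, weighted parentage, midparent inheritance and
ancestry propagation.  Stream-born offspring are always "natural-origin" in
the next generation, regardless of ancestry.

Indexing convention: "generation g" denotes the stream-born cohort produced
by spawning event g (events 1..n_generations_total; strays join events
1..n_generations_hatchery).  Generation 0 is the founder cohort.
"""

from __future__ import annotations

import dataclasses
import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_seed_sequence, child_rng, child_seed
from .mating import assign_parentage, build_pool, inherit, propagate_ancestry, recruit_count
from .params import MetapopulationParams, SimulationParams
from .population import HATCHERY, NATURAL, Cohort, balanced_sexes, init_founders, make_strays, merge
from .selection import daily_abundance, density_adjust, draw_optima, expected_rs


@contextmanager
def _quiet_nan():
    """Silence the benign all-NaN / empty-slice warnings raised when a
    generation has no strays or no surviving replicates."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore",
            r".*(empty slice|[Dd]egrees of freedom|invalid value).*",
            RuntimeWarning,
        )
        with np.errstate(invalid="ignore"):
            yield

__all__ = [
    "GenerationSummary",
    "ScenarioResult",
    "MetapopulationResult",
    "cv_percent",
    "step_generation",
    "run_replicate",
    "run_scenario",
    "run_metapopulation",
]


@dataclass
class GenerationSummary:
    """Per-generation scalars: the stream-born cohort this event produced,
    the strays that joined the event, and the event's landscape and fitness
    outcomes."""

    generation: int
    nc_natural: int
    n_strays: int
    mean_return_natural: float
    var_return_natural: float
    mean_rls_natural: float
    var_rls_natural: float
    mean_return_hatchery: float
    var_return_hatchery: float
    mean_rls_hatchery: float
    var_rls_hatchery: float
    phoa: float
    rrs: float
    mean_rs_natural: float
    mean_rs_hatchery: float
    theta_return: float
    theta_rls: float
    extinct: bool


_TRAIT_FIELDS = (
    "mean_return_natural",
    "var_return_natural",
    "mean_rls_natural",
    "var_rls_natural",
    "mean_return_hatchery",
    "var_return_hatchery",
    "mean_rls_hatchery",
    "var_rls_hatchery",
    "phoa",
    "rrs",
    "mean_rs_natural",
    "mean_rs_hatchery",
)

_SUMMARY_FIELDS = tuple(f.name for f in dataclasses.fields(GenerationSummary))


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else float("nan")


def _var(x: np.ndarray) -> float:
    return float(np.var(x)) if x.size else float("nan")


def _founder_summary(cohort: Cohort) -> GenerationSummary:
    return GenerationSummary(
        generation=0,
        nc_natural=len(cohort),
        n_strays=0,
        mean_return_natural=_mean(cohort.return_day),
        var_return_natural=_var(cohort.return_day),
        mean_rls_natural=_mean(cohort.rls),
        var_rls_natural=_var(cohort.rls),
        mean_return_hatchery=float("nan"),
        var_return_hatchery=float("nan"),
        mean_rls_hatchery=float("nan"),
        var_rls_hatchery=float("nan"),
        phoa=_mean(cohort.ancestry),
        rrs=float("nan"),
        mean_rs_natural=float("nan"),
        mean_rs_hatchery=float("nan"),
        theta_return=float("nan"),
        theta_rls=float("nan"),
        extinct=False,
    )


def step_generation(
    cohort_natural: Cohort,
    params: SimulationParams,
    hatchery_on: bool,
    rng: np.random.Generator,
    generation: int = 1,
    theta: tuple[float, float] | None = None,
) -> tuple[Cohort, GenerationSummary]:
    """Run one spawning event and return (offspring cohort, summary)."""
    if hatchery_on and params.phos > 0:
        strays = make_strays(len(cohort_natural), params, rng)
    else:
        strays = Cohort.empty()
    merged = merge(cohort_natural, strays)

    landscape = draw_optima(params, rng, theta=theta)
    rs = expected_rs(merged, landscape)
    abundance = daily_abundance(merged, params.season_length)
    rs_adj = density_adjust(rs, merged, abundance, params.beta)
    merged.expected_rs = rs_adj

    pool = build_pool(merged, rs_adj, params.lambda_mates, rng)
    n_recruits = recruit_count(
        rs_adj,
        params.carrying_capacity,
        rng,
        n_pairs=pool.size,
        dialect=params.recruit_dialect,
    )
    dam, sire = assign_parentage(pool, n_recruits, rng)
    realized = np.bincount(dam, minlength=len(merged)) + np.bincount(
        sire, minlength=len(merged)
    )
    merged.realized_rs = realized

    n_off = dam.size
    dam_traits = np.column_stack([merged.return_day[dam], merged.rls[dam]])
    sire_traits = np.column_stack([merged.return_day[sire], merged.rls[sire]])
    traits = (
        inherit(dam_traits, sire_traits, params, rng)
        if n_off
        else np.empty((0, 2))
    )
    offspring = Cohort(
        return_day=traits[:, 0],
        rls=traits[:, 1],
        sex=balanced_sexes(n_off, rng),
        origin=np.full(n_off, NATURAL, dtype=np.uint8),
        ancestry=propagate_ancestry(merged.ancestry[dam], merged.ancestry[sire]),
        dam_index=dam.astype(np.int64),
        sire_index=sire.astype(np.int64),
    )

    is_stray = merged.origin == HATCHERY
    nat_rs = realized[~is_stray]
    hat_rs = realized[is_stray]
    mean_nat = _mean(nat_rs)
    mean_hat = _mean(hat_rs)
    rrs = mean_hat / mean_nat if (hat_rs.size and mean_nat > 0) else float("nan")
    summary = GenerationSummary(
        generation=generation,
        nc_natural=n_off,
        n_strays=len(strays),
        mean_return_natural=_mean(offspring.return_day),
        var_return_natural=_var(offspring.return_day),
        mean_rls_natural=_mean(offspring.rls),
        var_rls_natural=_var(offspring.rls),
        mean_return_hatchery=_mean(strays.return_day),
        var_return_hatchery=_var(strays.return_day),
        mean_rls_hatchery=_mean(strays.rls),
        var_rls_hatchery=_var(strays.rls),
        phoa=_mean(offspring.ancestry),
        rrs=rrs,
        mean_rs_natural=mean_nat,
        mean_rs_hatchery=mean_hat,
        theta_return=landscape.theta_return,
        theta_rls=landscape.theta_rls,
        extinct=False,
    )
    return offspring, summary


def _frozen_summary(last: GenerationSummary, generation: int) -> GenerationSummary:
    """Post-extinction padding: census frozen, trait fields NaN so that
    across-replicate trait means exclude dead replicates."""
    frozen = dataclasses.replace(last, generation=generation, n_strays=0, extinct=True)
    for name in _TRAIT_FIELDS:
        setattr(frozen, name, float("nan"))
    frozen.theta_return = float("nan")
    frozen.theta_rls = float("nan")
    return frozen


def run_replicate(
    params: SimulationParams,
    seed: int | np.random.SeedSequence,
    theta_sequence: np.ndarray | None = None,
) -> list[GenerationSummary]:
    """One replicate: generations 0..n_generations_total.

    Hatchery influx is on for events 1..n_generations_hatchery (if pHOS > 0)
    and off afterwards.  The loop halts -- summaries padded, extinct flag set
    -- once the stream-born census falls below the extinction threshold.
    ``theta_sequence`` (shape (n_generations_total + 1, 2)) pins each event's
    optima; row g is used by event g.
    """
    ss = as_seed_sequence(seed)
    cohort = init_founders(params, child_rng(ss, 0))
    summaries = [_founder_summary(cohort)]
    extinct = False
    for g in range(1, params.n_generations_total + 1):
        if extinct:
            summaries.append(_frozen_summary(summaries[-1], g))
            continue
        theta = None
        if theta_sequence is not None:
            theta = (float(theta_sequence[g, 0]), float(theta_sequence[g, 1]))
        offspring, summary = step_generation(
            cohort,
            params,
            hatchery_on=g <= params.n_generations_hatchery,
            rng=child_rng(ss, g),
            generation=g,
            theta=theta,
        )
        if summary.nc_natural < params.extinction_threshold:
            summary.extinct = True
            extinct = True
        summaries.append(summary)
        cohort = offspring
    return summaries


@dataclass
class ScenarioResult:
    """Replicate x generation stack of summaries for one scenario."""

    fields: dict[str, np.ndarray]  # each (n_replicates, n_generations + 1)
    params: SimulationParams
    base_seed: int | None
    n_replicates: int
    metadata: dict

    def array(self, name: str) -> np.ndarray:
        return self.fields[name]

    def mean(self, name: str) -> np.ndarray:
        """Across-replicate mean per generation (NaN-aware)."""
        with _quiet_nan():
            return np.nanmean(self.fields[name], axis=0)

    def ci(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Normal-approximation 95% CI of the across-replicate mean."""
        x = self.fields[name]
        with _quiet_nan():
            m = np.nanmean(x, axis=0)
            sd = np.nanstd(x, axis=0, ddof=1)
        n = np.sum(np.isfinite(x), axis=0)
        half = 1.96 * sd / np.sqrt(np.maximum(n, 1))
        return m - half, m + half

    def extinction_fraction(self) -> np.ndarray:
        return self.fields["extinct"].mean(axis=0)

    def equals(self, other: "ScenarioResult") -> bool:
        """Bitwise equality of all stored trajectories."""
        if set(self.fields) != set(other.fields):
            return False
        return all(
            np.array_equal(self.fields[k], other.fields[k], equal_nan=True)
            for k in self.fields
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format replicate x generation trajectories."""
        n_rep, n_gen = self.fields["nc_natural"].shape
        rep = np.repeat(np.arange(n_rep), n_gen)
        out = {"replicate": rep}
        for name, arr in self.fields.items():
            out[name] = arr.reshape(-1)
        frame = pd.DataFrame(out)
        frame["generation"] = np.tile(np.arange(n_gen), n_rep)
        cols = ["replicate", "generation"] + [
            c for c in frame.columns if c not in ("replicate", "generation")
        ]
        return frame[cols]

    def summary_frame(self) -> pd.DataFrame:
        """Across-replicate mean and 95% CI per generation and output."""
        rows = []
        n_gen = self.fields["nc_natural"].shape[1]
        for name in self.fields:
            if name in ("generation", "extinct"):
                continue
            m = self.mean(name)
            lo, hi = self.ci(name)
            rows.append(
                pd.DataFrame(
                    {
                        "generation": np.arange(n_gen),
                        "output": name,
                        "mean": m,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            )
        frame = pd.concat(rows, ignore_index=True)
        frame["n_replicates"] = self.n_replicates
        return frame


def _stack(replicates: list[list[GenerationSummary]]) -> dict[str, np.ndarray]:
    fields: dict[str, np.ndarray] = {}
    for name in _SUMMARY_FIELDS:
        if name == "generation":
            continue
        dtype = bool if name == "extinct" else float
        fields[name] = np.array(
            [[getattr(s, name) for s in rep] for rep in replicates], dtype=dtype
        )
    return fields


def run_scenario(
    params: SimulationParams,
    replicates: int,
    base_seed: int | np.random.SeedSequence = 0,
    workers: int = 1,
    theta_deviations: np.ndarray | None = None,
) -> ScenarioResult:
    """Run ``replicates`` independent replicates of one scenario.

    Replicate r consumes the child stream (base_seed, r) regardless of
    worker count or execution order, so results are bitwise reproducible.
    ``theta_deviations`` (replicates, n_generations_total + 1, 2) pins each
    replicate's environmental deviations around the long-run means (used for
    synchronous metapopulation environments).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = as_seed_sequence(base_seed)

    def sequence_for(r: int) -> np.ndarray | None:
        if theta_deviations is None:
            return None
        dev = theta_deviations[r]
        means = np.array([params.mu_return_natural, params.mu_rls])
        return means[None, :] + dev

    def one(r: int) -> list[GenerationSummary]:
        return run_replicate(params, child_seed(ss, r), sequence_for(r))

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(one)(r) for r in range(replicates)
        )
    else:
        results = [one(r) for r in range(replicates)]
    return ScenarioResult(
        fields=_stack(results),
        params=params,
        base_seed=ss.entropy if isinstance(ss.entropy, int) else None,
        n_replicates=replicates,
        metadata={
            "recruit_dialect": params.recruit_dialect,
            "trait_bounds": params.trait_bounds,
            "w_max": params.w_max,
        },
    )


def cv_percent(values, ddof: int = 1) -> float:
    """Coefficient of variation in percent, sample-SD (n-1) convention by
    default; NaN entries (extinct demes) are excluded."""
    values = np.asarray(values, dtype=float)
    with _quiet_nan():
        return float(100.0 * np.nanstd(values, ddof=ddof) / np.nanmean(values))


@dataclass
class MetapopulationResult:
    """Per-deme scenario results plus among-deme diversity outputs."""

    deme_results: list[ScenarioResult]
    mp: MetapopulationParams
    cv_return_day: np.ndarray  # (replicates, generations + 1), percent
    any_deme_extinct: np.ndarray  # (replicates, generations + 1) flag

    @property
    def n_demes(self) -> int:
        return len(self.deme_results)

    def mean_cv(self) -> np.ndarray:
        with _quiet_nan():
            return np.nanmean(self.cv_return_day, axis=0)

    def cv_ci(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.cv_return_day
        with _quiet_nan():
            m = np.nanmean(x, axis=0)
            sd = np.nanstd(x, axis=0, ddof=1)
        n = np.sum(np.isfinite(x), axis=0)
        half = 1.96 * sd / np.sqrt(np.maximum(n, 1))
        return m - half, m + half


def run_metapopulation(
    mp: MetapopulationParams,
    replicates: int,
    base_seed: int | np.random.SeedSequence = 0,
    synchronous_env: bool = False,
    workers: int = 1,
) -> MetapopulationResult:
    """Run every deme independently (no dispersal) and compute the
    per-replicate among-deme coefficient of variation of deme mean return
    days (sample-SD convention, percent).

    Environmental optimum deviations are independent across demes by
    default; ``synchronous_env=True`` makes all demes share each
    generation's deviations within a replicate.
    """
    ss = as_seed_sequence(base_seed)
    theta_dev = None
    if synchronous_env:
        n_gen = mp.deme_params[0].n_generations_total
        p0 = mp.deme_params[0]
        sds = np.sqrt([p0.env_var_return, p0.env_var_rls])
        theta_dev = np.empty((replicates, n_gen + 1, 2))
        for r in range(replicates):
            rng = child_rng(ss, 1_000_000, r)
            theta_dev[r] = rng.standard_normal((n_gen + 1, 2)) * sds
    deme_results = [
        run_scenario(
            p,
            replicates,
            base_seed=child_seed(ss, d),
            workers=workers,
            theta_deviations=theta_dev,
        )
        for d, p in enumerate(mp.deme_params)
    ]
    means = np.stack(
        [res.fields["mean_return_natural"] for res in deme_results]
    )  # (demes, replicates, generations + 1)
    with _quiet_nan():
        cv = 100.0 * np.nanstd(means, axis=0, ddof=1) / np.nanmean(means, axis=0)
    any_extinct = np.any(
        np.stack([res.fields["extinct"] for res in deme_results]), axis=0
    )
    return MetapopulationResult(
        deme_results=deme_results,
        mp=mp,
        cv_return_day=cv,
        any_deme_extinct=any_extinct,
    )
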