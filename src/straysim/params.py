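"""Simulation parameters: defaults, validation, and flat-file config I/O.

Single source of truth for every scalar the simulator consumes.  The default
values describe a Prince William Sound-like pink salmon stream: a 45-day
spawning season, a founder census of 500 wild adults, return-day and
reproductive-lifespan (RLS) phenotypes with moderate negative correlation,
moderately strong stabilizing selection (omega = 2 phenotypic SD), weak
Ricker density dependence, and a hard habitat cap of 4000 recruits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SimulationParams",
    "MetapopulationParams",
    "CALIBRATED_W_MAX",
    "default_params",
    "load_config",
    "save_config",
    "serialize",
    "replace",
]

#: Maximum expected offspring of an individual sitting exactly on the
#: bivariate fitness optimum at zero density.  Produced once by
#: :func:`straysim.selection.calibrate_wmax` (pHOS = 0 pilots, bisection to a
#: mean generation-25 census within +/-10% of ``nc_initial``) and frozen here
#: so that the default parameterization yields an approximately stable wild
#: population before any hatchery influence.
CALIBRATED_W_MAX = 2.748046875

_BOUNDS_DIALECTS = ("clip", "resample")
_RECRUIT_DIALECTS = ("round", "poisson")


@dataclass(frozen=True)
class SimulationParams:
    """All scalar inputs for a single-stream simulation.

    Trait units are days (day-of-season for return timing, days of stream
    life for RLS); variances are days^2.  ``mu_return_natural`` doubles as the
    long-run optimum return day of the local fitness landscape.
    """

    #: Proportion of hatchery-origin spawners joining each generation.
    phos: float = 0.2
    #: Initial wild mean return day; also the long-run optimum return day.
    mu_return_natural: float = 10.0
    #: Hatchery mean return day, identical every generation.
    mu_return_hatchery: float = 20.0
    #: Mean reproductive lifespan (days), both origins; long-run RLS optimum.
    mu_rls: float = 7.0
    #: Phenotypic variance of return day (days^2).
    var_return: float = 20.0
    #: Phenotypic variance of RLS (days^2).
    var_rls: float = 10.0
    #: Phenotypic correlation between return day and RLS.
    rho: float = -0.3
    #: Width of the stabilizing-selection curve, in phenotypic SD multiples.
    omega: float = 2.0
    #: Interannual variance of the optimal return day (days^2).
    env_var_return: float = 20.0
    #: Interannual variance of the optimal RLS (days^2).
    env_var_rls: float = 1.0
    #: Poisson mean/variance of the per-female maximum mate number.
    lambda_mates: float = 2.0
    #: Ricker density-dependence strength (per fish present).
    beta: float = -1e-5
    #: Founder census size.
    nc_initial: int = 500
    #: Hard cap on recruits per generation (spawning-habitat limitation).
    carrying_capacity: int = 4000
    #: Census floor below which a population is functionally extinct.
    extinction_threshold: int = 50
    #: Spawning season duration (days).
    season_length: float = 45.0
    #: Number of generations with hatchery influx.
    n_generations_hatchery: int = 25
    #: Total generations per replicate.
    n_generations_total: int = 50
    #: Expected offspring at the optimum and zero density (calibrated).
    w_max: float = CALIBRATED_W_MAX
    #: Segregation covariance = seg_cov_scale * P (infinitesimal inheritance).
    seg_cov_scale: float = 0.5
    #: Generations excluded from RRS averaging.
    burn_in: int = 5
    #: Default RNG seed.
    seed: int = 0
    #: Optional override of the squared selection width for return day
    #: (days^2); ``None`` means ``omega**2 * var_return``.
    sel_var_return: float | None = None
    #: Optional override of the squared selection width for RLS (days^2).
    sel_var_rls: float | None = None
    #: Out-of-bounds trait draws: "clip" (default) or "resample".
    trait_bounds: str = "clip"
    #: Recruit-count rule: deterministic "round" (default) or "poisson".
    recruit_dialect: str = "round"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def P(self) -> np.ndarray:
        """2x2 phenotypic variance-covariance matrix of (return day, RLS)."""
        cov = self.rho * np.sqrt(self.var_return * self.var_rls)
        return np.array([[self.var_return, cov], [cov, self.var_rls]])

    @property
    def selection_var_return(self) -> float:
        """Squared selection width for return day, (omega * sigma)^2."""
        if self.sel_var_return is not None:
            return float(self.sel_var_return)
        return self.omega**2 * self.var_return

    @property
    def selection_var_rls(self) -> float:
        """Squared selection width for RLS."""
        if self.sel_var_rls is not None:
            return float(self.sel_var_rls)
        return self.omega**2 * self.var_rls

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValueError` naming the first offending field."""
        if not 0.0 <= self.phos <= 1.0:
            raise ValueError(f"phos must be in [0, 1], got {self.phos}")
        for name in ("var_return", "var_rls", "env_var_return", "env_var_rls"):
            value = getattr(self, name)
            if not value > 0 and name.startswith("var"):
                raise ValueError(f"{name} must be > 0, got {value}")
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not abs(self.rho) < 1.0:
            raise ValueError(f"rho must satisfy |rho| < 1, got {self.rho}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if not self.season_length > 0:
            raise ValueError(f"season_length must be > 0, got {self.season_length}")
        if self.carrying_capacity < self.nc_initial:
            raise ValueError(
                "carrying_capacity must be >= nc_initial, got "
                f"{self.carrying_capacity} < {self.nc_initial}"
            )
        if self.extinction_threshold >= self.nc_initial:
            raise ValueError(
                "extinction_threshold must be < nc_initial, got "
                f"{self.extinction_threshold} >= {self.nc_initial}"
            )
        if self.lambda_mates < 0:
            raise ValueError(f"lambda_mates must be >= 0, got {self.lambda_mates}")
        if not self.w_max > 0:
            raise ValueError(f"w_max must be > 0, got {self.w_max}")
        if self.seg_cov_scale < 0:
            raise ValueError(f"seg_cov_scale must be >= 0, got {self.seg_cov_scale}")
        if self.n_generations_hatchery < 0 or self.n_generations_total < 1:
            raise ValueError("generation counts must be positive")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")
        for name in ("sel_var_return", "sel_var_rls"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be > 0 when set, got {value}")
        if self.trait_bounds not in _BOUNDS_DIALECTS:
            raise ValueError(
                f"trait_bounds must be one of {_BOUNDS_DIALECTS}, got {self.trait_bounds!r}"
            )
        if self.recruit_dialect not in _RECRUIT_DIALECTS:
            raise ValueError(
                f"recruit_dialect must be one of {_RECRUIT_DIALECTS}, "
                f"got {self.recruit_dialect!r}"
            )
        # symmetric positive definiteness of P
        eigvals = np.linalg.eigvalsh(self.P)
        if not np.all(eigvals > 0):
            raise ValueError(
                f"P built from (var_return, var_rls, rho) is not positive definite: "
                f"eigenvalues {eigvals}"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MetapopulationParams:
    """A set of independent spawning streams (demes) sharing every parameter
    except the local wild mean return day / return-day optimum.

    The default mirrors a six-stream basin with optima spread over days 5-20
    and a single hatchery source returning, on average, on day 13 everywhere.
    """

    deme_params: tuple[SimulationParams, ...]

    def __post_init__(self) -> None:
        if len(self.deme_params) < 2:
            raise ValueError("a metapopulation needs at least 2 demes")
        ref = self.deme_params[0].to_dict()
        for i, p in enumerate(self.deme_params[1:], start=1):
            d = p.to_dict()
            for key, value in d.items():
                if key == "mu_return_natural":
                    continue
                if value != ref[key]:
                    raise ValueError(
                        f"deme {i} differs from deme 0 in shared field {key!r}"
                    )

    @property
    def n_demes(self) -> int:
        return len(self.deme_params)

    @property
    def deme_optima(self) -> tuple[float, ...]:
        return tuple(p.mu_return_natural for p in self.deme_params)

    @property
    def shared_hatchery_mean(self) -> float:
        return self.deme_params[0].mu_return_hatchery

    @classmethod
    def default(
        cls,
        phos: float = 0.2,
        deme_optima: tuple[float, ...] = (5.0, 10.0, 13.0, 15.0, 17.0, 20.0),
        hatchery_mean: float = 13.0,
        base: SimulationParams | None = None,
        **overrides,
    ) -> "MetapopulationParams":
        base = base if base is not None else default_params()
        base = replace(
            base, phos=phos, mu_return_hatchery=hatchery_mean, **overrides
        )
        return cls(
            deme_params=tuple(
                replace(base, mu_return_natural=float(opt)) for opt in deme_optima
            )
        )


def default_params(**overrides) -> SimulationParams:
    """Return the default parameter set, optionally overriding fields."""
    return SimulationParams(**overrides)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationParams)}


def load_config(path: str | Path) -> SimulationParams:
    """Load parameters from a flat YAML/JSON mapping.

    Unknown keys are rejected; missing keys fall back to the defaults; the
    resulting parameter set is validated.  An empty file yields the defaults.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationParams(**data)


def serialize(params: SimulationParams) -> str:
    """Serialize parameters to a YAML document that round-trips exactly."""
    return yaml.safe_dump(params.to_dict(), sort_keys=True)


def save_config(params: SimulationParams, path: str | Path) -> None:
    Path(path).write_text(serialize(params))
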