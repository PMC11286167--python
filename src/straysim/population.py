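"""Cohorts of spawners: founders, hatchery strays, and concatenation.

A :class:`Cohort` is a column-oriented record of every adult present in a
spawning season: the two phenotypes (return day, reproductive lifespan),
sex, origin (stream-born "natural" vs. hatchery stray that arrived this
generation), hatchery-origin ancestry proportion, expected and realized
reproductive success, and parent pointers for stream-born fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SimulationParams

__all__ = [
    "FEMALE",
    "MALE",
    "NATURAL",
    "HATCHERY",
    "Cohort",
    "init_founders",
    "make_strays",
    "merge",
    "balanced_sexes",
    "sample_traits",
]

FEMALE = np.uint8(0)
MALE = np.uint8(1)
NATURAL = np.uint8(0)
HATCHERY = np.uint8(1)


@dataclass
class Cohort:
    return_day: np.ndarray  # day-of-season, continuous
    rls: np.ndarray  # reproductive lifespan, days
    sex: np.ndarray  # FEMALE / MALE codes
    origin: np.ndarray  # NATURAL / HATCHERY codes
    ancestry: np.ndarray  # hatchery-origin ancestry proportion in [0, 1]
    expected_rs: np.ndarray = field(default=None)  # type: ignore[assignment]
    realized_rs: np.ndarray = field(default=None)  # type: ignore[assignment]
    dam_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    sire_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.return_day)
        if self.expected_rs is None:
            self.expected_rs = np.zeros(n)
        if self.realized_rs is None:
            self.realized_rs = np.zeros(n, dtype=np.int64)
        if self.dam_index is None:
            self.dam_index = np.full(n, -1, dtype=np.int64)
        if self.sire_index is None:
            self.sire_index = np.full(n, -1, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.return_day)

    @property
    def n_females(self) -> int:
        return int(np.count_nonzero(self.sex == FEMALE))

    @property
    def n_hatchery(self) -> int:
        return int(np.count_nonzero(self.origin == HATCHERY))

    @classmethod
    def empty(cls) -> "Cohort":
        z = np.empty(0)
        return cls(
            return_day=z.copy(),
            rls=z.copy(),
            sex=np.empty(0, dtype=np.uint8),
            origin=np.empty(0, dtype=np.uint8),
            ancestry=z.copy(),
        )

    def to_frame(self, generation: int | None = None, deme: int | None = None) -> pd.DataFrame:
        """Tidy per-individual snapshot (one row per fish)."""
        frame = pd.DataFrame(
            {
                "sex": np.where(self.sex == FEMALE, "female", "male"),
                "origin": np.where(self.origin == HATCHERY, "hatchery", "natural"),
                "return_day": self.return_day,
                "rls": self.rls,
                "ancestry": self.ancestry,
                "expected_rs": self.expected_rs,
                "realized_rs": self.realized_rs,
                "dam": self.dam_index,
                "sire": self.sire_index,
            }
        )
        if generation is not None:
            frame.insert(0, "generation", generation)
        if deme is not None:
            frame.insert(0, "deme", deme)
        return frame


def balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly balanced sexes by random permutation: floor(n/2) females,
    the odd fish (if any) male."""
    sexes = np.full(n, MALE, dtype=np.uint8)
    sexes[: n // 2] = FEMALE
    return rng.permutation(sexes)


def _bounded(
    traits: np.ndarray, params: SimulationParams, redraw, rng: np.random.Generator
) -> np.ndarray:
    """Apply the out-of-bounds dialect: return day in [1, season_length],
    RLS >= 1.  ``redraw(rows)`` must return fresh draws for those rows."""
    if params.trait_bounds == "resample":
        for _ in range(100):
            bad = (
                (traits[:, 0] < 1.0)
                | (traits[:, 0] > params.season_length)
                | (traits[:, 1] < 1.0)
            )
            rows = np.flatnonzero(bad)
            if rows.size == 0:
                break
            traits[rows] = redraw(rows)
    traits[:, 0] = np.clip(traits[:, 0], 1.0, params.season_length)
    traits[:, 1] = np.maximum(traits[:, 1], 1.0)
    return traits


def sample_traits(
    mean: np.ndarray,
    params: SimulationParams,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n (return_day, rls) pairs ~ bivariate Gaussian(mean, P), then
    apply the season bounds (clip by default)."""
    chol = np.linalg.cholesky(params.P)

    def draw(k: int) -> np.ndarray:
        return mean + rng.standard_normal((k, 2)) @ chol.T

    traits = draw(n)
    return _bounded(traits, params, lambda rows: draw(rows.size), rng)


def init_founders(params: SimulationParams, rng: np.random.Generator) -> Cohort:
    """Founder cohort: nc_initial natural-origin fish, traits centered on the
    wild means, ancestry 0, exactly balanced sexes."""
    n = params.nc_initial
    mean = np.array([params.mu_return_natural, params.mu_rls])
    traits = sample_traits(mean, params, n, rng)
    return Cohort(
        return_day=traits[:, 0],
        rls=traits[:, 1],
        sex=balanced_sexes(n, rng),
        origin=np.full(n, NATURAL, dtype=np.uint8),
        ancestry=np.zeros(n),
    )


def make_strays(
    nc_natural: int, params: SimulationParams, rng: np.random.Generator
) -> Cohort:
    """Hatchery strays for one generation.

    The influx is the rounded product of the returning natural census and
    pHOS.  Strays share the wild mean RLS and phenotypic covariance matrix;
    only their mean return day differs.  Ancestry is 1 for every stray.
    """
    if nc_natural < 0:
        raise ValueError(f"nc_natural must be >= 0, got {nc_natural}")
    n = int(np.rint(nc_natural * params.phos))
    if n == 0:
        return Cohort.empty()
    mean = np.array([params.mu_return_hatchery, params.mu_rls])
    traits = sample_traits(mean, params, n, rng)
    return Cohort(
        return_day=traits[:, 0],
        rls=traits[:, 1],
        sex=balanced_sexes(n, rng),
        origin=np.full(n, HATCHERY, dtype=np.uint8),
        ancestry=np.ones(n),
    )


def merge(cohort_a: Cohort, cohort_b: Cohort) -> Cohort:
    """Concatenate two cohorts (all fields preserved, size additive)."""
    return Cohort(
        return_day=np.concatenate([cohort_a.return_day, cohort_b.return_day]),
        rls=np.concatenate([cohort_a.rls, cohort_b.rls]),
        sex=np.concatenate([cohort_a.sex, cohort_b.sex]),
        origin=np.concatenate([cohort_a.origin, cohort_b.origin]),
        ancestry=np.concatenate([cohort_a.ancestry, cohort_b.ancestry]),
        expected_rs=np.concatenate([cohort_a.expected_rs, cohort_b.expected_rs]),
        realized_rs=np.concatenate([cohort_a.realized_rs, cohort_b.realized_rs]),
        dam_index=np.concatenate([cohort_a.dam_index, cohort_b.dam_index]),
        sire_index=np.concatenate([cohort_a.sire_index, cohort_b.sire_index]),
    )
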