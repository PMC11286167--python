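"""Temporal assortative mating, parentage, and infinitesimal inheritance.

Mating is assortative only through time: a dam and sire can pair only if
their stream presence windows [return_day, return_day + rls) intersect.
Each female draws a Poisson(lambda_mates) mate cap N_j and takes a uniform
without-replacement sample of N_j temporally overlapping males; each
candidate pair carries weight W_ij = RS'_dam * RS'_sire and offspring are
assigned to pairs by a categorical draw proportional to those weights.
Offspring traits are midparent plus bivariate Gaussian segregation noise
(infinitesimal model); ancestry is the parental mean.

Uniform mate sampling is implemented two ways behind :func:`build_pool`:
a dense random-key method over the full female x male matrix for small
cohorts (or very large mate caps), and a candidate-rejection method with an
exact per-female fallback for large cohorts.  Both produce exactly uniform
without-replacement samples of overlapping males; the switch is a
deterministic function of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimulationParams
from .population import FEMALE, MALE, Cohort, _bounded

__all__ = [
    "MatingPool",
    "overlaps",
    "build_pool",
    "recruit_count",
    "assign_parentage",
    "inherit",
    "propagate_ancestry",
]

#: Above this female x male product, pool construction switches from the
#: dense matrix method to candidate rejection sampling.
DENSE_PAIR_LIMIT = 250_000
#: Candidate draws per female in the rejection method.
N_CANDIDATES = 24


@dataclass
class MatingPool:
    """Candidate parent pairs for one spawning event.

    ``dam`` / ``sire`` index into the merged cohort; ``weight`` holds
    W_ij = RS'_dam * RS'_sire.  ``mate_cap`` is the Poisson draw N_j for each
    female in ``female_indices`` (before truncation to the number of
    overlapping males actually available).
    """

    dam: np.ndarray
    sire: np.ndarray
    weight: np.ndarray
    female_indices: np.ndarray
    male_indices: np.ndarray
    mate_cap: np.ndarray

    @property
    def size(self) -> int:
        return len(self.dam)

    @classmethod
    def empty(cls) -> "MatingPool":
        zi = np.empty(0, dtype=np.int64)
        return cls(
            dam=zi.copy(),
            sire=zi.copy(),
            weight=np.empty(0),
            female_indices=zi.copy(),
            male_indices=zi.copy(),
            mate_cap=zi.copy(),
        )


def overlaps(return_a, rls_a, return_b, rls_b):
    """True where presence intervals [d, d + rls) intersect with positive
    length.  Half-open: a fish arriving the day another departs does not
    overlap it.  Works on scalars or broadcastable arrays."""
    return (return_a < return_b + rls_b) & (return_b < return_a + rls_a)


def _pairs_dense(
    df: np.ndarray,
    lf: np.ndarray,
    dm: np.ndarray,
    lm: np.ndarray,
    caps: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform mate sampling via random keys over the full overlap matrix.
    Returns (row, local male index) for every selected pair."""
    ov = overlaps(df[:, None], lf[:, None], dm[None, :], lm[None, :])
    keys = rng.random(ov.shape)
    keys = np.where(ov, keys, np.inf)
    n_ov = ov.sum(axis=1)
    take = np.minimum(caps, n_ov)
    kmax = int(take.max()) if take.size else 0
    if kmax == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_m = dm.size
    if kmax >= n_m:
        part = np.argsort(keys, axis=1)[:, :kmax]
    else:
        part = np.argpartition(keys, kmax - 1, axis=1)[:, :kmax]
        sub = np.take_along_axis(keys, part, axis=1)
        order = np.argsort(sub, axis=1)
        part = np.take_along_axis(part, order, axis=1)
    mask = np.arange(kmax)[None, :] < take[:, None]
    rows = np.repeat(np.arange(df.size), take)
    return rows, part[mask]


def _pairs_candidates(
    df: np.ndarray,
    lf: np.ndarray,
    dm: np.ndarray,
    lm: np.ndarray,
    caps: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform mate sampling by rejection: draw candidate males with
    replacement, drop non-overlapping and repeated draws in draw order, keep
    the first N_j.  Sampling males uniformly with replacement and discarding
    misses/repeats reproduces sequential without-replacement sampling from
    the overlap set, so the kept sample is exactly uniform.  Females whose
    candidates are exhausted before reaching N_j fall back to an exact
    enumeration of their overlapping males."""
    n_f, n_m = df.size, dm.size
    cand = rng.integers(0, n_m, size=(n_f, n_candidates))
    ok = overlaps(df[:, None], lf[:, None], dm[cand], lm[cand])
    # order-preserving de-duplication within each row
    srt = np.argsort(cand, axis=1, kind="stable")
    sc = np.take_along_axis(cand, srt, axis=1)
    dup_sorted = np.zeros_like(ok)
    dup_sorted[:, 1:] = sc[:, 1:] == sc[:, :-1]
    dup = np.empty_like(dup_sorted)
    np.put_along_axis(dup, srt, dup_sorted, axis=1)
    ok &= ~dup
    rank = np.cumsum(ok, axis=1)
    sel = ok & (rank <= caps[:, None])
    got = sel.sum(axis=1)
    short = np.flatnonzero(got < caps)  # may have overlapping males unseen

    full = np.setdiff1d(np.arange(n_f), short, assume_unique=True)
    rows_list = [np.repeat(full, got[full])]
    sires_list = [cand[full][sel[full]]]
    for j in short:
        ovj = np.flatnonzero(overlaps(df[j], lf[j], dm, lm))
        if ovj.size > caps[j]:
            chosen = rng.choice(ovj, size=int(caps[j]), replace=False)
        else:
            chosen = ovj
        rows_list.append(np.full(chosen.size, j, dtype=np.int64))
        sires_list.append(chosen)
    return np.concatenate(rows_list), np.concatenate(sires_list)


def build_pool(
    cohort: Cohort,
    adjusted_rs: np.ndarray,
    lambda_mates: float,
    rng: np.random.Generator,
    *,
    dense_limit: int = DENSE_PAIR_LIMIT,
    n_candidates: int = N_CANDIDATES,
) -> MatingPool:
    """Assemble all candidate (dam, sire) pairs for one spawning event."""
    f_idx = np.flatnonzero(cohort.sex == FEMALE)
    m_idx = np.flatnonzero(cohort.sex == MALE)
    if f_idx.size == 0 or m_idx.size == 0:
        return MatingPool.empty()
    caps = rng.poisson(lambda_mates, f_idx.size)
    df, lf = cohort.return_day[f_idx], cohort.rls[f_idx]
    dm, lm = cohort.return_day[m_idx], cohort.rls[m_idx]
    use_dense = (
        f_idx.size * m_idx.size <= dense_limit or lambda_mates > n_candidates / 2
    )
    if use_dense:
        rows, sires_local = _pairs_dense(df, lf, dm, lm, caps, rng)
    else:
        rows, sires_local = _pairs_candidates(
            df, lf, dm, lm, caps, rng, n_candidates
        )
    dam = f_idx[rows]
    sire = m_idx[sires_local]
    weight = adjusted_rs[dam] * adjusted_rs[sire]
    return MatingPool(
        dam=dam,
        sire=sire,
        weight=weight,
        female_indices=f_idx,
        male_indices=m_idx,
        mate_cap=caps,
    )


def recruit_count(
    adjusted_rs: np.ndarray,
    carrying_capacity: int,
    rng: np.random.Generator | None = None,
    *,
    n_pairs: int | None = None,
    dialect: str = "round",
) -> int:
    """Recruits for the next generation: min(K, round(sum(RS') / 2)).

    The halving reflects that each expected offspring of a dam is also the
    expected offspring of some sire.  If the pool holds no pairs at all,
    recruitment fails entirely (0 recruits).  The "poisson" dialect draws
    R ~ Poisson(sum / 2) instead of rounding.
    """
    if n_pairs == 0:
        return 0
    total = float(np.sum(adjusted_rs)) / 2.0
    if dialect == "poisson":
        if rng is None:
            raise ValueError("poisson recruit dialect needs an rng")
        r = int(rng.poisson(total))
    else:
        r = int(np.rint(total))
    return min(r, int(carrying_capacity))


def assign_parentage(
    pool: MatingPool, n_recruits: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw each offspring's (dam, sire) from the categorical distribution
    over candidate pairs with probabilities W_ij / sum(W).

    Returns index arrays of length n_recruits (or empty on reproductive
    failure: no pairs, or all weights zero)."""
    empty = np.empty(0, dtype=np.int64)
    if n_recruits <= 0 or pool.size == 0:
        return empty, empty
    total = pool.weight.sum()
    if not total > 0:
        return empty, empty
    counts = rng.multinomial(n_recruits, pool.weight / total)
    reps = np.repeat(np.arange(pool.size), counts)
    return pool.dam[reps], pool.sire[reps]


def inherit(
    dam_traits: np.ndarray,
    sire_traits: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring (return_day, rls) ~ Gaussian(midparent, seg_cov_scale * P),
    bounded to the season as for sampled adults.  Accepts (n, 2) arrays or
    single trait pairs."""
    dam_traits = np.atleast_2d(np.asarray(dam_traits, dtype=float))
    sire_traits = np.atleast_2d(np.asarray(sire_traits, dtype=float))
    mid = 0.5 * (dam_traits + sire_traits)
    if params.seg_cov_scale == 0.0:
        traits = mid.copy()
    else:
        chol = np.linalg.cholesky(params.seg_cov_scale * params.P)

        def noisy(rows: np.ndarray) -> np.ndarray:
            return mid[rows] + rng.standard_normal((rows.size, 2)) @ chol.T

        traits = mid + rng.standard_normal(mid.shape) @ chol.T
        return _bounded(traits, params, noisy, rng)
    return _bounded(traits, params, lambda rows: mid[rows].copy(), rng)


def propagate_ancestry(dam_ancestry, sire_ancestry):
    """Offspring hatchery-origin ancestry = parental mean: a hatchery x wild
    cross yields exactly 0.5."""
    return (np.asarray(dam_ancestry) + np.asarray(sire_ancestry)) / 2.0
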