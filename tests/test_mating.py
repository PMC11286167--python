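"""Temporal overlap, mating-pool construction, parentage, inheritance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from straysim import assign_parentage, build_pool, default_params, inherit, overlaps, propagate_ancestry, recruit_count
from straysim.mating import MatingPool
from straysim.params import replace
from straysim.population import FEMALE, MALE, NATURAL, Cohort


def _cohort(return_day, rls, sex):
    return_day = np.asarray(return_day, dtype=float)
    n = return_day.size
    return Cohort(
        return_day=return_day,
        rls=np.asarray(rls, dtype=float),
        sex=np.asarray(sex, dtype=np.uint8),
        origin=np.full(n, NATURAL),
        ancestry=np.zeros(n),
    )


class TestOverlaps:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((10, 7), (16, 5), True),  # shared days 16-17
            ((10, 7), (17, 5), False),  # half-open boundary touch
            ((10, 7), (10, 7), True),  # reflexive
            ((1, 2), (3.5, 4), False),
            ((1, 3), (2.9, 4), True),
        ],
    )
    def test_examples(self, a, b, expected):
        assert bool(overlaps(a[0], a[1], b[0], b[1])) is expected
        assert bool(overlaps(b[0], b[1], a[0], a[1])) is expected  # symmetric

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        da=st.floats(1, 45), la=st.floats(1, 30),
        db=st.floats(1, 45), lb=st.floats(1, 30),
    )
    def test_matches_interval_intersection(self, da, la, db, lb):
        lo, hi = max(da, db), min(da + la, db + lb)
        assert bool(overlaps(da, la, db, lb)) == (hi - lo > 0)


class TestBuildPool:
    def test_two_by_two_weight_matrix_is_outer_product(self, rng):
        c = _cohort([10, 11, 10, 12], [7, 7, 7, 7], [FEMALE, FEMALE, MALE, MALE])
        rs = np.array([1.0, 2.0, 3.0, 5.0])
        # lambda large enough that every female draws all overlapping males
        pool = build_pool(c, rs, lambda_mates=1000.0, rng=rng)
        assert pool.size == 4
        got = sorted(pool.weight.tolist())
        assert got == sorted([1 * 3, 1 * 5, 2 * 3, 2 * 5])

    def test_empty_without_both_sexes(self, rng):
        c = _cohort([10, 11], [7, 7], [FEMALE, FEMALE])
        assert build_pool(c, np.ones(2), 2.0, rng).size == 0

    @pytest.mark.parametrize("dense_limit", [250_000, 0])
    def test_pool_invariants_random_cohorts(self, dense_limit, rng):
        p = default_params()
        for _ in range(20):
            n = int(rng.integers(5, 120))
            c = _cohort(
                rng.uniform(1, 45, n),
                rng.uniform(1, 12, n),
                rng.permutation(np.r_[np.zeros(n // 2), np.ones(n - n // 2)]).astype(np.uint8),
            )
            rs = rng.uniform(0.01, 3.0, n)
            pool = build_pool(c, rs, p.lambda_mates, rng, dense_limit=dense_limit)
            assert np.all(c.sex[pool.dam] == FEMALE)
            assert np.all(c.sex[pool.sire] == MALE)
            assert np.all(
                overlaps(
                    c.return_day[pool.dam], c.rls[pool.dam],
                    c.return_day[pool.sire], c.rls[pool.sire],
                )
            )
            assert np.allclose(pool.weight, rs[pool.dam] * rs[pool.sire])
            # per-female counts = min(cap, number of overlapping males)
            for cap, f in zip(pool.mate_cap, pool.female_indices):
                n_ov = int(
                    np.count_nonzero(
                        overlaps(
                            c.return_day[f], c.rls[f],
                            c.return_day[pool.male_indices], c.rls[pool.male_indices],
                        )
                    )
                )
                n_pairs = int(np.count_nonzero(pool.dam == f))
                assert n_pairs == min(int(cap), n_ov)
                # distinct sires only
                sires = pool.sire[pool.dam == f]
                assert len(set(sires.tolist())) == len(sires)

    def test_candidate_path_samples_mates_uniformly(self, rng):
        # one female, six interchangeable overlapping males; the selection
        # frequency of each male must be uniform under the rejection sampler
        c = _cohort(
            [10, 10, 10, 10, 10, 10, 10],
            [7, 7, 7, 7, 7, 7, 7],
            [FEMALE] + [MALE] * 6,
        )
        rs = np.ones(7)
        counts = np.zeros(7)
        for _ in range(3000):
            pool = build_pool(c, rs, 2.0, rng, dense_limit=0, n_candidates=4)
            np.add.at(counts, pool.sire, 1)
        male_counts = counts[1:]
        from scipy.stats import chisquare

        _, p_value = chisquare(male_counts)
        assert p_value > 1e-3


class TestRecruitCount:
    def test_rule_arithmetic(self):
        assert recruit_count(np.full(500, 2.0), 4000, n_pairs=9) == 500
        assert recruit_count(np.full(4500, 2.0), 4000, n_pairs=9) == 4000
        assert recruit_count(np.full(500, 2.0), 4000, n_pairs=0) == 0

    def test_poisson_dialect_mean(self, rng):
        draws = [
            recruit_count(
                np.full(100, 2.0), 4000, rng, n_pairs=9, dialect="poisson"
            )
            for _ in range(500)
        ]
        assert abs(np.mean(draws) - 100.0) < 3 * np.sqrt(100 / 500)


class TestAssignParentage:
    def _pool(self, weights):
        w = np.asarray(weights, dtype=float)
        k = w.size
        return MatingPool(
            dam=np.arange(k),
            sire=np.arange(k) + k,
            weight=w,
            female_indices=np.arange(k),
            male_indices=np.arange(k) + k,
            mate_cap=np.ones(k, dtype=np.int64),
        )

    def test_weighted_frequencies_chi_square(self, rng):
        from scipy.stats import chisquare

        pool = self._pool([3.0, 1.0])
        dam, _ = assign_parentage(pool, 10_000, rng)
        counts = np.bincount(dam, minlength=2)
        _, p_value = chisquare(counts, f_exp=[7500, 2500])
        assert p_value > 1e-3

    def test_single_pair_takes_everything(self, rng):
        dam, sire = assign_parentage(self._pool([2.5]), 50, rng)
        assert np.all(dam == 0) and np.all(sire == 1) and dam.size == 50

    def test_conservation(self, rng):
        pool = self._pool([1.0, 2.0, 3.0])
        dam, sire = assign_parentage(pool, 777, rng)
        assert dam.size == sire.size == 777

    def test_reproductive_failure_returns_empty(self, rng):
        dam, sire = assign_parentage(MatingPool.empty(), 10, rng)
        assert dam.size == 0
        dam, sire = assign_parentage(self._pool([0.0, 0.0]), 10, rng)
        assert dam.size == 0


class TestInherit:
    def test_zero_segregation_gives_exact_midparent(self, rng):
        p = replace(default_params(), seg_cov_scale=0.0)
        out = inherit(np.array([[8.0, 6.0]]), np.array([[12.0, 8.0]]), p, rng)
        assert np.allclose(out, [[10.0, 7.0]])

    def test_midparent_mean_monte_carlo(self, params, rng):
        n = 10_000
        dam = np.tile([8.0, 6.0], (n, 1))
        sire = np.tile([12.0, 8.0], (n, 1))
        out = inherit(dam, sire, params, rng)
        se = np.sqrt(0.5 * np.diag(params.P) / n)
        assert np.all(np.abs(out.mean(axis=0) - [10.0, 7.0]) < 3 * se + 0.02)

    def test_segregation_covariance_is_half_p(self, rng):
        # center far from the bounds so clipping is inert
        p = replace(
            default_params(),
            season_length=1000.0,
        )
        n = 100_000
        dam = np.tile([500.0, 500.0], (n, 1))
        sire = np.tile([500.0, 500.0], (n, 1))
        out = inherit(dam, sire, p, rng)
        cov = np.cov(out.T)
        assert np.all(np.abs(cov - 0.5 * p.P) <= 0.03 * np.abs(0.5 * p.P) + 0.1)


@pytest.mark.parametrize(
    "dam, sire, expected", [(1.0, 0.0, 0.5), (0.0, 0.0, 0.0), (0.5, 1.0, 0.75)]
)
def test_ancestry_is_parental_mean(dam, sire, expected):
    assert propagate_ancestry(dam, sire) == expected
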