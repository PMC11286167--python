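"""Generation loop, replicate orchestration, determinism, extinction."""

import numpy as np
import pytest

from straysim import default_params, init_founders, run_replicate, run_scenario, step_generation
from straysim.params import MetapopulationParams, replace
from straysim.simulate import cv_percent, run_metapopulation


def test_step_without_hatchery(params, rng):
    founders = init_founders(params, np.random.default_rng(5))
    offspring, summary = step_generation(founders, params, hatchery_on=False, rng=rng)
    assert summary.n_strays == 0
    assert summary.phoa == 0.0
    assert np.all(offspring.ancestry == 0.0)


def test_step_stray_influx_from_parent_census(params, rng):
    founders = init_founders(params, np.random.default_rng(5))
    _, summary = step_generation(founders, params, hatchery_on=True, rng=rng)
    assert summary.n_strays == 100  # round(500 * 0.2)


def test_recruits_never_exceed_carrying_capacity(rng):
    p = replace(default_params(), w_max=50.0)  # strongly supercritical
    cohort = init_founders(p, np.random.default_rng(5))
    for _ in range(3):
        cohort, summary = step_generation(cohort, p, hatchery_on=True, rng=rng)
        assert summary.nc_natural <= 4000
    assert summary.nc_natural == 4000


def test_offspring_pedigree_points_at_valid_parents(params, rng):
    from straysim.population import FEMALE, MALE, make_strays, merge
    from straysim.mating import overlaps

    founders = init_founders(params, np.random.default_rng(6))
    # replay the event deterministically to recover the merged parent cohort
    offspring, _ = step_generation(founders, params, True, np.random.default_rng(7))
    strays = make_strays(len(founders), params, np.random.default_rng(7))
    merged = merge(founders, strays)
    assert np.all(merged.sex[offspring.dam_index] == FEMALE)
    assert np.all(merged.sex[offspring.sire_index] == MALE)
    assert np.all(
        overlaps(
            merged.return_day[offspring.dam_index],
            merged.rls[offspring.dam_index],
            merged.return_day[offspring.sire_index],
            merged.rls[offspring.sire_index],
        )
    )


def test_hatchery_cessation_schedule():
    p = replace(default_params(), n_generations_total=30)
    summaries = run_replicate(p, seed=3)
    strays = np.array([s.n_strays for s in summaries])
    assert np.all(strays[1:26] > 0)
    assert np.all(strays[26:] == 0)
    assert strays[0] == 0


def test_phoa_zero_without_strays():
    p = replace(default_params(), phos=0.0, n_generations_total=10)
    summaries = run_replicate(p, seed=4)
    assert all(s.phoa == 0.0 for s in summaries if not s.extinct)


def test_extinction_freezes_summaries():
    p = replace(default_params(), phos=0.0, w_max=0.4, n_generations_total=25)
    summaries = run_replicate(p, seed=5)
    assert summaries[-1].extinct
    g_ext = next(i for i, s in enumerate(summaries) if s.extinct)
    assert g_ext < 25
    for s in summaries[g_ext + 1 :]:
        assert s.extinct
        assert s.nc_natural == summaries[g_ext].nc_natural
        assert np.isnan(s.mean_return_natural)


def test_same_seed_bitwise_identical():
    p = replace(default_params(), n_generations_total=8)
    a = run_scenario(p, replicates=5, base_seed=11)
    b = run_scenario(p, replicates=5, base_seed=11)
    assert a.equals(b)
    c = run_scenario(p, replicates=5, base_seed=12)
    assert not a.equals(c)


def test_worker_count_does_not_change_results():
    p = replace(default_params(), n_generations_total=6)
    serial = run_scenario(p, replicates=6, base_seed=13, workers=1)
    parallel = run_scenario(p, replicates=6, base_seed=13, workers=2)
    assert serial.equals(parallel)


def test_ci_halfwidth_shrinks_with_replicates():
    p = replace(default_params(), n_generations_total=10)
    small = run_scenario(p, replicates=36, base_seed=21)
    large = run_scenario(p, replicates=144, base_seed=22)

    def halfwidth(res):
        lo, hi = res.ci("nc_natural")
        return (hi - lo)[10] / 2

    ratio = halfwidth(small) / halfwidth(large)
    assert 1.2 < ratio < 3.3  # ~2 expected from the 1/sqrt(n) law


def test_mean_return_day_evolves_toward_fixed_optimum():
    p = replace(default_params(), phos=0.0, n_generations_total=15)
    theta = np.tile([15.0, 7.0], (16, 1))  # optimum displaced from founders
    means = np.zeros(16)
    for r in range(20):
        summaries = run_replicate(p, seed=100 + r, theta_sequence=theta)
        means += np.array([s.mean_return_natural for s in summaries])
    means /= 20
    assert means[0] == pytest.approx(10.0, abs=0.5)
    assert means[5] > means[0] + 0.5
    assert means[15] > means[5]
    assert means[15] > 13.0  # most of the gap to theta closed


def test_cv_percent_conventions():
    demes = [5.0, 10.0, 13.0, 15.0, 17.0, 20.0]
    assert cv_percent(demes) == pytest.approx(39.875, abs=0.05)
    assert cv_percent(demes, ddof=0) == pytest.approx(36.4, abs=0.05)
    assert cv_percent([3 * d for d in demes]) == pytest.approx(cv_percent(demes))


def test_metapopulation_identical_demes_have_near_zero_cv():
    mp = MetapopulationParams.default(
        phos=0.0, deme_optima=(12.0, 12.0, 12.0), hatchery_mean=13.0
    )
    mp = MetapopulationParams(
        tuple(replace(p, n_generations_total=6) for p in mp.deme_params)
    )
    res = run_metapopulation(mp, replicates=12, base_seed=31)
    # demes are statistically identical: only sampling noise and independent
    # environmental wander remain, far below the ~40% CV of spread optima
    assert res.mean_cv()[6] < 12.0
    assert res.mean_cv()[0] < 3.0


def test_metapopulation_determinism():
    mp = MetapopulationParams.default(phos=0.1, deme_optima=(8.0, 15.0))
    mp = MetapopulationParams(
        tuple(replace(p, n_generations_total=5) for p in mp.deme_params)
    )
    a = run_metapopulation(mp, replicates=4, base_seed=41)
    b = run_metapopulation(mp, replicates=4, base_seed=41)
    assert np.array_equal(a.cv_return_day, b.cv_return_day, equal_nan=True)
    for x, y in zip(a.deme_results, b.deme_results):
        assert x.equals(y)


def test_synchronous_environment_shares_theta_across_demes():
    mp = MetapopulationParams.default(phos=0.0, deme_optima=(8.0, 15.0))
    mp = MetapopulationParams(
        tuple(replace(p, n_generations_total=5) for p in mp.deme_params)
    )
    res = run_metapopulation(mp, replicates=3, base_seed=51, synchronous_env=True)
    d0 = res.deme_results[0].fields["theta_return"]
    d1 = res.deme_results[1].fields["theta_return"]
    # same deviations around different long-run means
    assert np.allclose(d0[:, 1:] - 8.0, d1[:, 1:] - 15.0)
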