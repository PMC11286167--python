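# Methods

## Scope and assumptions

`straysim` simulates only the spawning grounds of a semelparous, two-year
salmon: adults return, mate for a number of days, and die.  There is no age
structure, no juvenile or ocean stage, no harvest, no dispersal among
streams, no spatial structure within a stream, and no selection against
hatchery ancestry per se — strays are penalized only through the phenotypes
they carry.  Sex ratios are exactly balanced (odd cohorts give the extra
fish to males), both sexes share the same trait distribution, and the
phenotypic covariance matrix **P** is treated as constant: selection widths
and stray trait distributions are always computed from the initial **P**.

## Traits, selection, and environment

Return day and reproductive lifespan (RLS) are jointly Gaussian with
variances 20 and 10 days², correlation −0.3 (later fish stay for less
time).  Expected reproductive success is a diagonal bivariate Gaussian in
the distance from this generation's optimum with widths ω·σ per trait
(ω = 2); there is no correlational selection term, because only a per-trait
width is specified.  The optima are *independent* draws each generation
around fixed long-run means (variances 20 and 1 days²), not a random walk:
demes must retain distinct long-run optima for the metapopulation analysis,
and a walk would not.  The wild long-run mean return day doubles as the
local optimum; the hatchery mean return day never changes.

Out-of-bounds trait draws (return day outside [1, season] or RLS < 1) are
clipped by default; at the default parameterization ≲2% of mass is clipped
and group means move by well under half a day.  A `resample` dialect redraws
instead, for users who prefer no boundary atom.

## Density dependence and recruitment

A fish's Ricker census day is the first integer day of its half-open
presence window [d, d + RLS) — this guarantees each fish is counted in the
crowd it experiences, and an integer return day counts itself.  Daily
abundance is computed from the merged cohort, so strays compete and are
competed against.  With β = −10⁻⁵ the Ricker factor is mild (≥ 0.96 even at
the 4000-fish cap); the hard cap and the calibrated `w_max` do most of the
regulating.

The next census is min(K, round(Σ ŵ′ / 2)): summing every spawner's
density-adjusted expected RS and halving, because each offspring consumes
one dam-unit and one sire-unit of expected output.  A `poisson` dialect
draws Poisson(Σ/2) instead; the deterministic rounding is the default and is
recorded in output metadata.  If the mating pool holds no pairs at all,
recruitment fails outright.

## Mating

Each female's mate cap N_j ~ Poisson(λ = 2); she takes a uniform
without-replacement sample of N_j of her temporally overlapping males (all
of them if fewer).  Caps bind females only.  Pair weights are the product
of the two parents' adjusted expected RS, and offspring parentage is a
categorical draw over pairs.  Presence windows are half-open, consistently
with daily abundance: arriving the day another fish departs does not
overlap it.

Two interchangeable samplers implement the uniform mate draw: a dense
random-key ranking over the full female × male matrix (used when
n_f · n_m ≤ 250 000 or λ is very large) and, for big cohorts, rejection
sampling of male indices with order-preserving de-duplication and an exact
per-female fallback when the candidate budget is exhausted.  Both are
exactly uniform; the switch depends only on cohort size, so reproducibility
is unaffected.

## Inheritance and ancestry

Offspring traits are Gaussian around the midparent value with segregation
covariance `seg_cov_scale`·**P**, default 0.5: under random mating the
midparent variance is **P**/2, so ½**P** of segregation noise keeps the
stationary phenotypic covariance ≈ **P**, matching the constant-**P**
assumption.  The scale is exposed because only "set as an input parameter"
is specified for the base quantity.  Hatchery ancestry is averaged through
the pedigree: strays carry 1, founders 0, a hatchery × wild cross 0.5.

## w_max calibration

`w_max` (expected offspring at the optimum, zero density) is not printed
anywhere; it is pinned by requiring the no-hatchery control to be
approximately stable.  `calibrate_wmax` bisects `w_max` until the mean
generation-25 census of pHOS = 0 pilots lies within ±10% of the founder
census (500), reusing the same pilot seeds at every candidate so the
objective is monotone and the procedure deterministic.  Near criticality
the final census is heavy-tailed (each generation's selection load varies
with the squared optimum deviation), so the shipped default was produced
with 512 pilot replicates — enough to make the Monte-Carlo error on the
mean (~±20 fish) small against the ±10% band — giving
`CALIBRATED_W_MAX = 2.748046875` (mean final census 494).  The calibration
settings are recorded in run metadata.

## Replication, seeding, and summaries

Every replicate / deme / generation consumes its own counter-derived child
stream of the base seed, so results are bitwise independent of worker count
and execution order.  Scenario outputs are replicate × generation stacks of
per-generation scalars; across-replicate summaries use the normal
approximation (mean ± 1.96·SE).  "Generation g" denotes the stream-born
cohort produced by spawning event g; generation 0 is the founder cohort,
and hatchery influx joins events 1–25.

Replicates whose stream-born census falls below 50 are functionally
extinct: the loop halts, the census is frozen at its final value, trait and
ancestry fields become NaN (excluded from across-replicate trait means),
and the extinction fraction is reported separately.  Strays do not count
toward the extinction floor.

RRS is the ratio of mean *realized* (pedigree) offspring counts of strays
vs. stream-born spawners, averaged over post-burn-in hatchery generations
(burn-in 5); the expected-RS fields are also stored for diagnostics.  The
among-deme coefficient of variation of mean return day uses the sample-SD
(n−1) convention, in percent, computed per replicate and then averaged;
extinct demes are dropped from a replicate's CV.  Metapopulation
environments are independent across demes by default; a
`synchronous_env` switch shares each generation's optimum deviations
across demes within a replicate.

## Problem sizes

Statistical tests and the acceptance analyses use 200 replicates per
scenario and the standard 25- or 50-generation horizons; the calibration
tests use 8–24 pilots.  These sizes put Monte-Carlo standard errors well
inside the tolerances being checked while keeping the default suite quick
on a single core.

## Known limitations

* The demographic subsidy from strays compounds as ≈ pHOS × (stray/wild
  expected-RS ratio) per generation and, below the habitat cap, is only
  weakly opposed by the Ricker term at the default β; mid-range pHOS ×
  mismatch scenarios therefore equilibrate noticeably above what a stronger
  density regime would give, and post-cessation declines are correspondingly
  slower.
* The no-hatchery control is a near-critical branching process: individual
  replicate trajectories wander geometrically (the across-replicate SD of
  the mean return day is ~4 days by generation 25), and census means are
  heavy-tailed.  Quantities conditioned on the control level inherit that
  noise.
* With independent deme environments and spread optima {5, 10, 13, 15, 17,
  20}, the no-hatchery among-deme CV of mean return day is necessarily
  ≈ 40% (the CV of the optima themselves) under the sample-SD convention.
* Clipping at day 1 biases the lowest-optimum deme slightly upward; the
  `resample` dialect removes the atom but not the truncation.
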