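# Methods

## Scope

`mammosim` estimates the yearly budget impact, from a national-health-system
perspective, of running a population-based biennial mammography screening
program (women aged 50–69) with full-field digital instead of screen-film
mammography. It is an individual-level microsimulation: the same simulated
women are pushed through the program twice, once per technique, with common
random numbers, so that the paired yearly cost differences have low variance
and isolate the technique effect. Costs are undiscounted 2009 euros in three
categories — screening, additional (work-up) tests, cancer treatment — over a
20-year horizon (simulation years 2010–2029).

## Population dynamics

The target population starts with 100,000 women aged uniformly over [50, 70).
Every two years a wave of 50–51-year-olds enters; ten equal waves (at the
close of each cycle, simulation times 2, 4, …, 20) total 151,960 entrants, so
251,960 women pass through the program at full scale. Screening rounds are
anchored at ages 50, 52, …, 68 (at most 10 lifetime invitations); entrants
are invited uniformly within their first cycle, which keeps the yearly screen
volume steady. Women leave the screening pool at 70 unless diagnosed;
diagnosed women (including interval cancers from the last round, surfacing
within 2 years of the last mammogram) are followed to the horizon for
treatment costing. Death from other causes competes with every event: a
woman's timeline is truncated at the earliest of her other-cause and
breast-cancer death.

A `scale` factor shrinks the initial population and entrant stream
proportionally (0.2 is used for desk-scale replication batches); all rate
outcomes are scale-free.

## Participation

The printed program statistics give 78.7% participation in initial and 83.2%
in successive screens. Treating these as *independent* per-invitation
probabilities is inconsistent with the program's own cumulative volume: with
~4.5 invitations per woman it predicts ~0.93 million screens for 251,960
women, about 27% more than the ~731,500 the program reports. The package
therefore defaults to a *sticky* participation model: a single
Bernoulli(0.787) gate at the first invitation decides whether a woman ever
participates, and participants attend each later invitation independently
with probability 0.832. Under this model the observed initial and successive
attendance rates among participants match the printed values, and the
cumulative screen volume and the ~15.3% share of initial screens are both
reproduced. `participation.model = "independent"` restores the independent
variant. Profiles are generated once per woman and shared by both arms.

Initial-population women have all been invited before (their in-horizon
screens are successive); a `naive_fraction` (default 0.064, set analytically
so initial rounds are ~15.3% of screens at steady state) is treated as new to
the program.

## Natural history

* **Onset.** Pre-clinical onset is drawn by inverse transform of an
  age-increasing hazard λ(a) = m · r₀ · exp(γ(a−50)) (r₀ = 0.003/yr,
  γ = 0.02/yr, zero below age 30) over the woman's remaining lifetime,
  censored at her other-cause death. The global multiplier m is calibrated by
  bisection on reduced-scale pilot runs (common random numbers make the
  detection rate monotone in m) until the screen-detection rate is
  0.643% ± 0.05 pp per screen; the shipped default (m = 0.993) is the frozen
  result of that calibration. At most one cancer per woman; no spontaneous
  remission.
* **Sojourn.** The pre-clinical screen-detectable phase lasts 2 years at
  onset age ≤ 40 and 4 years at ≥ 50, linearly interpolated between — the two
  published anchors; the interpolation shape is our choice.
* **Stage.** There is no stage-progression clock: stage is assigned at
  detection from the context's distribution. Screen-detected cancers use
  technique-specific distributions (defaults: DM 21.4/41.3/29.4/7.4/0.4% and
  SFM 17.9/44.1/26.1/11.7/0.3% over CIS/I/II/III/IV, the realized program
  distributions); clinically detected cancers (interval cancers,
  nonparticipants) share one distribution across arms, a synthetic stand-in
  defaulting to 8/30/35/21/6%.
* **Survival.** Breast-cancer survival after detection is exponential with
  stage-specific medians (defaults CIS 300, I 25, II 12, III 6, IV 3 years),
  a deliberately simple stand-in for stage/age/cohort-specific survival
  curves. The CIS median is set long so that carcinoma in situ contributes
  only ~1% of breast-cancer deaths. The decreasing medians give strict
  stochastic ordering of survival across stages.

## Screening process

An attended screen of a woman in the pre-clinical (or clinical) phase is
positive with probability Se (one Beta mode 0.8666 shared by both techniques
but sampled separately per technique each replication); a cancer-free woman
is recalled falsely with probability 1 − Sp, with Sp specific to technique
and round type (initial/successive). A false negative surfaces clinically at
the woman's clinical onset unless a later screen detects her first. Round
type is the woman's first *attended* screen. Recalled women (TP or FP)
receive a work-up combination drawn from a per-technique distribution over
non-empty subsets of {additional mammogram, ultrasound, FNAC, core biopsy,
open surgical biopsy}.

The work-up distributions are derived at config-build time from per-test
program counts divided by recalls (per-round-type margins are not published,
so the same margins serve both round types). The decomposition is
structural — each invasive test is accompanied by an ultrasound, leftover
ultrasound margin becomes ultrasound-only, women with no other test receive
an additional mammogram, and additional mammograms attach to the remaining
groups at a constant rate — which reproduces all five margins exactly and
yields ~32% ultrasound-only work-ups for digital and ~22% ultrasound+FNAC
for screen-film, matching the programs' reported patterns.

## Costs

Screening mammograms cost 42.28€ (DM) and 39.29€ (SFM) per woman screened;
diagnostic (additional) mammograms are priced the same as screening ones.
Work-up unit costs: ultrasound 16.69€, FNAC 303.25€, core biopsy 270.16€,
open surgical biopsy 1,388€. Treatment is a monthly accrual by stage and
phase: an initial phase (5.75–11.11 months at 2,006–2,237€/month), a
follow-up phase lasting 120 − (initial − 1) months (132–738€/month), and an
advanced phase at 3,438.71€/month that starts at detection for stage IV or,
with stage-specific probability (2.75–35.38%), at a recurrence time drawn
uniformly between the end of the initial phase and the end of follow-up, and
runs for the rest of life. Phase-table prices are 2005 values inflated by the
cumulative 7.9% CPI to 2009 (a config flag treats them as already-2009).
Accrual is continuous (1/12-year months), apportioned to calendar years by
position, truncated at death and at the horizon; only cancers detected within
the horizon accrue treatment costs. Costs are not discounted.

## Probabilistic sensitivity analysis

Each replication draws one parameter set: sensitivity per technique from
Beta(mode 0.8666, κ = 200); specificities per technique × round and
participation probabilities from Beta(mode at the printed values, κ = 500);
stage distributions from Dirichlet(realized proportions × 100). κ = 500 makes
the across-replication spread of realized false-positive rates match the
published gaps between realized rates and the specificity modes (e.g. a
successive-round FP rate averaging ~4.4% against a 4.2% mode, because the
Beta mean exceeds 1 − mode). Replications are classified as DM-better,
SFM-better or intermediate from their realized detection (±0.5‰) and recall
(±0.5 pp) differences; boundary values count as "better". Aggregation uses
normal-approximation 95% CIs (mean ± 1.96·SD/√n across replications).

Because screens, recalls and false positives are linear in the sampled
parameters, a single replication run at the *distribution means*
(`psa_mode="mean"`) estimates the across-replication mean of those outcomes
directly; the validation suite and the acceptance script use this for
cumulative volumes and rates, and full PSA sampling for cost differences.

## Synthetic fixtures

The life table is Gompertz–Makeham (h(x) = 5·10⁻⁴ + 1.25·10⁻⁵·e^{0.10x},
terminal age 110), giving a remaining life expectancy at 50 of ~35 years;
the onset-incidence curve and the ten-wave entry stream are as above. These
stand-ins carry the statistical structure the analysis needs (age-increasing
hazards, steady entry, conservation of totals) but are not national
statistics: absolute mortality and incidence levels, cohort effects and
real age structures are not reproduced. Passing tests therefore demonstrate
the mechanics and internal consistency of the pipeline on realistic inputs,
not fidelity to any specific national dataset; both fixtures read and write
two-column CSV so real tables can be dropped in.

## Numerical and implementation choices

* The event-queue formulation is computed vectorized: a round's outcome never
  influences the random numbers of later rounds, only whether they are used,
  so per-round arrays over the whole cohort give bit-identical results to a
  sequential event queue and run a full-scale replication in ~2 s.
* Per-replication seeds come from `SeedSequence(master, spawn_key=(i,))`, so
  replications are independent of execution order.
* All uniforms are drawn once per replication and shared by both arms: the
  same number drives a given woman's screen outcome, stage, survival quantile
  and recurrence in both arms (with identical parameters the arms are
  bit-identical, the pairing test of the suite).
* Death sampling inverts the life table's piecewise-constant hazard; a year
  with q = 1 returns the year start exactly.
* Onset inversion uses one global cumulative-hazard curve on a 1/8-year grid.
* Stage and work-up sampling use `searchsorted` on cumulative probabilities;
  stage vectors are validated to sum to 1 within 10⁻⁹.

## Known limitations

* **Interval cancers.** With a deterministic 4-year sojourn and 2-year
  screening interval, a cancer arising after a negative screen is always
  still pre-clinical at the next screen, so "true" interval cancers
  (surfacing within 2 years of a true negative) cannot occur; interval
  cancers arise only from false negatives and the post-last-mammogram
  window — an order of magnitude fewer than real programs observe. A
  stochastic sojourn would be needed to reproduce interval-cancer volumes.
* **Treatment-cost difference ceiling.** The between-arm treatment-cost
  difference has two channels: the phase-cost mix of the stage distributions
  (~0.5M€/yr at full scale, steady state) and extra advanced-phase
  person-time from the screen-film arm's excess stage-III recurrences. With
  the default stage mixes and recurrence probabilities the net excess is
  ~54 recurrence assignments over 20 years, of which at most ~40 can have
  reached their recurrence time by year 20 even with no mortality — an upper
  bound of roughly 2.3M€/yr on the year-20 treatment difference, and
  ~0.9–1.3M€/yr realized under the survival stand-in. Year-20 overall
  savings therefore plateau near 2–3.5% of the screen-film overall cost in
  this implementation; reported program-level analyses with richer survival
  models place it substantially higher, so the late-horizon savings here
  should be read as conservative.
* **Mortality level.** With the default medians, cumulative 20-year
  breast-cancer mortality is ~0.6% of invited women; pushing it higher
  requires survival medians short enough to be inconsistent with observed
  stage-specific survival and further suppresses the late treatment
  difference. The split of deaths across stages matches observed patterns
  better than the level.
* Costs of the switching process itself, discounting, indirect costs,
  opportunistic screening, migration and radiologist-level mechanics are out
  of scope; recurrence is a cost phase, not a biological event, and
  overdiagnosis is not quantified.
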