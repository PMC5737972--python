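# Methods

## Lexis geometry and conventions

Analyses live on a rectangular Lexis grid of 1-year × 1-year cells,
half-open `[a, a+1) × [y, y+1)`, age in completed years at the start of the
calendar year.  A birth cohort occupies the diagonal `c = y − a`.  The
default grid spans ages 50–85 and years 2000–2013 (36 × 14 = 504 cells).

**Eligibility partition.**  Cell `(a, y)` is *eligible* iff
`a − (y − reference_year) ≤ cutoff` (default cutoff 64, reference year
2000): the cohort on its diagonal was still young enough at the reference
year ever to be invited.  On the default grid this gives 301 eligible and
203 too-old cells.  Classification is purely geometric — deaths in women
diagnosed after 64 but belonging to eligible cohorts stay in the eligible
polygon, which is what lets the grid capture benefits that surface at ages
beyond the invitation window.

**Invitation schedules.**  A programme is `(first_round_year, interval,
age window, last follow-up year)`.  Programme rounds are biennial from the
first round year; a woman under 50 at the programme start is first invited
in the calendar year she turns 50 and follows her own biennial clock.
Under the default early-region schedule (2000, 2, 50–64, 2013) no cohort
can accumulate more than 7 invitations by end-2013.

**Time granularity.**  Whole calendar years throughout.  A programme
starting in December of year *t* is modelled as first inviting in *t*+1; a
February start as year *t*.  Person-time is counted in whole years: a woman
is exposed in every grid year up to and including her death year, so cells
containing deaths always carry person-time.

**Smoothing.**  Display smoothing of count surfaces is a 3 × 3 moving mean
truncated at the grid edges (corner cells average 4 values): no values are
invented outside the grid, at the price of higher variance on the border.

## Mortality contrasts

Each Lexis cell is a stratum.  The Mantel–Haenszel rate ratio is
`Σ d₁T₀/T ÷ Σ d₀T₁/T`; the variance of its log uses the Breslow–Day
person-time form `Σ dT₁T₀/T² / (R·S)` with `R`, `S` the MH sums.  For a
single stratum this reduces *exactly* to `1/d₁ + 1/d₀`; with near-balanced
person-time the reciprocal-counts approximation `1/D₁ + 1/D₀` is reported
alongside.  Strata with zero total person-time are dropped and counted.

The double difference divides the eligible-cohort ratio by the too-old
ratio; its log-variance is the sum of the two component variances
(independent strata), approximated by the Woolf-like
`1/D₁ + 1/D₀ + 1/D₁′ + 1/D₀′` — the CI width is governed by the smallest
of the four death counts.  Intervals are 95 % with z = 1.96 fixed; display
rounding is two decimals.  Derived summaries: percent reduction
`100(1 − net)`, deaths averted `(1 − net)·D₀(eligible)`, and
full-participation efficacy `reduction ÷ participation` (valid if
non-participants would have benefited like participants; participation is
modelled as a fixed latent trait, which is what makes the invited effect an
exact 70/30 mixture of the maximal and null effects).

## Stage 2–4 trend models

*Band trends.*  Within one region, stage 2–4 counts over a band of cells
are fitted by a log-linear Poisson model
`log E[count] = α + β·year + log(WY)` (statsmodels GLM, exposure offset);
the annual change is `100(exp(β) − 1)`.  Default bands cover the
pre-rollout years 2000–2007: three 5-year attained-age bands (50–54,
55–59, 60–64) and four diagonal bands of 5 birth cohorts each (aged 50–54,
55–59, 60–64 in 2000, and reaching 50 in 2001–2005; cohorts reaching 50 in
2006–07 are omitted as too briefly observed).  Band membership bounds are
configurable rather than hard-coded.

*Yearly matched ratios.*  For each study year, an MH summary over that
year's eligible cells, age = stratum.  Years without events return an
undefined marker rather than raising.

*Conditional Poisson.*  Conditioning on the cell total `n_ay` of stage 2–4
cases, the region-1 count is `Binomial(n_ay, p_ay)` with
`logit p_ay = log(T₁/T₀) + b_bg + log netRR(y)`.  Two steps: `b_bg` is
estimated from the too-old cells (constant model, no net term) and plugged
into the eligible-cell fit as a fixed offset — background and net effects
are deliberately not jointly estimated, so that the net term can only load
on the cells screening can affect.  `log netRR(y)` is constant, linear or
quadratic in year centred at the study midpoint (centring is purely
numerical; fits with raw year agree to tolerance).  Maximisation is by
statsmodels' binomial GLM (IRLS, tolerance 1e-10); separation (all events
in one region) and events in cells lacking person-time on either side are
rejected with errors.  The fitted `1 − netRR(y)` is the fraction of the
stage 2–4 cases expected in year `y` that earlier screening had already
detected — at stage 1, in an earlier year.

Joinpoint regression is not implemented; the Poisson log-linear fit is the
single trend engine (the two give identical results on data of this kind).

## The synthetic registry

The microsimulator generates the *stated world* the estimators assume.
Per woman, on a whole-year clock: a latent clinical diagnosis hazard
`0.0018·exp(0.03(a − 50))` per year from age 50 (≈ 180 rising to ≈ 520 per
100,000 WY over ages 50–85); stage 2–4 with probability 0.70 at clinical
presentation; 70 % of women are latent always-attenders; an attender
invited in year `r` has any clinical diagnosis due within her lead-time
horizon (2/3/4 years with probability 0.25/0.50/0.25; mean 3) advanced to
year `r`, and a would-be stage 2–4 cancer is recorded at stage 1 with
probability 0.5; survival after diagnosis is geometric with annual
breast-cancer death hazard 0.01 (stage 1) vs 0.06 (stage 2–4); no
other-cause mortality by default (a competing constant hazard can be
enabled, in which case the analytic oracle below declines to run).
Cohorts default to 9,000 women per single-year age per region — the scale
of the motivating setting.

The stage-shift probability 0.5 was fixed once, on the noise-free expected
surfaces, so that the implied long-run net mortality ratio is ≈ 0.91 —
the scale of effect reported by such programmes; with the lead-time and
fatality parameters above this same mechanism produces the prevalence-round
stage 2–4 *excess* followed by a sustained deficit, and mortality benefits
that emerge only several years after the first round.  All values are
illustrative of a realistic programme, not estimates of any particular one.

`expected_cell_rates` computes the exact per-cell expectations of the same
mechanism by dynamic programming over (latent diagnosis year, participation
and lead class, recorded stage, death year).  It is the oracle against
which the sampler is tested (law-of-large-numbers checks at ~10⁵ women)
and the deterministic surface on which the mechanism's sign patterns are
asserted.  For estimator-calibration studies (bias, CI coverage) replicates
are drawn as independent Poisson counts per cell (`expected_death_grid` +
`sample_count_grid`): the Lexis count grid is a sufficient statistic for
every contrast estimator, and the cell-level model imposes the true net
ratio exactly, which a mechanism-level simulation cannot do.

What a green test does **not** establish: the simulator has no
overdiagnosis, no tumour natural history, no migration between regions, no
secular treatment trends, no opportunistic screening in the control region,
and whole-year timing only.  Agreement here validates the estimators'
arithmetic and calibration under their own assumptions, not the substantive
conclusions one would draw from any real registry.

## Numerical choices and degenerate inputs

- MH ratio undefined (no events, or a zero MH sum) raises rather than
  returning NaN; yearly ratio sequences map those years to `None`.
- Woolf-like variance requires all four counts positive.
- Poisson/binomial GLM non-convergence raises with diagnostics; the
  binomial fit's log-likelihood is checked against the null in tests.
- Registry rows violating invariants (death before diagnosis, unknown
  stage labels, unknown region) are rejected row-wise with line-numbered
  diagnostics; a missing mandatory column aborts.  Unknown stage is
  excluded from stage analyses, never imputed.
- Seeds: a single `numpy` Generator drives each simulation; identical
  config + seed reproduces byte-identical record lists.

## Known limitations

- Person-time is supplied (or simulated), never reconstructed from census
  interpolation; the whole-year exposure convention slightly overstates
  exposure in death years.
- The background ratio is a plug-in, so the net-model coefficient standard
  errors do not propagate step-1 uncertainty (the double-difference
  variance, by contrast, does include both components).
- Diagonal band bounds beyond the invitation window are configuration, not
  inference; defaults follow the 5-cohort convention described above.
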