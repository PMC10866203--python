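# Methods

## Study design being modelled

The analysis treats pandemic waves as natural experiments on emergency
department (ED) attendance. Government-action-delimited wave periods shift
the daily number of ED visits abruptly; if those shifts affect non-COVID
28-day mortality only through attendance (exclusion restriction), the wave
indicators are valid instruments and two-stage least squares (2SLS)
identifies the causal effect of avoided visits on subsequent deaths.

Outcome construction matters: a 28-day death is a death registered 0–28
days (both ends inclusive) after a patient's **last** ED visit, and the
daily outcome series tallies deaths by that last-visit date, not the death
date. This timestamps the death at the moment care was last sought, which
is the quantity a visit-reduction model can act on. Day 0 (death on the
visit day) is included; deaths on arrival (DOA/DBA) would otherwise vanish
from the outcome.

## Estimator

Per stratum and lag `i` (days, 0–14):

* stage 1: OLS of visits `A_t` on `[1, Z_t, s_t]`;
* stage 2: OLS of `D_{t+i}` on `[1, Â_t, s_t]`, trailing `i` rows trimmed.

`Z_t` holds five binary columns — wave1..wave4 (1 inside the closed wave
interval) and after-wave (1 on non-wave days strictly after the first
wave's end). `s_t` = (year index with the first study year as 0; `t` =
zero-based day of year; `t²`; `t³`), evaluated at the exposure day in both
stages so the two stages share covariates.

Numerics: both stages solve via Householder QR; a column whose scaled
`R`-diagonal falls below 1e-10 raises a singularity error naming the
offending column (e.g. a wave absent from the study window). Standard
errors are proper 2SLS errors — the residual is formed by substituting the
**actual** exposure into the fitted structural equation, `σ̂² = e'e/(n−k)`,
`cov = σ̂²(X̂'X̂)⁻¹`; an HC1 sandwich variant is available behind
`se_type="hc1"` (the classical homoskedastic form is the default, matching
standard IV-regression software defaults). Confidence intervals are normal:
half-width `z_{0.975}·SE ≈ 1.96·SE`.

Weak instruments are diagnosed with the first-stage partial F test against
the seasonal-covariates-only restriction,
`F = [(RSS_r − RSS_f)/q]/[RSS_f/(n−k)]` with `q = 5`, `k = 10`; an F below
a configurable floor (default 10) attaches a warning to the fit rather than
failing, because a weak-but-reportable fit is still informative in a sweep.

Reporting transforms: `late_per_100 = −100·θ̂1` with the CI end-points sign
flipped and reordered; total excess deaths sum per-stratum
`θ̂1 × (−visit reduction)` with variance `Σ reduction²·SE(θ̂1)²` — strata
are treated as independent, an explicit assumption since cross-stratum
error correlation is unidentifiable from per-stratum fits.

## Cohort rules

* COVID-PCR-positive visits are removed before any tally (they would link
  the instrument to the outcome directly).
* Visit tallies count every visit; mortality tallies count each decedent
  once, at the last visit. Two same-day visits by a decedent count twice as
  visits and once as a death.
* Age is assigned at visit time; a patient crossing an age-bin boundary
  between visits contributes to each stratum per visit.
* Strata with mean daily 28-day deaths ≤ 1 over the full window are
  excluded from causal fitting; the comparison is deliberately inclusive at
  exactly 1.

## Synthetic data generator

No public ED registry with death linkage exists at this grain, so every
stage is validated against simulated data whose causal structure is known.
Per stratum the generator draws, for each extended-window day,

```
A_t     = b0·(1 + trend_t + season_t) + Σ_k βk Z_kt + u_t
D_{t+i} = θ0 + θ1·A_t + d0·(trend_t + season_t) + v_t,   θ0 = d0 − θ1·b0
```

with `(u_t, v_t)` bivariate normal, `sd_u = √b0`, `sd_v = √d0` (Poisson-like
scale) and `corr(u, v) = confound_rho`; counts are rounded and clipped at
zero. Deaths respond to the *realized* visit count, so the injected causal
link is exact; the shared noise component biases naive OLS in the direction
of rho while leaving the instruments clean. The seasonal shape is a cubic
polynomial in fractional day-of-year (a least-squares cubic fit to an
annual cosine — winter-high, summer-low), deliberately inside the span of
the estimator's seasonal covariates: the generator realizes exactly the
structural model the estimator assumes, so estimator validation is not
confounded with seasonal misspecification. Configs whose noiseless expected
counts go negative on more than 1% of study days are rejected as
implausible before any noise is drawn.

Record expansion preserves the daily counts exactly: each stratum-day emits
as many visit records as the series says, and `deaths28[t]` of them belong
to patients whose last visit is day `t` with a death 0–28 days later
(DOA/DBA decedents die on the visit day and carry no diagnosis codes).
Repeat visits reuse patients seen within the previous year; decedents adopt
the identity of a recently active patient (who is then retired), which
gives them genuine pre-death visit histories without ever violating the
last-visit rule. Death dates are patient-level and propagate to all of a
decedent's records. ICD-9-CM codes are painted per-record from
category-representative code lists at configured Deyo-category prevalences,
plus non-Deyo filler codes.

### Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| stratum visit rates | visits/day | 350–880 per sex | totals ≈ 5,900/day ≈ 2.15M/yr, the scale of a large urban ED network |
| stratum death rates | deaths/day | 0.05–42 per sex | ≈ 110/day ≈ 40k/yr, concentrated in ≥65; the three youngest bins sit below 1/day so the sparse-stratum rule has real work |
| `theta1` | deaths/visit | 0 to −0.02 by age | −0.02 in ≥65 ⇒ 2 excess deaths per 100 avoided visits |
| `beta_wave` | visits/day | −120 to −180 per wave, −60 after-wave | 20–50% attendance drops inside waves, partial rebound after |
| `confound_rho` | — | 0.3 (0.5 in recovery studies) | enough shared noise to visibly bias OLS |
| `season_amp`, `year_trend` | fraction | 0.05, 0.01 | mild seasonality and drift |
| `lag` | days | 0 (0–14 configurable) | where the death response is injected |
| `ltc_fraction`, `doa_fraction` | fraction | 0.3, 0.15 | LTC share of ≥65 visitors; DOA/DBA share of decedents |
| `covid_positive_count` | records | 3716 | exercised by the exclusion stage; scaled with the cohort |
| `repeat_visit_fraction` | fraction | 0.35 | elderly repeat attendance; drives multi-visit histories |
| `decedent_history_fraction` | fraction | 0.6 | share of decedents with prior-visit history |
| lookback horizons | days | 365 reuse / 900 history | visits cluster within a year; decedents' activity horizon spans the control periods of the longitudinal analysis |

The default wave calendar (four waves across 2020–2021, the fourth receding
2021-02-18) is **illustrative**: real analyses must supply the calendar
that actually timed the policy actions.

## Validation studies and problem sizes

* Oracle equivalence: 50 random small designs (n = 40–90) against a
  projection-matrix IV solution written independently of the engine, to
  1e-8 relative error; a 12-row just-identified fixture against the
  hand-computed Wald ratio −2/3; a statsmodels IV2SLS cross-check.
* Recovery: 100 seeded replicates of a single ≥65-type stratum at ~3,000
  visits/day over 2016–2021 (2,192 days), `theta1 = −0.02`,
  `confound_rho = 0.5`. Naive OLS must be biased with the sign of rho; the
  2SLS 95% CI must cover the truth in ≥90 replicates (measured coverage
  ≈ 96%).
* Lag localization: the same study with the effect injected at lag 5;
  `|θ̂1|` across a 0–14 sweep must peak at 5 in a majority of 100
  replicates.
* Partial-F monotonicity: scaling all wave shifts by 0.5/1.0/1.5 on shared
  seeds must strictly increase F.
* ETL exactness: tallying generated records reproduces the generated series
  bit-for-bit; the 28-day boundary (28 in, 29 out) asserts exactly.

The analysis drivers run the cohort at one tenth of registry scale
(~1.25M records); at that scale only the ≥65 strata clear the ≤1-death
exclusion, which is the expected behavior of a fixed cohort rule under
downscaling.

## Tie and degeneracy rules

* Incidence-rate categories for DOA/DBA decedents partition the eligible
  set (≥2 control-period visits): `no_visits` iff zero treatment-period
  visits, else `increase` iff treatment rate strictly exceeds control rate,
  else `reduction` — rate ties land in `reduction`.
* The category z test is a pooled two-proportion z (row count over group
  total); an unpooled variant is available. A degenerate pooled proportion
  (0 or 1) yields NaN with a warning instead of an exception, as does a
  comparison against an empty decedent group.
* Same-window baselines average identical month-day windows over the
  baseline years; Feb 29 is dropped from the mapping.
* Zero baselines leave percent changes undefined (None), flagged in logs.

## Known limitations

* The generator's Gaussian-rounded counts have no overdispersion beyond the
  Poisson-like scale, its seasonality lies inside the estimator's covariate
  span by construction, and patient ages are frozen at first appearance —
  passing tests demonstrate estimator correctness under the assumed model,
  not robustness to misspecified seasonality or count distributions.
* Individual visit-frequency distributions are thinner than a real elderly
  registry's, so the longitudinal incidence-rate analysis yields small
  eligible groups at demo scale and a category mix tilted toward
  `no_visits`; the machinery, not the realized frequencies, is what the
  simulation validates.
* Cross-stratum independence is assumed when pooling excess-death
  variances.
* Wave intervals are user-supplied; results are conditional on that
  calendar, and the after-wave indicator's definition (non-wave days after
  the first wave's end) encodes one of several defensible readings of
  "after each wave".
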