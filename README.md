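# ed-avoidance

Causal estimation of the excess mortality cost of **hospital-avoidance
behavior**: when pandemic waves frighten people away from emergency
departments (EDs), how many additional non-COVID deaths follow?

The package is written for epidemiologists and health-services researchers
who have (or must simulate) visit-level ED registry data. It implements the
full analysis chain: a synthetic ED-record generator with known causal
ground truth, cohort ETL into per-stratum daily series, a wave-instrumented
two-stage least squares (2SLS) estimator with weak-instrument diagnostics,
excess-death aggregation, and the descriptive DOA/DBA (death on/before
arrival) and Deyo-comorbidity analytics.

## The model

For each age x sex stratum, daily ED visits `A_t` (exposure) and 28-day
deaths `D_t` (deaths within 28 days of a patient's last visit, tallied by
that visit's date; outcome) are linked through 2SLS with five binary
instruments `Z = (after-wave, wave1..wave4)` derived from a wave calendar:

```
stage 1:   A_t     = b0 + Σ_k βk Z_kt + γ' s_t + u_t
stage 2:   D_{t+i} = θ0 + θ1 Â_t      + γ'' s_t + e_t
```

with seasonal covariates `s_t = (year index, t, t², t³)` (`t` = days since
Jan 1, zero-based; first study year = 0) and an optional outcome lag
`i ∈ [0, 14]` days. Wave onsets/recessions shift attendance abruptly and
non-seasonally, which is what makes the wave indicators valid instruments;
`θ1` is then the local average treatment effect (LATE) among wave
"compliers", in deaths per visit. The interpretable rescaling is
`−100·θ1` — excess deaths per 100 avoided visits — and a first-stage
partial F test guards against weak instruments. Per-stratum LATEs times
observed pandemic-period visit reductions sum to total excess deaths.

Strata averaging ≤ 1 daily 28-day death over the study window are excluded
from causal fitting (model instability); COVID-PCR-positive visits are
excluded from the cohort up front.

## Worked example

The generator realizes exactly the structural model above, with correlated
visit/death noise (`confound_rho`) so that naive OLS is biased while the
instruments still identify `θ1`:

```python
from ed_avoidance import synthetic, iv

cfg = synthetic.recovery_config(seed=0)      # one >=65 stratum, ~3000 visits/day,
                                             # theta1 = -0.02, rho = 0.5
series, truth = synthetic.generate_daily_counts(cfg)
s = series[next(iter(series))]

design = iv.build_design(s, cfg.calendar, lag=0)
fit = iv.fit_2sls(design)
late = iv.late_per_100(fit)
```

Output (printed by the snippet with the naive OLS slope added):

```
true theta1          : -0.0200 deaths per visit
naive OLS slope      : -0.0139  (biased toward zero by confounding)
2SLS estimate        : -0.0200  (95% CI -0.0217 to -0.0183)
excess deaths /100   : 2.00 (95% CI 1.83 to 2.17)
first-stage partial F: 3503 (p < 1e-300)
```

Read: every 100 ED visits avoided during waves causes about two additional
28-day deaths in this stratum; the confounded OLS slope (-0.0139)
understates the harm by a third, and the instruments are very strong.

## Analysis pipeline

Numbered drivers under `analysis/` run the study end to end on a simulated
cohort (12 strata, 2016-2021, four waves, one tenth of registry scale) and
write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1     # records, daily series, ground truth
python analysis/02_cohort_etl.py            # tallies + sparse-stratum exclusion
python analysis/03_fit_iv.py                # 2SLS lag sweep, LATEs, total excess
python analysis/04_avoidance_tables.py      # DOA/DBA breakdowns, rate z tests
python analysis/05_comorbidity.py           # Deyo per-comorbidity changes
```

The same stages are available as a CLI (`ed-avoidance simulate|etl|fit-iv|
excess|doa-dba|comorbidity|run-all`) with a YAML config for wave dates, lag
range, standard-error type (classical or HC1) and seed.

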