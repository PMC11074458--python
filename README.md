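# templag

Time-stratified case-crossover analysis of daily mean temperature and
sparse daily event counts — road-traffic fatalities in particular —
using distributed-lag nonlinear models (DLNM) fitted by conditional
Poisson regression.

## Who this is for

Environmental epidemiologists asking how ambient temperature, and
especially extreme temperature, relates to the daily number of deaths
(or injuries, admissions, …) in a city-scale registry, when the effect
may be nonlinear in temperature and delayed by days to weeks.

## The model

Each day *t* with count *y<sub>t</sub>* belongs to a stratum *s(t)*
formed by its calendar year, month and day of the week, so every
stratum holds the 4–5 days that share those labels ("up to 4 control
days per case") and season, trend and the day-of-week effect are
removed by design. The model is

&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>t</sub>* ~ Poisson(μ<sub>t</sub>),&nbsp;&nbsp;
log μ<sub>t</sub> = α<sub>s(t)</sub> + Σ<sub>l=0..L</sub> *f*(x<sub>t−l</sub>, l) + γ′z<sub>t</sub>

where *x* is daily mean temperature, *f*(x, l) is the
exposure-lag-response surface represented by a cross-basis — a tensor
product of a natural cubic spline in temperature (2 df) and one in lag
(2 df) over lags 0..14 — and z<sub>t</sub> are natural-spline
expansions of relative humidity (3 df) and of each pollutant (2 df)
whose Spearman correlation with temperature is below 0.6. The stratum
intercepts α<sub>s</sub> are profiled out of the likelihood, which
reduces it to the within-stratum multinomial (conditional) likelihood;
estimates and covariance are identical to the dummy-variable Poisson
regression, and the package verifies that equivalence against
statsmodels.

Effects are reported as odds ratios exp{[B<sub>x</sub>(x) −
B<sub>x</sub>(ref)] ⊗ B<sub>l</sub>(l) · β} with delta-method 95% CIs,
referenced to the minimum-mortality temperature (MMT) — the minimum of
the fitted overall cumulative curve — with extreme temperatures defined
as the 1st/99th percentiles of the observed series.

Because no public registry series exists, the package ships a
synthetic-data generator that emulates the marginal structure of a
ten-year temperate-city registry (≈3 deaths/day across five
transport-mode subgroups; temperature mean 15.1 °C ranging roughly −12
to +34 °C; correlated humidity, pressure, wind and six pollutants) with
a configurable closed-form truth surface, so the whole chain can be
validated by parameter recovery.

## Worked example

```python
from templag import AnalysisConfig, SimConfig, generate_series, run_analysis
from templag.experiments import default_truth

cfg = SimConfig(random_seed=42, truth_surface=default_truth("u-shaped"))
frame, truth = generate_series(cfg)          # 3,653 days, 12,790 deaths
report = run_analysis(frame, AnalysisConfig(subgroups=("total",)))
res = report.subgroups["total"]
print(res.mmt, res.thresholds)
print(res.effect_table.cumulative.tail(3))
```

With this seed the fitted MMT is 15.89 °C (the generator's U-shaped
truth has its minimum at 15 °C) and the extreme thresholds are −5.1 °C
and 31.4 °C. The cumulative odds ratios at the high threshold,
referenced to the fitted MMT, are

```
 label    or  ci_low  ci_high
 Lag01 1.074   1.002    1.152
 Lag07 1.267   1.056    1.521
Lag014 1.398   1.119    1.746
```

i.e. a day at the 99th-percentile temperature carries a 40% higher
cumulated fatality risk over the following two weeks than an MMT day,
with the effect building up across lags — the qualitative signature the
generator's truth surface encodes (its true lag-0..14 cumulative OR at
31.4 °C against the 15 °C reference is 1.508; the table above is
referenced to the slightly higher fitted MMT).

The same analysis runs from the shell:

```bash
templag simulate --seed 42 --out sim/
templag describe --data sim/daily_series.csv --out report/
templag analyze  --data sim/daily_series.csv --out report/
templag sensitivity --data sim/daily_series.csv --out report/
```

`analyze` writes per-subgroup cumulative and single-lag OR tables
(`Lag01`…`Lag014` rows at both extreme thresholds), the overall
exposure-response curve on a grid, descriptive tables (daily-count
summaries, meteorology summaries, the Spearman matrix with
strong-correlation flags) and a provenance manifest; `sensitivity` runs
the 27-cell grid {lag 0–7, 0–14, 0–21} × {humidity df 2, 3, 4} ×
{percentiles 1/99, 2.5/97.5, 10/90}.

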