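# charcoal-restriction

Statistical evaluation of a means-restriction suicide-prevention program:
did moving barbecue charcoal from open shelves to locked storage in one
large city reduce charcoal-burning suicides, and by how many lives?

The package is written for epidemiologists and biostatisticians running
quasi-experimental, controlled before–after evaluations of public-health
interventions on count time series. It implements the full pipeline —
descriptive rate tables, nonparametric intensity curves with a change-point
check, seasonal spline count regression, and a counterfactual
"lives saved" simulation — together with a calibrated synthetic-data
generator so every stage can be exercised and validated without access to
mortality registries.

## The model

Deaths are aggregated per site × method × interval (daily, weekly where only
weekly aggregates are released). The count `y_i` with population `Pop_i`
and interval length `T_i` days follows a Poisson (or NB2, if a dispersion
test rejects equidispersion) GLM:

    E[y_i] = Pop_i · T_i · exp{ β0 + B(t_i)β_tr + site + weekday + month
                                + postInt_i·β_post + site_i·postInt_i·β_extra }

with log(Pop·T) offset, a cubic B-spline secular trend B(t) whose interior
knot count is selected by AIC, and full weekday/month seasonality (weekly
records carry averaged dummies). The intervention city's interaction
coefficient β_extra is the effect of interest, reported as a percent rate
reduction `100(1−exp(β))` with Wald CI. Alongside the regression, the
per-capita intensity α(t) in λ(t) = P(t)α(t) is estimated by
local-polynomial Poisson likelihood separately before/after the intervention
date, and a downward change point is declared when the pre-boundary level
exceeds the post segment's 95% band. Lives saved are estimated by removing
the fitted intervention effect from the post-period means and resimulating
counts B = 10,000 times: the median and 2.5th/97.5th percentiles of
(simulated − observed) totals.

## Worked example

The numbered scripts under `analysis/` run the pipeline on a synthetic
series calibrated to the published study conditions (three cities, 2009–2013,
intervention 2012-05-01 in the largest city):

```
python analysis/01_simulate_study_data.py --seed 0
python analysis/02_rate_tables.py
python analysis/03_intensity_curves.py
python analysis/04_seasonal_glm.py
python analysis/05_lives_saved.py
```

With seed 0 the intervention city's charcoal rate falls from 6.2 to 3.7 per
100,000 person-years while other methods barely move, and only that one
series shows a change point:

```
downward change point at the intervention date:
  [  - ] Kaohsiung City     charcoal  pre  5.55 vs post CI ( 4.36,  6.26) per 100k py
  [DROP] New Taipei City    charcoal  pre  4.59 vs post CI ( 3.08,  4.41) per 100k py
  [  - ] Taipei City        charcoal  pre  2.76 vs post CI ( 2.12,  3.50) per 100k py
```

The seasonal GLM (0 interior knots by AIC this draw, Poisson retained —
dispersion p = 0.96) estimates the intervention-city charcoal contrast as
−0.41 (SE 0.11), a 34% [18%, 47%] rate reduction (generating value −0.36,
i.e. 30%), with no significant change in other-method suicide; and the
counterfactual simulation reports:

```
observed charcoal deaths in New Taipei City over the intervention period: 243
expected without the intervention: 347
lives saved: 103 (95% CI [68, 140]), B=10000
```

The same stages are exposed as a CLI
(`charcoal-restriction simulate|table1|intensity|fit|lives-saved|report`);
`report` writes the whole bundle (rate table, curves, coefficient tables,
diagnostics, lives saved, decision log) into an output directory.

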