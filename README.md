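# cfimpact

Quasi-experimental evaluation of zoning-based forest conservation —
community forests (CFs) — from annual tree-canopy-cover (TCC) and
land-cover panels.

Conservation zones are not placed at random: they tend to sit on
terrain whose canopy would have evolved differently anyway, so a naive
inside/outside comparison confounds placement with protection. This
package implements the controlled longitudinal design used to separate
the two: random pixel samples inside and outside zones are matched
cohort by cohort on nine confounders (exact on forest state in the
establishment year, nearest-neighbour on a propensity score, 1:1 and
without replacement), matched outcomes are realigned to event time
t = year − establishment year, and the treated-minus-control difference
series D(t) is analysed with a segmented regression

    D(t) = β0 + β1·time + β2·establishment + β3·time since establishment + e

where the establishment year itself is coded as pre-intervention
(both intervention terms are 0 at t = 0). β2 is the level change at
establishment, β3 the trend change per year; covariate balance is judged
by the standardized mean difference (|SMD| < 0.25 after matching), and
cohort-level regressions with an establishment-year interaction test
whether recently established zones protect less than older ones.
Mann–Kendall trend tests with Bonferroni correction screen the design.

It is aimed at researchers evaluating area-based conservation policies
(community forests, protected areas, concessions) with raster outcome
panels — and at methodologists who want the whole chain validated: a
synthetic landscape generator with known injected effects makes every
stage testable by parameter recovery. See `docs/methods.md` for the full
model description and known limitations.

## Worked example

```python
from cfimpact import RunConfig, ScenarioConfig, run_pipeline

# 200x200 grid of 30-m pixels, annual panel 1989-2019, 40 zones in
# cohorts 1997-2010, placement biased toward high / road-remote terrain,
# true injected effect: +2.0 TCC points at establishment, +0.5 %/yr after
cfg = RunConfig(scenario=ScenarioConfig(), seed=6)
print(run_pipeline(cfg).summary())
```

```
cfimpact pipeline run
  samples: 17714 (2831 treated)
  matched pairs: 1921 over phases [1997, 1999, 2000, 2001, 2003, 2005, 2006, 2007, 2008]; excluded phases: [1998, 2002, 2004, 2009, 2010]
  pooled max |SMD|: pre 0.418 -> post 0.038
  pooled event window: [-8, 11]
  ITS tcc: level +1.797 (p=1.06e-10), trend +0.496/yr (p=1.51e-13)
  ITS forest: level +0.000 (p=nan), trend +0.000/yr (p=nan)
  ITS tcc_forest_throughout: level +2.102 (p=5.1e-08), trend +0.497/yr (p=1.04e-09)
  cohort interaction tcc/forest: +0.0026 (p=0.872)
  ...
```

Reading the output: the sample frame held 17,714 eligible pixels, 2,831
of them inside zones. Phased matching produced 1,921 balanced pairs —
matching cut the worst pooled covariate imbalance from 0.42 to 0.04
standardized units, and five cohorts whose per-phase balance failed the
0.25 rule were excluded. The segmented regression on the TCC difference
series estimates a +1.80-point level change and +0.50 %/yr trend change
(truth: 2.0 and 0.5; single-run estimates scatter around the truth —
run `replicate_study` for the distribution). The forest-cover series is
identically zero here because the default scenario has no stochastic
clearing, and the cohort interactions are near zero because cohort
effects were not varied (`cohort_effect_slope=0`).

The same run is available from the shell, stage by stage or end to end:

```bash
cfimpact simulate -o work --seed 6          # rasters, zones, ground truth
cfimpact sample -d work --seed 6            # random pixel frame
cfimpact covariates -d work                 # nine confounders per phase year
cfimpact match -d work                      # phased matching + balance tables
cfimpact panel -d work                      # event-time difference series
cfimpact fit -d work                        # ITS and post-trend fits
cfimpact run-all --seed 6 -o work           # all of the above, one manifest
cfimpact replicate --seed 6 -n 20 -o reps   # recovery distribution
```

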