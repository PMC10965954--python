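# sibloc

Sibling birth-location discordance: decomposing household moves from
reporting error, and quantifying the biases mismeasured birth locations
induce in location-linked regressions.

Many cohort studies record where participants were born from decades-old
recall. When two full siblings report different birth locations, either
the household moved between the births or at least one report is wrong.
`sibloc` is a simulation-and-analysis package for researchers who use such
retrospective location data (or merge exposures onto it): it generates a
synthetic sibling cohort with both mechanisms, estimates their rates from
the discordance pattern, and measures the downstream estimation bias by
Monte Carlo.

## The model

For family *s* with age gap `agegap_s` (years), the discordance indicator
*y_s* (different parish / district / county, or coordinates more than
*d* km apart) follows the linear probability model

```
P(y_s = 1 | agegap_s) = alpha + beta * agegap_s
```

* `beta = q`, the annual household move probability (moves accumulate with
  birth spacing);
* `alpha = 2p - p^2`, the probability that either of two independent
  reports is wrong, so the per-report error probability is
  `p = 1 - sqrt(1 - alpha)`, with delta-method standard error
  `se_alpha / (2 sqrt(1 - alpha))`.

The Monte Carlo engine then merges spatially autocorrelated, time-varying
exposures `V = sqrt(k) T + sqrt(1-k) S_rho` (SAR field `S`, year-month
effects `T`) onto the cohort and measures the attenuation of the slope in
`Y = X + e` when the observed exposure uses the own-reported location:
percentage bias `100 (b1 - b2) / b1` for pooled OLS and sibling
fixed-effects estimators, plus an ORIV (sibling-instrumented 2SLS)
sensitivity, and the "partially omitted variable bias" when mismeasured
district fixed effects are used as *controls*.

See `docs/methods.md` for the full model description, calibration and
limitations.

## Worked example

```python
import sibloc as sl

geography = sl.build_geography()                      # 98 counties, 1,372 districts
cohort = sl.simulate_cohort(geography, sl.CohortConfig(seed=1))
table1 = sl.make_table1(cohort, geography)
print(table1[["definition", "alpha", "beta", "q_hat", "p_hat"]].round(4))
```

```
definition  alpha   beta  q_hat  p_hat
    parish 0.3123 0.0095 0.0095 0.1707
  district 0.2778 0.0087 0.0087 0.1502
    county 0.1415 0.0077 0.0077 0.0735
     d>0km 0.4834 0.0118 0.0118 0.2813
     d>5km 0.2572 0.0101 0.0101 0.1382
    d>10km 0.1642 0.0082 0.0082 0.0858
    d>30km 0.0844 0.0071 0.0071 0.0431
    d>50km 0.0621 0.0062 0.0062 0.0315
```

The cohort was generated with per-report error probability 0.283 and
annual move probability 0.012 at the coordinate level; the `d>0km` row
recovers both (intercept 0.483 ~ 2p - p^2, slope 0.0118 ~ q), and the
derived `p_hat` falls with aggregation (15% of district reports wrong,
7% of county reports) and with distance (3% of errors beyond 50 km).

```python
bias = sl.run_bias_grid(cohort, geography, levels=["district"],
                        rho_grid=[0.0, 0.9], k_grid=[0.0, 1.0],
                        p_by_level={"district": 0.158},
                        q_by_level={"district": 0.009},
                        n_reps=200, seed=7)
print(bias[["estimator", "rho", "k", "mean_bias_pct", "mc_se"]].round(2))
```

```
 estimator  rho   k  mean_bias_pct  mc_se
       ols  0.0 0.0          14.48   0.03
sibling_fe  0.0 0.0          87.88   0.10
       ols  0.0 1.0           0.00   0.00
sibling_fe  0.0 1.0           0.00   0.00
       ols  0.9 0.0           8.16   0.04
sibling_fe  0.9 0.0          87.47   0.13
       ols  0.9 1.0           0.00   0.00
sibling_fe  0.9 1.0           0.00   0.00
```

For a time-invariant, spatially uncorrelated district exposure, OLS
estimates are attenuated ~15% while sibling fixed-effects estimates lose
~88% of the effect (within-pair exposure differences are mostly error);
spatial correlation (`rho`) softens the OLS bias but barely helps the FE
estimator, and purely temporal exposures (`k = 1`) are unbiased.

## Command line

Every stage also runs from a YAML config:

```
sibloc all --config config.yaml          # geography -> cohort -> table1 ->
                                         # bias-grid -> fe-bias -> trait-corr
```

writing `cohort.csv`, `table1.csv`, `bias_grid.csv`, `fe_control_bias.csv`,
`trait_corr.csv` and a `manifest.json` (config hash, seed, versions) to the
configured output directory. Individual subcommands (`geography`,
`cohort`, `table1`, `bias-grid`, `fe-bias`, `trait-corr`) run single
stages.

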