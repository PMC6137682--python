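# rtcondep

Joint modeling of item response **t**imes and accuracies with **con**ditional
**dep**endence, plus nonparametric tools for detecting and characterizing
that dependence.

The package implements four joint models for a binary accuracy matrix `X`
(N persons × K items) and a positive response-time matrix `T`:

| kind        | ICC slope/intercept as a function of the residual log time z |
|-------------|---------------------------------------------------------------|
| `ci`        | constant (conditional independence)                           |
| `linear`    | linear in z                                                   |
| `quadratic` | quadratic in z                                                |
| `multicat`  | piecewise constant over fixed z-categories                    |

All four share a probit accuracy measurement model, a log-normal
response-time model `ln t ~ N(xi - tau, sigma^2)`, a bivariate-normal
person distribution (ability variance fixed at 1) and a multivariate-normal
item-parameter distribution.  Estimation is Metropolis-within-Gibbs with
probit data augmentation; model fit is compared by a modified BIC evaluated
at posterior means.

On top of the parametric models:

- **Nonparametric moderation** (`rtcondep.npmod`): ICC slope and intercept
  estimated at fixed focal points of the standardized residual log time via
  kernel-weighted marginal ML with iteratively updated response-specific
  parameters.
- **Permutation test** (`rtcondep.checks.permutation_test`): variance of
  the curve across focal points as the statistic; residual columns shuffled
  per item.
- **Posterior-predictive linearity check**
  (`rtcondep.checks.ppc_linearity`): replicates simulated from the linear
  model's posterior are pushed through the full two-step nonparametric
  pipeline; the discrepancy is the maximum absolute cumulative sum of OLS
  residuals of the curve on the focal points.
- **Simulator** (`rtcondep.simulate`): data generation under every model
  kind, with explicit or hierarchically drawn item parameters, used as
  ground truth for recovery studies.

## CLI

```sh
# simulate a dataset under the quadratic model
rtcondep simulate --model quadratic --n-persons 3000 --n-items 20 \
    --seed 1 --out sim/

# fit a joint model; writes posterior_summary.csv and fit.json
# (minus2LL, parameter counts, modified BIC)
rtcondep fit --model linear --x sim/x.csv --t sim/t.csv \
    --config cfg.yaml --out fit/

# nonparametric curves over the focal-point grid
rtcondep npmod --x sim/x.csv --t sim/t.csv --out np/

# conditional-independence permutation test / linearity PPC
rtcondep check permute --x sim/x.csv --t sim/t.csv --n-perm 500 --out perm/
rtcondep check ppc-linearity --x sim/x.csv --t sim/t.csv --n-rep 500 --out ppc/
```

The configuration file (JSON or YAML) may set any of: `model`, `n_iter`,
`burn_in`, `thin`, `seed`, `multicat_thresholds`, `multicat_baseline`,
`focal_points`, `bandwidth_h`, `n_permutations`, `n_ppc_replicates`.
Unset fields take the published defaults (10,000 iterations with 5,000
burn-in; thresholds -1.5,-0.5,0.5,1.5 with the middle category as baseline;
focal points -2 to 2 in steps of 0.5; h = 1.1; 500 permutations and 500
PPC replicates).

## Data format

`X` and `T` are separate CSV files with a header row of item ids and one
row per person (first column the person id).  Accuracies must be 0/1,
times strictly positive, no missing cells.

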