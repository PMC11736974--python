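# npsample

Nonparametric sampling of times to events from arbitrary hazards, for
individual-level simulation models (discrete-event simulation,
microsimulation).

Many events in health-policy and epidemiological simulations do not follow a
convenient parametric time-to-event distribution: mortality given by a life
table, or hazards driven by time-varying covariates such as smoking history
or tumor size. `npsample` draws event times from *any* hazard by
discretizing it into a categorical distribution over time intervals,
sampling an interval, and correcting back to continuous time — an
implementation of sampling from a nonhomogeneous Poisson point process that
needs neither numerical inversion nor rejection at draw time.

## Method

Let `h_t` be a piecewise-constant hazard on intervals `[tΔt, (t+1)Δt)`,
`t = 0, …, Z`. Then

- cumulative hazard `H_t = Σ_{x<t} h_x·Δt`,
- CDF `F_t = 1 − exp(−H_t)`,
- interval probabilities `p_t = F_{t+1} − F_t`, with residual beyond-horizon
  mass `1 − F_{Z+1}` carried explicitly.

The event interval is drawn as `X ~ Cat[p_0, …, p_Z]`. For K heterogeneous
individuals (e.g., each with their own covariate path) a multivariate
categorical draw takes one uniform variate per row of a K×(Z+1)
row-stochastic matrix and maps it through that row's cumulative sums. A
continuous-time correction `X_c = X·Δt + Y`, `Y ~ U[0, Δt)`, removes the
systematic `Δt/2` downward bias of reporting interval left edges — akin to a
half-cycle correction, but preserving within-interval spread.

Hazards can enter at any point of the chain: interval hazards `h_t`,
discrete cumulative hazards `H_t`, a continuous `H(t)` (finite-differenced),
a continuous `h(t)` (integrated by quadrature or evaluated at interval
starts), a parametric family (exponential, gamma, log-normal, Gompertz,
Weibull in PH or AFT form), a life table (`h_x = −ln(1 − q_x)`), or a
proportional-hazards model `h_i(t) = h_0(t)·m^{x_i(t)}` with time-independent
or time-dependent covariates.

## Worked example

Draw event times from three parametric hazards on a yearly grid (10,000
draws per repetition, 100 repetitions) and compare with the analytic means:

```sh
npsample example 1 --seed 1
```

```text
 example_id       label  corrected_mean  uncorrected_mean    mc_se  reference reference_kind
          1 exponential       10.008119          9.508061 0.011111  10.000000  analytic_mean
          1       gamma       40.025150         39.525460 0.021706  40.000000  analytic_mean
          1   lognormal       33.482620         32.982783 0.005831  33.490104  analytic_mean
```

The corrected means land on the analytic values (10, 40, 33.49) within
Monte-Carlo error; the uncorrected means sit ≈0.5 below them — exactly the
`Δt/2` bias the uniform correction removes at `Δt = 1`.

The same from the library:

```python
import npsample as nps

grid = nps.HazardGrid(delta_t=1.0, hazards=[0.1] * 400)   # exponential, rate 0.1
pmf = nps.pmf_from_hazards(grid, renormalize=True)
draws = nps.continuous_time_correction(
    nps.sample_univariate(pmf, 100_000, seed=1), seed=2)
print(draws.mean())                        # ~10.0
print(nps.expected_time(pmf))              # 10.008..., the exact expectation
```

Five bundled examples cover parametric hazards (1), life-table mortality for
homogeneous and heterogeneous cohorts (2–3, synthetic Gompertz–Makeham
schedules by default, `--lifetable your.csv` for real ones), a linearly
increasing time-dependent covariate under proportional hazards checked
against direct inverse-cumulative-hazard sampling (4), and Gaussian
random-walk covariate paths sampled jointly with the multivariate
categorical distribution (5). The CLI also offers `convert` (between
hazard / cumulative-hazard / CDF / pmf CSVs) and `sample` (CSV in, drawn
times out).

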