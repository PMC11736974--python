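# Methods

## Model

`npsample` treats a time-to-event process as a nonhomogeneous Poisson point
process whose first event is sampled through a discretized categorical
distribution. The core assumption is a **piecewise-constant hazard**: within
each half-open interval `[tΔt, (t+1)Δt)` the hazard is a constant `h_t`.
Under that assumption the chain

```
H_t = Σ_{x<t} h_x·Δt      F_t = 1 − exp(−H_t)      p_t = F_{t+1} − F_t
```

is exact, and the event interval follows `Cat[p_0, …, p_Z]`. Two deliberate
conventions:

- **Δt-scaled accumulation.** The cumulative hazard is `Σ h_x·Δt`, not the
  unitless `Σ h_x`, so the same hazard values are correct on any grid and a
  constant hazard reduces to `H(t) = λt`. Changing time units is then a pure
  relabelling (`rescale_hazards`: values ×r, Δt ÷r), with `refine` to
  subdivide intervals when sampling on a finer grid.
- **Explicit residual.** A finite grid leaves beyond-horizon mass
  `1 − F_{Z+1}`. It is carried as an explicit residual category — sampled
  draws beyond the horizon return a sentinel and are excluded from means
  with a logged count — rather than silently renormalized, because silent
  renormalization biases expected values. Conditioning on the event is
  opt-in (`EventPmf.renormalized()`, `expected_time(..., conditional=True)`).

## Discretizing continuous hazards: two routes

Given a continuous model there are two ways onto the grid, and they are both
provided because they answer different questions:

1. **Exact route** — difference the true cumulative hazard or CDF at grid
   points (`interval_hazards_from_continuous_cumulative`, or
   `parametric.cdf_grid` when `F` is available in closed form).
   Re-accumulation reproduces `H` at the grid points exactly, so the only
   remaining error is the within-interval placement of the event. This is
   the route used for parametric baselines without covariates.
2. **Left-endpoint route** — evaluate `h(t)` at each interval's left edge
   (`HazardGrid.from_function`). This is the natural (and standard)
   convention for covariate-driven hazards, where the covariate itself is
   known per interval: the covariate is evaluated at the interval start and
   the hazard frozen across the interval. For an increasing hazard it
   understates `H`, giving means slightly above the exact value; the gap
   shrinks linearly with Δt (verified by the Δt-refinement test).

The continuous-time correction adds `Y ~ U[0, Δt)` to the sampled interval's
left edge. A half-open interval is used (the closed/open distinction is
measure-zero) so corrected times satisfy `X·Δt ≤ X_c < (X+1)·Δt` exactly.
The correction raises the mean by exactly `Δt/2`; `expected_time` returns
the resulting exact expectation `Σ tΔt·p_t (+ Δt/2)` as the deterministic
oracle that Monte-Carlo means must converge to. Note the uniform
within-interval placement is itself an approximation — under a constant
within-interval hazard the true placement is truncated-exponential — so for
a constant hazard λ the corrected expectation is `Δt/2 + Δt·q/(1−q)` with
`q = e^{−λΔt}`, which differs from `1/λ` by O(λΔt²/12). At λΔt ≈ 0.1 the
bias is below 0.01 time units.

## Sampling

- **Univariate:** inverse-CDF on the cumulative sums of `p_t`, one uniform
  per draw (`numpy.random.Generator` streams; any function taking a seed
  also accepts a Generator).
- **Multivariate:** one draw per individual across K heterogeneous hazards.
  One uniform per row, mapped through the row's cumulative sums — a
  vectorized row-wise inverse CDF, O(K·Z), fully reproducible. This is what
  makes covariate-path cohorts cheap: the K×(Z+1) probability matrix is
  built once (vectorized over individuals) and redrawing costs one uniform
  per individual.
- The correction consumes an independent random stream, so corrected and
  uncorrected results from the same sampling seed are paired draw-by-draw.

## Covariates

Proportional hazards: `h_i(t) = h_0(t)·m^{x_i(t)}`. The effect multiplier
`m` per covariate unit is specified either as a log-hazard ratio
(`m = e^β`, the Cox convention) or directly as a hazard ratio (`m = β`).
The two are deliberately explicit in `EffectSpec` because published effect
sizes are quoted in both conventions and confusing them changes hazards by
orders of magnitude; the bundled time-dependent-covariate example uses the
hazard-ratio reading (`1.02^x(t)`), validated against the direct-sampling
comparator's survival integral. Covariates are evaluated at interval left
endpoints, consistent with the piecewise-constant assumption. Gaussian
random-walk paths (`y(t) = y(t−1) + ε`, `ε ~ N(0, σ)`, `y(0) = 0` by
default) model individual exposure histories.

## Parametric families and oracles

Six baseline families with explicit parameterizations (see
`parametric.py`); Weibull appears in both proportional-hazards form
(`h = shape·scale·t^{shape−1}`) and accelerated-failure-time form
(`h = (shape/scale)(t/scale)^{shape−1}`) because both circulate in the
survival literature. Three mutually independent references triangulate the
sampler:

1. `analytic_mean` — closed forms (Gompertz via `e^{a/b}·E1(a/b)/b`).
2. `numeric_mean_from_hazard` — `E[T] = ∫ exp(−H(t)) dt` by composite
   Simpson on a dense grid (200 points per time unit), with a hard check
   that survival at the horizon is below tolerance (default 1e−8) so
   truncation bias stays below reporting precision.
3. `direct_sample` — `T = H^{−1}(−log U)`: exact inverse CDFs via
   scipy.stats without covariates; with a linear covariate path the combined
   cumulative hazard is closed-form for the exponential, Gompertz, and
   quadratic Weibull-PH baselines and inverted by vectorized bisection to
   1e−10, falling back to a dense cumulative-Simpson grid (200k points) for
   other shapes.

## Life tables

`q_x → h_x = −ln(1 − q_x)` (exact under the within-interval constant-hazard
assumption; central rates `m_x` pass through unchanged). The final
tabulated row is an open interval: its hazard is extended to a terminal cap
age (default 110) so the residual mass is negligible, instead of forcing
`F = 1` at the last age, which would spike the final category. `q_x = 1`
before the terminal row is rejected (infinite hazard); in the terminal row
the preceding age's hazard is used for the extension.

The synthetic schedule used by the examples and tests is a
**Gompertz–Makeham law** `h(x) = c + a·e^{bx}` with `a = 1e−4`,
`b = 0.09`, `c = 2e−4` — an adult-mortality doubling time of ≈8 years and a
small age-independent background, yielding a life expectancy of ≈69 years
and `q_x` profiles shaped like national all-cause schedules. The
heterogeneous cohort scales the law's level by 0.85/1.15 for the two
groups. What the synthetic tables do *not* emulate: infant mortality (no
early-age hump), cohort effects, and late-age mortality deceleration.
Passing tests therefore demonstrate the life-table pipeline's correctness
against the generating law, not demographic realism; user-supplied tables
go through the identical code path via `read_life_table`.

## Problem sizes and numerical choices

- Example defaults: 10,000 draws × 100 repetitions for the parametric
  comparisons; 100,000 draws for the cohort examples; 1,000,000 for the
  time-dependent-covariate comparison; 1,000 random-walk paths × 100
  repeated draws. These match the library's accuracy targets at
  desk-friendly runtimes; `--n`/`--reps` scale them.
- Grid horizons are set where the baseline survival drops below 1e−13
  (parametric examples) or at the covariate examples' fixed spans (200
  intervals; 100 years for the random-walk cohort, whose ≈1% beyond-horizon
  draws are reported, not hidden).
- Negative numerical noise: finite differences of a supplied `H(t)` or CDF
  more negative than −1e−12 raise; smaller noise is clipped to zero.
  `p_t + residual` sums to 1 to better than 1e−12 by construction.
- Degenerate inputs: zero hazards everywhere give all mass to the residual;
  `expected_time` refuses a residual without explicit conditioning; a
  defective combined hazard (bounded `H`) makes the bisection bracket
  expansion fail with a diagnostic rather than loop.

## Known limitations

- No guidance on choosing Δt: interval width is the user's call, and wide
  intervals on fast-changing hazards misrepresent the process.
- Uniform grids only (one Δt per grid).
- The within-interval uniform correction leaves the O(λΔt²) bias described
  above; for expected values only, `expected_time` gives the exact
  discretized expectation without sampling noise.
- Beyond-horizon draws are excluded from means (with counts logged and
  reported); analyses where censoring at the horizon matters should treat
  the sentinel draws explicitly.
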