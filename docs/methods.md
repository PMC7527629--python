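# Methods

## Model and assumptions

The HSC compartment is modelled as a Moran process: a constant population of
`N` cells in which, at each event, one cell dies and one proliferates. With
directional selection the wildtype proliferates with weight `1 − s`, `s ∈ [0, 1)`;
recurrent mutation converts each wildtype cell to mutant at rate `μ` per cell
per generation. In continuous time the mutant count `i` jumps with intensities

    q(i→i+1) = (N−i)·i/N + μ·(N−i),    q(i→i−1) = i·(1−s)·(N−i)/N.

Assumptions inherited by everything downstream:

- **Constant N.** No growth of the HSC pool (not valid in early childhood);
  `N` cancels out of the mean-field curve and the estimator, so it only
  affects stochastic variability.
- **Two alleles, one-way mutation.** A single mutant receptor class; back
  mutation is ignored. Multiple distinct truncating variants can be absorbed
  as a multiplicity factor on `μ` (≲10×), which changes nothing qualitatively.
- **Time unit.** One generation = one expected division per cell. Calendar
  time enters only through `λ` (divisions per year) in the estimator layer.
- **Monotone growth regime.** The estimator assumes the clone's frequency
  moved monotonically between the two samplings; persistent reversals are
  outside the model.

With `μ > 0` the state `i = 0` is live (extinct lineages are re-seeded) and the
chain is eventually absorbed at `i = N`. The mutation-free absorption
probability `(1−(1−s)^i)/(1−(1−s)^N)` is computed via `expm1`/`log1p`, which
keeps full precision as `s → 0` and connects continuously to the neutral limit
`i/N` (returned exactly at `s = 0`). The fixation-time asymptotic `(2/s)·ln N`
is exposed for reference only; it is coarse at moderate `N` and is never used
in estimation.

## Mean-field curve and its bias

Replacing the count by its expectation gives `ẏ = s·y(1−y) + μ(1−y)` and the
explicit solution quoted in the README. This is an approximation, not the
exact expectation: the exact mean obeys `dȳ/dt = s(ȳ(1−ȳ) − Var[y]) + μ(1−ȳ)`,
so the closed form runs slightly ahead of the true mean while the ensemble
variance is large. At `N = 10⁴`, `s = 0.01`, starting from `y₀ = 0.2`, the gap
peaks around 0.012 in frequency near the middle of the logistic ramp and
vanishes at both ends; it shrinks roughly like `1/N`. Tests therefore compare
simulation means to the curve within Monte-Carlo error rather than exactly,
and a single 200-replicate ensemble can occasionally brush a 3-standard-error
band precisely because the deterministic gap is a sizeable fraction of that
band.

At `s = 0` the ratio `u = μ/s` is undefined; the curve falls back to the exact
pure-mutation solution `y(t) = 1 − (1−y₀)e^{−μ(t−t₀)}`, keeping the API total
over the parameter space.

## Estimator

    ŝ = ln(α₀/α₁) / [(1+u)·λ·Δt],    αᵢ = (1−yᵢ)/(yᵢ+u),    u = μ/s.

Sign convention: since `α` decreases in `y`, a growing clone has `α₁ < α₀` and
the ratio is written `α₀/α₁` so that growth gives positive `ŝ` (consistent with
`α₁ = α₀·e^{−(μ+s)Δt}`; the inverted ratio sometimes seen in print is an
apparent sign slip). Each `EstimateResult` carries both the `α` values and the
plain odds `y/(1−y)` — clinical tabulations print the odds, which at `u = 0`
are the reciprocals of the `α`s.

One frequency pair cannot identify `(s, μ)` jointly; `tradeoff_curve` traces
`ŝ(u)` with its implied mutation rate `u·ŝ(u)`. For the weakest growing clone
in the shipped dataset (ŝ(0) ≈ 0.0024), a 10% depression of ŝ is reached once
the implied μ is of order 10⁻⁵–10⁻⁴ per generation — several orders of
magnitude above typical human per-nucleotide rates, hence μ = 0 is the default
reporting assumption. `ŝ` scales exactly as `1/λ`; `λ = 24/year` (15-day
interdivision time) is the default, and `sensitivity_to_lambda` quantifies the
dependence.

Estimates may be negative (shrinking clone); parameter containers for the
*chain* enforce `0 ≤ s < 1`, while estimation output is unconstrained.

## Clinical dataset

`data/table1.csv` holds the 14 two-time-point records (frequencies, interval,
λ = 24, printed odds and ŝ, disease phase, variant label) exactly as published.
Recomputing from the printed inputs reproduces the printed ŝ for records
4, 8, 9, 11, 13, 14 at 3-decimal rounding; records 1, 2, 3, 5, 6, 7, 10, 12
differ in the last digit or worse (e.g. record 1: 0.008 recomputed vs 0.002
printed). The printed frequencies are rounded readings of source-publication
figures, so the original spreadsheet presumably used unrounded inputs;
`reproduce_table1` reports both values side by side with match flags and never
substitutes one for the other. Only the exactly-reproducing records serve as
hard regression anchors.

The interval summary reports Pearson and Spearman correlations of ŝ against
the observation interval, both with and without the single negative-ŝ record
(a shrinking clone sits outside the growth model). The negative association is
plausibly ascertainment: faster progression gets re-sequenced sooner, which
also means the estimates are, if anything, biased upward. No correction is
attempted. Phase means are reported for MDS, AML and unclassified records.

## Simulation

The sampler is the exact Gillespie algorithm: exponential holding time at rate
`q↑ + q↓`, upward jump with probability `q↑/(q↑+q↓)`. Two code paths:

- `simulate_trajectory` stores every jump (sparse times + states) for
  inspection of individual paths; an event cap (default `10·N·t_max`) guards
  against off-scale parameters.
- a numba-compiled kernel evaluates the chain on a fixed time grid without
  storing jumps; ensembles at `N = 10⁴` over 600 generations involve ~10⁶
  jumps per replicate, so this path is what makes ensemble studies practical.
  The kernel was validated against a master-equation (matrix-exponential)
  oracle at small `N`.

Replicate seeds are spawned from one master seed via `SeedSequence`, making
ensembles reproducible and order-independent. Ensemble standard deviations use
the population convention (`ddof=0`), so a single replicate reports SD 0.

## Synthetic data and what it does (not) show

`SyntheticScenario` emulates exactly the structure the estimator consumes: a
true Moran trajectory with known `(N, s, μ)` started from `round(y₀·N)`
mutants, sampled at two times `λ·Δt` generations apart, optionally observed
through binomial sampling at a finite read depth. Defaults mirror the
simulation studies: `y₀ = 0.2`, `λ = 24/year`, 200 replicates, noise-free
(infinite depth). The binomial read-depth model is this package's own
stand-in — the clinical sources report no noise model — and real sequencing
error (mapping bias, batch effects, CNV-distorted allele fractions) is richer
than binomial thinning. Recovery experiments choose the interval so the mean
frequency grows from 0.2 to about 0.5 (`Δt = ln 4 / s` generations), the
regime where the logistic signal is strongest.

Boundary handling: finite-depth draws landing exactly on 0 or 1 are redrawn
(the estimator's domain is open; silent clamping would bias recovery);
trajectories truly absorbed at 0 or `N` raise an explicit error and are
counted, not imputed.

Passing recovery tests show the estimator is consistent with its own
generative model at realistic scale (median ŝ within 20% of truth at
`N = 10⁴`, 200 noise-free replicates); they do not certify accuracy on real
patients, where `N`, `λ`, measurement error and ascertainment are all
uncertain.

## Numerical and design choices

- Problem sizes in the test suite are chosen for desk-scale runs: 200
  replicates for ensemble/recovery studies, `N ≤ 10⁴`, horizons ≤ 600
  generations; the variance-scaling study uses `N ∈ {1000, 4000, 10000}`.
- Closed form vs ODE: verified to 1e−8 relative against adaptive
  Runge–Kutta integration across the full simulation parameter grid.
- Estimator/curve round trip is exact to 1e−10 at `μ = 0`.
- Rounding for reproduction mirrors the published printing: ŝ to 3 decimals,
  odds to 2.
- CSV (UTF-8, comma, header, `.` decimal) is the only tabular format; outputs
  carry a `.meta.json` sidecar with parameters, seed and package version, so
  identical configurations give byte-identical results.
- Errors: invalid parameters raise `InvalidParameterError` (CLI exit code 2);
  runaway simulations raise `RunawaySimulationError`; unusable synthetic
  observations raise `BoundaryObservationError`.

## Limitations

- No variance dynamics for the mean-field model (only simulation-based).
- No joint `(s, μ)` identification, confidence intervals, or >2 time points.
- No ascertainment-bias correction; estimates from interval-censored clinical
  sampling are likely upper-ish bounds.
- Constant `N` excludes childhood HSC-pool growth.
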