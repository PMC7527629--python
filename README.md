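# moranselect

Severe congenital neutropenia (SCN) patients treated long-term with G-CSF often
acquire truncating somatic mutations in *CSF3R*, the G-CSF receptor gene; the
expansion of these mutant clones in the hematopoietic stem cell (HSC) pool marks
the transition toward myelodysplastic syndrome (MDS) and acute myeloid leukemia
(AML). `moranselect` models that expansion as a Moran process with directional
selection and recurrent mutation, and estimates the selection coefficient *s* of
a mutant clone from as little as two sequencing-based frequency measurements.

It is aimed at researchers in clonal hematopoiesis and population genetics who
want ballpark, reproducible selection-coefficient estimates from longitudinal
variant-allele-frequency data, together with the stochastic machinery to
validate the estimator end to end.

## Model

A constant population of *N* HSCs holds *i* mutant cells. In continuous time
(one generation = one expected division per cell) the mutant count jumps with
intensities

    q(i → i+1) = (N−i)·i/N + μ·(N−i)        q(i → i−1) = i·(1−s)·(N−i)/N

where *s* ∈ [0, 1) is the mutant's selective advantage and μ the per-cell
per-generation rate of recurrent mutation (which re-seeds extinct mutant
lineages). Replacing the count by its expectation and rescaling *y = i/N* gives
the mean-field ODE *ẏ = s·y(1−y) + μ(1−y)*, whose explicit solution, with
*u = μ/s* and *α₀ = (1−y₀)/(y₀+u)*, is

    y(t) = [1 − u·α₀·e^{−(μ+s)(t−t₀)}] / [1 + α₀·e^{−(μ+s)(t−t₀)}].

Inverting this for two observed frequencies *y₀*, *y₁* taken Δt years apart,
with λ divisions per year (default 24, a 15-day interdivision time), yields

    ŝ = ln(α₀/α₁) / [(1+u)·λ·Δt],     which at u = 0 is the
    per-generation change in log-odds:  ŝ = ln[(y₁/(1−y₁))/(y₀/(1−y₀))] / (λ·Δt).

A single frequency pair constrains (*s*, μ) only to a trade-off curve indexed
by *u*; unless the mutation site is an extreme hot-spot (μ approaching 10⁻⁴ per
generation), the μ = 0 estimate is essentially unchanged. *N* never enters the
estimate.

## Worked example

The package ships a 14-record clinical dataset of truncated-*CSF3R* frequencies
collated from three published longitudinal sequencing studies:

```python
>>> from moranselect import TwoPointObservation, estimate_s_given_u
>>> obs = TwoPointObservation(y0=0.56, y1=0.83, dt_years=3.0, lam=24.0)
>>> res = estimate_s_given_u(obs, u=0.0)
>>> round(res.s_hat, 3), round(res.odds0, 2), round(res.odds1, 2)
(0.019, 1.27, 4.88)
```

The clone grew from 56% to 83% in 3 years (72 generations), a log-odds change
of ln(4.88/1.27), i.e. a selective advantage of about 1.9% per generation —
this is the dataset's "pt. 6 ph. 2" AML-phase record. Reproducing the whole
table and its interval summary from the shell:

```sh
moranselect table1 --out-dir out/
```

writes `table1_reproduction.csv` (recomputed vs printed odds and ŝ per record,
with match flags: 6 of 14 records reproduce the printed ŝ exactly at 3-decimal
rounding; the rest differ in the last digit or worse because the printed
frequencies are rounded figure readings, and are flagged rather than altered)
and `fig3_summary.json`, which on the shipped data reports a negative
association between ŝ and the observation interval (Pearson r = −0.48 excluding
the sole shrinking clone) and a higher mean ŝ for AML-phase than MDS-phase
records (0.024 vs 0.009).

Other subcommands: `simulate` (exact Gillespie trajectories/ensembles),
`mean-curve` (the closed form), `estimate` (batch CSV estimation), `recover`
(parameter-recovery experiments on synthetic ground truth). All accept
`--config file.yaml` and write run metadata next to every output.

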