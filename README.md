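# hetsvar

Structural vector-autoregression (SVAR) analysis of daily count time series,
with the contemporaneous effects identified **through heteroskedasticity**
rather than exclusion restrictions.

The package was built for a specific class of problem in quantitative
criminology / epidemiology of violence: three jointly evolving daily series —
law-enforcement officers shot to death (`law`), citizens shot by police
(`ctz`, either minorities or white non-Hispanics), and the daily volume of
Black-Lives-Matter-related tweets (`twt`) — where the question is how a
same-day shock to one series moves the others. Nothing in the code is
specific to those labels; any trivariate daily system of zero-heavy counts
plus a nonstationary volume series fits.

## The model

Counts are stabilized with the inverse hyperbolic sine (IHS),
`g = ln(θy + √(1+θ²y²))` with `θ = 1` (i.e. `asinh`), which is log-like for
large `y` but defined at zero, so coefficients read as elasticities. The
nonstationary tweet series additionally enters in first differences. The
reduced form is a VAR(p),

```
Z_t = D_0 + D_1 Z_{t-1} + … + D_p Z_{t-p} + e_t ,
```

whose residuals are correlated composites of uncorrelated structural shocks,
`e_t = A⁻¹ ε_t`, with `A⁻¹` normalized to a unit diagonal (six free
off-diagonal coefficients `δ_jk`). One residual covariance matrix gives 6
moments for 9 unknowns; identification comes from a **volatility regime
break**: with two regimes the moment system

```
Σ_i = A⁻¹ diag(var ε^(i)) A⁻ᵀ ,   i = 1, 2
```

has 12 equations and 12 unknowns. The break is located by least-squares
mean-shift segmentation (dynamic programming, BIC-selected break count) of
the 20-day rolling volatility of the tweet series. Standard errors come from
a fixed-design wild bootstrap of the whole chain; impulse responses are
`Φ_h = Ψ_h A⁻¹` from companion-matrix powers, with the differenced tweet row
reported cumulatively.

A synthetic-data generator (`hetsvar.simulate`) draws panels from a known
ground truth (deltas, lag matrices, two-regime shock variances, break day),
so every stage is testable by parameter recovery.

## Worked example

```python
from hetsvar.pipeline import RunConfig, run

config = RunConfig(simulate_preset="paper", T=639, B=199, seed=7,
                   output_dir="bundle")
res = run(config)["minorities"]
print("lag order       ", res.lag_order)
print("break date      ", res.break_date.date())
print("deltas          ", res.solution.deltas.round(3))
print("tweet var ratio ", res.diagnostics.variance_ratios[2].round(3))
```

prints (exactly, for this seed):

```
lag order        1
break date       2016-06-20
deltas           [-0.067  0.475  0.555  0.574 -0.109 -0.007]
tweet var ratio  2.968
```

Reading: the generator placed its variance break at 2016-06-26 and the
pipeline dated it 2016-06-20 from the rolling volatility alone; the
recovered contemporaneous coefficients (ordered `d12, d13, d21, d23, d31,
d32`) show the sign pattern of the generating system — e.g. `d21 = 0.555`
means a 1% structural shock to officer deaths is associated with a ~0.56%
same-day increase in citizens shot — and the tweet-shock variance is ~3×
larger after the break. Magnitudes are attenuated relative to the
generating values because the pipeline here estimates from round-clamped
integer counts; see `docs/methods.md`.

The same run from a shell:

```
hetsvar simulate --T 639 --seed 7 --out panel.csv
hetsvar run --input panel.csv --bootstrap 199 --seed 7 --out bundle
```

The bundle contains per-model summary tables, stationarity tests,
coefficient/variance tables with bootstrap p-values, the IRF grid with 1-
and 2-sd bands, practical count conversions, and an echoed config for
provenance.

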