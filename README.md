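# standres — stand-level forest resilience under gap-cut management

`standres` quantifies how *gap cuts* — partial harvests that establish a
young regeneration cohort inside an even-aged stand before rotation age —
change the resilience and the economic/carbon performance of managed forest
stands exposed to stochastic, age-dependent disturbances (storms, bark
beetles).  It is written for forest economists and silviculture researchers
who want a transparent, fully simulation-based alternative to closed-form
stand valuation.

## The model in brief

A stand is at most two age-homogeneous cohorts (ages on a 5-year grid, area
shares summing to 1), managed under a regime *R*: the clear-cut baseline
(plant, thin per yield table, harvest at rotation age *u* = 85, replant) or
a gap-cut regime removing a canopy share *s*<sub>gap</sub> at stand age
*age*<sub>gap</sub> (grid: *s*<sub>gap</sub> ∈ {0.10 … 0.30} ×
*age*<sub>gap</sub> ∈ {20, 40, 60} → 15 regimes).

**Disturbance.** A survival function *S*(*a*) (default: Weibull) is
converted to per-step hazard rates *hz*(*a*) = 1 − *S*(*a*+5)/*S*(*a*).
One uniform draw *y* ~ *U*(0,1) per stand per step is shared by both
cohorts: cohort *i* drops out completely iff *y* ≤ *hz<sub>i</sub>*,
followed by salvage logging and replanting.  Sheltered (non-leading)
cohorts get a reduced hazard *hz*<sub>new</sub> = *red*<sub>hz</sub> · *hz*
with 0 ≤ *red*<sub>hz</sub> ≤ 1.  Draw streams are **common random
numbers**: identical across regimes within a run, so every disturbance has
an exact counterfactual analogue under every regime.

**Valuation.** Each trajectory yields two provision series: net-revenue
cash flows *CF<sub>t</sub>* (thinnings + harvests + gap cuts + salvage −
planting costs; salvage at 74 % price / 115 % cost; planting 2000 €/ha,
doubled after salvage, halved in gaps) and aboveground carbon sequestration
(gross volume increment × 205 kg<sub>C</sub> m⁻³ = 410 kg m⁻³ × 0.5).

**Present values.** The value of the ecosystem service *ES* at a stand
state is

&nbsp;&nbsp;&nbsp;&nbsp;*V*<sub>ES</sub> = 𝔼[ Σ<sub>t≥0</sub>
*p*<sub>ES,t</sub> (1+*r*)<sup>−t</sup> ],&nbsp;&nbsp; *r* = 1.5 %
(financial) / 0.5 % (carbon),

estimated by Monte Carlo: a 1000-year moving window rolled along each
simulated series (default 1000 runs × 2000 yr per regime) gives one
discounted sample per step; samples are pooled by stand state and averaged.
The first (bare-soil) sample of each run is that run's soil expectation
value (SEV, the Faustmann value).

**Resilience.** Recovery time of a disturbance is the (linearly
interpolated) time until the stand's value path regains the threshold
*F*<sub>bound</sub> / *C*<sub>bound</sub>, the average baseline value.
Counterfactually paired recovery-time gains and SEV differences give the
trade-off metric

&nbsp;&nbsp;&nbsp;&nbsp;τ = Δ̄P / Δ̄t<sub>rec</sub>
&nbsp;&nbsp;(SEV change per year of average recovery-time reduction).

The three empirical inputs — survival coefficients, yield table, timber
price/cost system — are pluggable config files; the package ships a
*synthetic* but structurally faithful default bundle so everything runs
out of the box.

## Worked example

```python
from standres import RunConfig, run_experiment

cfg = RunConfig(seed=1, n_runs=50, series_years=2000,
                gap_sizes=[0.1, 0.3], gap_ages=[40, 60])
res = run_experiment(cfg)

fin = res.summary.query("es == 'financial'")
cols = ["regime", "sev_mean", "sev_delta", "mean_recovery_gain", "tau"]
print(fin[cols].round(2).to_string(index=False))
print(f"\nfinancial recovery threshold: {res.thresholds['financial'].value:,.0f} EUR/ha")
base = fin.query("regime == 'clearcut'").iloc[0]
print(f"baseline mean recovery time:  {base['mean_own_recovery']:.1f} years")
```

prints (seed 1, synthetic default parameters):

```
       regime  sev_mean  sev_delta  mean_recovery_gain   tau
     clearcut   4679.11       0.00                0.00   NaN
gap_s0.10_a40   4480.61    -198.50               -4.76 41.75
gap_s0.10_a60   4635.19     -43.92               -3.01 14.58
gap_s0.30_a40   4147.02    -532.09               -8.39 63.45
gap_s0.30_a60   4553.29    -125.82               -3.15 39.90

financial recovery threshold: 15,203 EUR/ha
baseline mean recovery time:  47.9 years
```

Reading this: under the synthetic defaults the clear-cut baseline earns a
mean SEV of ≈ 4679 €/ha and needs ≈ 48 years to regain the average-value
threshold after a disturbance.  Every gap-cut regime here pays an SEV
premium (`sev_delta` < 0); with these default competition/hazard
coefficients the gap regimes' depressed value paths also lengthen mean
paired recovery (`mean_recovery_gain` < 0 means slower than baseline).
With empirical parameter files the balance of the structural benefit
(surviving regeneration) against the performance premium shifts — that
trade-off is exactly what τ measures.

The same analysis is available from the shell:

```sh
standres fixtures --out params/          # write the synthetic bundle
standres run-all --seed 1 --out output/  # simulate, value, assess, export CSVs
```

## Layout

| module | contents |
| --- | --- |
| `stand_model` | regimes, cohorts, stand states, management scheduler |
| `disturbance` | survival/hazard model, hazard reduction, shared-draw engine |
| `growth_yield` | yield table, young-age interpolation, competition modifiers |
| `es_valuation` | net revenues, planting costs, carbon conversion |
| `value_estimation` | moving-window discounting, state aggregation, SEV |
| `resilience` | thresholds, event typing, recovery times, pairing, τ |
| `config` / `fixtures` / `pipeline` / `cli` | configuration, synthetic parameter bundle, orchestration, CLI |

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
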