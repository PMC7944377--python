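# selsurv

Microsimulation of **selective-survival (collider) bias** in estimated
sex/gender differences in dementia incidence.

Most people living with dementia are women, and several cohort studies report
higher age-specific dementia incidence in women than in men after age 85. One
candidate explanation is not biological at all: if some characteristic *U*
(genetic risk, childhood disadvantage, cardiovascular disease, ...) harms both
survival and late-life cognition, and harms *men's* survival more than
women's, then men who reach old age are a more favorably selected group than
women who reach old age — and women will show higher dementia rates among
survivors even when sex/gender has exactly **zero** causal effect on dementia
for every individual. `selsurv` quantifies how large that bias can plausibly
be. It is aimed at epidemiologists and biostatisticians studying survival
bias, and is equally usable as a general template for seeded, calibrated
cohort microsimulations.

## Model

A cohort of *n* = 100 000 adults starts dementia-free at age 50 (51% women)
and is followed to age 95. Each person *i* carries sex *S_i* ∈ {0 = man,
1 = woman}, a selection characteristic *U_i* ~ N(0, 1) independent of sex at
baseline, and cognitive random effects (b₀, b₁, b₂).

**Mortality** is piecewise-exponential over 5-year age bands *b* with a
frailty term on *U*:

    h_i(b) = exp( λ_{b,S_i} + β_U(S_i) · U_i )

Per scenario, β_U is 0 for both sexes (*no selection*), equal for both sexes
(*homogeneous*), or nonzero for men only (*heterogeneous*); effect sizes are
log 2.0 (*moderate*) or log 3.5 (*large*). The baseline log hazards λ are
recalibrated for every scenario so that each sex reproduces a lifetable's
conditional 5-year survival probabilities *marginally over U* — survival
totals are identical across scenarios, only *who* survives changes.

**Cognition** follows a person-specific quadratic in t = years since age 50:

    C_i(t) = (γ₀ + δ_U·U_i + b₀ᵢ) + (γ₁ + b₁ᵢ)·t + (γ₂ + b₂ᵢ)·t²

with δ_U = −0.1 (moderate) or −0.5 (large) SD of cognition per SD of *U*.
Dementia onset is the earlier of (a) the first downward crossing of an
age-constant cutoff θ (closed-form quadratic root) and (b) an exogenous
"shock" event (piecewise-exponential, independent of everything). θ and the
per-band shock hazards are calibrated so men's age-band incidence tracks a
target rate table. **Sex appears nowhere in the dementia model** — the sharp
null — so any estimated sex difference downstream is bias.

**Estimand.** Within each band, the women-vs-men incidence rate ratio is
IRR = (cases_w / PY_w) / (cases_m / PY_m) with person-years accumulated in
continuous time until min(onset, death, 95). Across Monte-Carlo iterations a
band is summarized as exp(mean log IRR) with empirical 2.5/97.5-percentile
intervals; the bias is the departure from the true IRR of 1.00.

Bundled calibration inputs are *synthetic, documented stand-ins* (see
`src/selsurv/data/manifest.json`): a Gompertz-built lifetable matching median
survival 22.6/23.6 years (men/women) and ~99.1% cumulative mortality by 95,
and a male incidence-target schedule doubling from 2 to 80 per 1000
person-years across ages 65–94.

## Worked example

```python
import warnings
from selsurv import ScenarioConfig, run_scenario, summarize_irr, bias_report

config = ScenarioConfig(
    scenario="heterogeneous",   # U raises mortality for men only
    effect_size="moderate",     # beta_u = log 2.0, delta_u = -0.1
    n=100_000,
    n_iterations=200,
    master_seed=7,
)
result = run_scenario(config)

irr = summarize_irr(result.tallies)
print(bias_report(irr[irr.band_start >= 80]).round(3).to_string(index=False))
print(result.calibration.report.round(2).to_string(index=False))
```

prints

```
 band_start  point  ci_low  ci_high  n_iterations_used  n_excluded  bias  ci_excludes_truth
         80  1.105   1.013    1.206                200           0 0.105               True
         85  1.106   0.992    1.213                200           0 0.106              False
         90  1.090   0.916    1.297                200           0 0.090              False

 band_start  target  achieved  rel_error
         65     2.0      2.06       0.03
         70     4.5      4.49      -0.00
         75    10.0     10.05       0.00
         80    22.0     22.08       0.00
         85    40.0     40.43       0.01
         90    80.0     82.48       0.03
```

Reading: the data were generated with **no** sex/gender effect on dementia,
yet male-only selection on *U* makes estimated dementia incidence ~10% higher
in women at ages 80+ (`bias` column); the calibration report confirms men's
incidence tracks the target schedule within a few percent. Under
`scenario="no_selection"` the same pipeline returns points within ~0.01 of
1.00 — the built-in null check.

The same runs are available from the shell:

```bash
selsurv simulate --scenario heterogeneous --effect-size moderate \
    --iterations 200 --seed 7 --out out/het_mod
selsurv summarize --tallies out/het_mod/tallies.csv --out out/het_mod
```

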