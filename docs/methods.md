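# Methods

This note documents the data-generating model, its parameters and defaults,
the calibration procedures, the numerical choices, and what the synthetic
study conditions do and do not establish about real data.

## 1. Population and causal structure

Each simulated person starts at age 50, dementia-free, with:

* sex/gender `S` (woman = 1): a deterministic count split, exactly
  `round(n · p_female)` women (default 51%), randomly positioned — the split
  is exact rather than binomial because the emulated cohort is described by
  an exact count;
* selection characteristic `U ~ N(0, 1)`, independent of sex at baseline.
  Larger `U` is harmful to both survival (in selection scenarios) and
  cognition;
* random effects `(b0, b1, b2)` of the cognitive trajectory. `b0` and `b1`
  are correlated (`rho01`); `b2` is independent of both, because the
  substantive claim being encoded is a dependence between *level* at 50 and
  *rate of change*, not curvature.

The three scenarios differ only in the mortality coefficient on `U`:
none / both sexes equally / men only. Sex never enters the dementia model
(sharp null): every estimated sex difference in incidence is selection bias
by construction. Follow-up is the half-open interval [50, 95) in continuous
time; age bands are [a, a+5).

## 2. Mortality

Piecewise-constant per-year hazard in band `b`:
`h = exp(lambda[b, S] + beta_u(S) * U)`, with `beta_u` = 0, log 2.0 or
log 3.5 per scenario and effect size. Death ages are drawn by exact
piecewise-exponential inversion of a single Exp(1) draw per person through
the person's cumulative hazard. Age 95.0 denotes administrative censoring.

**Calibration.** For each sex, band by band in age order, `lambda` is chosen
by bisection on [−20, 5] so that the *conditional* band survival of the
current survivor population equals the lifetable `s5`. The survivor
population is carried forward as importance weights
`w_i <- w_i · exp(−5·h_i)` over the baseline `U` sample, and the bisection
target is the exact weighted mean `sum(w · exp(−5h)) / sum(w)`. This carries
the post-selection (non-normal) `U` distribution into later bands exactly,
is deterministic given the seed, and has no within-bisection Monte-Carlo
noise; single-band results agree with Gauss–Hermite quadrature over normal
`U` to <0.02 on the log scale (tested). Calibration is re-run for every
`beta_u` configuration, which is why all scenarios share identical marginal
survival (tested: cumulative mortality by 95 agrees across scenarios within
0.3 percentage points).

Dementia does not feed back into mortality: the causal diagrams being
emulated draw no arrow from dementia to survival, so death ages are drawn
independently of onset; at-risk person-time for incidence nevertheless ends
at onset. This is the package's default and only behavior.

## 3. Cognition and dementia onset

`C(t) = (gamma0 + delta_u·U + b0) + (gamma1 + b1)·t + (gamma2 + b2)·t²`,
in SD-of-cognition-at-50 units. `sigma0` is always derived as
`sqrt(1 − delta_u²)` so that the marginal SD of `C(0)` is exactly 1 and
`delta_u` (−0.1 moderate, −0.5 large) reads in SD units.

Onset is `min(crossing time, shock time)`:

* **Crossing**: the earliest `t` in [0, 45] with `C(t) < theta`, from the
  closed-form quadratic roots (linear and constant degenerate cases handled;
  a tangency never goes strictly below the cutoff and counts as no
  crossing). Verified against a 0.001-year grid search on 1000 random
  quadratics.
* **Shock**: piecewise-exponential over bands, independent of `U`, sex and
  cognition — the simplest structure that preserves the sharp null.
* An exact tie resolves to "crossing" (deterministic, documented).
* Onset is absorbing; later recovery of the trajectory is irrelevant.

**Baseline screening**: anyone with `C(0) <= theta` has `b0` redrawn until
the cohort is dementia-free at 50 (rejection rate above 50% raises). The
redraw intentionally touches only the intercept; with the default cutoffs the
redraw rate is ≲0.01%, so the broken `b0`–`b1` correlation among redrawn
individuals is negligible.

**Calibration of (theta, shock hazards)** against a male target-rate table:

1. `theta` is bisected to the *largest* cutoff at which the crossing-driven
   incidence of a male calibration sample (n = 100 000, death ages drawn from
   the calibrated schedule) overshoots no target band. Shocks can only add
   incidence, so any crossing overshoot would be uncorrectable; this choice
   makes the procedure able to recover an arbitrary feasible
   (theta, shock) truth from its own rates (tested round trip). `theta` is
   additionally capped at the 1st percentile of baseline cognition so
   screening perturbs the population by at most ~1%.
2. Each target band receives a shock hazard equal to its remaining rate
   shortfall (shocks are additive for band rates to first order); bands
   overshooting despite step 1 (Monte-Carlo noise) get zero and a warning.

The calibration report (band, target, achieved, relative error) is the
authoritative statement of fidelity; targets are a guide, and a band off by
more than twice the stated relative tolerance is an error. Women's incidence
is never calibrated — it is emergent, which is the entire point.

## 4. Estimation

Per iteration and band: `IRR = (cases_w/PY_w) / (cases_m/PY_m)`, with a case
credited to the band of its onset age only when onset strictly precedes both
death and 95, and person-years accrued continuously until
`min(onset, death, 95)`. Iterations with zero cases in either sex leave the
band's IRR undefined; they are dropped and counted, with no continuity
correction (corrections would bias the mean-log estimator). Across
iterations: point = exp(mean log IRR); the default 95% interval is the
empirical 2.5/97.5 percentile of per-iteration IRRs, with a normal-theory
log-scale interval available as an option (the estimator's interval
construction is not otherwise pinned down; percentile is the weaker
assumption).

## 5. Default parameters

| parameter | default | units / rationale |
|---|---|---|
| n | 100 000 | cohort size; balances old-age survivor counts vs runtime |
| p_female | 0.51 | 51% women at 50 |
| beta_u | log 2.0 / log 3.5 | mortality hazard ratio per SD of U, moderate / large |
| delta_u | −0.1 / −0.5 | SD of cognition at 50 per SD of U |
| gamma0 | 0 | mean cognition at 50 (units anchor) |
| gamma1 | −0.025 | mean linear decline, SD/yr |
| gamma2 | −0.0012 | mean quadratic acceleration, SD/yr² |
| sigma0 | sqrt(1 − delta_u²) | unit-variance normalization at t = 0 |
| sigma1 | 0.012 | SD of linear-slope deviations (~half the mean slope) |
| sigma2 | 0.0002 | SD of quadratic deviations |
| rho01 | 0.3 | level–slope correlation |
| calib_n | 100 000 | calibration sample size |
| calib_tol | 1e-3 | lifetable band-survival tolerance |
| tol_rel | 0.2 | per-band relative tolerance for incidence targets |

The trajectory-shape parameters (gamma1, gamma2, sigma1, sigma2, rho01) are
not identifiable from any published quantity; they were fixed once by a grid
search minimizing the worst per-band relative error of the calibration
report under the bundled target schedule (best achieved: 1.4%), i.e. by
calibration fidelity alone. The resulting mean decline is ~3.6 SD over 45
years with gently accelerating curvature.

## 6. Synthetic fixtures and what the tests show

Both bundled calibration tables are synthetic constructions (checksummed and
labeled in `data/manifest.json`): a Gompertz lifetable solved to hit median
survival 22.6/23.6 years and ~99.1% cumulative mortality by 95, and a
doubling incidence-target schedule (2 → 80 per 1000 PY over ages 65–94).
They emulate the *shape* of early-20th-century US cohort mortality and the
canonical dementia age gradient. They do not reproduce: within-band hazard
curvature of a real lifetable (medians land ~0.2 y early because a
piecewise-constant hazard front-loads deaths within a band), the exact
sex-specific mortality gap of any real cohort, cause-of-death structure, or
sampling noise of real incidence estimates.

Consequences worth stating plainly:

* Null-scenario unbiasedness, survival calibration, the direction and
  age-monotonicity of survivor-U selection, women's U distribution staying
  standard normal under male-only selection, and parameter recovery are
  structural results — they hold for any reasonable fixture and are tested
  at full scale.
* The *magnitude* of the heterogeneous-scenario IRR bias is not structural:
  it depends on how much old-age incidence flows through the U-sensitive
  crossing channel versus U-insensitive shocks, and on the dispersion of
  crossing times — all set by the free trajectory parameters. Under this
  package's defaults the moderate heterogeneous scenario yields IRR ≈ 1.10
  at ages 85–89 and the large scenario ≈ 1.6, versus published
  reference values of 1.15 and 1.20 from a model whose trajectory parameters
  are unpublished. The reference numbers imply a strongly saturating bias
  (much lower elasticity at the large effect size), consistent with more
  shock-dominated or more dispersed trajectories than the
  fidelity-optimal defaults here. The reproduction report therefore treats
  heterogeneous rows as fixture-sensitive; they are reported, not tuned.
* The homogeneous-scenario survivor-U sex gap at 95 is likewise
  fixture-dependent: ~0.18 SD under the synthetic lifetable (vs ~0.11
  reported against a real lifetable). Tests assert the qualitative claim —
  the gap is an order of magnitude smaller than the selection shift itself.

## 7. Numerical and reproducibility choices

* One master seed; named `SeedSequence` spawn-key substreams (cohort,
  mortality, shocks, screening, two calibrations, per-iteration). Changing
  the iteration count never perturbs calibration; every module is
  independently reproducible.
* All event times are continuous; no annual discretization anywhere.
* Censored survival times enter median/IQR order statistics at 45 years;
  medians are flagged invalid unless cumulative mortality exceeds 50%.
* Bisections: mortality, 200 steps max on lambda ∈ [−20, 5], tolerance on
  the survival probability; dementia cutoff, interval shrunk to 1e-4 on
  theta, no-overshoot side taken.
* Degenerate inputs: s5 = 1 bands calibrate to the hazard floor
  (~2·10⁻⁹/yr); all-zero target rates, cutoffs at/above the baseline mean,
  and invalid covariances raise typed errors; an all-dead summary mask warns
  and returns flagged-empty rows.

## 8. Known limitations

Everyone is exactly 50 at baseline; no immigration or attrition other than
death; no dementia subtypes, measurement error, practice effects, or
reversible impairment; no cause-specific or calendar-time mortality; shocks
are age-band-constant and independent of U (a U-dependent shock channel, or
U effects on the rate of decline rather than level, would change bias
magnitudes); simulation sizes in tests (n = 100 000, 200 iterations) give
Monte-Carlo SEs of ~0.004 on aggregated IRR points, so reported third
decimals are noise.
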