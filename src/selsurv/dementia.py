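"""Latent cognitive trajectories and dementia onset.

Cognition of person *i*, in SD-at-age-50 units, evolves from age 50 along a
person-specific quadratic,

    C_i(t) = (gamma0 + delta_u * u_i + b0_i) + (gamma1 + b1_i) t + (gamma2 + b2_i) t^2,

with t = years since age 50. Dementia onset happens the first time either

* the trajectory crosses below an age-constant cutoff ``theta`` (the
  culmination of gradual decline), or
* an exogenous "shock" (e.g. a serious stroke) fires — a piecewise-
  exponential event over age bands, independent of U, sex and cognition.

Crucially, *sex appears nowhere in this module*: dementia is generated under
the sharp null of no sex/gender effect, so any estimated sex difference in
incidence downstream is selection bias by construction.

``calibrate_dementia`` chooses ``theta`` (bisection, to the largest cutoff
whose crossing-driven incidence overshoots no band of a target rate
schedule) and per-band shock hazards (closing the remaining gaps) so that
men's simulated age-band incidence tracks a published-style target table.
Targets are a guide: per-band relative errors are reported, not forced to
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_generator
from .cohort import Cohort
from .mortality import BAND_STARTS, BAND_WIDTH, MAX_AGE, HazardSchedule, sample_death_age

FOLLOW_UP_YEARS = 45.0


class DementiaParameterError(ValueError):
    pass


class DementiaCalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GrowthCurveParams:
    """Fixed effects of the cognitive trajectory plus the effect of U.

    ``delta_u`` is the change in cognition at age 50 per 1-SD of U: -0.1 in
    moderate scenarios, -0.5 in large ones (U is harmful). The marginal SD
    of cognition at t=0 should be 1 so delta_u reads in SD units; that
    normalization couples delta_u to sigma0 and is checked by
    :func:`check_intercept_normalization`.
    """

    gamma0: float = 0.0
    gamma1: float = -0.025
    gamma2: float = -0.0012
    delta_u: float = -0.1


def normalized_sigma0(delta_u: float) -> float:
    """sigma0 such that Var(delta_u*U + b0) = 1."""
    if abs(delta_u) >= 1.0:
        raise DementiaParameterError("|delta_u| must be < 1 for unit baseline SD")
    return float(np.sqrt(1.0 - delta_u**2))


def check_intercept_normalization(gc: GrowthCurveParams, sigma0: float, atol: float = 1e-8) -> None:
    if abs(gc.delta_u**2 + sigma0**2 - 1.0) > atol:
        raise DementiaParameterError(
            "delta_u^2 + sigma0^2 != 1: cognition at age 50 is not in SD units"
        )


@dataclass
class DementiaModelParams:
    """Age-constant cutoff plus per-band shock hazards (per year)."""

    theta: float
    shock_hazard: np.ndarray = field(default_factory=lambda: np.zeros(len(BAND_STARTS)))

    def __post_init__(self):
        self.shock_hazard = np.asarray(self.shock_hazard, dtype=float)
        if self.shock_hazard.shape != (len(BAND_STARTS),):
            raise DementiaParameterError("shock_hazard must have one entry per band")
        if (self.shock_hazard < 0).any():
            raise DementiaParameterError("shock hazards must be nonnegative")

    def validate_against(self, gc: GrowthCurveParams) -> None:
        if self.theta >= gc.gamma0:
            raise DementiaParameterError(
                "theta must lie below the marginal mean cognition at age 50"
            )


def cognition_at(t, u, b0, b1, b2, gc: GrowthCurveParams):
    """Evaluate the quadratic trajectory at t years since age 50."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > FOLLOW_UP_YEARS):
        raise ValueError(f"t outside follow-up [0, {FOLLOW_UP_YEARS}]")
    return (gc.gamma0 + gc.delta_u * u + b0) + (gc.gamma1 + b1) * t + (gc.gamma2 + b2) * t**2


def crossing_times(cohort: Cohort, gc: GrowthCurveParams, theta: float) -> np.ndarray:
    """Earliest downward-crossing time of theta for each person (inf = none).

    Closed-form root of C(t) - theta = 0 on [0, 45]. Requires everyone
    dementia-free at baseline (C(0) > theta); tangencies never dip strictly
    below the cutoff and count as no crossing.
    """
    a = gc.gamma2 + cohort.b2
    b = gc.gamma1 + cohort.b1
    c = gc.gamma0 + gc.delta_u * cohort.u + cohort.b0 - theta
    if np.any(c <= 0):
        raise DementiaParameterError(
            "cohort contains members at/below the cutoff at baseline; screen first"
        )
    t = np.full(cohort.n, np.inf)

    lin = a == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lin = np.where(b < 0, -c / b, np.inf)
    t[lin] = t_lin[lin]

    quad = ~lin
    disc = b * b - 4.0 * a * c
    real = quad & (disc > 0.0)
    sq = np.sqrt(np.where(real, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_minus = (-b - sq) / (2.0 * a)
        r_plus = (-b + sq) / (2.0 * a)
    lo = np.minimum(r_minus, r_plus)
    hi = np.maximum(r_minus, r_plus)
    # a > 0: trajectory dips below between the roots; with C(0) > theta both
    # roots share a sign, so a future crossing exists iff lo > 0.
    up = real & (a > 0)
    t[up] = np.where(lo[up] > 0, lo[up], np.inf)
    # a < 0: roots straddle 0 (product c/a < 0); the downward crossing is hi.
    down = real & (a < 0)
    t[down] = hi[down]

    t[t > FOLLOW_UP_YEARS] = np.inf
    return t


def crossing_time(u, b0, b1, b2, gc: GrowthCurveParams, theta: float):
    """Scalar convenience wrapper around :func:`crossing_times`."""
    one = Cohort(
        sex=np.zeros(1, dtype=np.int8),
        u=np.array([float(u)]),
        b0=np.array([float(b0)]),
        b1=np.array([float(b1)]),
        b2=np.array([float(b2)]),
    )
    t = crossing_times(one, gc, theta)[0]
    return None if np.isinf(t) else float(t)


def sample_shock_times(params: DementiaModelParams, n: int, seed) -> np.ndarray:
    """Draw shock times (years since 50) for n persons; inf = no shock by 95.

    Piecewise-exponential over age bands with the per-band shock hazards;
    independent of everything else in the model.
    """
    rng = as_generator(seed)
    if not params.shock_hazard.any():
        return np.full(n, np.inf)
    cum = np.cumsum(BAND_WIDTH * params.shock_hazard)
    e = rng.exponential(size=n)
    idx = np.searchsorted(cum, e, side="left")
    t = np.full(n, np.inf)
    hit = idx < len(BAND_STARTS)
    i = idx[hit]
    prev = np.where(i > 0, cum[np.maximum(i - 1, 0)], 0.0)
    with np.errstate(divide="ignore"):
        t[hit] = (BAND_STARTS[i] - 50.0) + (e[hit] - prev) / params.shock_hazard[i]
    return t


def onset_ages(
    cohort: Cohort, gc: GrowthCurveParams, params: DementiaModelParams, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Dementia onset age (inf = none) and cause per person.

    Onset is the earlier of threshold crossing and shock; an exact tie is
    attributed to crossing. Onset is absorbing: later cognitive recovery is
    irrelevant.
    """
    t_cross = crossing_times(cohort, gc, params.theta)
    t_shock = sample_shock_times(params, cohort.n, seed)
    t = np.minimum(t_cross, t_shock)
    cause = np.where(t_cross <= t_shock, "crossing", "shock")
    cause = np.where(np.isinf(t), "none", cause)
    return 50.0 + t, cause


def screen_baseline(
    cohort: Cohort, gc: GrowthCurveParams, theta: float, seed, sigma0: float = None
) -> tuple[Cohort, int]:
    """Enforce dementia-free-at-50: redraw b0 for anyone at/below the cutoff.

    Rejection sampling on the intercept deviation only; returns the screened
    cohort and the number of redraws. A first-pass rejection rate above 50%
    signals a cutoff too close to the mean and raises.
    """
    if theta >= gc.gamma0:
        raise DementiaParameterError("theta above marginal mean cognition at baseline")
    rng = as_generator(seed)
    if sigma0 is None:
        sigma0 = float(np.std(cohort.b0)) if cohort.n > 1 else 1.0
    b0 = cohort.b0.copy()
    c0 = gc.gamma0 + gc.delta_u * cohort.u + b0
    bad = c0 <= theta
    n_redraws = 0
    first_rate = bad.mean()
    if first_rate > 0.5:
        raise DementiaParameterError(
            f"baseline rejection rate {first_rate:.2f} > 0.5: theta too high"
        )
    guard = 0
    while bad.any():
        n_redraws += int(bad.sum())
        b0[bad] = sigma0 * rng.standard_normal(int(bad.sum()))
        c0 = gc.gamma0 + gc.delta_u * cohort.u + b0
        bad = c0 <= theta
        guard += 1
        if guard > 10_000:
            raise DementiaCalibrationError("baseline screening failed to converge")
    out = Cohort(sex=cohort.sex, u=cohort.u, b0=b0, b1=cohort.b1, b2=cohort.b2)
    return out, n_redraws


# --------------------------------------------------------------------------
# Calibration of theta and shock hazards against a male target rate table
# --------------------------------------------------------------------------

def _band_tally(onset_t: np.ndarray, death_age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cases and person-years per band for one (sub)population.

    At-risk time ends at min(onset, death, 95); a case is credited to the
    band containing the onset age when onset precedes both death and 95.
    """
    onset_age = 50.0 + onset_t
    exit_age = np.minimum(np.minimum(onset_age, death_age), MAX_AGE)
    cases = np.zeros(len(BAND_STARTS))
    py = np.zeros(len(BAND_STARTS))
    is_case = (onset_age < death_age) & (onset_age < MAX_AGE)
    case_band = np.floor((onset_age[is_case] - 50.0) / BAND_WIDTH).astype(int)
    np.add.at(cases, case_band, 1.0)
    for bi, band in enumerate(BAND_STARTS):
        py[bi] = np.clip(np.minimum(exit_age, band + BAND_WIDTH) - band, 0.0, BAND_WIDTH).sum()
    return cases, py


def load_target_rates(path) -> pd.DataFrame:
    """Read a band_start,rate_per_1000py CSV of male incidence targets."""
    t = pd.read_csv(path)
    required = {"band_start", "rate_per_1000py"}
    if not required.issubset(t.columns):
        raise ValueError(f"target table missing columns {required - set(t.columns)}")
    return t.sort_values("band_start").reset_index(drop=True)


@dataclass
class DementiaCalibration:
    gc: GrowthCurveParams
    params: DementiaModelParams
    report: pd.DataFrame
    n_redraws: int = 0


def calibrate_dementia(
    target_rates: pd.DataFrame,
    gc: GrowthCurveParams,
    schedule: HazardSchedule,
    re_params,
    tol_rel: float = 0.1,
    calib_n: int = 100_000,
    seed=0,
) -> DementiaCalibration:
    """Calibrate (theta, shock hazards) so men's band incidence tracks targets.

    Stage 1 bisects theta to the largest cutoff at which the crossing-driven
    incidence of a male calibration sample overshoots no target band (shocks
    can only add incidence, so any overshoot would be uncorrectable). Stage 2
    assigns each target band a shock hazard equal to its remaining rate
    shortfall (a band overshooting despite stage 1 — Monte-Carlo noise — gets
    zero and a warning). The returned report lists per-band target, achieved
    and relative error; a band off by more than 2*tol_rel raises.
    """
    from .cohort import draw_cohort  # local import to avoid cycle at module load

    if tol_rel < 0.1:
        raise ValueError("tol_rel must be >= 0.1: targets are a guide, not a constraint")
    rates = np.asarray(target_rates.rate_per_1000py, dtype=float)
    bands = np.asarray(target_rates.band_start, dtype=int)
    if (rates < 0).any():
        raise DementiaCalibrationError("negative target rates")
    if np.any(np.diff(rates) < 0):
        warnings.warn("target incidence rates are not monotone nondecreasing")
    if not rates.any():
        raise DementiaParameterError("all-zero target rates: no finite cutoff exists")

    rate_vec = np.zeros(len(BAND_STARTS))
    for band, r in zip(bands, rates):
        rate_vec[list(BAND_STARTS).index(band)] = r / 1000.0

    rng = as_generator(seed)
    men = draw_cohort(calib_n, 0.0, re_params, rng)
    death = sample_death_age(men, schedule, rng)
    target_bis = [list(BAND_STARTS).index(b) for b in bands]

    def band_overshoot(theta: float) -> float:
        """Worst excess of crossing-driven rate over its band target (per
        year); increasing in theta."""
        t = crossing_times(_clamped(men, gc, theta), gc, theta)
        cases, py = _band_tally(t, death)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(py > 0, cases / py, 0.0)
        return float(max(r[bi] - rate_vec[bi] for bi in target_bis))

    # theta is the largest cutoff at which the crossing channel overshoots no
    # target band, so the additive shock channel can close every remaining
    # gap; theta stays below the ~1st percentile of baseline cognition so
    # screening perturbs the population by <=1%
    theta_hi = gc.gamma0 + float(stats.norm.ppf(0.01))
    theta_lo = gc.gamma0 - 40.0
    if band_overshoot(theta_hi) <= 0.0:
        theta = theta_hi  # even at the guard crossings undershoot everywhere
    else:
        while theta_hi - theta_lo > 1e-4:
            mid = 0.5 * (theta_lo + theta_hi)
            if band_overshoot(mid) > 0.0:
                theta_hi = mid
            else:
                theta_lo = mid
        theta = theta_lo

    # stage 2: shocks close per-band shortfalls of the crossing channel
    screened = _clamped(men, gc, theta)
    t_cross = crossing_times(screened, gc, theta)
    cases, py = _band_tally(t_cross, death)
    with np.errstate(invalid="ignore", divide="ignore"):
        achieved = np.where(py > 0, cases / py, 0.0)
    shock = np.zeros(len(BAND_STARTS))
    for band, r in zip(bands, rates):
        bi = list(BAND_STARTS).index(band)
        gap = r / 1000.0 - achieved[bi]
        if gap >= 0:
            shock[bi] = gap
        elif achieved[bi] > (1 + tol_rel) * r / 1000.0:
            warnings.warn(
                f"band {band}: crossing incidence overshoots target by "
                f"{100 * (achieved[bi] * 1000 / r - 1):.0f}%; shock hazard set to 0"
            )

    params = DementiaModelParams(theta=theta, shock_hazard=shock)
    params.validate_against(gc)

    # final achieved rates with shocks, fresh draws
    t_shock = sample_shock_times(params, calib_n, rng)
    t_onset = np.minimum(t_cross, t_shock)
    cases2, py2 = _band_tally(t_onset, death)
    rows = []
    for band, r in zip(bands, rates):
        bi = list(BAND_STARTS).index(band)
        got = 1000.0 * cases2[bi] / py2[bi] if py2[bi] > 0 else np.nan
        rel = (got - r) / r if r > 0 else np.nan
        rows.append(dict(band_start=int(band), target=r, achieved=got, rel_error=rel))
    report = pd.DataFrame(rows)
    worst = report.rel_error.abs().max()
    if worst > 2 * tol_rel:
        raise DementiaCalibrationError(
            f"calibration missed a band by {100 * worst:.0f}% (> {200 * tol_rel:.0f}%):\n"
            f"{report}"
        )
    return DementiaCalibration(gc=gc, params=params, report=report)


def _clamped(cohort: Cohort, gc: GrowthCurveParams, theta: float) -> Cohort:
    """Calibration-time stand-in for baseline screening: reflect the few
    intercepts at/below the cutoff just above it (theta is guarded to keep
    this fraction ~<=1%, so the approximation is negligible)."""
    c0 = gc.gamma0 + gc.delta_u * cohort.u + cohort.b0
    bad = c0 <= theta
    if not bad.any():
        return cohort
    b0 = cohort.b0.copy()
    b0[bad] = b0[bad] + 2.0 * (theta - c0[bad]) + 1e-9
    return Cohort(sex=cohort.sex, u=cohort.u, b0=b0, b1=cohort.b1, b2=cohort.b2)
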