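"""Piecewise-exponential mortality with a frailty term on the selection
characteristic U.

The per-year mortality hazard of person *i* of sex *s* inside 5-year age
band *b* is

    h_i(b) = exp(lambda_{b,s} + beta_u(s) * u_i)

with band-specific log baseline hazards ``lambda`` and an age-constant
log-hazard effect ``beta_u`` of a 1-SD increase in U (0, log 2 or log 3.5
depending on the causal scenario). Baseline hazards are calibrated so that,
*marginally over U*, each sex reproduces the conditional 5-year survival
probabilities of a lifetable — which is why calibration must be redone for
every ``beta_u`` configuration: the lifetable holds in every scenario and
the selective-survival signal lives entirely in *who* survives.

Calibration proceeds band by band in age order. The baseline U sample is
carried forward as importance weights ``w_i <- w_i * P(survive band | u_i)``,
so the survivor U distribution after earlier bands (no longer normal once
beta_u != 0) enters later bands exactly; within a band the calibrated
``lambda`` is the root of the exact conditional survival
``sum(w * exp(-5 h)) / sum(w) = s5``, found by bisection. Given the seed the
whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_generator
from .cohort import Cohort

#: Band start ages; bands are half-open [a, a+5), follow-up is [50, 95).
BAND_STARTS = np.arange(50, 95, 5)
BAND_WIDTH = 5.0
MAX_AGE = 95.0

_LAMBDA_LO, _LAMBDA_HI = -20.0, 5.0
_MAX_BISECT = 200


class LifeTableError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class LifeTable:
    """Conditional 5-year band survival probabilities s5, by band and sex.

    ``table`` has columns band_start, sex ("man"/"woman"), s5; all nine
    bands 50..90 must be present for both sexes and 0 < s5 <= 1.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"band_start", "sex", "s5"}
        if not required.issubset(t.columns):
            raise LifeTableError(f"lifetable missing columns {required - set(t.columns)}")
        missing = []
        for band in BAND_STARTS:
            for sex in ("man", "woman"):
                if not ((t.band_start == band) & (t.sex == sex)).any():
                    missing.append(f"{band},{sex}")
        if missing:
            raise LifeTableError("lifetable missing rows: " + "; ".join(missing))
        bad = t[(t.s5 <= 0) | (t.s5 > 1)]
        if len(bad):
            raise LifeTableError(f"s5 outside (0, 1] in rows {bad.index.tolist()}")
        self.table = t.sort_values(["band_start", "sex"]).reset_index(drop=True)

    def s5(self, band_start: int, sex: str) -> float:
        row = self.table[(self.table.band_start == band_start) & (self.table.sex == sex)]
        return float(row.s5.iloc[0])

    def s5_vector(self, sex: str) -> np.ndarray:
        """s5 for all nine bands in age order, one sex."""
        sub = self.table[self.table.sex == sex].sort_values("band_start")
        return sub.s5.to_numpy(dtype=float)

    def cumulative_survival(self, sex: str) -> float:
        """Probability of surviving 50 -> 95 implied by the table."""
        return float(np.prod(self.s5_vector(sex)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def load_lifetable(path) -> LifeTable:
    """Read a band_start,sex,s5 CSV and validate it."""
    return LifeTable(pd.read_csv(path))


@dataclass
class HazardSchedule:
    """Calibrated log baseline hazards, indexed [band, sex] (man=0, woman=1),
    plus the per-sex frailty coefficient beta_u."""

    log_lambda: np.ndarray  # shape (n_bands, 2)
    beta_u: np.ndarray  # shape (2,)
    band_starts: np.ndarray = None

    def __post_init__(self):
        if self.band_starts is None:
            self.band_starts = BAND_STARTS.copy()
        self.log_lambda = np.asarray(self.log_lambda, dtype=float)
        self.beta_u = np.asarray(self.beta_u, dtype=float)
        if self.log_lambda.shape != (len(self.band_starts), 2):
            raise ValueError("log_lambda must have shape (n_bands, 2)")
        if not np.all(np.isfinite(self.log_lambda)):
            raise ValueError("log hazards must be finite")

    def person_hazards(self, sex: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Per-year hazard matrix, shape (n_bands, n)."""
        lam = self.log_lambda[:, np.asarray(sex, dtype=int)]  # (bands, n)
        return np.exp(lam + self.beta_u[np.asarray(sex, dtype=int)] * u)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, band in enumerate(self.band_starts):
            for code, label in ((0, "man"), (1, "woman")):
                rows.append(
                    dict(band_start=int(band), sex=label,
                         log_lambda=self.log_lambda[bi, code],
                         beta_u=self.beta_u[code])
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def schedule_from_frame(frame: pd.DataFrame) -> HazardSchedule:
    bands = np.sort(frame.band_start.unique())
    lam = np.empty((len(bands), 2))
    beta = np.zeros(2)
    for bi, band in enumerate(bands):
        for code, label in ((0, "man"), (1, "woman")):
            row = frame[(frame.band_start == band) & (frame.sex == label)].iloc[0]
            lam[bi, code] = row.log_lambda
            beta[code] = row.beta_u
    return HazardSchedule(log_lambda=lam, beta_u=beta, band_starts=bands)


def _band_survival(lam: float, beta_u: float, u: np.ndarray, w: np.ndarray) -> float:
    """Exact conditional 5-year survival of the weighted survivor sample."""
    p = np.exp(-BAND_WIDTH * np.exp(lam + beta_u * u))
    return float(np.dot(w, p) / w.sum())


def calibrate_hazards(
    lifetable: LifeTable,
    beta_u_by_sex,
    calib_n: int = 100_000,
    tol: float = 1e-3,
    seed=0,
) -> HazardSchedule:
    """Calibrate band/sex baseline hazards to a lifetable under frailty.

    ``beta_u_by_sex`` maps "man"/"woman" to the log-hazard effect of U.
    Sequential per-band bisection on lambda against the exact conditional
    survival of the carried-forward survivor sample (see module docstring).
    """
    if calib_n < 10_000:
        raise ValueError("calib_n too small for stable calibration (need >= 10000)")
    if not 0.0 < tol < 0.01:
        raise ValueError("tol must be in (0, 0.01)")
    beta = np.array([beta_u_by_sex["man"], beta_u_by_sex["woman"]], dtype=float)
    rng = as_generator(seed)
    lam_out = np.empty((len(BAND_STARTS), 2))

    for code, label in ((0, "man"), (1, "woman")):
        u = rng.standard_normal(calib_n)
        w = np.ones(calib_n)
        targets = lifetable.s5_vector(label)
        for bi, band in enumerate(BAND_STARTS):
            s5 = targets[bi]
            lo, hi = _LAMBDA_LO, _LAMBDA_HI
            f_lo = _band_survival(lo, beta[code], u, w) - s5
            if f_lo <= 0.0:
                # even a ~1e-9/yr hazard undershoots the target: s5 ~ 1
                if abs(f_lo) < tol:
                    lam = lo
                else:
                    raise CalibrationError(
                        f"cannot bracket lambda for band {band}, sex {label}"
                    )
            else:
                lam = None
                for _ in range(_MAX_BISECT):
                    mid = 0.5 * (lo + hi)
                    f_mid = _band_survival(mid, beta[code], u, w) - s5
                    if abs(f_mid) < tol:
                        lam = mid
                        break
                    if f_mid > 0:  # surviving too many -> raise hazard
                        lo = mid
                    else:
                        hi = mid
                if lam is None:
                    raise CalibrationError(
                        f"bisection did not reach tol={tol} for band {band}, sex {label}"
                    )
            lam_out[bi, code] = lam
            w = w * np.exp(-BAND_WIDTH * np.exp(lam + beta[code] * u))

    return HazardSchedule(log_lambda=lam_out, beta_u=beta)


def band_conditional_survival(
    schedule: HazardSchedule, n: int = 200_000, seed=0
) -> pd.DataFrame:
    """Diagnostic: expected conditional band survival under a schedule,
    evaluated on a fresh U sample (independent check of calibration)."""
    rng = as_generator(seed)
    rows = []
    for code, label in ((0, "man"), (1, "woman")):
        u = rng.standard_normal(n)
        w = np.ones(n)
        for bi, band in enumerate(schedule.band_starts):
            s5 = _band_survival(schedule.log_lambda[bi, code], schedule.beta_u[code], u, w)
            rows.append(dict(band_start=int(band), sex=label, s5=s5))
            w = w * np.exp(
                -BAND_WIDTH * np.exp(schedule.log_lambda[bi, code] + schedule.beta_u[code] * u)
            )
    return pd.DataFrame(rows)


def sample_death_age(cohort: Cohort, schedule: HazardSchedule, seed) -> np.ndarray:
    """Draw one death age per person by piecewise-exponential inversion.

    A single Exp(1) draw per person is inverted through the person's
    cumulative hazard, which is piecewise linear across bands. Ages lie in
    (50, 95]; exactly 95.0 means administratively censored (alive at end of
    follow-up).
    """
    rng = as_generator(seed)
    h = schedule.person_hazards(cohort.sex, cohort.u)  # (bands, n)
    cum = np.cumsum(BAND_WIDTH * h, axis=0)  # (bands, n)
    e = rng.exponential(size=cohort.n)
    # number of complete bands survived
    idx = (cum < e).sum(axis=0)
    death = np.full(cohort.n, MAX_AGE)
    cols = np.nonzero(idx < len(schedule.band_starts))[0]
    i = idx[cols]
    prev = np.where(i > 0, cum[np.maximum(i - 1, 0), cols], 0.0)
    # residual exponential time within the death band
    t_in = (e[cols] - prev) / h[i, cols]
    death[cols] = schedule.band_starts[i] + t_in
    return death


def survival_summary(death_ages: np.ndarray, sex: np.ndarray, max_age: float = MAX_AGE) -> pd.DataFrame:
    """Median/IQR survival time from age 50 by sex, plus cumulative mortality.

    Censored persons (death age == ``max_age``) enter the order statistics
    at 45 years; the median/IQR are meaningful (``median_valid``) only when
    cumulative mortality exceeds 50%.
    """
    death_ages = np.asarray(death_ages, dtype=float)
    if death_ages.size == 0:
        raise ValueError("empty death-age array")
    sex = np.asarray(sex)
    rows = []
    groups = [("man", sex == 0), ("woman", sex == 1), ("all", np.ones_like(sex, dtype=bool))]
    for label, mask in groups:
        if not mask.any():
            continue
        t = death_ages[mask] - 50.0
        cum_mort = float(np.mean(death_ages[mask] < max_age))
        q25, q50, q75 = np.percentile(t, [25, 50, 75])
        rows.append(
            dict(sex=label, n=int(mask.sum()), median=float(q50), q25=float(q25),
                 q75=float(q75), cumulative_mortality=cum_mort,
                 median_valid=cum_mort > 0.5)
        )
    return pd.DataFrame(rows)
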