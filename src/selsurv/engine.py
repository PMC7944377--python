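"""Scenario orchestration.

A *scenario* fixes the causal structure linking the selection characteristic
U to mortality:

* ``no_selection``   — U affects cognition only (the bias-free check),
* ``homogeneous``    — U raises mortality equally for both sexes,
* ``heterogeneous``  — U raises mortality for men only (U x sex interaction).

with a *moderate* (beta_u = log 2.0, delta_u = -0.1) or *large*
(beta_u = log 3.5, delta_u = -0.5) effect size. Dementia is always generated
under the sharp null (sex enters only through mortality), so women-vs-men
incidence contrasts among survivors measure selective-survival bias.

``run_scenario`` calibrates mortality (per scenario) and the dementia model
(against men's target rates) once, then simulates ``n_iterations`` fresh
cohorts and tallies incident cases and person-years per 5-year age band and
sex. Everything is reproducible from the master seed; calibration and
iterations use separate substreams so the calibrated parameters never depend
on the iteration count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .cohort import Cohort, RandomEffectParams, draw_cohort, u_summary_by_sex
from .dementia import (
    DementiaCalibration,
    GrowthCurveParams,
    calibrate_dementia,
    check_intercept_normalization,
    normalized_sigma0,
    onset_ages,
    screen_baseline,
)
from .mortality import (
    BAND_STARTS,
    BAND_WIDTH,
    MAX_AGE,
    HazardSchedule,
    LifeTable,
    load_lifetable,
    calibrate_hazards,
    sample_death_age,
    survival_summary,
)

SCENARIOS = ("no_selection", "homogeneous", "heterogeneous")
EFFECT_SIZES = {
    "moderate": {"beta_u_mortality": float(np.log(2.0)), "delta_u_cognition": -0.1},
    "large": {"beta_u_mortality": float(np.log(3.5)), "delta_u_cognition": -0.5},
}

# Default random-slope structure of the cognitive trajectories (sigma0 is
# derived from delta_u by the unit-variance normalization at age 50); see
# docs/methods.md for the rationale behind these magnitudes.
DEFAULT_SIGMA1 = 0.012
DEFAULT_SIGMA2 = 0.0002
DEFAULT_RHO01 = 0.3


@dataclass
class ScenarioConfig:
    """Complete, serializable description of one simulation scenario."""

    scenario: str = "no_selection"
    effect_size: str = "moderate"
    n: int = 100_000
    p_female: float = 0.51
    n_iterations: int = 1000
    master_seed: int = 0
    gamma0: float = 0.0
    gamma1: float = GrowthCurveParams.gamma1
    gamma2: float = GrowthCurveParams.gamma2
    sigma1: float = DEFAULT_SIGMA1
    sigma2: float = DEFAULT_SIGMA2
    rho01: float = DEFAULT_RHO01
    calib_n: int = 100_000
    calib_tol: float = 1e-3
    tol_rel: float = 0.2
    lifetable_path: str | None = None
    target_rates_path: str | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.effect_size not in EFFECT_SIZES:
            raise ValueError(f"effect_size must be one of {tuple(EFFECT_SIZES)}")

    # -- derived quantities -------------------------------------------------
    @property
    def beta_u_mortality(self) -> float:
        return EFFECT_SIZES[self.effect_size]["beta_u_mortality"]

    @property
    def delta_u_cognition(self) -> float:
        return EFFECT_SIZES[self.effect_size]["delta_u_cognition"]

    def beta_u_by_sex(self) -> dict:
        b = self.beta_u_mortality
        if self.scenario == "no_selection":
            return {"man": 0.0, "woman": 0.0}
        if self.scenario == "homogeneous":
            return {"man": b, "woman": b}
        return {"man": b, "woman": 0.0}  # heterogeneous: men only

    def growth_curve(self) -> GrowthCurveParams:
        return GrowthCurveParams(
            gamma0=self.gamma0, gamma1=self.gamma1, gamma2=self.gamma2,
            delta_u=self.delta_u_cognition,
        )

    def random_effects(self) -> RandomEffectParams:
        re = RandomEffectParams(
            sigma0=normalized_sigma0(self.delta_u_cognition),
            sigma1=self.sigma1, sigma2=self.sigma2, rho01=self.rho01,
        )
        check_intercept_normalization(self.growth_curve(), re.sigma0)
        return re

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    schedule: HazardSchedule
    calibration: DementiaCalibration
    tallies: pd.DataFrame  # iteration, band_start, sex, cases, person_years
    survival: pd.DataFrame  # per-iteration survival summaries
    u_summary: pd.DataFrame  # survivor U distribution by age, first iteration

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tallies.to_csv(out / "tallies.csv", index=False)
        self.survival.to_csv(out / "survival_summary.csv", index=False)
        self.u_summary.to_csv(out / "u_summary.csv", index=False)
        self.schedule.to_csv(out / "hazard_schedule.csv")
        self.calibration.report.to_csv(out / "dementia_calibration.csv", index=False)
        manifest = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "n_iterations": int(self.tallies.iteration.nunique()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def tally_iteration(
    sex: np.ndarray, onset_age: np.ndarray, death_age: np.ndarray, iteration: int = 0
) -> pd.DataFrame:
    """Cases and person-years per (band, sex) for one simulated cohort.

    At-risk time runs over [50, min(onset, death, 95)) in continuous time; a
    case is credited to the band containing the onset age only when onset
    strictly precedes both death and the age-95 administrative boundary.
    """
    exit_age = np.minimum(np.minimum(onset_age, death_age), MAX_AGE)
    is_case = (onset_age < death_age) & (onset_age < MAX_AGE)
    rows = []
    for code, label in ((0, "man"), (1, "woman")):
        m = sex == code
        e = exit_age[m]
        case_ages = onset_age[m & is_case]
        band_of_case = np.floor((case_ages - 50.0) / BAND_WIDTH).astype(int)
        cases = np.bincount(band_of_case, minlength=len(BAND_STARTS)).astype(float)
        for bi, band in enumerate(BAND_STARTS):
            py = np.clip(np.minimum(e, band + BAND_WIDTH) - band, 0.0, BAND_WIDTH).sum()
            rows.append(
                dict(iteration=iteration, band_start=int(band), sex=label,
                     cases=float(cases[bi]), person_years=float(py))
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: ScenarioConfig,
    schedule: HazardSchedule,
    calibration: DementiaCalibration,
    iteration: int = 0,
):
    """Simulate one fresh cohort; returns (cohort, death_age, onset_age)."""
    seed = config.master_seed
    cohort = draw_cohort(
        config.n, config.p_female, config.random_effects(),
        substream(seed, "cohort", iteration),
    )
    cohort, _ = screen_baseline(
        cohort, calibration.gc, calibration.params.theta,
        substream(seed, "screening", iteration),
        sigma0=config.random_effects().sigma0,
    )
    death_age = sample_death_age(cohort, schedule, substream(seed, "mortality", iteration))
    onset_age, _ = onset_ages(
        cohort, calibration.gc, calibration.params, substream(seed, "shocks", iteration)
    )
    return cohort, death_age, onset_age


def run_iteration(
    config: ScenarioConfig,
    schedule: HazardSchedule,
    calibration: DementiaCalibration,
    iteration: int,
) -> pd.DataFrame:
    cohort, death_age, onset_age = simulate_cohort(config, schedule, calibration, iteration)
    return tally_iteration(cohort.sex, onset_age, death_age, iteration)


def survivor_u_table(cohort: Cohort, death_age: np.ndarray, ages=None) -> pd.DataFrame:
    """Survivor U distribution by age and sex (box-plot style summaries)."""
    if ages is None:
        ages = list(BAND_STARTS) + [int(MAX_AGE)]
    frames = []
    for age in ages:
        alive = death_age >= age if age >= MAX_AGE else death_age > age
        tab = u_summary_by_sex(cohort, alive)
        tab.insert(0, "age", age)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_scenario(
    config: ScenarioConfig,
    lifetable: LifeTable = None,
    target_rates: pd.DataFrame = None,
    progress: bool = False,
) -> ScenarioResult:
    """Calibrate once, then simulate all iterations of a scenario."""
    from . import fixtures  # default synthetic calibration tables

    if lifetable is None:
        lifetable = (
            fixtures.load_lifetable_fixture()
            if config.lifetable_path is None
            else load_lifetable(config.lifetable_path)
        )
    if target_rates is None:
        target_rates = (
            fixtures.load_target_rates_fixture()
            if config.target_rates_path is None
            else pd.read_csv(config.target_rates_path)
        )

    seed = config.master_seed
    schedule = calibrate_hazards(
        lifetable, config.beta_u_by_sex(), calib_n=config.calib_n,
        tol=config.calib_tol, seed=substream(seed, "calibration_mortality"),
    )
    calibration = calibrate_dementia(
        target_rates, config.growth_curve(), schedule, config.random_effects(),
        tol_rel=config.tol_rel, calib_n=config.calib_n,
        seed=substream(seed, "calibration_dementia"),
    )

    tallies, survival_rows = [], []
    u_summary = None
    for i in range(config.n_iterations):
        cohort, death_age, onset_age = simulate_cohort(config, schedule, calibration, i)
        tallies.append(tally_iteration(cohort.sex, onset_age, death_age, i))
        surv = survival_summary(death_age, cohort.sex)
        surv.insert(0, "iteration", i)
        survival_rows.append(surv)
        if i == 0:
            u_summary = survivor_u_table(cohort, death_age)
        if progress and (i + 1) % 50 == 0:
            print(f"[selsurv] {config.scenario}/{config.effect_size}: "
                  f"iteration {i + 1}/{config.n_iterations}")

    return ScenarioResult(
        config=config,
        schedule=schedule,
        calibration=calibration,
        tallies=pd.concat(tallies, ignore_index=True),
        survival=pd.concat(survival_rows, ignore_index=True),
        u_summary=u_summary,
    )
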