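import inspect
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selsurv.cohort import Cohort, RandomEffectParams, draw_cohort
from selsurv.dementia import (
    DementiaCalibrationError,
    DementiaModelParams,
    DementiaParameterError,
    GrowthCurveParams,
    _band_tally,
    calibrate_dementia,
    cognition_at,
    crossing_time,
    crossing_times,
    normalized_sigma0,
    onset_ages,
    sample_shock_times,
    screen_baseline,
)
from selsurv.mortality import BAND_STARTS, sample_death_age, calibrate_hazards

from conftest import constant_hazard_schedule


def one_person(u=0.0, b0=0.0, b1=0.0, b2=0.0, sex=0):
    return Cohort(sex=np.array([sex], dtype=np.int8), u=np.array([float(u)]),
                  b0=np.array([float(b0)]), b1=np.array([float(b1)]),
                  b2=np.array([float(b2)]))


# ---------------------------------------------------------------- trajectories

def test_cognition_baseline_identity():
    gc = GrowthCurveParams(gamma0=0.4, gamma1=-0.1, gamma2=-0.001, delta_u=-0.1)
    assert cognition_at(0.0, 0.0, 0.0, 0.0, 0.0, gc) == pytest.approx(0.4)


def test_delta_u_shifts_baseline_cognition_exactly():
    gc = GrowthCurveParams(delta_u=-0.1)
    c1 = cognition_at(0.0, 1.0, 0.0, 0.0, 0.0, gc)
    c0 = cognition_at(0.0, 0.0, 0.0, 0.0, 0.0, gc)
    assert c1 - c0 == pytest.approx(-0.1)


def test_cognition_polynomial_evaluation():
    gc = GrowthCurveParams(gamma0=0.0, gamma1=-0.1, gamma2=-0.001, delta_u=0.0)
    assert cognition_at(10.0, 0.0, 0.0, 0.0, 0.0, gc) == pytest.approx(-1.1)
    with pytest.raises(ValueError):
        cognition_at(46.0, 0.0, 0.0, 0.0, 0.0, gc)


# ---------------------------------------------------------------- crossing time

def test_crossing_linear_closed_form():
    # C(t) = 1 - 0.1 t, theta = 0 -> t = 10
    gc = GrowthCurveParams(gamma0=1.0, gamma1=-0.1, gamma2=0.0, delta_u=0.0)
    assert crossing_time(0, 0, 0, 0, gc, theta=0.0) == pytest.approx(10.0)


def test_no_crossing_when_increasing():
    gc = GrowthCurveParams(gamma0=1.0, gamma1=0.05, gamma2=0.0, delta_u=0.0)
    assert crossing_time(0, 0, 0, 0, gc, theta=0.0) is None


def test_first_crossing_even_if_trajectory_recovers():
    # upward parabola dips below the cutoff and recovers: onset is the first
    # crossing and is never rescinded by the later recovery
    gc = GrowthCurveParams(gamma0=1.0, gamma1=-0.5, gamma2=0.02, delta_u=0.0)
    t = crossing_time(0, 0, 0, 0, gc, theta=0.0)
    roots = np.sort(np.roots([0.02, -0.5, 1.0]))
    assert t == pytest.approx(roots[0])
    assert cognition_at(45.0, 0, 0, 0, 0, gc) > 0  # recovered by end of follow-up


def test_baseline_precondition_enforced():
    gc = GrowthCurveParams(gamma0=0.0, gamma1=0.0, gamma2=0.0, delta_u=0.0)
    with pytest.raises(DementiaParameterError):
        crossing_times(one_person(b0=-1.0), gc, theta=0.0)


def test_crossing_matches_grid_search_oracle():
    """Closed-form roots vs brute-force first sub-cutoff point on a
    0.001-year grid, over 1000 random quadratics."""
    rng = np.random.default_rng(42)
    n = 1000
    gc = GrowthCurveParams(gamma0=0.0, gamma1=0.0, gamma2=0.0, delta_u=0.0)
    cohort = Cohort(
        sex=np.zeros(n, dtype=np.int8),
        u=np.zeros(n),
        b0=rng.uniform(0.05, 3.0, n),  # C(0) > theta = 0
        b1=rng.uniform(-0.4, 0.2, n),
        b2=rng.uniform(-0.02, 0.02, n),
    )
    t = crossing_times(cohort, gc, theta=0.0)

    grid = np.arange(0.0, 45.0 + 1e-9, 0.001)
    for i in range(n):
        c = cohort.b0[i] + cohort.b1[i] * grid + cohort.b2[i] * grid**2
        below = np.nonzero(c < 0.0)[0]
        if below.size == 0:
            # grid may miss a dip narrower than 1 ms-of-year; closed form may
            # still find it only within one grid step of a tangency
            assert np.isinf(t[i]) or (
                cohort.b0[i] + cohort.b1[i] * t[i] + cohort.b2[i] * t[i] ** 2
            ) == pytest.approx(0.0, abs=1e-9)
        else:
            t_grid = grid[below[0]]
            assert t_grid - 0.001 <= t[i] <= t_grid + 1e-9


def test_lower_u_crosses_weakly_later():
    # delta_u < 0: smaller U means higher cognition, hence later (or no) onset
    gc = GrowthCurveParams(gamma0=0.0, gamma1=-0.05, gamma2=-0.001, delta_u=-0.1)
    times = []
    for u in np.linspace(-3, 3, 13):
        t = crossing_time(u, b0=1.0, b1=0.0, b2=0.0, gc=gc, theta=-1.5)
        times.append(np.inf if t is None else t)
    assert np.all(np.diff(times) <= 0)


# ---------------------------------------------------------------- shock channel

def test_shock_zero_hazard_never_fires():
    params = DementiaModelParams(theta=-4.0)
    assert np.all(np.isinf(sample_shock_times(params, 1000, seed=0)))


def test_shock_huge_hazard_fires_immediately():
    params = DementiaModelParams(theta=-4.0, shock_hazard=np.full(9, 10.0))
    t = sample_shock_times(params, 1000, seed=0)
    assert np.all(t < 5.0)


def test_shock_constant_hazard_matches_exponential_cdf():
    params = DementiaModelParams(theta=-4.0, shock_hazard=np.full(9, 0.02))
    t = sample_shock_times(params, 200_000, seed=1)
    expected = 1 - np.exp(-0.02 * 45)  # ~0.593
    assert np.mean(np.isfinite(t)) == pytest.approx(expected, abs=0.005)
    d = stats.kstest(t[np.isfinite(t)], lambda x: (1 - np.exp(-0.02 * x)) / expected).statistic
    assert d < 1.628 / np.sqrt(np.isfinite(t).sum())


# ---------------------------------------------------------------- onset rules

def test_onset_is_min_of_channels_and_tie_goes_to_crossing():
    gc = GrowthCurveParams(gamma0=1.0, gamma1=-0.05, gamma2=0.0, delta_u=0.0)
    # crossing at t = 20; shock hazard so large the shock fires almost surely first
    params = DementiaModelParams(theta=0.0, shock_hazard=np.full(9, 50.0))
    onset, cause = onset_ages(one_person(), gc, params, seed=3)
    assert onset[0] < 51.0 and cause[0] == "shock"
    params0 = DementiaModelParams(theta=0.0)
    onset, cause = onset_ages(one_person(), gc, params0, seed=3)
    assert onset[0] == pytest.approx(70.0) and cause[0] == "crossing"
    # exact tie resolves to crossing
    t_cross = crossing_times(one_person(), gc, 0.0)
    t_shock = t_cross.copy()
    assert np.all(np.where(t_cross <= t_shock, "crossing", "shock") == "crossing")


def test_onset_none_when_no_channel_fires():
    gc = GrowthCurveParams(gamma0=1.0, gamma1=0.0, gamma2=0.0, delta_u=0.0)
    onset, cause = onset_ages(one_person(), gc, DementiaModelParams(theta=0.0), seed=0)
    assert np.isinf(onset[0]) and cause[0] == "none"


def test_dementia_model_is_sex_blind():
    """Sharp-null contract: no dementia operation takes sex as input, and
    flipping every sex label changes no onset age."""
    for fn in (cognition_at, crossing_times, sample_shock_times, onset_ages):
        assert "sex" not in inspect.signature(fn).parameters
    re = RandomEffectParams(1.0, 0.01, 0.0005, 0.3)
    gc = GrowthCurveParams(delta_u=-0.1)
    params = DementiaModelParams(theta=-3.0, shock_hazard=np.full(9, 0.005))
    cohort, _ = screen_baseline(draw_cohort(2000, 0.5, re, seed=9), gc,
                                params.theta, seed=10, sigma0=re.sigma0)
    onset_a, _ = onset_ages(cohort, gc, params, seed=11)
    flipped = Cohort(sex=1 - cohort.sex, u=cohort.u, b0=cohort.b0,
                     b1=cohort.b1, b2=cohort.b2)
    onset_b, _ = onset_ages(flipped, gc, params, seed=11)
    assert np.array_equal(onset_a, onset_b)


# ---------------------------------------------------------------- screening

def test_screen_far_cutoff_is_noop(re_params):
    cohort = draw_cohort(5000, 0.5, re_params, seed=1)
    gc = GrowthCurveParams(delta_u=-0.1)
    out, redraws = screen_baseline(cohort, gc, theta=-10.0, seed=2,
                                   sigma0=re_params.sigma0)
    assert redraws == 0
    assert np.array_equal(out.b0, cohort.b0)


def test_screen_redraw_rate_matches_normal_quantile(re_params):
    cohort = draw_cohort(100_000, 0.5, re_params, seed=1)
    gc = GrowthCurveParams(delta_u=-0.1)
    theta = float(stats.norm.ppf(0.01))  # 1st percentile of C(0) ~ N(0,1)
    out, redraws = screen_baseline(cohort, gc, theta=theta, seed=2,
                                   sigma0=re_params.sigma0)
    first_pass = np.mean(gc.delta_u * cohort.u + cohort.b0 <= theta)
    assert first_pass == pytest.approx(0.01, abs=0.002)
    assert redraws >= first_pass * cohort.n
    c0 = gc.delta_u * out.u + out.b0
    assert np.all(c0 > theta)


def test_screen_theta_above_mean_rejected(re_params):
    cohort = draw_cohort(100, 0.5, re_params, seed=1)
    with pytest.raises(DementiaParameterError):
        screen_baseline(cohort, GrowthCurveParams(delta_u=-0.1), theta=0.5, seed=2)


# ---------------------------------------------------------------- calibration

def test_calibration_recovers_selfgenerated_band_rates(lifetable, re_params):
    """Round trip: rates produced by a known (theta*, shock*) truth are fed
    back as targets; calibration reproduces every band rate within tol_rel
    on an independently simulated cohort."""
    tol_rel = 0.15
    gc = GrowthCurveParams(delta_u=-0.1)
    sched = calibrate_hazards(lifetable, {"man": 0.0, "woman": 0.0},
                              calib_n=100_000, seed=21)
    truth = DementiaModelParams(theta=-3.9, shock_hazard=np.where(
        BAND_STARTS >= 65, 0.003, 0.0))
    men, _ = screen_baseline(draw_cohort(100_000, 0.0, re_params, seed=22),
                             gc, truth.theta, seed=26, sigma0=re_params.sigma0)
    death = sample_death_age(men, sched, seed=23)
    t_cross = crossing_times(men, gc, truth.theta)
    t_shock = sample_shock_times(truth, men.n, seed=24)
    cases, py = _band_tally(np.minimum(t_cross, t_shock), death)
    keep = BAND_STARTS >= 65
    targets = pd.DataFrame({
        "band_start": BAND_STARTS[keep],
        "rate_per_1000py": 1000 * cases[keep] / py[keep],
    })

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cal = calibrate_dementia(targets, gc, sched, re_params,
                                 tol_rel=tol_rel, seed=25)
    assert cal.report.rel_error.abs().max() <= tol_rel

    # independent re-simulation with the recovered parameters
    men2, _ = screen_baseline(draw_cohort(100_000, 0.0, re_params, seed=31),
                              cal.gc, cal.params.theta, seed=34,
                              sigma0=re_params.sigma0)
    death2 = sample_death_age(men2, sched, seed=32)
    onset2, _ = onset_ages(men2, cal.gc, cal.params, seed=33)
    cases2, py2 = _band_tally(onset2 - 50.0, death2)
    achieved = 1000 * cases2[keep] / py2[keep]
    rel = np.abs(achieved - targets.rate_per_1000py.values) / targets.rate_per_1000py.values
    assert rel.max() <= tol_rel


def test_calibration_doubling_targets_raises_theta(lifetable, target_rates, re_params):
    gc = GrowthCurveParams(delta_u=-0.1)
    sched = calibrate_hazards(lifetable, {"man": 0.0, "woman": 0.0},
                              calib_n=100_000, seed=41)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cal1 = calibrate_dementia(target_rates, gc, sched, re_params, seed=42)
        doubled = target_rates.assign(rate_per_1000py=2 * target_rates.rate_per_1000py)
        cal2 = calibrate_dementia(doubled, gc, sched, re_params, seed=42)
    assert cal2.params.theta > cal1.params.theta


def test_calibration_rejects_all_zero_targets(lifetable, target_rates, re_params):
    gc = GrowthCurveParams(delta_u=-0.1)
    sched = calibrate_hazards(lifetable, {"man": 0.0, "woman": 0.0},
                              calib_n=100_000, seed=41)
    zeros = target_rates.assign(rate_per_1000py=0.0)
    with pytest.raises(DementiaParameterError):
        calibrate_dementia(zeros, gc, sched, re_params, seed=42)


def test_normalized_sigma0():
    assert normalized_sigma0(-0.1) == pytest.approx(np.sqrt(0.99))
    assert (-0.5) ** 2 + normalized_sigma0(-0.5) ** 2 == pytest.approx(1.0)
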