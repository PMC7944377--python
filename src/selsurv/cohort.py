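"""Baseline cohort generation.

A cohort is a population of 50-year-olds, dementia-free at baseline, each
carrying

* a binary sex/gender indicator (woman = 1, man = 0),
* a latent selection characteristic ``U`` ~ N(0, 1), independent of sex at
  baseline, representing traits (genetic risk, social disadvantage, ...)
  that harm both survival (in some scenarios) and cognition, and
* random effects ``(b0, b1, b2)`` of a person-specific quadratic cognitive
  trajectory: intercept, linear-slope and quadratic-slope deviations.

The intercept and linear slope are correlated (worse baseline cognition may
go with faster decline); the quadratic deviation is independent of both.
This module doubles as the synthetic-data generator for the whole package:
every test and simulation consumes cohorts drawn here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_generator

SEX_LABELS = {0: "man", 1: "woman"}


@dataclass(frozen=True)
class RandomEffectParams:
    """Standard deviations and correlation of the cognitive random effects.

    ``rho01`` couples intercept and linear slope only; the quadratic
    deviation ``b2`` is independent of the pair.
    """

    sigma0: float
    sigma1: float
    sigma2: float
    rho01: float = 0.0

    def __post_init__(self):
        if min(self.sigma0, self.sigma1, self.sigma2) < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if not -1.0 <= self.rho01 <= 1.0:
            raise ValueError(f"rho01={self.rho01} outside [-1, 1]")

    def covariance(self) -> np.ndarray:
        """Implied 3x3 covariance matrix of (b0, b1, b2)."""
        c01 = self.rho01 * self.sigma0 * self.sigma1
        return np.array(
            [
                [self.sigma0**2, c01, 0.0],
                [c01, self.sigma1**2, 0.0],
                [0.0, 0.0, self.sigma2**2],
            ]
        )


@dataclass
class Cohort:
    """Per-person baseline arrays; all of length ``n``."""

    sex: np.ndarray  # int8, woman=1 / man=0
    u: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        n = len(self.sex)
        if n == 0:
            raise ValueError("cohort must contain at least one individual")
        for name in ("u", "b0", "b1", "b2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} has length != n={n}")

    @property
    def n(self) -> int:
        return len(self.sex)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "sex": self.sex,
                "u": self.u,
                "b0": self.b0,
                "b1": self.b1,
                "b2": self.b2,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_cohort(n: int, p_female: float, re_params: RandomEffectParams, seed) -> Cohort:
    """Draw a baseline cohort of ``n`` 50-year-olds.

    The sex split is a deterministic count: exactly ``round(n * p_female)``
    women, randomly positioned. U is standard normal and independent of sex;
    (b0, b1) are jointly normal with correlation ``rho01``; b2 independent.

    Identical ``seed`` gives a bit-identical cohort.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p_female <= 1.0:
        raise ValueError(f"p_female must be in [0, 1], got {p_female}")
    rng = as_generator(seed)

    n_women = int(np.floor(n * p_female + 0.5))
    sex = np.zeros(n, dtype=np.int8)
    sex[:n_women] = 1
    rng.shuffle(sex)

    u = rng.standard_normal(n)
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    r = re_params
    b0 = r.sigma0 * z0
    b1 = r.sigma1 * (r.rho01 * z0 + np.sqrt(1.0 - r.rho01**2) * z1)
    b2 = r.sigma2 * z2
    return Cohort(sex=sex, u=u, b0=b0, b1=b1, b2=b2)


def u_summary_by_sex(cohort: Cohort, alive_mask: np.ndarray) -> pd.DataFrame:
    """Summarize U among the alive, per sex: mean, SD, quartiles.

    Rows for a sex with no alive member are flagged ``empty``; singleton
    groups get SD = NaN. An all-false mask warns and returns the two
    flagged-empty rows rather than raising.
    """
    alive_mask = np.asarray(alive_mask, dtype=bool)
    if len(alive_mask) != cohort.n:
        raise ValueError("alive_mask length differs from cohort size")
    if not alive_mask.any():
        warnings.warn("no one alive: U summary is empty", stacklevel=2)
    rows = []
    for code, label in SEX_LABELS.items():
        vals = cohort.u[alive_mask & (cohort.sex == code)]
        if vals.size == 0:
            rows.append(
                dict(sex=label, n_alive=0, mean=np.nan, sd=np.nan,
                     q25=np.nan, q50=np.nan, q75=np.nan, empty=True)
            )
            continue
        sd = np.nan if vals.size < 2 else float(np.std(vals, ddof=1))
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append(
            dict(sex=label, n_alive=int(vals.size), mean=float(np.mean(vals)),
                 sd=sd, q25=float(q25), q50=float(q50), q75=float(q75), empty=False)
        )
    return pd.DataFrame(rows)
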