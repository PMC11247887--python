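"""Synthetic survey and vital-statistics generator.

Emulates the statistical structure of repeated national health surveys
(four cross-sectional waves of ~44,000 adults each, ~50% women, binary
self-reported diabetes, heterogeneous sampling weights) and of a
general-population mortality schedule, with a known ground truth so every
pipeline stage can be validated without external data.  Disease status is
drawn from the prevalence field produced by the forward illness-death
solver, and the emitted mortality schedule is the general-population
mixture that same solver implies — so the generator and the estimator are
mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MRRProfile,
    PrevalenceTruth,
    ScenarioSpec,
    SexParams,
    solve_prevalence_forward,
)

__all__ = [
    "SEXES",
    "MortalitySchedule",
    "make_default_scenario",
    "scenario_truth",
    "generate_survey",
    "generate_mortality_schedule",
]

SEXES = ("male", "female")

SURVEY_COLUMNS = ["id", "age", "sex", "survey_year", "disease", "weight"]


# ---------------------------------------------------------------------------
# Mortality schedule container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalitySchedule:
    """General-population mortality m(age, year, sex) per person-year on a
    rectangular grid; bilinear interpolation inside the grid, constant
    extrapolation at the edges."""

    ages: np.ndarray
    years: np.ndarray
    rates: dict  # sex -> (n_ages, n_years) array

    def __post_init__(self) -> None:
        for sex, r in self.rates.items():
            r = np.asarray(r)
            if r.shape != (len(self.ages), len(self.years)):
                raise ValueError(f"rate grid for {sex!r} has shape {r.shape}")
            if np.any(r < 0):
                raise ValueError(f"negative mortality rate for sex {sex!r}")

    def rate(self, age, year, sex: str):
        """Interpolated rate; exact at grid nodes, clamped beyond the grid."""
        if sex not in self.rates:
            raise KeyError(f"sex {sex!r} not in mortality schedule")
        a = np.clip(np.asarray(age, dtype=float), self.ages[0], self.ages[-1])
        y = np.clip(np.asarray(year, dtype=float), self.years[0], self.years[-1])
        grid = self.rates[sex]
        ia = np.clip(np.searchsorted(self.ages, a, side="right") - 1, 0, len(self.ages) - 2)
        iy = np.clip(np.searchsorted(self.years, y, side="right") - 1, 0, len(self.years) - 2)
        if len(self.years) == 1:
            iy = np.zeros_like(iy)
            fy = np.zeros_like(y, dtype=float)
        else:
            fy = (y - self.years[iy]) / (self.years[iy + 1] - self.years[iy])
        fa = (a - self.ages[ia]) / (self.ages[ia + 1] - self.ages[ia])
        iy1 = iy + (0 if len(self.years) == 1 else 1)
        out = (
            grid[ia, iy] * (1 - fa) * (1 - fy)
            + grid[ia + 1, iy] * fa * (1 - fy)
            + grid[ia, iy1] * (1 - fa) * fy
            + grid[ia + 1, iy1] * fa * fy
        )
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------

def _peaked_incidence(peak_rate, peak_age, width, trend_per_year, ref_year):
    """Incidence rising to a peak near ``peak_age`` then declining, with a
    mild linear calendar trend; clipped at zero."""

    def inc(a, t):
        a = np.asarray(a, dtype=float)
        t = np.asarray(t, dtype=float)
        shape = np.exp(-0.5 * ((a - peak_age) / width) ** 2)
        trend = 1.0 + trend_per_year * (t - ref_year)
        return np.clip(peak_rate * shape * trend, 0.0, None)

    return inc


def _gompertz(alpha, beta):
    def m0(a):
        return alpha * np.exp(beta * np.asarray(a, dtype=float))

    return m0


def make_default_scenario(seed: int = 0) -> ScenarioSpec:
    """Default ground truth at national-survey scale.

    Four waves six years apart (2000...2018), 44,000 persons per wave,
    incidence peaking near age 65 at roughly 18-20 per 1000 person-years
    with a mild upward calendar trend (steeper for women), Gompertz
    disease-free mortality, and MRR anchors 8.0 at age 30 and 2.75 at
    age 80 (midpoints of the plausible ranges used for estimation).
    """
    sexes = {
        "male": SexParams(
            incidence=_peaked_incidence(0.018, 65.0, 16.0, 0.015, 2009.0),
            mortality0=_gompertz(9e-5, 0.085),
        ),
        "female": SexParams(
            incidence=_peaked_incidence(0.019, 65.0, 16.0, 0.018, 2009.0),
            mortality0=_gompertz(6e-5, 0.088),
        ),
    }
    return ScenarioSpec(
        sexes=sexes,
        mrr=MRRProfile(mrr_lo=8.0, mrr_hi=2.75),
        wave_years=(2000, 2006, 2012, 2018),
        n_per_wave=44_000,
        seed=seed,
    )


def scenario_truth(
    scenario: ScenarioSpec,
    years=None,
    age_offset: float = 0.5,
) -> PrevalenceTruth:
    """Forward-solve the scenario on the integer-age grid of its age range.

    Grid ages are the integer record ages; the PDE is evaluated at
    ``age + age_offset`` (records code age in completed years, so the cell
    centre is half a year above the integer label).
    """
    lo, hi = scenario.age_range
    ages = np.arange(int(lo), int(hi) + 1) + age_offset
    if years is None:
        years = np.asarray(scenario.wave_years, dtype=float)
    return solve_prevalence_forward(scenario, ages, np.asarray(years, dtype=float))


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

def generate_survey(
    scenario: ScenarioSpec,
    wave_year: int,
    n: int | None = None,
    seed: int | None = None,
    truth: PrevalenceTruth | None = None,
) -> pd.DataFrame:
    """Draw one cross-sectional survey wave as a SurveyRecord table.

    Ages are integers from an exponentially tilted adult age pyramid,
    sex is balanced, disease is Bernoulli at the forward-solved true
    prevalence of ``age + 0.5`` in the wave year, and weights are
    log-normal with unit mean (``scenario.weight_sigma``).  A nonzero
    ``scenario.weight_informative`` multiplies diseased persons' weights
    by ``exp(weight_informative)`` to emulate an informative design.
    Fixed seed gives byte-identical output.
    """
    if wave_year not in scenario.wave_years:
        raise ValueError(f"wave year {wave_year} is not one of {scenario.wave_years}")
    if n is None:
        n = scenario.n_per_wave
    if n <= 0:
        raise ValueError("sample size must be positive")
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)

    lo, hi = int(scenario.age_range[0]), int(scenario.age_range[1])
    ages = np.arange(lo, hi + 1)
    age_p = np.exp(-scenario.age_dist_rate * (ages - lo))
    age_p /= age_p.sum()

    if truth is None:
        truth = scenario_truth(scenario, years=[float(wave_year)])
    iy = int(np.argmin(np.abs(truth.years - wave_year)))
    if abs(truth.years[iy] - wave_year) > 1e-9:
        raise ValueError(f"truth grid does not contain wave year {wave_year}")

    age = rng.choice(ages, size=n, p=age_p)
    sex_idx = rng.integers(0, 2, size=n)  # 0 male, 1 female
    sex = np.where(sex_idx == 0, "male", "female")
    p_true = np.empty(n)
    for k, s in enumerate(SEXES):
        col = truth.prevalence[s][:, iy]
        mask = sex_idx == k
        p_true[mask] = col[age[mask] - lo]
    disease = (rng.random(n) < p_true).astype(int)
    sigma = scenario.weight_sigma
    weight = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    if scenario.weight_informative:
        weight = weight * np.exp(scenario.weight_informative * disease)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "survey_year": np.full(n, wave_year),
            "disease": disease,
            "weight": weight,
        }
    )


def generate_mortality_schedule(
    scenario: ScenarioSpec,
    ages=None,
    years=None,
) -> MortalitySchedule:
    """General-population mortality schedule implied by the scenario:
    ``m = m0 * (1 + p*(MRR-1))`` with p from the forward solver."""
    lo, hi = scenario.age_range
    if ages is None:
        ages = np.arange(int(lo), int(hi) + 1) + 0.5
    if years is None:
        y0, y1 = scenario.wave_years[0], scenario.wave_years[-1]
        years = np.arange(y0, y1 + 1, dtype=float)
    ages = np.asarray(ages, dtype=float)
    years = np.asarray(years, dtype=float)
    truth = solve_prevalence_forward(scenario, ages, years)
    return MortalitySchedule(
        ages=ages, years=years,
        rates={s: truth.m_general[s] for s in truth.m_general},
    )
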