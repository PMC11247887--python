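"""Illness-death model mathematics.

The three-state illness-death model (healthy -> diseased -> dead,
healthy -> dead, no recovery) links the age/time field of prevalence
p(a, t) to the incidence rate i, the general-population mortality m and
the mortality rate ratio MRR through

    i = (d/da + d/dt) p / (1 - p)  +  m * p (MRR - 1) / (p (MRR - 1) + 1)

where (d/da + d/dt) p is the change of prevalence along a birth cohort.
This module evaluates that identity, its rearrangement for the cohort
derivative, the log-linear MRR age profile, and a forward solver that
integrates the prevalence field along cohort characteristics (lines of
constant birth year t - a) so that synthetic ground truth is available
for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MRRProfile",
    "ModelPoint",
    "ScenarioSpec",
    "SexParams",
    "eval_incidence_equation",
    "eval_pde_rhs",
    "solve_prevalence_forward",
    "PrevalenceTruth",
]

# Characteristic-ODE integration tolerances (adaptive DOP853).
ODE_ATOL = 1e-10
ODE_RTOL = 1e-10


# ---------------------------------------------------------------------------
# Mortality rate ratio profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MRRProfile:
    """Age profile of the mortality rate ratio (diseased vs disease-free).

    log(MRR) is affine in age between the two anchors and clamped to the
    anchor value outside ``[age_lo, age_hi]``.  The anchors default to the
    ages at which diabetes MRR estimates are conventionally reported
    (30 and 80 years).
    """

    mrr_lo: float
    mrr_hi: float
    age_lo: float = 30.0
    age_hi: float = 80.0

    def __post_init__(self) -> None:
        if not (self.mrr_lo > 0 and self.mrr_hi > 0):
            raise ValueError(
                f"MRR anchors must be positive (got {self.mrr_lo}, {self.mrr_hi}); "
                "log-linear interpolation needs log(MRR)"
            )
        if not self.age_lo < self.age_hi:
            raise ValueError("age_lo must be strictly below age_hi")

    def __call__(self, age: float | np.ndarray) -> float | np.ndarray:
        a = np.clip(np.asarray(age, dtype=float), self.age_lo, self.age_hi)
        frac = (a - self.age_lo) / (self.age_hi - self.age_lo)
        out = np.exp((1.0 - frac) * np.log(self.mrr_lo) + frac * np.log(self.mrr_hi))
        return out if out.ndim else float(out)


def mrr_at_age(profile: MRRProfile, age: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the MRR profile at ``age`` (functional alias of the call)."""
    return profile(age)


# ---------------------------------------------------------------------------
# Eq. (1) and its rearrangement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelPoint:
    """One point of the illness-death identity: prevalence ``p``, cohort
    derivative ``dp`` (per year), general-population mortality ``m`` (per
    person-year) and mortality rate ratio ``mrr``."""

    p: float
    dp: float
    m: float
    mrr: float


def _validate_pm(p: np.ndarray, m: np.ndarray, mrr: np.ndarray) -> None:
    if np.any(p < 0) or np.any(p >= 1):
        bad = np.asarray(p)[(np.asarray(p) < 0) | (np.asarray(p) >= 1)]
        raise ValueError(f"prevalence must lie in [0, 1); offending value(s): {bad[:5]}")
    if np.any(m < 0):
        raise ValueError("general-population mortality m must be nonnegative")
    if np.any(mrr <= 0):
        raise ValueError("mortality rate ratio must be positive")
    denom = p * (mrr - 1.0) + 1.0
    if np.any(denom <= 0):
        raise ValueError(
            "excess-mortality denominator p*(MRR-1)+1 is non-positive "
            "(MRR < 1 with large prevalence)"
        )


def eval_incidence_equation(point=None, *, p=None, dp=None, m=None, mrr=None):
    """Incidence per person-year from the illness-death identity.

    ``i = dp/(1-p) + m * p(MRR-1) / (p(MRR-1)+1)``.  Accepts a
    :class:`ModelPoint` or the four fields as (broadcastable) keyword
    arrays.  Negative results are returned as computed — truncating them
    would bias resampling percentiles downstream.
    """
    if point is not None:
        p, dp, m, mrr = point.p, point.dp, point.m, point.mrr
    p = np.asarray(p, dtype=float)
    dp = np.asarray(dp, dtype=float)
    m = np.asarray(m, dtype=float)
    mrr = np.asarray(mrr, dtype=float)
    _validate_pm(p, m, mrr)
    excess = p * (mrr - 1.0)
    out = dp / (1.0 - p) + m * excess / (excess + 1.0)
    return out if out.ndim else float(out)


def eval_pde_rhs(p, i, m, mrr):
    """Cohort derivative of prevalence given incidence: the exact algebraic
    inverse of :func:`eval_incidence_equation`,

    ``dp = (1-p) * [ i - m * p(MRR-1)/(p(MRR-1)+1) ]``.
    """
    p = np.asarray(p, dtype=float)
    i = np.asarray(i, dtype=float)
    m = np.asarray(m, dtype=float)
    mrr = np.asarray(mrr, dtype=float)
    _validate_pm(p, m, mrr)
    excess = p * (mrr - 1.0)
    out = (1.0 - p) * (i - m * excess / (excess + 1.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Scenario specification (synthetic ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexParams:
    """Per-sex ground-truth functions: incidence i(a, t) and disease-free
    mortality m0(a), both per person-year."""

    incidence: Callable[[np.ndarray, np.ndarray], np.ndarray]
    mortality0: Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for the synthetic-data generator and for validation.

    The forward solver integrates each sex's prevalence from ``p(a0) = p0``
    using the disease-free mortality ``m0`` and the MRR profile; the
    general-population mortality the estimator consumes is derived as
    ``m = m0 * (1 + p*(MRR-1))`` so simulator and estimator are internally
    consistent.
    """

    sexes: Mapping[str, SexParams]
    mrr: MRRProfile
    wave_years: tuple[int, ...]
    n_per_wave: int
    age_range: tuple[float, float] = (20.0, 79.0)
    a0: float = 0.0
    p0: float = 0.0
    seed: int = 0
    age_dist_rate: float = 0.035  # exponential tilt of the adult age pyramid
    weight_sigma: float = 0.5    # log-normal sd of sampling weights (unit mean)
    weight_informative: float = 0.0  # weight-disease dependence knob, 0 = none

    def __post_init__(self) -> None:
        years = tuple(self.wave_years)
        if len(years) < 2:
            raise ValueError(
                "at least two survey waves are required: the cohort derivative "
                "of prevalence needs cross-sections from at least two years"
            )
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("wave years must be strictly increasing")
        if not (0.0 <= self.p0 < 1.0):
            raise ValueError("initial prevalence p0 must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Forward solver along cohort characteristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceTruth:
    """Forward-solved prevalence field on an (age, year) grid, per sex,
    together with the implied general-population mortality."""

    ages: np.ndarray
    years: np.ndarray
    prevalence: Mapping[str, np.ndarray]   # sex -> (n_ages, n_years)
    m_general: Mapping[str, np.ndarray]    # sex -> (n_ages, n_years)
    scenario: ScenarioSpec = field(repr=False, compare=False, default=None)

    def p(self, sex: str, age: float, year: float) -> float:
        ia = int(np.argmin(np.abs(self.ages - age)))
        iy = int(np.argmin(np.abs(self.years - year)))
        if abs(self.ages[ia] - age) > 1e-9 or abs(self.years[iy] - year) > 1e-9:
            raise KeyError(f"({age}, {year}) is not a grid node")
        return float(self.prevalence[sex][ia, iy])


def solve_prevalence_forward(
    scenario: ScenarioSpec,
    ages: Sequence[float],
    years: Sequence[float],
    sexes: Sequence[str] | None = None,
) -> PrevalenceTruth:
    """Integrate the illness-death PDE along cohort characteristics.

    Along the line of constant birth year (t - a fixed) the PDE reduces to
    an ODE in age,

        dp/da = (1 - p) * [ i(a, t0 + (a - a0)) - p * m0(a) * (MRR(a) - 1) ],

    started from ``p(a0) = p0``.  One stacked ODE system (one component per
    requested (age, year) cell and sex) is integrated adaptively with dense
    output and evaluated at each cell's own age.  Also returns the implied
    general-population mortality ``m = m0 * (1 + p*(MRR-1))`` on the grid.
    """
    ages = np.asarray(ages, dtype=float)
    years = np.asarray(years, dtype=float)
    if sexes is None:
        sexes = list(scenario.sexes)
    if ages.min() < scenario.a0:
        raise ValueError(f"requested age {ages.min()} precedes start age {scenario.a0}")

    mrr = scenario.mrr
    # Cells: all (age, year) pairs share the integration in age; each cell's
    # characteristic is fixed by its birth year  c = year - age.
    A, Y = np.meshgrid(ages, years, indexing="ij")
    birth = (Y - A).ravel()
    a_end = A.ravel()
    a_max = float(a_end.max())

    prevalence: dict[str, np.ndarray] = {}
    m_general: dict[str, np.ndarray] = {}
    for sex in sexes:
        par = scenario.sexes[sex]

        def rhs(a: float, pvec: np.ndarray) -> np.ndarray:
            t = birth + a
            inc = np.asarray(par.incidence(np.full_like(pvec, a), t), dtype=float)
            m0 = float(par.mortality0(np.asarray(a)))
            r = float(mrr(a))
            return (1.0 - pvec) * (inc - pvec * m0 * (r - 1.0))

        sol = solve_ivp(
            rhs,
            (scenario.a0, a_max),
            np.full(birth.shape, scenario.p0, dtype=float),
            method="DOP853",
            dense_output=True,
            rtol=ODE_RTOL,
            atol=ODE_ATOL,
        )
        if not sol.success:
            raise RuntimeError(
                f"characteristic integration failed for sex={sex!r}: {sol.message}"
            )
        pcells = np.array([sol.sol(a)[j] for j, a in enumerate(a_end)])
        if np.any(pcells < -1e-8) or np.any(pcells >= 1.0):
            j = int(np.argmax((pcells < -1e-8) | (pcells >= 1.0)))
            raise RuntimeError(
                f"prevalence left [0, 1) on characteristic with birth year "
                f"{birth[j]:.1f} (age {a_end[j]:.1f})"
            )
        p = np.clip(pcells, 0.0, None).reshape(A.shape)
        m0_grid = np.asarray(par.mortality0(ages), dtype=float)[:, None]
        mg = m0_grid * (1.0 + p * (np.asarray(mrr(ages))[:, None] - 1.0))
        prevalence[sex] = p
        m_general[sex] = mg

    return PrevalenceTruth(
        ages=ages, years=years, prevalence=prevalence, m_general=m_general,
        scenario=scenario,
    )
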