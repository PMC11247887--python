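"""Incidence estimation pipeline.

Applies the illness-death identity at the midpoints between survey waves,
propagates input uncertainty by resampling (coefficient draws from the
prevalence surface, MRR anchors from uniform plausibility ranges), and
produces the reporting quantities: age-specific incidence curves, 10-year
age-group rates evaluated at group midpoints, directly age-standardized
rates, and incidence rate ratios between years — each with 2.5/50/97.5
percentile bands computed replicate-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MRRProfile, eval_incidence_equation
from .smoothing import PrevalenceSurface
from .synthetic import MortalitySchedule

__all__ = [
    "AGE_GROUPS",
    "StandardPopulation",
    "ResamplingConfig",
    "IncidenceResult",
    "midpoint_years",
    "estimate_curve",
    "resample",
    "age_group_rate",
    "age_standardize",
    "incidence_rate_ratio",
    "report_table",
    "format_report",
]

# Percentiles are linear interpolation between order statistics
# (numpy's "linear" method), pinned for reproducibility.
PCTL = dict(method="linear")

AGE_GROUPS: tuple[tuple[int, int], ...] = (
    (20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79),
)


def group_midpoint(group: tuple[int, int]) -> float:
    """Evaluation age of a 10-year group: 55 for 50-59, 25 for 20-29, etc."""
    lo, hi = group
    return (lo + hi + 1) / 2.0


def group_label(group: tuple[int, int]) -> str:
    return f"{group[0]}-{group[1]}"


# ---------------------------------------------------------------------------
# Standard population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights for direct standardization; normalized to sum 1."""

    groups: tuple[tuple[int, int], ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("standard-population weights must be >= 0, not all zero")
        gs = sorted(self.groups)
        for (lo1, hi1), (lo2, _) in zip(gs, gs[1:]):
            if lo2 != hi1 + 1:
                raise ValueError(f"age groups do not tile: gap/overlap after {lo1}-{hi1}")
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def uniform(cls, groups=AGE_GROUPS) -> "StandardPopulation":
        return cls(groups=tuple(groups), weights=np.full(len(groups), 1.0 / len(groups)))

    @classmethod
    def from_survey(cls, records: pd.DataFrame, groups=AGE_GROUPS) -> "StandardPopulation":
        """Standard from a (pooled) survey's own weighted age distribution."""
        w = []
        for lo, hi in groups:
            sel = (records["age"] >= lo) & (records["age"] <= hi)
            w.append(float(records.loc[sel, "weight"].sum()))
        return cls(groups=tuple(groups), weights=np.asarray(w))


@dataclass(frozen=True)
class ResamplingConfig:
    """Resampling scheme: R repetitions; per repetition one coefficient draw
    of the prevalence surface and one MRR profile with anchors drawn from
    uniform plausibility ranges (independently unless ``common_quantile``)."""

    repetitions: int = 2000
    mrr_lo_range: tuple[float, float] = (7.5, 8.5)   # at age 30
    mrr_hi_range: tuple[float, float] = (2.5, 3.0)   # at age 80
    seed: int = 0
    common_quantile: bool = False
    derivative_method: str = "analytic"

    def __post_init__(self) -> None:
        if self.repetitions < 2:
            raise ValueError("resampling needs at least 2 repetitions")
        for lo, hi in (self.mrr_lo_range, self.mrr_hi_range):
            if lo > hi:
                raise ValueError(f"MRR range ({lo}, {hi}) has lo > hi")

    def mid_profile(self) -> MRRProfile:
        return MRRProfile(
            mrr_lo=float(np.mean(self.mrr_lo_range)),
            mrr_hi=float(np.mean(self.mrr_hi_range)),
        )

    def draw_profile(self, rng: np.random.Generator) -> MRRProfile:
        if self.common_quantile:
            q = rng.random()
            qs = (q, q)
        else:
            qs = (rng.random(), rng.random())
        lo = self.mrr_lo_range[0] + qs[0] * (self.mrr_lo_range[1] - self.mrr_lo_range[0])
        hi = self.mrr_hi_range[0] + qs[1] * (self.mrr_hi_range[1] - self.mrr_hi_range[0])
        return MRRProfile(mrr_lo=lo, mrr_hi=hi)


# ---------------------------------------------------------------------------
# Point estimation
# ---------------------------------------------------------------------------

def midpoint_years(wave_years: Sequence[float]) -> tuple[float, ...]:
    """Midpoints of consecutive survey-wave pairs: the years at which the
    cohort derivative, hence the incidence, is identified."""
    years = list(wave_years)
    if len(years) < 2:
        raise ValueError("need at least two wave years")
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("wave years must be strictly increasing")
    return tuple((a + b) / 2.0 for a, b in zip(years, years[1:]))


def estimate_curve(
    surface: PrevalenceSurface,
    mortality: MortalitySchedule,
    mrr: MRRProfile,
    year: float,
    sex: str,
    ages: np.ndarray,
    derivative_method: str = "analytic",
) -> np.ndarray:
    """Incidence per person-year at each age, from the illness-death
    identity: p and its cohort derivative from the surface, m from the
    mortality schedule, MRR from the profile."""
    ages = np.asarray(ages, dtype=float)
    y0, y1 = surface.year_range
    if not (y0 <= year <= y1):
        raise ValueError(f"year {year} outside surface domain [{y0}, {y1}]")
    # The schedule's own rule covers half-a-year beyond its node range
    # (records at integer ages vs nodes at age+0.5); farther out is an error.
    if ages.min() < mortality.ages[0] - 0.5 or ages.max() > mortality.ages[-1] + 0.5:
        raise ValueError(
            f"ages [{ages.min()}, {ages.max()}] outside mortality grid "
            f"[{mortality.ages[0]}, {mortality.ages[-1]}]"
        )
    yr = np.full(ages.shape, float(year))
    p = surface.predict(ages, yr, sex)
    dp = surface.directional_derivative(ages, yr, sex, method=derivative_method)
    m = np.asarray(mortality.rate(ages, yr, sex))
    return eval_incidence_equation(p=p, dp=dp, m=m, mrr=np.asarray(mrr(ages)))


def age_group_rate(curve, group: tuple[int, int]):
    """Rate of a 10-year group: the incidence curve evaluated at the group
    midpoint (55 for 50-59).  ``curve`` is a callable age -> rate or an
    ``(ages, values)`` pair interpolated linearly."""
    mid = group_midpoint(group)
    if callable(curve):
        return float(np.asarray(curve(mid)))
    ages, values = curve
    ages = np.asarray(ages, dtype=float)
    if not (ages.min() <= mid <= ages.max()):
        raise ValueError(f"group midpoint {mid} outside curve domain")
    return float(np.interp(mid, ages, np.asarray(values, dtype=float)))


def age_standardize(curve, std: StandardPopulation):
    """Directly standardized rate: normalized-weight sum of group rates
    (each group evaluated at its midpoint)."""
    rates = np.asarray([age_group_rate(curve, g) for g in std.groups])
    return float(std.weights @ rates)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

@dataclass
class IncidenceResult:
    """Replicate-wise incidence estimates and their percentile summaries.

    All internal rates are per person-year; the x1000 reporting scale is
    applied only by :func:`report_table`.  ``rep_*`` arrays hold one row
    per resampling replicate; every derived summary (group rate,
    standardized rate, IRR) is computed within replicates and summarized
    by 2.5/50/97.5 percentiles.
    """

    ages: np.ndarray
    years: tuple[float, ...]
    sexes: tuple[str, ...]
    groups: tuple[tuple[int, int], ...]
    std: StandardPopulation
    plugin_curve: np.ndarray    # (S, Y, A) no-noise plug-in estimate
    plugin_group: np.ndarray    # (S, Y, G)
    plugin_std: np.ndarray      # (S, Y)
    rep_curve: np.ndarray | None = None    # (R, S, Y, A)
    rep_group: np.ndarray | None = None    # (R, S, Y, G)
    rep_std: np.ndarray | None = None      # (R, S, Y)
    seed: int | None = None
    config: ResamplingConfig | None = None

    @property
    def n_replicates(self) -> int:
        return 0 if self.rep_std is None else self.rep_std.shape[0]

    def _pct(self, arr):
        return np.percentile(arr, [2.5, 50.0, 97.5], axis=0, **PCTL)

    def curve_band(self, sex: str, year: float) -> np.ndarray:
        """(3, A): 2.5th, median, 97.5th percentile curves."""
        s, y = self.sexes.index(sex), self.years.index(year)
        return self._pct(self.rep_curve[:, s, y, :])

    def group_band(self, sex: str, year: float) -> np.ndarray:
        s, y = self.sexes.index(sex), self.years.index(year)
        return self._pct(self.rep_group[:, s, y, :])

    def standardized_band(self, sex: str, year: float) -> np.ndarray:
        s, y = self.sexes.index(sex), self.years.index(year)
        return self._pct(self.rep_std[:, s, y])

    def point_standardized(self, sex: str, year: float) -> float:
        """Reported point estimate: the replicate median (falls back to the
        plug-in value in point-only mode)."""
        s, y = self.sexes.index(sex), self.years.index(year)
        if self.rep_std is None:
            return float(self.plugin_std[s, y])
        return float(np.median(self.rep_std[:, s, y]))

    def negative_flags(self) -> np.ndarray:
        """(S, Y, A) boolean: plug-in incidence negative at that cell."""
        return self.plugin_curve < 0


def resample(
    surface: PrevalenceSurface,
    mortality: MortalitySchedule,
    config: ResamplingConfig,
    years: Sequence[float],
    std: StandardPopulation,
    sexes: Sequence[str] | None = None,
    ages: np.ndarray | None = None,
    groups=AGE_GROUPS,
) -> IncidenceResult:
    """Run the full resampling estimation.

    Each replicate draws one surface (multivariate-normal coefficient
    draw) and one MRR profile (uniform anchors), evaluates the incidence
    curve at every (sex, year, age) and at the group midpoints, and
    standardizes.  Percentile summaries are taken cell-wise over
    replicates.  Deterministic under a fixed ``config.seed``.
    """
    if sexes is None:
        sexes = surface.sexes
    if ages is None:
        lo, hi = surface.age_range
        ages = np.arange(int(lo), int(hi) + 1) + 0.5
    ages = np.asarray(ages, dtype=float)
    years = tuple(float(y) for y in years)
    sexes = tuple(sexes)
    groups = tuple(groups)
    mids = np.asarray([group_midpoint(g) for g in groups])
    rng = np.random.default_rng(config.seed)
    R = config.repetitions

    def eval_all(surf, mrr):
        curve = np.empty((len(sexes), len(years), len(ages)))
        grp = np.empty((len(sexes), len(years), len(groups)))
        for si, sex in enumerate(sexes):
            for yi, year in enumerate(years):
                curve[si, yi] = estimate_curve(
                    surf, mortality, mrr, year, sex, ages,
                    derivative_method=config.derivative_method,
                )
                grp[si, yi] = estimate_curve(
                    surf, mortality, mrr, year, sex, mids,
                    derivative_method=config.derivative_method,
                )
        stdized = np.tensordot(grp, std.weights, axes=([2], [0]))
        return curve, grp, stdized

    plugin_curve, plugin_group, plugin_std = eval_all(surface, config.mid_profile())

    # Replicates reuse fixed design matrices (only coefficients and MRR
    # anchors vary), so each replicate is a handful of small matmuls.
    all_ages = np.concatenate([ages, mids])
    fd = config.derivative_method == "finite_difference"
    from .smoothing import ETA_MAX, FD_STEP

    X_pred, X_der, m_vec = {}, {}, {}
    for si, sex in enumerate(sexes):
        for yi, year in enumerate(years):
            yr = np.full(all_ages.shape, year)
            X_pred[si, yi] = surface.design_row(all_ages, yr, sex)
            if fd:
                X_der[si, yi] = (
                    surface.design_row(all_ages + FD_STEP, yr + FD_STEP, sex),
                    surface.design_row(all_ages - FD_STEP, yr - FD_STEP, sex),
                )
            else:
                X_der[si, yi] = (
                    surface.design_row(all_ages, yr, sex, age_deriv=1)
                    + surface.design_row(all_ages, yr, sex, year_deriv=1)
                )
            m_vec[si, yi] = np.asarray(mortality.rate(all_ages, yr, sex))

    from scipy.special import expit

    rep_curve = np.empty((R, len(sexes), len(years), len(ages)))
    rep_group = np.empty((R, len(sexes), len(years), len(groups)))
    rep_std = np.empty((R, len(sexes), len(years)))
    nA = len(ages)
    for r in range(R):
        coef_r = surface.coef + surface._cov_factor @ rng.standard_normal(
            len(surface.coef)
        )
        mrr_r = config.draw_profile(rng)
        mrr_vals = np.asarray(mrr_r(all_ages))
        for si in range(len(sexes)):
            for yi in range(len(years)):
                p = expit(np.clip(X_pred[si, yi] @ coef_r, -ETA_MAX, ETA_MAX))
                if fd:
                    Xp, Xm = X_der[si, yi]
                    dp = (expit(Xp @ coef_r) - expit(Xm @ coef_r)) / (2.0 * FD_STEP)
                else:
                    dp = p * (1.0 - p) * (X_der[si, yi] @ coef_r)
                i_all = eval_incidence_equation(
                    p=p, dp=dp, m=m_vec[si, yi], mrr=mrr_vals
                )
                rep_curve[r, si, yi] = i_all[:nA]
                rep_group[r, si, yi] = i_all[nA:]
        rep_std[r] = np.tensordot(rep_group[r], std.weights, axes=([2], [0]))

    return IncidenceResult(
        ages=ages, years=years, sexes=sexes, groups=groups, std=std,
        plugin_curve=plugin_curve, plugin_group=plugin_group,
        plugin_std=plugin_std, rep_curve=rep_curve, rep_group=rep_group,
        rep_std=rep_std, seed=config.seed, config=config,
    )


# ---------------------------------------------------------------------------
# Incidence rate ratios
# ---------------------------------------------------------------------------

def incidence_rate_ratio(
    result: IncidenceResult,
    year_num: float,
    year_den: float,
    level: str = "standardized",
    sex: str | None = None,
    group: tuple[int, int] | None = None,
) -> dict:
    """Ratio of incidence between two years, replicate-wise.

    Per replicate the chosen summary (standardized rate, or one group's
    rate) in ``year_num`` is divided by the same summary in ``year_den``;
    the point IRR is the median of replicate ratios with a 2.5/97.5
    percentile band.  Replicates with non-positive denominator are
    excluded and counted in ``n_excluded``.
    """
    yn, yd = result.years.index(float(year_num)), result.years.index(float(year_den))
    out = {}
    sexes = result.sexes if sex is None else (sex,)
    for s in sexes:
        si = result.sexes.index(s)
        if level == "standardized":
            num = result.rep_std[:, si, yn]
            den = result.rep_std[:, si, yd]
        elif level == "group":
            gi = result.groups.index(tuple(group))
            num = result.rep_group[:, si, yn, gi]
            den = result.rep_group[:, si, yd, gi]
        else:
            raise ValueError(f"unknown IRR level {level!r}")
        ok = den > 0
        ratios = num[ok] / den[ok]
        if len(ratios) == 0:
            # every replicate denominator non-positive: ratio undefined
            out[s] = {"irr": np.nan, "lo": np.nan, "hi": np.nan,
                      "n_excluded": int((~ok).sum())}
            continue
        lo, med, hi = np.percentile(ratios, [2.5, 50.0, 97.5], **PCTL)
        out[s] = {
            "irr": float(med), "lo": float(lo), "hi": float(hi),
            "n_excluded": int((~ok).sum()),
        }
    return out[sex] if sex is not None else out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_table(result: IncidenceResult, irr_baseline: float | None = None) -> pd.DataFrame:
    """Tidy table of reported rates: one row per (sex, row-kind, year) with
    rate/lo/hi per 1000 person-years, plus IRR rows versus the baseline
    year (default: the earliest estimation year)."""
    if irr_baseline is None:
        irr_baseline = result.years[0]
    rows = []
    have_reps = result.rep_std is not None
    for si, sex in enumerate(result.sexes):
        for yi, year in enumerate(result.years):
            kinds = [("age-standardized", None)] + [
                (group_label(g), gi) for gi, g in enumerate(result.groups)
            ]
            for kind, gi in kinds:
                if gi is None:
                    point = result.point_standardized(sex, year)
                    band = result.standardized_band(sex, year) if have_reps else None
                else:
                    if have_reps:
                        b = result.group_band(sex, year)
                        point, band = float(b[1, gi]), b[:, gi]
                    else:
                        point, band = float(result.plugin_group[si, yi, gi]), None
                rows.append(
                    {
                        "sex": sex, "row": kind, "year": year,
                        "rate_per_1000": point * 1000.0,
                        "lo_per_1000": band[0] * 1000.0 if band is not None else np.nan,
                        "hi_per_1000": band[2] * 1000.0 if band is not None else np.nan,
                        "measure": "incidence",
                    }
                )
        if have_reps:
            for year in result.years:
                if year == irr_baseline:
                    continue
                irr = incidence_rate_ratio(result, year, irr_baseline, sex=sex)
                rows.append(
                    {
                        "sex": sex, "row": "age-standardized",
                        "year": year, "rate_per_1000": irr["irr"],
                        "lo_per_1000": irr["lo"], "hi_per_1000": irr["hi"],
                        "measure": f"irr_vs_{irr_baseline:g}",
                    }
                )
                for g in result.groups:
                    irr = incidence_rate_ratio(result, year, irr_baseline,
                                               level="group", group=g, sex=sex)
                    rows.append(
                        {
                            "sex": sex, "row": group_label(g),
                            "year": year, "rate_per_1000": irr["irr"],
                            "lo_per_1000": irr["lo"], "hi_per_1000": irr["hi"],
                            "measure": f"irr_vs_{irr_baseline:g}",
                        }
                    )
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> str:
    """Aligned text rendering: '6.1 (3.5-9.2)' cells per year, one block
    per sex; missing bands (point-only mode) render as an em-dash."""
    lines = []
    inc = table[table["measure"] == "incidence"]
    for sex in inc["sex"].unique():
        sub = inc[inc["sex"] == sex]
        years = sorted(sub["year"].unique())
        lines.append(f"{sex.capitalize()} — incidence per 1000 person-years (95% CI)")
        header = f"{'':>16}" + "".join(f"{y:>20.6g}" for y in years)
        lines.append(header)
        for kind in sub["row"].unique():
            cells = []
            for y in years:
                r = sub[(sub["row"] == kind) & (sub["year"] == y)].iloc[0]
                if np.isnan(r["lo_per_1000"]):
                    cells.append(f"{r['rate_per_1000']:.1f} (—)")
                else:
                    cells.append(
                        f"{r['rate_per_1000']:.1f} "
                        f"({r['lo_per_1000']:.1f}–{r['hi_per_1000']:.1f})"
                    )
            lines.append(f"{kind:>16}" + "".join(f"{c:>20}" for c in cells))
        lines.append("")
    return "\n".join(lines)
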