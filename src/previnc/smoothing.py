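"""Two-stage prevalence smoothing.

Stage 1 fits each survey wave separately with a survey-weighted logistic
regression of disease on a natural cubic spline in age (five equally
spaced interior knots over the age range), per sex.  Stage 2 stacks the
stage-1 fitted logit prevalences, evaluated on the integer age grid, and
regresses them on a tensor design {cubic B-spline in age with 3 interior
knots} x {1, survey year} x {1, sex} — i.e. sex- and year-specific age
profiles with the full three-way age x year x sex interaction.  The
pooled fit provides point predictions, the cohort directional derivative
(d/da + d/dt)p needed by the illness-death identity, and a coefficient
sampling distribution for uncertainty propagation.

Age convention: records code age in completed integer years; the model is
evaluated at age + 0.5 so that discrete records and continuous model agree
at cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.special import expit, logit

__all__ = [
    "WaveFit",
    "PrevalenceSurface",
    "fit_wave",
    "pool_waves",
    "directional_derivative",
    "sample_surface",
]

AGE_OFFSET = 0.5
N_STAGE1_KNOTS = 5         # interior, equally spaced over the age range
STAGE2_KNOT_QUANTILES = (0.25, 0.50, 0.75)
SPLINE_DEGREE = 3
FD_STEP = 0.1              # years, diagonal finite-difference fallback
# |eta| cap keeping expit(eta) strictly inside (0, 1) in double precision
ETA_MAX = 35.0


# ---------------------------------------------------------------------------
# Stage 1: per-wave survey-weighted logistic spline fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveFit:
    """One survey wave's fitted logit-prevalence curves (per sex) on the
    integer age grid."""

    survey_year: int
    ages: np.ndarray                      # integer age labels
    logit_prev: Mapping[str, np.ndarray]  # sex -> fitted logit p at age+0.5
    logit_cov: Mapping[str, np.ndarray]   # sex -> covariance of those values
    n_effective: Mapping[str, float]
    knots: np.ndarray

    def prevalence(self, sex: str) -> np.ndarray:
        return expit(np.asarray(self.logit_prev[sex]))


def _stage1_knots(age_range: tuple[float, float]) -> np.ndarray:
    lo = age_range[0] + AGE_OFFSET
    hi = age_range[1] + AGE_OFFSET
    return np.linspace(lo, hi, N_STAGE1_KNOTS + 2)[1:-1]


def fit_wave(
    records: pd.DataFrame,
    age_range: tuple[float, float] = (20.0, 79.0),
    sexes: Sequence[str] = ("male", "female"),
) -> WaveFit:
    """Weighted maximum-likelihood logistic fit of one wave, per sex.

    Maximizes the weight-weighted Bernoulli log-likelihood (weights enter
    as likelihood weights, so doubling every record while halving its
    weight leaves the fit unchanged) with a natural cubic spline in age.
    """
    years = records["survey_year"].unique()
    if len(years) != 1:
        raise ValueError(f"fit_wave expects a single survey wave, got years {sorted(years)}")
    year = int(years[0])
    if (records["weight"] <= 0).any():
        raise ValueError(f"non-positive survey weight in wave {year}")

    lo, hi = age_range
    knots = _stage1_knots(age_range)
    grid_ages = np.arange(int(lo), int(hi) + 1)
    grid_x = grid_ages + AGE_OFFSET

    logit_prev: dict[str, np.ndarray] = {}
    logit_cov: dict[str, np.ndarray] = {}
    n_eff: dict[str, float] = {}
    for sex in sexes:
        sub = records[records["sex"] == sex]
        y = sub["disease"].to_numpy(dtype=float)
        if len(sub) == 0 or y.min() == y.max():
            raise ValueError(
                f"cannot fit wave {year}, sex {sex!r}: need both outcome classes"
            )
        x = sub["age"].to_numpy(dtype=float) + AGE_OFFSET
        # unit-mean normalization: the weighted MLE is invariant to weight
        # scale, and normalizing makes that exact at optimizer tolerance
        w = sub["weight"].to_numpy(dtype=float)
        w = np.ones_like(w) if np.ptp(w) == 0 else w / w.mean()
        data = {"x": x, "k": knots, "lb": lo + AGE_OFFSET, "ub": hi + AGE_OFFSET}
        X = np.asarray(
            patsy.dmatrix("cr(x, knots=k, lower_bound=lb, upper_bound=ub)", data)
        )
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
                tol=1e-10, maxiter=300
            )
        except Exception as exc:  # perfect separation, non-convergence
            raise ValueError(f"logistic fit failed for wave {year}, sex {sex!r}: {exc}")
        if not np.all(np.isfinite(res.params)):
            raise ValueError(
                f"logistic fit diverged (separation?) for wave {year}, sex {sex!r}"
            )
        Xg = np.asarray(
            patsy.dmatrix(
                "cr(x, knots=k, lower_bound=lb, upper_bound=ub)",
                {"x": grid_x, "k": knots, "lb": lo + AGE_OFFSET, "ub": hi + AGE_OFFSET},
            )
        )
        logit_prev[sex] = Xg @ res.params
        logit_cov[sex] = Xg @ np.asarray(res.cov_params()) @ Xg.T
        n_eff[sex] = float(w.sum() ** 2 / (w**2).sum())

    return WaveFit(
        survey_year=year, ages=grid_ages, logit_prev=logit_prev,
        logit_cov=logit_cov, n_effective=n_eff, knots=knots,
    )


# ---------------------------------------------------------------------------
# Stage 2: pooled logit-scale surface
# ---------------------------------------------------------------------------

def _stage2_knot_vector(age_range: tuple[float, float]) -> np.ndarray:
    """Full B-spline knot vector: 3 interior knots at the quartiles of the
    age grid, boundary knots repeated degree+1 times."""
    lo = age_range[0] + AGE_OFFSET
    hi = age_range[1] + AGE_OFFSET
    grid = np.arange(age_range[0], age_range[1] + 1) + AGE_OFFSET
    interior = np.quantile(grid, STAGE2_KNOT_QUANTILES)
    return np.concatenate(
        [[lo] * (SPLINE_DEGREE + 1), interior, [hi] * (SPLINE_DEGREE + 1)]
    )


@dataclass(frozen=True)
class PrevalenceSurface:
    """Pooled smooth logit-prevalence surface p(age, year, sex).

    The linear predictor is eta(a, t, s) = sum_j B_j(a) * (c_j0 + c_j1*u +
    c_j2*s + c_j3*u*s) with u the centred survey year and s the sex
    indicator; coefficients are stored with their covariance so the
    surface can be resampled.
    """

    coef: np.ndarray
    cov: np.ndarray
    knots: np.ndarray
    year_center: float
    age_range: tuple[float, float]
    year_range: tuple[float, float]
    sexes: tuple[str, ...] = ("male", "female")
    _cov_factor: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (len(self.coef), len(self.coef)):
            raise ValueError("covariance shape does not match coefficients")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        evals, evecs = np.linalg.eigh((cov + cov.T) / 2.0)
        if evals.min() < -1e-10 * max(evals.max(), 1.0):
            raise ValueError(
                f"covariance matrix is not positive semi-definite "
                f"(min eigenvalue {evals.min():.3e})"
            )
        factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
        object.__setattr__(self, "_cov_factor", factor)

    # -- basis ---------------------------------------------------------------
    @property
    def n_basis(self) -> int:
        return len(self.knots) - SPLINE_DEGREE - 1

    def _bmat(self, x: np.ndarray, deriv: int = 0) -> np.ndarray:
        b = BSpline(self.knots, np.eye(self.n_basis), SPLINE_DEGREE, extrapolate=True)
        if deriv:
            b = b.derivative(deriv)
        return b(np.asarray(x, dtype=float))

    def _sex_code(self, sex) -> np.ndarray:
        codes = {s: float(k) for k, s in enumerate(self.sexes)}
        if isinstance(sex, str):
            return np.asarray(codes[sex])
        return np.asarray([codes[s] for s in sex])

    def design_row(self, a, t, sex, age_deriv: int = 0, year_deriv: int = 0):
        """Tensor design rows; ``year_deriv=1`` differentiates the linear
        year factor (so d/dt of the u-free columns is 0)."""
        a = np.atleast_1d(np.asarray(a, dtype=float))
        t = np.atleast_1d(np.asarray(t, dtype=float))
        s = np.atleast_1d(self._sex_code(sex))
        a, t, s = np.broadcast_arrays(a, t, s)
        B = self._bmat(a, deriv=age_deriv)
        u = t - self.year_center
        if year_deriv == 0:
            f1, fu = np.ones_like(u), u
        elif year_deriv == 1:
            f1, fu = np.zeros_like(u), np.ones_like(u)
        else:
            raise ValueError("year_deriv must be 0 or 1")
        # column order per basis fn j: [1, u, s, u*s]
        fac = np.stack([f1, fu, f1 * s, fu * s], axis=-1)  # (n, 4)
        return (B[:, :, None] * fac[:, None, :]).reshape(len(a), -1)

    # -- evaluation ----------------------------------------------------------
    def linear_predictor(self, a, t, sex):
        return self.design_row(a, t, sex) @ self.coef

    def predict(self, a, t, sex):
        """Prevalence strictly inside (0, 1) at (age, year, sex)."""
        return expit(np.clip(self.linear_predictor(a, t, sex), -ETA_MAX, ETA_MAX))

    def directional_derivative(self, a, t, sex, method: str = "analytic",
                               h: float = FD_STEP):
        """Cohort derivative (d/da + d/dt) p, per year.

        ``analytic`` uses p(1-p) * (d eta/da + d eta/dt) with the exact
        B-spline derivative; ``finite_difference`` is a central difference
        of p along the cohort diagonal (a +/- h, t +/- h).
        """
        if method == "analytic":
            p = self.predict(a, t, sex)
            deta = (
                self.design_row(a, t, sex, age_deriv=1)
                + self.design_row(a, t, sex, year_deriv=1)
            ) @ self.coef
            return p * (1.0 - p) * deta
        if method == "finite_difference":
            a = np.atleast_1d(np.asarray(a, dtype=float))
            t = np.atleast_1d(np.asarray(t, dtype=float))
            return (
                self.predict(a + h, t + h, sex) - self.predict(a - h, t - h, sex)
            ) / (2.0 * h)
        raise ValueError(f"unknown derivative method {method!r}")

    # -- resampling ----------------------------------------------------------
    def sample(self, rng: np.random.Generator) -> "PrevalenceSurface":
        """One multivariate-normal coefficient draw around the estimate."""
        draw = self.coef + self._cov_factor @ rng.standard_normal(len(self.coef))
        return self.with_coef(draw)

    def with_coef(self, coef: np.ndarray) -> "PrevalenceSurface":
        return PrevalenceSurface(
            coef=np.asarray(coef, dtype=float), cov=np.zeros_like(self.cov),
            knots=self.knots, year_center=self.year_center,
            age_range=self.age_range, year_range=self.year_range,
            sexes=self.sexes,
        )

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "knots": self.knots.tolist(),
            "degree": SPLINE_DEGREE,
            "year_center": self.year_center,
            "age_range": list(self.age_range),
            "year_range": list(self.year_range),
            "sexes": list(self.sexes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrevalenceSurface":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            knots=np.asarray(d["knots"], dtype=float),
            year_center=float(d["year_center"]),
            age_range=tuple(d["age_range"]),
            year_range=tuple(d["year_range"]),
            sexes=tuple(d["sexes"]),
        )


def pool_waves(
    wave_fits: Sequence[WaveFit],
    age_range: tuple[float, float] = (20.0, 79.0),
    precision_weighted: bool = False,
    cov_mode: str = "propagate",
) -> PrevalenceSurface:
    """Pool per-wave logit prevalences into one smooth surface.

    Ordinary least squares of the stacked stage-1 logit values (every
    integer age, sex and wave) on the tensor design; optionally weighted
    by each wave/sex effective sample size (``precision_weighted``).
    Raises on a rank-deficient design, listing the aliased columns.

    ``cov_mode`` selects the coefficient covariance used for resampling:

    * ``"propagate"`` (default): exact delta-method propagation of the
      stage-1 logistic-regression covariances through the stage-2 linear
      map, ``Cov = A blockdiag(Cov_k) A'`` with ``A = (X'X)^{-1} X'`` —
      i.e. the sampling distribution of the input prevalence itself.
    * ``"ols"``: the stage-2 OLS covariance conditional on the stage-1
      point estimates (reflects only smoothing-residual scatter).
    """
    if len(wave_fits) < 2:
        raise ValueError(
            "at least two survey waves are required to identify the year trend"
        )
    years = [wf.survey_year for wf in wave_fits]
    if len(set(years)) != len(years):
        raise ValueError(f"duplicate wave years: {sorted(years)}")
    sexes = tuple(wave_fits[0].logit_prev.keys())
    year_center = float(np.mean(years))
    knots = _stage2_knot_vector(age_range)

    surface = PrevalenceSurface(
        coef=np.zeros(4 * (len(knots) - SPLINE_DEGREE - 1)),
        cov=np.zeros((4 * (len(knots) - SPLINE_DEGREE - 1),) * 2),
        knots=knots, year_center=year_center, age_range=age_range,
        year_range=(float(min(years)), float(max(years))), sexes=sexes,
    )

    rows, yvals, wts, blocks = [], [], [], []
    for wf in wave_fits:
        x = wf.ages + AGE_OFFSET
        for sex in sexes:
            rows.append(surface.design_row(x, np.full(len(x), wf.survey_year), sex))
            yvals.append(np.asarray(wf.logit_prev[sex], dtype=float))
            wts.append(np.full(len(x), wf.n_effective[sex]))
            blocks.append(np.asarray(wf.logit_cov[sex], dtype=float))
    X = np.vstack(rows)
    yv = np.concatenate(yvals)
    if precision_weighted:
        sw = np.sqrt(np.concatenate(wts))
        X, yv = X * sw[:, None], yv * sw
        blocks = [
            b * s[:, None] * s[None, :]
            for b, s in zip(blocks, np.split(sw, np.cumsum([len(v) for v in yvals])[:-1]))
        ]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        aliased = np.where(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())[0]
        raise ValueError(f"rank-deficient pooled design; aliased columns: {aliased.tolist()}")

    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    xtx_inv = np.linalg.inv(X.T @ X)
    if cov_mode == "propagate":
        # Wave/sex stage-1 fits are independent: block-diagonal input
        # covariance pushed through the projector A = (X'X)^{-1} X'.
        A = xtx_inv @ X.T
        cov = np.zeros((X.shape[1], X.shape[1]))
        start = 0
        for blk in blocks:
            stop = start + blk.shape[0]
            Ab = A[:, start:stop]
            cov += Ab @ blk @ Ab.T
            start = stop
        cov = (cov + cov.T) / 2.0
    elif cov_mode == "ols":
        resid = yv - X @ coef
        dof = max(X.shape[0] - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * xtx_inv
    else:
        raise ValueError(f"unknown cov_mode {cov_mode!r}")

    return PrevalenceSurface(
        coef=coef, cov=cov, knots=knots, year_center=year_center,
        age_range=age_range,
        year_range=(float(min(years)), float(max(years))), sexes=sexes,
    )


def directional_derivative(surface: PrevalenceSurface, a, t, sex,
                           method: str = "analytic"):
    """Cohort derivative (d/da + d/dt) p of a fitted surface."""
    return surface.directional_derivative(a, t, sex, method=method)


def sample_surface(surface: PrevalenceSurface, seed) -> PrevalenceSurface:
    """One coefficient draw from the surface's sampling distribution;
    ``seed`` may be an int or a Generator."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return surface.sample(rng)
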