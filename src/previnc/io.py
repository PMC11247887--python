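"""File formats and configuration.

CSV dialects (all comma-separated, UTF-8, '.' decimal point):

* survey:   header ``id,age,sex,survey_year,disease,weight``
* mortality: header ``year,sex,age,rate`` (rate per person-year)
* standard population: header ``age_lo,age_hi,weight``

Plus JSON serialization of the fitted prevalence surface and the run
metadata.  Readers validate and report the offending file and row; no
malformed value is silently coerced.  Age in files is integer completed
years, interpreted as the interval [age, age+1) and evaluated at
age + 0.5 by the models.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import IncidenceResult, StandardPopulation, report_table
from .smoothing import PrevalenceSurface
from .synthetic import SEXES, SURVEY_COLUMNS, MortalitySchedule

__all__ = [
    "read_survey",
    "write_survey",
    "read_mortality",
    "write_mortality",
    "read_standard",
    "write_standard",
    "read_surface",
    "write_surface",
    "write_results",
    "load_config",
    "default_config",
]


def _err(path, row, msg):
    where = f"{path}" + (f", data row {row}" if row is not None else "")
    return ValueError(f"{where}: {msg}")


# ---------------------------------------------------------------------------
# Survey CSV
# ---------------------------------------------------------------------------

def write_survey(records: pd.DataFrame, path) -> None:
    records = records[SURVEY_COLUMNS]
    records.to_csv(path, index=False)


def read_survey(path, permissive: bool = False) -> pd.DataFrame:
    """Read and validate a survey CSV; row numbers are 1-based data rows."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise _err(path, None, f"missing column(s) {missing}")
    extra = [c for c in df.columns if c not in SURVEY_COLUMNS]
    if extra and not permissive:
        raise _err(path, None, f"unknown column(s) {extra} (use permissive=True)")
    df = df[SURVEY_COLUMNS]
    if len(df) == 0:
        raise _err(path, None, "no records")

    bad = ~df["sex"].isin(SEXES)
    if bad.any():
        raise _err(path, int(bad.idxmax()) + 1, f"sex must be one of {SEXES}")
    bad = ~df["disease"].isin([0, 1])
    if bad.any():
        raise _err(path, int(bad.idxmax()) + 1, "disease must be 0 or 1")
    bad = ~(df["weight"] > 0)
    if bad.any():
        raise _err(path, int(bad.idxmax()) + 1, "weight must be positive")
    if not np.array_equal(df["age"], df["age"].astype(int)):
        bad = df["age"] != df["age"].astype(int)
        raise _err(path, int(bad.idxmax()) + 1, "age must be integer years")
    df["age"] = df["age"].astype(int)
    df["survey_year"] = df["survey_year"].astype(int)
    df["disease"] = df["disease"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Mortality CSV
# ---------------------------------------------------------------------------

def write_mortality(schedule: MortalitySchedule, path) -> None:
    rows = []
    for sex in schedule.rates:
        for ia, a in enumerate(schedule.ages):
            for iy, y in enumerate(schedule.years):
                rows.append({"year": y, "sex": sex, "age": a,
                             "rate": schedule.rates[sex][ia, iy]})
    pd.DataFrame(rows)[["year", "sex", "age", "rate"]].to_csv(path, index=False)


def read_mortality(path) -> MortalitySchedule:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    need = ["year", "sex", "age", "rate"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise _err(path, None, f"missing column(s) {missing}")
    dup = df.duplicated(subset=["year", "sex", "age"])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise _err(path, int(dup.idxmax()) + 1,
                   f"duplicate (year={r['year']}, sex={r['sex']}, age={r['age']})")
    if (df["rate"] < 0).any():
        bad = df["rate"] < 0
        raise _err(path, int(bad.idxmax()) + 1, "rate must be >= 0")
    ages = np.sort(df["age"].unique()).astype(float)
    years = np.sort(df["year"].unique()).astype(float)
    rates = {}
    for sex, sub in df.groupby("sex"):
        grid = sub.pivot(index="age", columns="year", values="rate")
        if grid.isna().any().any() or grid.shape != (len(ages), len(years)):
            raise _err(path, None, f"incomplete (age, year) grid for sex {sex!r}")
        rates[str(sex)] = grid.sort_index().to_numpy(dtype=float)
    return MortalitySchedule(ages=ages, years=years, rates=rates)


# ---------------------------------------------------------------------------
# Standard population CSV
# ---------------------------------------------------------------------------

def write_standard(std: StandardPopulation, path) -> None:
    pd.DataFrame(
        {
            "age_lo": [g[0] for g in std.groups],
            "age_hi": [g[1] for g in std.groups],
            "weight": std.weights,
        }
    ).to_csv(path, index=False)


def read_standard(path) -> StandardPopulation:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    need = ["age_lo", "age_hi", "weight"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise _err(path, None, f"missing column(s) {missing}")
    groups = tuple((int(lo), int(hi)) for lo, hi in zip(df["age_lo"], df["age_hi"]))
    try:
        return StandardPopulation(groups=groups, weights=df["weight"].to_numpy(float))
    except ValueError as exc:
        raise _err(path, None, str(exc))


# ---------------------------------------------------------------------------
# Surface JSON
# ---------------------------------------------------------------------------

def write_surface(surface: PrevalenceSurface, path) -> None:
    Path(path).write_text(json.dumps(surface.to_dict(), indent=1))


def read_surface(path) -> PrevalenceSurface:
    return PrevalenceSurface.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(result: IncidenceResult, out_dir, config: dict | None = None) -> dict:
    """Write the report CSV, the per-age incidence CSV and run metadata;
    returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = report_table(result)
    table_path = out_dir / "incidence_table.csv"
    table.to_csv(table_path, index=False)

    rows = []
    have = result.rep_curve is not None
    for si, sex in enumerate(result.sexes):
        for yi, year in enumerate(result.years):
            band = result.curve_band(sex, year) if have else None
            for ai, a in enumerate(result.ages):
                rows.append(
                    {
                        "sex": sex, "year": year, "age": a,
                        "incidence_per_1000": result.plugin_curve[si, yi, ai] * 1000.0,
                        "lo_per_1000": band[0, ai] * 1000.0 if have else np.nan,
                        "median_per_1000": band[1, ai] * 1000.0 if have else np.nan,
                        "hi_per_1000": band[2, ai] * 1000.0 if have else np.nan,
                        "negative_flag": bool(result.plugin_curve[si, yi, ai] < 0),
                    }
                )
    curve_path = out_dir / "incidence_by_age.csv"
    pd.DataFrame(rows).to_csv(curve_path, index=False)

    import previnc

    meta = {
        "seed": result.seed,
        "repetitions": result.n_replicates,
        "config": config or {},
        "previnc_version": previnc.__version__,
        "numpy_version": np.__version__,
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, default=str))
    return {"table": table_path, "curve": curve_path, "metadata": meta_path}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Packaged defaults (flat YAML key-value file)."""
    text = (
        importlib.resources.files("previnc") / "default_config.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_config(path=None) -> dict:
    """Defaults overridden by the user's flat YAML file, if given."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = [k for k in user if k not in cfg]
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {unknown}")
        cfg.update(user)
    return cfg
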