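"""CSV/JSON schemas, run configuration and reproducibility manifest.

All artifacts are plain UTF-8 CSV with a header row, or JSON.  Readers
validate schemas row by row and reject malformed rows with the offending
field and 1-based file line number (header = line 1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import MARGINAL_COLUMNS
from .rates import RATE_COLUMNS, EVENTS, VitalRates
from .records import (
    HH_TYPES,
    HOUSEHOLD_COLUMNS,
    PERSON_COLUMNS,
    ROLES,
    SEXES,
    Population,
)

INTERVAL_COLUMNS = ["area_id", "characteristic", "point", "lower", "upper", "B", "level"]
REPORT_COLUMNS = ["area_id", "characteristic", "actual", "estimate", "rb"]


class SchemaError(ValueError):
    """A file does not conform to its schema."""

    def __init__(self, path, message: str, line: int | None = None) -> None:
        where = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}: {message}")
        self.path, self.line = path, line


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(path, "file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise SchemaError(path, f"expected columns {columns}, found {list(df.columns)}")
    return df


def _fail(path, idx: int, message: str):
    raise SchemaError(path, message, line=idx + 2)  # +1 header, +1 one-based


def _require_int(df, col, path, minimum=None):
    out = np.empty(len(df), dtype=np.int64)
    for idx, val in enumerate(df[col]):
        try:
            out[idx] = int(val)
        except ValueError:
            _fail(path, idx, f"field {col!r}: {val!r} is not an integer")
        if minimum is not None and out[idx] < minimum:
            _fail(path, idx, f"field {col!r}: {out[idx]} below {minimum}")
    return out


def _require_in(df, col, path, allowed):
    for idx, val in enumerate(df[col]):
        if val not in allowed:
            _fail(path, idx, f"field {col!r}: unknown value {val!r}")


# -- persons / households ----------------------------------------------------

def read_persons(path) -> pd.DataFrame:
    df = _read_csv(path, PERSON_COLUMNS)
    ages = _require_int(df, "age", path, minimum=0)
    _require_in(df, "sex", path, SEXES)
    _require_in(df, "role", path, ROLES)
    out = df.copy()
    out["age"] = ages
    return out


def write_persons(persons: pd.DataFrame, path) -> None:
    persons[PERSON_COLUMNS].to_csv(path, index=False)


def read_households(path) -> pd.DataFrame:
    df = _read_csv(path, HOUSEHOLD_COLUMNS)
    _require_in(df, "hh_type", path, HH_TYPES)
    return df


def write_households(households: pd.DataFrame, path) -> None:
    households[HOUSEHOLD_COLUMNS].to_csv(path, index=False)


def read_population(persons_path, households_path) -> Population:
    pop = Population(read_persons(persons_path), read_households(households_path))
    pop.validate()
    return pop


def write_population(pop: Population, persons_path, households_path) -> None:
    write_persons(pop.persons, persons_path)
    write_households(pop.households, households_path)


# -- marginals ----------------------------------------------------------------

def read_marginals(path) -> pd.DataFrame:
    df = _read_csv(path, MARGINAL_COLUMNS)
    counts = _require_int(df, "count", path, minimum=0)
    _require_in(df, "variable", path, ("age_sex", "hh_type"))
    for idx, (var, cat) in enumerate(zip(df["variable"], df["category"])):
        if var == "hh_type" and cat not in HH_TYPES:
            _fail(path, idx, f"field 'category': unknown hh_type {cat!r}")
        if var == "age_sex" and (":" not in cat or cat.split(":", 1)[0] not in SEXES):
            _fail(path, idx, f"field 'category': malformed age_sex cell {cat!r}")
    out = df.copy()
    out["count"] = counts
    out["perturbed"] = out["perturbed"].map({"True": True, "False": False})
    if out["perturbed"].isna().any():
        idx = int(out["perturbed"].isna().idxmax())
        _fail(path, idx, "field 'perturbed': must be True or False")
    return out


def write_marginals(marginals: pd.DataFrame, path) -> None:
    marginals[MARGINAL_COLUMNS].to_csv(path, index=False)


# -- rates --------------------------------------------------------------------

def read_rates(path, w: int = 100, rate_scale: dict | None = None) -> VitalRates:
    df = _read_csv(path, RATE_COLUMNS)
    _require_in(df, "event", path, EVENTS)
    for idx, val in enumerate(df["rate"]):
        try:
            if float(val) < 0:
                _fail(path, idx, f"field 'rate': negative rate {val!r}")
        except ValueError:
            _fail(path, idx, f"field 'rate': {val!r} is not a number")
    out = df.copy()
    out["rate"] = out["rate"].astype(float)
    out["per"] = out["per"].astype(float)
    return VitalRates(out, w=w, rate_scale=rate_scale or {})


def write_rates(rates: VitalRates, path) -> None:
    rates.table[RATE_COLUMNS].to_csv(path, index=False)


# -- intervals / report / summary ---------------------------------------------

def read_intervals(path) -> pd.DataFrame:
    df = _read_csv(path, INTERVAL_COLUMNS)
    out = df.copy()
    for col in ("point", "lower", "upper", "level"):
        out[col] = out[col].astype(float)
    out["B"] = _require_int(df, "B", path, minimum=2)
    return out


def write_intervals(intervals: pd.DataFrame, path) -> None:
    intervals[INTERVAL_COLUMNS].to_csv(path, index=False)


def write_report(cells: pd.DataFrame, path) -> None:
    cells[REPORT_COLUMNS].round(6).to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    df = _read_csv(path, REPORT_COLUMNS)
    out = df.copy()
    for col in ("actual", "estimate", "rb"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# -- run configuration and manifest -------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see the ``run`` CLI subcommand)."""

    outdir: str
    seed: int = 0
    years: int = 5
    mode: str = "micro"
    b: int = 200
    level: float = 0.95
    n_periods: int = 1
    w: int = 100
    rate_scale: dict = dc_field(default_factory=dict)
    age_band_size: int = 20
    # fixture generation (used when no external inputs are given)
    n_areas: int = 3
    persons_per_area: int = 100
    sampling_fraction: float = 0.5
    perturbation: int = 0
    # optional external inputs
    rates_path: str | None = None
    search: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.mode not in ("deterministic", "micro"):
            raise ValueError("mode must be 'deterministic' or 'micro'")


def load_config(path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(**raw)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, config: RunConfig, stage_seeds: dict, artifacts: list[str]) -> Path:
    import dynapop

    manifest = {
        "package_version": getattr(dynapop, "__version__", "unknown"),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {k: v for k, v in config.__dict__.items()},
        "stage_seeds": stage_seeds,
        "artifacts": {a: sha256_of(Path(outdir) / a) for a in artifacts},
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
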