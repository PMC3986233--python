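"""Bootstrap prediction intervals for evolved population characteristics.

The whole micro-simulation is replicated from resampled baselines: each
bootstrap replicate draws households with replacement from the optimised
baseline population (resampling whole households keeps the two-fold
nesting intact), evolves the replicate forward, and records the
area-level characteristics of interest.  Percentile intervals are formed
from order statistics of the B replicate predictions; the bootstrap
standard error is the replicate standard deviation.

Per-replicate RNG streams are spawned from the root seed with
``numpy.random.SeedSequence(seed).spawn(B)``, so increasing B extends the
replicate set without perturbing earlier replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import MicroState, Trajectory, evolve
from .rates import VitalRates
from .records import Population

DEFAULT_B = 1000
DEFAULT_AGE_BANDS = tuple((lo, lo + 20) for lo in range(0, 100, 20))


class EmpiricalCDF:
    """Right-continuous empirical distribution F(x) = #{x_i <= x} / n."""

    def __init__(self, sample) -> None:
        arr = np.asarray(sample, dtype=float)
        if arr.size == 0:
            raise ValueError("empty sample has no empirical distribution")
        self.points = np.sort(arr)

    def __call__(self, x) -> np.ndarray | float:
        out = np.searchsorted(self.points, np.asarray(x, dtype=float), side="right") / len(self.points)
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def ecdf(sample) -> EmpiricalCDF:
    return EmpiricalCDF(sample)


def bootstrap_se(replicates) -> float:
    """Replicate standard deviation with the mean-of-replicates centring."""
    arr = np.asarray(replicates, dtype=float)
    if arr.size < 2:
        raise ValueError("bootstrap SE needs at least two replicates")
    return float(math.sqrt(np.sum((arr - arr.mean()) ** 2) / (arr.size - 1)))


def percentile_interval(replicates, level: float = 0.95) -> tuple[float, float]:
    """Order-statistic percentile interval.

    lower = ceil(B * alpha/2)-th and upper = ceil(B * (1 - alpha/2))-th
    order statistics (1-indexed), alpha = 1 - level; both endpoints are
    elements of the replicate set.
    """
    arr = np.sort(np.asarray(replicates, dtype=float))
    b = arr.size
    if b < 2:
        raise ValueError("interval needs at least two replicates")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    eps = 1e-9  # guard against float slop in b * alpha / 2 at exact ranks
    lo_rank = max(1, math.ceil(b * alpha / 2.0 - eps))
    hi_rank = min(b, math.ceil(b * (1.0 - alpha / 2.0) - eps))
    return float(arr[lo_rank - 1]), float(arr[hi_rank - 1])


@dataclass
class BootstrapResult:
    characteristic: str
    point: float
    replicates: np.ndarray
    se: float
    lower: float
    upper: float
    level: float
    b: int


def characteristics_of(state, age_bands=DEFAULT_AGE_BANDS) -> dict[str, float]:
    """SA-level characteristics: totals by sex x age band and by hh type."""
    from .dynamics import PopulationState

    out: dict[str, float] = {}
    if isinstance(state, PopulationState):
        out["persons_total"] = state.total()
        for lo, hi in age_bands:
            out[f"F:{lo}-{hi - 1}"] = float(state.pf[lo:hi].sum())
            out[f"M:{lo}-{hi - 1}"] = float(state.pm[lo:hi].sum())
        return out
    micro: MicroState = state
    out["persons_total"] = float(micro.n_persons)
    out["households_total"] = float(micro.n_households)
    for lo, hi in age_bands:
        in_band = (micro.age >= lo) & (micro.age < hi)
        out[f"F:{lo}-{hi - 1}"] = float(np.sum(in_band & (micro.sex == 0)))
        out[f"M:{lo}-{hi - 1}"] = float(np.sum(in_band & (micro.sex == 1)))
    for t, c in micro.hh_type_counts().items():
        out[f"hh:{t}"] = float(c)
    return out


def resample_households(micro: MicroState, rng: np.random.Generator) -> MicroState:
    """Draw households with replacement up to the original household count."""
    m = micro.n_households
    chosen = rng.integers(0, m, size=m)
    arrays = {k: [] for k in ("age", "sex", "role", "marital", "partner", "hh")}
    types, areas = [], []
    next_person = 0
    for new_h, h in enumerate(chosen):
        members = np.flatnonzero(micro.hh == h)
        remap = {int(p): next_person + k for k, p in enumerate(members)}
        arrays["age"].append(micro.age[members])
        arrays["sex"].append(micro.sex[members])
        arrays["role"].append(micro.role[members])
        arrays["marital"].append(micro.marital[members])
        arrays["partner"].append(
            np.array([remap.get(int(p), -1) if p >= 0 else -1 for p in micro.partner[members]], np.int64)
        )
        arrays["hh"].append(np.full(len(members), new_h, np.int64))
        types.append(micro.hh_type[h])
        areas.append(micro.hh_area[h])
        next_person += len(members)
    return MicroState(
        np.concatenate(arrays["age"]),
        np.concatenate(arrays["sex"]),
        np.concatenate(arrays["role"]),
        np.concatenate(arrays["marital"]),
        np.concatenate(arrays["partner"]),
        np.concatenate(arrays["hh"]),
        np.array(types, dtype=object),
        np.array(areas, dtype=object),
        micro.w,
        micro.t,
    )


def bootstrap_predict(
    baseline,
    rates: VitalRates,
    years: int,
    b: int = DEFAULT_B,
    seed: int = 0,
    level: float = 0.95,
    mode: str = "micro",
    age_bands=DEFAULT_AGE_BANDS,
    immigrant_households_per_year: int = 0,
) -> dict[str, BootstrapResult]:
    """B replicate evolutions from household-resampled baselines.

    The point prediction evolves the original baseline.  By default the
    resampled baselines re-run the evolution only; re-running the baseline
    synthesis inside each replicate is a caller decision (resample an
    upstream pool and call this per replicate).
    """
    if b < 2:
        raise ValueError("B must be >= 2")
    if isinstance(baseline, Population):
        baseline = MicroState.from_population(baseline, w=rates.w)
    if baseline.n_households == 0:
        raise ValueError("cannot bootstrap an empty baseline population")
    root = np.random.SeedSequence(seed)
    point_stream, resample_stream = root.spawn(2)
    replicate_streams = resample_stream.spawn(b)

    def predict(micro: MicroState, stream) -> dict[str, float]:
        traj: Trajectory = evolve(
            micro,
            rates,
            years,
            mode=mode,
            seed=int(stream.generate_state(1)[0] % (2**31)),
            immigrant_households_per_year=immigrant_households_per_year,
        )
        return characteristics_of(traj.states[-1], age_bands)

    point = predict(baseline, point_stream)
    rows: dict[str, list[float]] = {k: [] for k in point}
    for stream in replicate_streams:
        draw_stream, evolve_stream = stream.spawn(2)
        rng = np.random.default_rng(draw_stream)
        rep = predict(resample_households(baseline, rng), evolve_stream)
        for k in rows:
            rows[k].append(rep.get(k, 0.0))

    out: dict[str, BootstrapResult] = {}
    for k, reps in rows.items():
        arr = np.asarray(reps, dtype=float)
        lo, hi = percentile_interval(arr, level)
        out[k] = BootstrapResult(k, point[k], arr, bootstrap_se(arr), lo, hi, level, b)
    return out


def intervals_frame(results: dict[str, BootstrapResult], area_id: str = "ALL") -> pd.DataFrame:
    rows = [
        (area_id, k, r.point, r.lower, r.upper, r.b, r.level)
        for k, r in results.items()
    ]
    return pd.DataFrame(
        rows, columns=["area_id", "characteristic", "point", "lower", "upper", "B", "level"]
    )
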