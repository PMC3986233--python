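"""Baseline population synthesis by combinatorial optimisation.

An area population is assembled as a multiset of households drawn from a
seed microdata pool.  The candidate sample X is scored against the area's
marginal tables with the quadratic fitness

    F(X) = sum_k (theta_k(X) - E[theta_k])^2 / Var(theta_k),

one estimator theta_k per marginal cell: person counts per (sex, age band)
and household counts per household type, so the two-fold nesting is
enforced — individual-level cells are always recomputed from household
members.  The search swaps whole households (a random selected slot against
a random pool household), accepting strictly improving swaps; simulated
annealing (Metropolis acceptance with geometric cooling) and random
restarts are available to escape local optima, and the pool can be widened
with households from a larger surrounding area when the local pool is too
small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import Population
from .rates import parse_band

__all__ = [
    "FitnessSpec",
    "SearchOptions",
    "SynthesisResult",
    "fitness",
    "build_spec",
    "reconcile_marginals",
    "household_contributions",
    "synthesize_area",
    "synthesize_region",
]

#: fallback mean household sizes when no seed pool is available
CANONICAL_HH_SIZES = {
    "couple_only": 2.0,
    "couple_with_children": 3.8,
    "lone_person": 1.0,
    "one_parent": 2.8,
    "other_family": 2.5,
}

#: variance floor: keeps zero-variance cells from dominating the fitness
V_MIN = 0.5


@dataclass
class FitnessSpec:
    """Estimator cells, their target counts and variances for one area."""

    cells: list[tuple[str, str]]  # (variable, category)
    targets: np.ndarray
    variances: np.ndarray
    age_bands: list[tuple[int, int]]
    area_id: str = ""

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if len(self.cells) < 1:
            raise ValueError("at least one estimator cell required")
        if not (len(self.cells) == len(self.targets) == len(self.variances)):
            raise ValueError("cells, targets and variances must align")
        if (self.variances <= 0).any():
            raise ValueError("all estimator variances must be positive")

    @property
    def k(self) -> int:
        return len(self.cells)

    @property
    def target_households(self) -> int:
        idx = [i for i, (v, _) in enumerate(self.cells) if v == "hh_type"]
        return int(round(self.targets[idx].sum()))


@dataclass
class SearchOptions:
    max_iterations: int = 20000
    patience: int = 500
    n_restarts: int = 5
    anneal: bool = False
    initial_temperature: float = 1.0
    cooling: float = 0.995
    epsilon: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.anneal and self.initial_temperature <= 0:
            raise ValueError("annealing requires a positive temperature")


@dataclass
class SynthesisResult:
    population: Population
    fitness: float
    trace: pd.DataFrame  # iteration, restart, fitness, accepted
    converged: bool
    warning: str | None = None


class InfeasibleAreaError(RuntimeError):
    """The pool cannot supply the requested number of households."""


def fitness(sample, spec: FitnessSpec) -> float:
    """Quadratic goodness-of-fit of a candidate sample against targets.

    ``sample`` is either a :class:`Population` (cell counts are tallied
    from it) or a precomputed vector of estimator values theta_k.
    """
    if isinstance(sample, Population):
        theta = household_contributions(sample, spec).sum(axis=0)
    else:
        theta = np.asarray(sample, dtype=float)
    dev = theta - spec.targets
    return float(np.sum(dev * dev / spec.variances))


def household_contributions(pool: Population, spec: FitnessSpec) -> np.ndarray:
    """Per-household integer contribution vectors to every estimator cell.

    Row h gives, for each cell, the count that household h adds to a sample
    containing it: member tallies for (sex, age band) cells and a one-hot
    for its household type.
    """
    hh_ids = pool.households["household_id"].to_numpy()
    hh_index = {h: i for i, h in enumerate(hh_ids)}
    v = np.zeros((len(hh_ids), spec.k), dtype=np.int64)
    cell_index = {cell: k for k, cell in enumerate(spec.cells)}

    for t, hid in zip(pool.households["hh_type"].to_numpy(), hh_ids):
        key = ("hh_type", t)
        if key in cell_index:
            v[hh_index[hid], cell_index[key]] += 1
    ages = pool.persons["age"].to_numpy()
    sexes = pool.persons["sex"].to_numpy()
    owners = pool.persons["household_id"].to_numpy()
    band_of = _band_lookup(spec.age_bands)
    for age, sex, hid in zip(ages, sexes, owners):
        band = band_of(int(age))
        if band is None:
            continue
        key = ("age_sex", f"{sex}:{band[0]}-{band[1] - 1}")
        if key in cell_index:
            v[hh_index[hid], cell_index[key]] += 1
    return v


def _band_lookup(age_bands):
    bands = sorted(age_bands)

    def lookup(age: int):
        for lo, hi in bands:
            if lo <= age < hi:
                return (lo, hi)
        return None

    return lookup


def reconcile_marginals(
    tables: pd.DataFrame,
    persons_per_hh_type: dict | None = None,
) -> pd.DataFrame:
    """Adjust one area's marginal tables onto a consensus person total.

    Released census tables are independently perturbed, so the person total
    implied by the age x sex table need not agree with the person total
    implied by the household-type table (household counts times mean
    persons per household of that type).  The consensus total T is the mean
    of the two implied totals, rounded half-to-even; the age x sex cells
    are re-apportioned to sum to T by largest-remainder rounding, which
    changes cells in one direction only and therefore minimises the total
    absolute adjustment.  Household counts are left untouched.
    """
    if (tables["count"] < 0).any():
        raise ValueError("negative marginal count")
    if tables["count"].sum() == 0:
        raise ValueError("all-zero marginal tables cannot be reconciled")
    age_sex = tables[tables["variable"] == "age_sex"]
    hh = tables[tables["variable"] == "hh_type"]
    if age_sex.empty or hh.empty or persons_per_hh_type is None:
        return tables.copy()
    s_person = age_sex["count"].sum()
    s_implied = sum(
        persons_per_hh_type.get(t, CANONICAL_HH_SIZES[t]) * c
        for t, c in zip(hh["category"], hh["count"])
    )
    if s_person == 0:
        return tables.copy()
    # round half to even, as numpy does
    t_consensus = int(np.round((s_person + s_implied) / 2.0))
    if t_consensus == s_person:
        return tables.copy()
    new_counts = _apportion(age_sex["count"].to_numpy(), t_consensus)
    out = tables.copy()
    out.loc[age_sex.index, "count"] = new_counts
    return out


def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    quota = counts / counts.sum() * total
    out = np.floor(quota).astype(int)
    short = total - out.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    out[order[:short]] += 1
    return out


def build_spec(
    marginals: pd.DataFrame,
    seed_pool: Population,
    area_id: str,
    reconcile: bool | str = "auto",
) -> FitnessSpec:
    """Fitness specification for one area from its marginal tables.

    Targets are the (optionally reconciled) marginal counts.  With the
    default ``reconcile="auto"`` the tables are reconciled only when at
    least one of them is flagged perturbed — exact cross-tabulations are
    already consistent and are used verbatim.  Variances are estimated
    from the seed pool under simple random sampling of M households:
    Var(theta_k) ~= M * s2_k where s2_k is the pool variance of the
    per-household contribution to cell k, floored at 0.5.
    """
    area_tables = marginals[marginals["area_id"] == area_id]
    if area_tables.empty:
        raise KeyError(f"area {area_id!r} absent from marginal tables")
    if reconcile == "auto":
        reconcile = bool(area_tables["perturbed"].any()) if "perturbed" in area_tables else False
    if reconcile:
        sizes = (
            seed_pool.persons.groupby(seed_pool.persons["household_id"]).size()
            .rename("size")
            .to_frame()
            .join(seed_pool.households.set_index("household_id")["hh_type"])
            .groupby("hh_type")["size"]
            .mean()
            .to_dict()
        )
        area_tables = reconcile_marginals(area_tables, persons_per_hh_type=sizes)

    cells = [(v, c) for v, c in zip(area_tables["variable"], area_tables["category"])]
    targets = area_tables["count"].to_numpy(dtype=float)
    age_bands = sorted(
        {parse_band(c.split(":", 1)[1] , _infer_w(area_tables)) for v, c in cells if v == "age_sex"}
    )
    spec = FitnessSpec(cells, targets, np.ones(len(cells)), age_bands or [(0, 100)], area_id)

    m = spec.target_households or 1
    v = household_contributions(seed_pool, spec)
    s2 = v.var(axis=0, ddof=0) if len(v) > 1 else np.zeros(spec.k)
    spec.variances = np.maximum(m * s2, V_MIN)
    return spec


def _infer_w(tables: pd.DataFrame) -> int:
    top = 0
    for v, c in zip(tables["variable"], tables["category"]):
        if v != "age_sex":
            continue
        band = c.split(":", 1)[1]
        if band.endswith("+"):
            return max(top, int(band[:-1]) + 35)
        top = max(top, int(band.split("-")[1]) + 1)
    return top or 100


def synthesize_area(
    seed_pool: Population,
    spec: FitnessSpec,
    target_m: int,
    options: SearchOptions,
    wider_pool: Population | None = None,
) -> SynthesisResult:
    """Hill-climbing / annealing search for an area's household multiset.

    Households may be replicated across draws (a 1% pool is far smaller
    than the area it represents); selected households are cloned with fresh
    ids in the returned population.  The trace records fitness at every
    accepted move and is non-increasing within a restart in pure
    hill-climbing mode (equal-fitness swaps are rejected).
    """
    pool = seed_pool
    if wider_pool is not None and wider_pool.n_households > 0:
        pool = Population(
            pd.concat([seed_pool.persons, wider_pool.persons], ignore_index=True),
            pd.concat([seed_pool.households, wider_pool.households], ignore_index=True),
        )
    n = pool.n_households
    if n == 0:
        raise InfeasibleAreaError("empty seed pool")
    if target_m > n:
        raise InfeasibleAreaError(
            f"pool of {n} households cannot seed {target_m} households"
            + ("" if wider_pool is not None else "; supply a wider pool")
        )

    v = household_contributions(pool, spec)
    rng = np.random.default_rng(options.seed)
    inv_var = 1.0 / spec.variances
    targets = spec.targets

    best_idx: np.ndarray | None = None
    best_f = math.inf
    trace_rows: list[tuple] = []
    iterations_used = 0
    converged = False

    for restart in range(max(1, options.n_restarts)):
        idx = rng.integers(0, n, size=target_m)
        theta = v[idx].sum(axis=0).astype(float)
        dev = theta - targets
        f = float(np.sum(dev * dev * inv_var))
        temperature = options.initial_temperature
        since_improvement = 0
        if f < best_f:
            best_f, best_idx = f, idx.copy()
        trace_rows.append((0, restart, f, True))
        for it in range(1, options.max_iterations + 1):
            iterations_used += 1
            slot = int(rng.integers(target_m))
            cand = int(rng.integers(n))
            delta_v = v[cand] - v[idx[slot]]
            new_dev = dev + delta_v
            new_f = float(np.sum(new_dev * new_dev * inv_var))
            df = new_f - f
            accept = new_f < f
            if not accept and options.anneal and df > 0 and temperature > 0:
                accept = rng.random() < math.exp(-df / temperature)
            if options.anneal:
                temperature *= options.cooling
            if accept:
                idx[slot] = cand
                dev = new_dev
                f = new_f
                trace_rows.append((it, restart, f, True))
                if f < best_f:
                    best_f, best_idx = f, idx.copy()
                if df < 0:
                    since_improvement = 0
                else:
                    since_improvement += 1
            else:
                since_improvement += 1
            if best_f <= options.epsilon:
                converged = True
                break
            if since_improvement >= options.patience:
                break
        if converged:
            break

    warning = None
    if not converged and best_f > options.epsilon:
        warning = f"search exhausted without reaching epsilon (best fitness {best_f:.4g})"

    population = _materialise(pool, best_idx, spec.area_id)
    trace = pd.DataFrame(trace_rows, columns=["iteration", "restart", "fitness", "accepted"])
    return SynthesisResult(population, best_f, trace, converged, warning)


def _materialise(pool: Population, idx: np.ndarray, area_id: str) -> Population:
    """Clone the selected pool households into a fresh area population."""
    hh = pool.households
    persons_by_hh = dict(tuple(pool.persons.groupby("household_id", sort=False)))
    hh_rows, person_rows = [], []
    for copy_no, i in enumerate(idx):
        src = hh.iloc[int(i)]
        new_hid = f"{area_id}-H{copy_no:06d}"
        hh_rows.append((new_hid, area_id, src["hh_type"]))
        members = persons_by_hh[src["household_id"]]
        for member_no, (_, m) in enumerate(members.iterrows()):
            person_rows.append(
                (f"{new_hid}-P{member_no:02d}", new_hid, m["age"], m["sex"], m["role"])
            )
    return Population(
        pd.DataFrame(person_rows, columns=["person_id", "household_id", "age", "sex", "role"]),
        pd.DataFrame(hh_rows, columns=["household_id", "area_id", "hh_type"]),
    )


def synthesize_region(
    seed_pool: Population,
    marginals: pd.DataFrame,
    options: SearchOptions,
    wider_pool: Population | None = None,
) -> tuple[Population, pd.DataFrame]:
    """Synthesize every area present in the marginal tables.

    Returns the concatenated baseline population and a per-area report with
    final fitness, convergence flag and the relative bias of every marginal
    cell.  A failing area is flagged in the report; the others are still
    synthesized.
    """
    from .records import concat_populations

    areas = list(pd.unique(marginals["area_id"]))
    reports = []
    pieces = []
    rng = np.random.default_rng(options.seed)
    for area in areas:
        opts = SearchOptions(**{**options.__dict__, "seed": int(rng.integers(2**31 - 1))})
        try:
            spec = build_spec(marginals, seed_pool, area)
            result = synthesize_area(seed_pool, spec, spec.target_households, opts, wider_pool)
        except (InfeasibleAreaError, KeyError, ValueError) as exc:
            reports.append(
                {"area_id": area, "status": "failed", "fitness": np.nan, "detail": str(exc)}
            )
            continue
        pieces.append(result.population)
        theta = household_contributions(result.population, spec).sum(axis=0)
        rb = [
            100.0 * (est - tgt) / tgt if tgt != 0 else np.nan
            for est, tgt in zip(theta, spec.targets)
        ]
        reports.append(
            {
                "area_id": area,
                "status": "ok" if result.converged else "best_effort",
                "fitness": result.fitness,
                "detail": result.warning or "",
                "rb_by_cell": dict(zip([f"{v}:{c}" for v, c in spec.cells], rb)),
            }
        )
    return concat_populations(pieces), pd.DataFrame(reports)
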