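"""Synthetic study regions, seed microdata pools and marginal tables.

Real inputs for this kind of work — a confidentialised 1% census sample
file as seed microdata, plus area-level census tables — are proprietary.
This module generates stand-ins with the same structure: a ground-truth
nested individual/household population for a set of areas, a simple random
household sample of it (the "1% pool"), and area-level marginal tables
(age x sex person counts, household-type counts), optionally perturbed by
small integer adjustments the way statistical agencies perturb released
census tables.

It also ships the published NSW 2010 age-specific birth and death rate
tables verbatim (per 1000 and per 10000 respectively) via
:func:`vital_rates_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    DEFAULT_MAX_AGE,
    HH_TYPES,
    Population,
    tabulate_age_sex,
    tabulate_hh_types,
)
from .rates import VitalRates, rates_from_records

MARGINAL_COLUMNS = ["area_id", "variable", "category", "count", "perturbed"]

#: Published NSW 2010 age-specific birth rates, per 1000 females per year.
NSW_2010_BIRTH_RATES_PER_1000 = {
    "15-19": 15.3,
    "20-24": 51.4,
    "25-29": 101.0,
    "30-34": 120.4,
    "35-39": 63.4,
    "40-44": 11.3,
    "45-49": 0.6,
}

#: Published NSW 2010 age-specific death rates, per 10000 persons per year.
#: The males-65+ figure is reproduced verbatim even though it implies an
#: implausible annual mortality; use ``rate_scale`` on VitalRates to rescale.
NSW_2010_DEATH_RATES_PER_10000 = {
    "M": {
        "0-4": 64.1,
        "5-14": 24.9,
        "15-24": 133.7,
        "25-34": 242.9,
        "35-44": 507.5,
        "45-54": 1093.5,
        "55-64": 2176.8,
        "65+": 8960.0,
    },
    "F": {
        "0-4": 63.3,
        "5-14": 16.8,
        "15-24": 43.1,
        "25-34": 122.6,
        "35-44": 268.3,
        "45-54": 575.5,
        "55-64": 1445.8,
        "65+": 8008.4,
    },
}


class ConfigurationError(ValueError):
    """Infeasible region configuration."""


@dataclass
class RegionConfig:
    """Parameters of a synthetic ground-truth region.

    Exactly one of ``persons_per_area`` / ``households_per_area`` drives the
    area size (both may be set; households win).  The household-type mixture
    is a probability vector over the five census types.  Adult and child
    ages come from piecewise-uniform band distributions; a spouse's age is
    the partner's age plus a discrete-triangular gap (male minus female).
    """

    n_areas: int = 1
    persons_per_area: int | None = None
    households_per_area: int | None = None
    hh_type_mixture: dict = field(
        default_factory=lambda: {
            "couple_only": 0.26,
            "couple_with_children": 0.30,
            "lone_person": 0.24,
            "one_parent": 0.11,
            "other_family": 0.09,
        }
    )
    adult_age_bands: list = field(
        default_factory=lambda: [(18, 30, 0.25), (30, 45, 0.30), (45, 65, 0.25), (65, 90, 0.20)]
    )
    child_age_bands: list = field(
        default_factory=lambda: [(0, 5, 0.30), (5, 10, 0.30), (10, 15, 0.25), (15, 18, 0.15)]
    )
    #: distribution of the number of children in family households (1-based)
    children_dist: list = field(default_factory=lambda: [0.45, 0.35, 0.20])
    #: spousal age gap (male minus female) support; triangular weights
    age_gap_range: tuple = (-5, 10)
    sampling_fraction: float = 0.01
    perturbation: int = 2
    w: int = DEFAULT_MAX_AGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ConfigurationError("n_areas must be positive")
        if self.persons_per_area is None and self.households_per_area is None:
            raise ConfigurationError("set persons_per_area or households_per_area")
        for size in (self.persons_per_area, self.households_per_area):
            if size is not None and size < 1:
                raise ConfigurationError("area size must be positive")
        if not (0 < self.sampling_fraction <= 1):
            raise ConfigurationError("sampling_fraction must lie in (0, 1]")
        total = sum(self.hh_type_mixture.get(t, 0.0) for t in HH_TYPES)
        if total <= 0:
            raise ConfigurationError("household mixture sums to zero")
        unknown = set(self.hh_type_mixture) - set(HH_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown hh types in mixture: {sorted(unknown)}")


def _piecewise_uniform(rng: np.random.Generator, bands, size: int) -> np.ndarray:
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    wts = np.array([b[2] for b in bands], dtype=float)
    wts = wts / wts.sum()
    idx = rng.choice(len(bands), size=size, p=wts)
    return rng.integers(lows[idx], highs[idx])


def _triangular_gap(rng: np.random.Generator, lo: int, hi: int, size: int) -> np.ndarray:
    support = np.arange(lo, hi + 1)
    wts = np.minimum(support - lo + 1, hi - support + 1).astype(float)
    return rng.choice(support, size=size, p=wts / wts.sum())


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights sum to zero")
    quota = weights / weights.sum() * total
    out = np.floor(quota).astype(int)
    short = total - out.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    out[order[:short]] += 1
    return out


def generate_true_population(config: RegionConfig) -> Population:
    """Draw a ground-truth nested region population.

    Households partition persons; each household satisfies its type
    invariant; area totals match the configuration within rounding (with a
    person-driven size, the last household added may overshoot by its own
    size).
    """
    rng = np.random.default_rng(config.seed)
    mix = np.array([config.hh_type_mixture.get(t, 0.0) for t in HH_TYPES], dtype=float)
    mix = mix / mix.sum()

    persons_rows: list[tuple] = []
    hh_rows: list[tuple] = []
    pid = 0
    hid = 0

    def add_household(area: str, hh_type: str) -> None:
        nonlocal pid, hid
        hh_id = f"H{hid:07d}"
        hid += 1
        members: list[tuple] = []

        def person(age, sex, role):
            nonlocal pid
            members.append((f"P{pid:08d}", hh_id, int(age), sex, role))
            pid += 1

        if hh_type in ("couple_only", "couple_with_children"):
            f_age = _piecewise_uniform(rng, config.adult_age_bands, 1)[0]
            gap = _triangular_gap(rng, *config.age_gap_range, 1)[0]
            m_age = int(np.clip(f_age + gap, 18, config.w - 1))
            person(f_age, "F", "independent_adult")
            person(m_age, "M", "independent_adult")
        elif hh_type in ("lone_person", "one_parent"):
            age = _piecewise_uniform(rng, config.adult_age_bands, 1)[0]
            sex = "F" if rng.random() < (0.8 if hh_type == "one_parent" else 0.5) else "M"
            person(age, sex, "independent_adult")
        else:  # other_family: 2-3 related independent adults (e.g. siblings);
            # an opposite-sex pair would classify as couple_only, so pairs
            # are drawn same-sex
            n_adults = int(rng.integers(2, 4))
            ages = _piecewise_uniform(rng, config.adult_age_bands, n_adults)
            if n_adults == 2:
                s = "F" if rng.random() < 0.5 else "M"
                sexes = [s, s]
            else:
                sexes = ["F" if rng.random() < 0.5 else "M" for _ in range(n_adults)]
            for age, s in zip(ages, sexes):
                person(age, s, "independent_adult")
        if hh_type in ("couple_with_children", "one_parent"):
            k = int(rng.choice(np.arange(1, len(config.children_dist) + 1), p=config.children_dist))
            ages = _piecewise_uniform(rng, config.child_age_bands, k)
            for age in ages:
                person(age, "F" if rng.random() < 0.5 else "M", "dependent_child")
        hh_rows.append((hh_id, area, hh_type))
        persons_rows.extend(members)

    for g in range(config.n_areas):
        area = f"A{g:04d}"
        if config.households_per_area is not None:
            counts = _largest_remainder(mix, config.households_per_area)
            for t, c in zip(HH_TYPES, counts):
                for _ in range(c):
                    add_household(area, t)
        else:
            target = config.persons_per_area
            start = pid
            while pid - start < target:
                t = HH_TYPES[int(rng.choice(len(HH_TYPES), p=mix))]
                add_household(area, t)

    persons = pd.DataFrame(persons_rows, columns=["person_id", "household_id", "age", "sex", "role"])
    households = pd.DataFrame(hh_rows, columns=["household_id", "area_id", "hh_type"])
    return Population(persons, households)


def sample_seed_pool(population: Population, fraction: float, seed: int) -> Population:
    """Simple random sample of households, without replacement.

    All members travel with their household.  The number of sampled
    households is max(1, round(fraction * M)) so tiny fixtures still yield a
    non-empty pool.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if population.n_households == 0:
        raise ValueError("cannot sample from an empty population")
    rng = np.random.default_rng(seed)
    m = population.n_households
    k = max(1, int(round(fraction * m)))
    chosen = rng.choice(m, size=k, replace=False)
    hh = population.households.iloc[np.sort(chosen)].reset_index(drop=True)
    keep = set(hh["household_id"])
    pp = population.persons[population.persons["household_id"].isin(keep)].reset_index(drop=True)
    return Population(pp, hh)


def tabulate_marginals(
    population: Population,
    age_bands: list[tuple[int, int]],
    perturbation: int = 0,
    seed: int = 0,
    w: int = DEFAULT_MAX_AGE,
) -> pd.DataFrame:
    """Area-level marginal tables: age x sex person counts and hh_type counts.

    With ``perturbation = p > 0`` every cell receives independent integer
    noise uniform on {-p, ..., +p}, truncated at zero, and is flagged
    ``perturbed`` — emulating the small random adjustments applied to
    released census tables.
    """
    _check_bands(age_bands, w)
    rng = np.random.default_rng(seed)
    rows = []
    for area in population.area_ids():
        sub = population.subset_areas([area])
        for cat, count in tabulate_age_sex(sub.persons, age_bands).items():
            rows.append((area, "age_sex", cat, count))
        for cat, count in tabulate_hh_types(sub.households).items():
            rows.append((area, "hh_type", cat, count))
    df = pd.DataFrame(rows, columns=["area_id", "variable", "category", "count"])
    if perturbation > 0:
        noise = rng.integers(-perturbation, perturbation + 1, size=len(df))
        df["count"] = np.maximum(0, df["count"] + noise)
        df["perturbed"] = True
    else:
        df["perturbed"] = False
    return df[MARGINAL_COLUMNS]


def _check_bands(age_bands: list[tuple[int, int]], w: int) -> None:
    bands = sorted(age_bands)
    if not bands or bands[0][0] != 0 or bands[-1][1] != w:
        raise ValueError(f"age bands must cover [0, {w})")
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        if hi1 != lo2:
            raise ValueError(f"age bands must partition [0, {w}) without overlap")


#: Synthetic annual event probabilities for the unpublished rate families
#: (marriage, divorce, leaving home were released only graphically).
#: Values are plausible magnitudes for an Australian state circa 2010:
#: first-marriage rates peak near 0.08/yr for single women in their late
#: twenties, remarriage is slower, divorce is ~1-2%/yr per couple, and
#: dependants over 15 leave the parental home at 12-25%/yr.
SYNTHETIC_FIRST_MARRIAGE_RATES = {
    "15-19": 0.01, "20-24": 0.05, "25-29": 0.08, "30-34": 0.06,
    "35-44": 0.03, "45-59": 0.01, "60+": 0.002,
}
SYNTHETIC_REMARRIAGE_RATES = {"15-39": 0.03, "40-59": 0.015, "60+": 0.003}
SYNTHETIC_DIVORCE_RATES = {"15-29": 0.02, "30-49": 0.015, "50+": 0.005}
SYNTHETIC_LEAVING_HOME_RATES = {"16-24": 0.12, "25-34": 0.20, "35+": 0.25}


def synthetic_event_rates(w: int = DEFAULT_MAX_AGE, rate_scale: dict | None = None) -> VitalRates:
    """Full event-rate set: printed birth/death tables plus synthetic
    marriage, remarriage, divorce and leaving-home probabilities.

    Marriage-family rates are indexed by the female (or leaver's) age band
    with partners admitted from 15 up; see the module constants for the
    synthetic values and their rationale.
    """
    records = list(vital_rates_fixture(w=w).table.to_dict("records"))
    for band, rate in SYNTHETIC_FIRST_MARRIAGE_RATES.items():
        records.append({"event": "marriage1", "sex": "", "age_band": band,
                        "age_band_partner": "15+", "rate": rate, "per": 1})
    for band, rate in SYNTHETIC_REMARRIAGE_RATES.items():
        records.append({"event": "marriage2", "sex": "", "age_band": band,
                        "age_band_partner": "15+", "rate": rate, "per": 1})
    for band, rate in SYNTHETIC_DIVORCE_RATES.items():
        records.append({"event": "divorce", "sex": "", "age_band": band,
                        "age_band_partner": "15+", "rate": rate, "per": 1})
    for sex in ("F", "M"):
        for band, rate in SYNTHETIC_LEAVING_HOME_RATES.items():
            records.append({"event": "leaving_home", "sex": sex, "age_band": band,
                            "age_band_partner": "", "rate": rate, "per": 1})
    return rates_from_records(records, w=w, rate_scale=rate_scale or {})


def vital_rates_fixture(w: int = DEFAULT_MAX_AGE, rate_scale: dict | None = None) -> VitalRates:
    """The published NSW 2010 birth and death rate tables, verbatim.

    Births are per 1000 females by age band; deaths per 10000 persons by
    sex and age band.  Marriage, divorce, leaving-home and migration rates
    are zero (they were published only graphically).
    """
    records = []
    for band, rate in NSW_2010_BIRTH_RATES_PER_1000.items():
        records.append(
            {"event": "birth", "sex": "F", "age_band": band, "age_band_partner": "", "rate": rate, "per": 1000}
        )
    for sex, table in NSW_2010_DEATH_RATES_PER_10000.items():
        for band, rate in table.items():
            records.append(
                {"event": "death", "sex": sex, "age_band": band, "age_band_partner": "", "rate": rate, "per": 10000}
            )
    return rates_from_records(records, w=w, rate_scale=rate_scale or {})
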