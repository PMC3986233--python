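"""Core record containers: persons nested in households nested in areas.

The synthetic population follows a two-fold nested design: individuals
(age, sex, household role) belong to households (one of the five census
household types), and households belong to geographic areas.  Persons and
households are carried as plain :class:`pandas.DataFrame` objects wrapped
in a :class:`Population` container that enforces the structural invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HH_TYPES: tuple[str, ...] = (
    "couple_only",
    "couple_with_children",
    "lone_person",
    "one_parent",
    "other_family",
)
SEXES: tuple[str, ...] = ("F", "M")
ROLES: tuple[str, ...] = ("independent_adult", "dependent_child")

PERSON_COLUMNS = ["person_id", "household_id", "age", "sex", "role"]
HOUSEHOLD_COLUMNS = ["household_id", "area_id", "hh_type"]

#: Default maximum age: everyone dies before reaching this age.
DEFAULT_MAX_AGE = 100


class InvalidPopulationError(ValueError):
    """A population violates a structural invariant."""


def derive_hh_type(n_adult_f: int, n_adult_m: int, n_children: int) -> str:
    """Household type implied by a membership composition.

    Follows the five census categories.  A household consisting of a single
    dependent child has no census slot; callers should promote such a child
    to an independent adult (see :func:`dynapop.dynamics.step_micro`).
    """
    n_adults = n_adult_f + n_adult_m
    n_members = n_adults + n_children
    if n_members == 0:
        raise ValueError("empty household has no type")
    if n_members == 1 and n_adults == 1:
        return "lone_person"
    if n_adult_f == 1 and n_adult_m == 1:
        return "couple_with_children" if n_children >= 1 else "couple_only"
    if n_adults == 1 and n_children >= 1:
        return "one_parent"
    return "other_family"


@dataclass
class Population:
    """Persons + households for one or more areas.

    persons:    person_id, household_id, age, sex, role
    households: household_id, area_id, hh_type
    """

    persons: pd.DataFrame
    households: pd.DataFrame

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_households(self) -> int:
        return len(self.households)

    def area_ids(self) -> list:
        return list(self.households["area_id"].unique())

    def copy(self) -> "Population":
        return Population(self.persons.copy(), self.households.copy())

    def subset_areas(self, area_ids) -> "Population":
        hh = self.households[self.households["area_id"].isin(set(area_ids))]
        pp = self.persons[self.persons["household_id"].isin(set(hh["household_id"]))]
        return Population(pp.reset_index(drop=True), hh.reset_index(drop=True))

    def validate(self, w: int = DEFAULT_MAX_AGE) -> None:
        """Raise :class:`InvalidPopulationError` on any broken invariant."""
        p, h = self.persons, self.households
        if list(p.columns) != PERSON_COLUMNS:
            raise InvalidPopulationError(f"person columns must be {PERSON_COLUMNS}")
        if list(h.columns) != HOUSEHOLD_COLUMNS:
            raise InvalidPopulationError(f"household columns must be {HOUSEHOLD_COLUMNS}")
        if p["person_id"].duplicated().any():
            raise InvalidPopulationError("duplicate person_id")
        if h["household_id"].duplicated().any():
            raise InvalidPopulationError("duplicate household_id")
        if ((p["age"] < 0) | (p["age"] >= w)).any():
            raise InvalidPopulationError(f"ages must lie in [0, {w})")
        if not p["sex"].isin(SEXES).all():
            raise InvalidPopulationError("sex must be F or M")
        if not p["role"].isin(ROLES).all():
            raise InvalidPopulationError("unknown person role")
        if not h["hh_type"].isin(HH_TYPES).all():
            raise InvalidPopulationError("unknown hh_type")
        known = set(h["household_id"])
        if not p["household_id"].isin(known).all():
            raise InvalidPopulationError("person references missing household")
        # every household must have at least one member and a consistent type
        comp = _composition_table(p)
        missing = known - set(comp.index)
        if missing:
            raise InvalidPopulationError(f"empty households: {sorted(missing)[:5]}")
        merged = h.set_index("household_id").join(comp)
        for hid, row in merged.iterrows():
            expected = derive_hh_type(int(row["naf"]), int(row["nam"]), int(row["nc"]))
            if expected != row["hh_type"]:
                raise InvalidPopulationError(
                    f"household {hid}: type {row['hh_type']} inconsistent with "
                    f"membership (expected {expected})"
                )


def _composition_table(persons: pd.DataFrame) -> pd.DataFrame:
    """Per-household counts of female adults, male adults and children."""
    p = persons
    adult = p["role"] == "independent_adult"
    out = pd.DataFrame(
        {
            "naf": (adult & (p["sex"] == "F")).groupby(p["household_id"]).sum(),
            "nam": (adult & (p["sex"] == "M")).groupby(p["household_id"]).sum(),
            "nc": (~adult).groupby(p["household_id"]).sum(),
        }
    )
    return out


def concat_populations(pops: list[Population]) -> Population:
    if not pops:
        return Population(
            pd.DataFrame(columns=PERSON_COLUMNS), pd.DataFrame(columns=HOUSEHOLD_COLUMNS)
        )
    return Population(
        pd.concat([p.persons for p in pops], ignore_index=True),
        pd.concat([p.households for p in pops], ignore_index=True),
    )


def tabulate_age_sex(persons: pd.DataFrame, age_bands: list[tuple[int, int]]) -> dict:
    """Counts of persons per (sex, age band), keyed ``"F:0-14"`` style."""
    ages = persons["age"].to_numpy()
    sexes = persons["sex"].to_numpy()
    out = {}
    for sex in SEXES:
        for lo, hi in age_bands:
            key = f"{sex}:{lo}-{hi - 1}"
            out[key] = int(np.sum((sexes == sex) & (ages >= lo) & (ages < hi)))
    return out


def tabulate_hh_types(households: pd.DataFrame) -> dict:
    counts = households["hh_type"].value_counts()
    return {t: int(counts.get(t, 0)) for t in HH_TYPES}
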