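"""Vital rates: age/sex-specific event probabilities with their denominators.

Rates are stored in a long table with one row per (event, sex, age band,
partner age band) and a ``per`` denominator column, mirroring the published
tables (births per 1000 females, deaths per 10000 persons).  Accessors
expand banded rates into dense per-single-year probability arrays over ages
``[0, w)`` (constant within a band) and into female-age x male-age matrices
for pair events.

Events
------
``death``         per sex and age band
``birth``         per female age band (couple birth rate taken from the
                  wife's age; a couple-indexed rate table with a partner
                  band is also accepted)
``marriage1``     first-marriage rate, (female band, male band)
``marriage2``     remarriage rate, (female band, male band)
``divorce``       (female band, male band)
``leaving_home``  per sex and age band, ages strictly above 15
``immigration`` / ``emigration``  per sex and age band

The per-age growth rate of the two-sex model is derived, not stored:
R = immigration - emigration - death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import DEFAULT_MAX_AGE, SEXES

RATE_COLUMNS = ["event", "sex", "age_band", "age_band_partner", "rate", "per"]

EVENTS = (
    "death",
    "birth",
    "marriage1",
    "marriage2",
    "divorce",
    "leaving_home",
    "immigration",
    "emigration",
)
PAIR_EVENTS = ("marriage1", "marriage2", "divorce")


def parse_band(text: str, w: int) -> tuple[int, int]:
    """Parse ``"25-29"`` (inclusive) or ``"65+"`` into a half-open [lo, hi)."""
    text = str(text).strip()
    if text.endswith("+"):
        return int(text[:-1]), w
    lo, hi = text.split("-")
    return int(lo), int(hi) + 1


def format_band(lo: int, hi: int, w: int) -> str:
    return f"{lo}+" if hi >= w else f"{lo}-{hi - 1}"


@dataclass
class VitalRates:
    """Long-format rate table plus helpers producing probability arrays."""

    table: pd.DataFrame
    w: int = DEFAULT_MAX_AGE
    #: multiplicative rescaling per event, e.g. {"death": 0.5}; applied on
    #: top of the per-denominator conversion, never altering the stored table
    rate_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != RATE_COLUMNS:
            raise ValueError(f"rate table columns must be {RATE_COLUMNS}")
        if (t["rate"] < 0).any():
            raise ValueError("negative rate")
        if (t["per"] <= 0).any():
            raise ValueError("non-positive denominator")
        unknown = set(t["event"]) - set(EVENTS)
        if unknown:
            raise ValueError(f"unknown events: {sorted(unknown)}")

    # -- scalar-array accessors -------------------------------------------

    def prob(self, event: str, sex: str) -> np.ndarray:
        """Annual event probability per single year of age for one sex."""
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        out = np.zeros(self.w)
        scale = self.rate_scale.get(event, 1.0)
        rows = self.table[(self.table["event"] == event)]
        rows = rows[(rows["sex"] == sex) | (rows["sex"].isna()) | (rows["sex"] == "")]
        for _, r in rows.iterrows():
            lo, hi = parse_band(r["age_band"], self.w)
            out[lo:hi] = r["rate"] / r["per"] * scale
        return np.clip(out, 0.0, 1.0)

    def pair_prob(self, event: str) -> np.ndarray:
        """Annual probability matrix indexed (female age, male age)."""
        out = np.zeros((self.w, self.w))
        scale = self.rate_scale.get(event, 1.0)
        rows = self.table[self.table["event"] == event]
        for _, r in rows.iterrows():
            flo, fhi = parse_band(r["age_band"], self.w)
            partner = r["age_band_partner"]
            if pd.isna(partner) or str(partner).strip() == "":
                mlo, mhi = 0, self.w  # female-age-only rate, constant in male age
            else:
                mlo, mhi = parse_band(partner, self.w)
            out[flo:fhi, mlo:mhi] = r["rate"] / r["per"] * scale
        return np.clip(out, 0.0, 1.0)

    def growth(self, sex: str) -> np.ndarray:
        """Per-age growth rate R = immigration - emigration - death."""
        return self.prob("immigration", sex) - self.prob("emigration", sex) - self.prob("death", sex)

    # -- period conversion -------------------------------------------------

    def per_period(self, n: int) -> "VitalRates":
        """Convert annual probabilities to per-period (1/n year) ones.

        Uses q = 1 - (1 - p)^(1/n) on every stored rate; with n = 1 this is
        the identity.
        """
        if n == 1:
            return self
        t = self.table.copy()
        p = np.clip(t["rate"] / t["per"] * t["event"].map(lambda e: self.rate_scale.get(e, 1.0)), 0, 1)
        t["rate"] = 1.0 - (1.0 - p) ** (1.0 / n)
        t["per"] = 1.0
        return VitalRates(t, w=self.w)


def rates_from_records(records: list[dict], w: int = DEFAULT_MAX_AGE, **kw) -> VitalRates:
    """Build a :class:`VitalRates` from dicts with the schema columns."""
    df = pd.DataFrame(records)
    for col in RATE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "age_band_partner" else ""
    return VitalRates(df[RATE_COLUMNS], w=w, **kw)


def zero_rates(w: int = DEFAULT_MAX_AGE) -> VitalRates:
    return VitalRates(pd.DataFrame(columns=RATE_COLUMNS), w=w)
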