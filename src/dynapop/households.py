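"""Household-type transitions driven by demographic event components.

A household state is summarised as (female-adult age band, male-adult age
band, up to two tracked children with sex and age band); the five census
household types are derived from that composition, with an explicit
``extinct`` state for a household whose last member has left.

m = 10 event components act on a state within one period, in a fixed
order: [death of independent male adult, death of independent female
adult, death of dependent female, death of dependent male, first
marriage, remarriage, birth, divorce, daughter leaves home, son leaves
home].  An outcome of a period is a full 0/1 indicator vector delta over
the ten components; assuming independent events, its probability is the
product  prod_{c: delta_c=1} pi_c * prod_{c: delta_c=0} (1 - pi_c)  with
pi the per-component probabilities for the source state.  The transition
probability g1 -> g2 sums this over the D outcome vectors whose
application maps g1 to g2; full outcome vectors are mutually exclusive, so
the inclusion-exclusion union formula collapses to a plain sum (the
general union form over partially specified cases is provided as
:func:`union_probability` and agrees on disjoint inputs).

Conventions (one period):

* events apply in the semantic order marriage -> birth -> divorce ->
  deaths -> leaving home; an event inapplicable at its turn is a no-op,
  so the 2^10 outcomes always partition the probability mass;
* birth and divorce require a couple at the *start* of the period (a
  couple formed within the period can neither have a birth nor divorce);
* a marriage adds an opposite-sex partner drawn from the same age band;
* on divorce the male adult leaves (children stay), forming a new
  household that is not tracked by this row's transition;
* a newborn is recorded as a girl in the aggregated state (a single birth
  component cannot split destinations by sex; the micro-simulation draws
  newborn sex properly, and household-type level quantities are
  unaffected);
* child components act on the oldest tracked child of the relevant sex;
  at most two children are tracked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .rates import VitalRates

EVENTS: tuple[str, ...] = (
    "death_male_adult",
    "death_female_adult",
    "death_female_dependent",
    "death_male_dependent",
    "first_marriage",
    "remarriage",
    "birth",
    "divorce",
    "daughter_leaves_home",
    "son_leaves_home",
)
N_EVENTS = len(EVENTS)

DEFAULT_ADULT_BANDS: tuple[tuple[int, int], ...] = ((15, 35), (35, 55), (55, 75), (75, 100))
DEFAULT_CHILD_BANDS: tuple[tuple[int, int], ...] = ((0, 16), (16, 30))

MAX_TRACKED_CHILDREN = 2

EXTINCT = "extinct"


class HouseholdState(NamedTuple):
    """(female adult band, male adult band, children) with bands as (lo, hi).

    ``fa``/``ma`` are ``None`` when no adult of that sex is present;
    ``children`` is a sorted tuple of ("F"/"M", band) pairs, at most
    :data:`MAX_TRACKED_CHILDREN` long.
    """

    fa: tuple[int, int] | None
    ma: tuple[int, int] | None
    children: tuple[tuple[str, tuple[int, int]], ...]

    @property
    def hh_type(self) -> str:
        from .records import derive_hh_type

        naf = 1 if self.fa is not None else 0
        nam = 1 if self.ma is not None else 0
        nc = len(self.children)
        if naf + nam + nc == 0:
            return EXTINCT
        if naf + nam == 0 and nc == 1:
            return "lone_person"  # sole surviving child is promoted
        return derive_hh_type(naf, nam, nc)

    def label(self) -> str:
        if self.is_extinct:
            return EXTINCT
        parts = []
        if self.fa is not None:
            parts.append(f"F{self.fa[0]}-{self.fa[1] - 1}")
        if self.ma is not None:
            parts.append(f"M{self.ma[0]}-{self.ma[1] - 1}")
        for sex, band in self.children:
            parts.append(f"c{sex}{band[0]}-{band[1] - 1}")
        return "|".join(parts)

    @property
    def is_extinct(self) -> bool:
        return self.fa is None and self.ma is None and not self.children


EXTINCT_STATE = HouseholdState(None, None, ())


def _sorted_children(children) -> tuple:
    return tuple(sorted(children, key=lambda c: (c[0], c[1][0])))


def apply_events(state: HouseholdState, delta) -> HouseholdState:
    """Deterministic result of realising an outcome vector on a state.

    Total on all 2^10 delta for every state: inapplicable components are
    no-ops, so every outcome maps to exactly one destination (possibly
    the extinct state) and destinations partition the outcome space.
    """
    if len(delta) != N_EVENTS:
        raise ValueError(f"delta must have length {N_EVENTS}")
    fa, ma = state.fa, state.ma
    children = list(state.children)
    couple_at_start = fa is not None and ma is not None

    # marriages: a sole adult gains an opposite-sex partner, same band
    for ev in ("first_marriage", "remarriage"):
        if delta[EVENTS.index(ev)]:
            if fa is not None and ma is None:
                ma = fa
            elif ma is not None and fa is None:
                fa = ma
    # birth: start-of-period couples only; newborn tracked as a girl
    if delta[EVENTS.index("birth")] and couple_at_start:
        if len(children) < MAX_TRACKED_CHILDREN:
            children.append(("F", _youngest_band(state)))
    # divorce: start-of-period couples only; the male adult leaves
    if delta[EVENTS.index("divorce")] and couple_at_start and ma is not None:
        ma = None
    # deaths
    if delta[EVENTS.index("death_male_adult")] and ma is not None:
        ma = None
    if delta[EVENTS.index("death_female_adult")] and fa is not None:
        fa = None
    if delta[EVENTS.index("death_female_dependent")]:
        children = _remove_oldest(children, "F")
    if delta[EVENTS.index("death_male_dependent")]:
        children = _remove_oldest(children, "M")
    # leaving the parental home (dependants strictly over 15)
    if delta[EVENTS.index("daughter_leaves_home")]:
        children = _remove_oldest(children, "F", leavers_only=True)
    if delta[EVENTS.index("son_leaves_home")]:
        children = _remove_oldest(children, "M", leavers_only=True)
    return HouseholdState(fa, ma, _sorted_children(children))


def _youngest_band(state: HouseholdState) -> tuple[int, int]:
    bands = sorted({c[1] for c in state.children})
    return bands[0] if bands else (0, 16)


def _remove_oldest(children: list, sex: str, leavers_only: bool = False) -> list:
    cands = [c for c in children if c[0] == sex and (not leavers_only or c[1][1] > 16)]
    if not cands:
        return children
    oldest = max(cands, key=lambda c: c[1][0])
    out = list(children)
    out.remove(oldest)
    return out


def enumerate_indicators(g1: HouseholdState, g2: HouseholdState) -> list[tuple[int, ...]]:
    """All outcome vectors delta whose application maps g1 to g2 (D cases)."""
    return [
        delta
        for delta in itertools.product((0, 1), repeat=N_EVENTS)
        if apply_events(g1, delta) == g2
    ]


def case_probability(delta, pi) -> float:
    """Probability of one full outcome vector under independent components."""
    pi = np.asarray(pi, dtype=float)
    delta = np.asarray(delta)
    if len(pi) != N_EVENTS or len(delta) != N_EVENTS:
        raise ValueError(f"vectors must have length {N_EVENTS}")
    return float(np.prod(np.where(delta == 1, pi, 1.0 - pi)))


def union_probability(cases: list[tuple], pi) -> float:
    """P(union of partially specified cases) by inclusion-exclusion.

    Each case is (must_occur, must_not_occur): two iterables of component
    indices; unspecified components are free.  On mutually exclusive fully
    specified cases this reduces to the plain sum of case probabilities.
    """
    pi = np.asarray(pi, dtype=float)
    norm = [(frozenset(a), frozenset(b)) for a, b in cases]
    for ones, zeros in norm:
        if ones & zeros:
            raise ValueError("a component cannot be required both to occur and not")
    total = 0.0
    for r in range(1, len(norm) + 1):
        for combo in itertools.combinations(norm, r):
            ones = frozenset().union(*(c[0] for c in combo))
            zeros = frozenset().union(*(c[1] for c in combo))
            if ones & zeros:
                continue  # contradictory intersection: empty event
            p = np.prod([pi[c] for c in ones]) * np.prod([1.0 - pi[c] for c in zeros])
            total += (-1) ** (r + 1) * float(p)
    return total


def transition_probability(g1: HouseholdState, g2: HouseholdState, pi) -> float:
    """Probability that one period maps state g1 to state g2."""
    return float(sum(case_probability(d, pi) for d in enumerate_indicators(g1, g2)))


def enumerate_states(
    adult_bands=DEFAULT_ADULT_BANDS,
    child_bands=DEFAULT_CHILD_BANDS,
    max_children: int = MAX_TRACKED_CHILDREN,
) -> list[HouseholdState]:
    """All non-empty household states over the given band grids."""
    adult_opts = [None] + [tuple(b) for b in adult_bands]
    child_types = [(s, tuple(b)) for s in ("F", "M") for b in child_bands]
    child_opts = []
    for k in range(max_children + 1):
        child_opts.extend(itertools.combinations_with_replacement(child_types, k))
    states = []
    for fa, ma, ch in itertools.product(adult_opts, adult_opts, child_opts):
        s = HouseholdState(fa, ma, _sorted_children(ch))
        if not s.is_extinct:
            states.append(s)
    return states


def event_probabilities(state: HouseholdState, rates: VitalRates) -> np.ndarray:
    """The length-10 component probability vector pi for one source state.

    Rates are looked up at band midpoints (constant-within-band rates make
    this exact); components inapplicable to the state get probability 0.
    """
    pi = np.zeros(N_EVENTS)
    d_f, d_m = rates.prob("death", "F"), rates.prob("death", "M")
    lam_f, lam_m = rates.prob("leaving_home", "F"), rates.prob("leaving_home", "M")
    mu1, mu2 = rates.pair_prob("marriage1"), rates.pair_prob("marriage2")
    nu, b = rates.pair_prob("divorce"), rates.pair_prob("birth")

    def rep(band: tuple[int, int], what: str) -> int:
        mid = (band[0] + min(band[1], rates.w) - 1) // 2
        if not (0 <= mid < rates.w):
            raise KeyError(f"no {what} rate available for age band {band}")
        return mid

    if state.ma is not None:
        pi[EVENTS.index("death_male_adult")] = d_m[rep(state.ma, "male death")]
    if state.fa is not None:
        pi[EVENTS.index("death_female_adult")] = d_f[rep(state.fa, "female death")]
    girls = [c for c in state.children if c[0] == "F"]
    boys = [c for c in state.children if c[0] == "M"]
    if girls:
        band = max(girls, key=lambda c: c[1][0])[1]
        pi[EVENTS.index("death_female_dependent")] = d_f[rep(band, "female death")]
        if band[1] > 16:
            pi[EVENTS.index("daughter_leaves_home")] = lam_f[rep((max(band[0], 16), band[1]), "leaving-home")]
    if boys:
        band = max(boys, key=lambda c: c[1][0])[1]
        pi[EVENTS.index("death_male_dependent")] = d_m[rep(band, "male death")]
        if band[1] > 16:
            pi[EVENTS.index("son_leaves_home")] = lam_m[rep((max(band[0], 16), band[1]), "leaving-home")]
    sole_adult = (state.fa is None) != (state.ma is None)
    if sole_adult:
        band = state.fa or state.ma
        a = rep(band, "marriage")
        pi[EVENTS.index("first_marriage")] = mu1[a, a]
        pi[EVENTS.index("remarriage")] = mu2[a, a]
    if state.fa is not None and state.ma is not None:
        i, j = rep(state.fa, "birth"), rep(state.ma, "divorce")
        pi[EVENTS.index("birth")] = b[i, j]
        pi[EVENTS.index("divorce")] = nu[i, j]
    return pi


@dataclass
class HHTTransitionMatrix:
    """Row-stochastic transition matrix over household states + extinct."""

    states: list[HouseholdState]
    matrix: np.ndarray  # shape (H, H + 1); last column is the extinct state

    @property
    def labels(self) -> list[str]:
        return [s.label() for s in self.states] + [EXTINCT]

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = self.labels
        for i, s in enumerate(self.states):
            for j, lab in enumerate(labels):
                p = self.matrix[i, j]
                if p > 0:
                    rows.append((s.label(), lab, p))
        return pd.DataFrame(rows, columns=["from_state", "to_state", "probability"])

    def hh_type_matrix(self) -> pd.DataFrame:
        """Transition matrix marginalised to the five census household types.

        Rows are averaged uniformly over the states of each type; columns
        aggregate destination mass by type (plus extinct).
        """
        from .records import HH_TYPES

        types = list(HH_TYPES) + [EXTINCT]
        out = pd.DataFrame(0.0, index=types[:-1], columns=types)
        counts = {t: 0 for t in types}
        dest_type = [s.hh_type for s in self.states] + [EXTINCT]
        for i, s in enumerate(self.states):
            t = s.hh_type
            counts[t] += 1
            for j, dt in enumerate(dest_type):
                out.loc[t, dt] += self.matrix[i, j]
        for t in out.index:
            if counts[t]:
                out.loc[t] /= counts[t]
        return out


def build_hht_matrix(
    states: list[HouseholdState],
    rates: VitalRates,
) -> HHTTransitionMatrix:
    """Assemble the transition matrix by exhausting the 2^10 outcomes per row."""
    index = {s: k for k, s in enumerate(states)}
    h = len(states)
    matrix = np.zeros((h, h + 1))
    all_deltas = list(itertools.product((0, 1), repeat=N_EVENTS))
    for i, g1 in enumerate(states):
        pi = event_probabilities(g1, rates)
        # group outcomes by destination, then accumulate probabilities
        for delta in all_deltas:
            p = case_probability(delta, pi)
            if p == 0.0:
                continue
            dest = apply_events(g1, delta)
            if dest.is_extinct:
                matrix[i, h] += p
            else:
                j = index.get(dest)
                if j is None:
                    raise KeyError(f"destination state {dest.label()} missing from state list")
                matrix[i, j] += p
    return HHTTransitionMatrix(states, matrix)


def project_households(counts: np.ndarray, tm: HHTTransitionMatrix, years: int) -> np.ndarray:
    """Project state counts forward: trajectory of shape (years+1, H+1).

    ``counts`` has one entry per state (an extra trailing entry for the
    extinct stock is accepted); total mass including the extinct stock is
    conserved.
    """
    h = len(tm.states)
    counts = np.asarray(counts, dtype=float)
    if counts.shape == (h,):
        counts = np.concatenate([counts, [0.0]])
    if counts.shape != (h + 1,):
        raise ValueError(f"counts must have length {h} or {h + 1}")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    full = np.vstack([tm.matrix, np.eye(1, h + 1, h)])  # extinct is absorbing
    traj = [counts]
    for _ in range(years):
        traj.append(traj[-1] @ full)
    return np.array(traj)
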