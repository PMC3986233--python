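"""Age-structured two-sex population dynamics.

The population evolves in discrete periods (default one year).  The
aggregate (deterministic-expectation) state carries female and male counts
by single year of age, a couples matrix C[i, j] (wife age i, husband age
j), and widow/widower stocks.  One step applies, in this order:

1. events computed from the start-of-period state: new couples N (two-sex
   harmonic-mean matching under first-marriage and remarriage rates),
   divorces D = C * nu, deaths, and births B = sum_ij C_ij * b_ij split by
   a fixed sex ratio at birth;
2. couples update      C' = (C + N - D) * s_f s_m;
3. widow recursions    W_f' = (W_f + sum_j C_ij d_m_j - remarriages) * s_f
   and symmetrically for widowers (with zero remarriage rates this is the
   classical no-outflow widow recursion);
4. age/sex totals grow by (1 + R) with R = immigration - emigration -
   death, plus births entering age 0;
5. ageing: all age indices shift by one year and age w-1 exits (everyone
   dies before reaching the maximum age w); a spouse aged out of a couple
   leaves a widow(er) behind.

The micro step realises exactly the same events per household with
Bernoulli draws, so that the mean of many replicate micro runs converges
to the deterministic step cell by cell.  Conventions shared by both paths
(these make the deterministic recursions the exact expectation of the
micro step):

* marriages and divorces are drawn from the start-of-period state;
  newly formed couples cannot divorce in the same period;
* births are drawn per start-of-period couple, regardless of a divorce or
  death later in the same period; newborns are not exposed to mortality in
  their birth period;
* a person whose start-of-period spouse dies becomes widowed even if the
  couple divorced within the period; a spouse of a couple formed within
  the period who loses the new partner reverts to single, not widowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import DEFAULT_MAX_AGE, Population, derive_hh_type
from .rates import VitalRates

logger = logging.getLogger(__name__)

#: sex ratio at birth: 105 males per 100 females
MALE_BIRTH_FRACTION = 105.0 / 205.0


# ---------------------------------------------------------------------------
# reference growth models


def malthusian_projection(p0: float, r: float, t: int) -> float:
    """Exponential-law projection P(t) = P0 * (1 + R)^t."""
    if r <= -1:
        raise ValueError("growth rate must exceed -1")
    if p0 < 0:
        raise ValueError("population size must be non-negative")
    return p0 * (1.0 + r) ** t


def logistic_growth_step(p: float, r: float, l: float) -> float:
    """One step of density-dependent growth with carrying capacity L.

    P(t+1) = P + R * P * (1 - P/L): growth is positive for 0 < P < L (with
    R > 0), negative above L, and exactly zero at P = L.
    """
    if l <= 0:
        raise ValueError("carrying capacity must be positive")
    if p < 0:
        raise ValueError("population size must be non-negative")
    return p + r * p * (1.0 - p / l)


# ---------------------------------------------------------------------------
# aggregate state


@dataclass
class StepLedger:
    """Pre-clamp accounting of one deterministic or micro step."""

    births: float = 0.0
    deaths: float = 0.0
    immigrants: float = 0.0
    emigrants: float = 0.0
    exits: float = 0.0
    clamped: float = 0.0


@dataclass
class PopulationState:
    """Deterministic-expectation state: counts by age, sex and partnership."""

    pf: np.ndarray  # females by age, length w
    pm: np.ndarray  # males by age
    couples: np.ndarray  # C[i, j]: wife age i, husband age j
    wf: np.ndarray  # widows by age
    wm: np.ndarray  # widowers by age
    t: int = 0

    @classmethod
    def empty(cls, w: int = DEFAULT_MAX_AGE) -> "PopulationState":
        return cls(np.zeros(w), np.zeros(w), np.zeros((w, w)), np.zeros(w), np.zeros(w))

    @property
    def w(self) -> int:
        return len(self.pf)

    def total(self) -> float:
        return float(self.pf.sum() + self.pm.sum())

    def singles(self) -> tuple[np.ndarray, np.ndarray]:
        """Never-married/divorced singles by age: P - married - widowed."""
        sf = np.clip(self.pf - self.couples.sum(axis=1) - self.wf, 0.0, None)
        sm = np.clip(self.pm - self.couples.sum(axis=0) - self.wm, 0.0, None)
        return sf, sm

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.pf.copy(), self.pm.copy(), self.couples.copy(), self.wf.copy(), self.wm.copy(), self.t
        )

    def validate(self) -> None:
        for name in ("pf", "pm", "couples", "wf", "wm"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative entries in {name}")


def match_couples(singles_f: np.ndarray, singles_m: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Expected new couples N[i, j] under harmonic-mean two-sex matching.

    N_ij = mu_ij * 2 S_f_i S_m_j / (S_f_i + S_m_j) when both sides are
    positive, zero otherwise; the result is then proportionally rescaled so
    that no row (column) total exceeds the available single females
    (males).  With no single males anywhere N is identically zero — the
    two-sex consistency requirement.
    """
    sf = np.asarray(singles_f, dtype=float)
    sm = np.asarray(singles_m, dtype=float)
    denom = sf[:, None] + sm[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(denom > 0, 2.0 * sf[:, None] * sm[None, :] / np.where(denom > 0, denom, 1.0), 0.0)
    n = np.asarray(mu, dtype=float) * h
    for _ in range(100):
        rows = n.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rscale = np.where(rows > sf, np.where(rows > 0, sf / np.where(rows > 0, rows, 1.0), 0.0), 1.0)
        n = n * rscale[:, None]
        cols = n.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cscale = np.where(cols > sm, np.where(cols > 0, sm / np.where(cols > 0, cols, 1.0), 0.0), 1.0)
        n = n * cscale[None, :]
        if (n.sum(axis=1) <= sf + 1e-12).all() and (n.sum(axis=0) <= sm + 1e-12).all():
            break
    return n


def step_deterministic(
    state: PopulationState,
    rates: VitalRates,
    male_birth_fraction: float = MALE_BIRTH_FRACTION,
    ageing: bool = True,
) -> tuple[PopulationState, StepLedger]:
    """Expectation update of the aggregate state over one period."""
    w = state.w
    if rates.w != w:
        raise ValueError(f"rates cover ages [0, {rates.w}) but state has w={w}")
    d_f, d_m = rates.prob("death", "F"), rates.prob("death", "M")
    s_f, s_m = 1.0 - d_f, 1.0 - d_m
    imm_f, imm_m = rates.prob("immigration", "F"), rates.prob("immigration", "M")
    emi_f, emi_m = rates.prob("emigration", "F"), rates.prob("emigration", "M")
    r_f = imm_f - emi_f - d_f
    r_m = imm_m - emi_m - d_m
    mu1, mu2 = rates.pair_prob("marriage1"), rates.pair_prob("marriage2")
    nu, b = rates.pair_prob("divorce"), rates.pair_prob("birth")

    ledger = StepLedger()
    sf1, sm1 = state.singles()
    n1 = match_couples(sf1, sm1, mu1)
    n2 = match_couples(state.wf, state.wm, mu2)
    d_couples = state.couples * nu
    births = float((state.couples * b).sum())
    births_m = births * male_birth_fraction
    births_f = births - births_m
    ledger.births = births
    ledger.deaths = float((state.pf * d_f).sum() + (state.pm * d_m).sum())
    ledger.immigrants = float((state.pf * imm_f).sum() + (state.pm * imm_m).sum())
    ledger.emigrants = float((state.pf * emi_f).sum() + (state.pm * emi_m).sum())

    c1 = (state.couples + n1 + n2 - d_couples) * np.outer(s_f, s_m)
    wf1 = (state.wf + state.couples @ d_m - n2.sum(axis=1)) * s_f
    wm1 = (state.wm + state.couples.T @ d_f - n2.sum(axis=0)) * s_m
    pf1 = state.pf * (1.0 + r_f)
    pm1 = state.pm * (1.0 + r_m)

    for name, arr in (("couples", c1), ("widows", wf1), ("widowers", wm1), ("females", pf1), ("males", pm1)):
        neg = arr < 0
        if neg.any():
            ledger.clamped += float(-arr[neg].sum())
            logger.warning("clamped %.6g negative mass in %s", -arr[neg].sum(), name)
            arr[neg] = 0.0

    out = PopulationState.empty(w)
    out.t = state.t + 1
    if ageing:
        out.pf[1:] = pf1[:-1]
        out.pm[1:] = pm1[:-1]
        out.pf[0] = births_f
        out.pm[0] = births_m
        ledger.exits = float(pf1[-1] + pm1[-1])
        out.couples[1:, 1:] = c1[:-1, :-1]
        out.wf[1:] = wf1[:-1]
        out.wm[1:] = wm1[:-1]
        # a spouse reaching the maximum age leaves a widow(er) behind
        out.wf[1:] += c1[:-1, -1]
        out.wm[1:] += c1[-1, :-1]
    else:
        out.pf, out.pm = pf1, pm1
        out.pf[0] += births_f
        out.pm[0] += births_m
        out.couples, out.wf, out.wm = c1, wf1, wm1
    return out, ledger


# ---------------------------------------------------------------------------
# record-level micro state

_SEX_CODE = {"F": 0, "M": 1}
_SEX_NAME = np.array(["F", "M"])
_ROLE_NAME = np.array(["independent_adult", "dependent_child"])


@dataclass
class MicroState:
    """Array-backed record-level population with marital links.

    ``partner`` holds the person index of the current spouse (-1 when
    unmarried); ``hh`` indexes the household arrays.  Marital codes:
    0 single (incl. divorced), 1 married, 2 widowed.
    """

    age: np.ndarray
    sex: np.ndarray  # 0 = F, 1 = M
    role: np.ndarray  # 0 = independent_adult, 1 = dependent_child
    marital: np.ndarray
    partner: np.ndarray
    hh: np.ndarray
    hh_type: np.ndarray  # per household, string codes
    hh_area: np.ndarray
    w: int = DEFAULT_MAX_AGE
    t: int = 0

    @property
    def n_persons(self) -> int:
        return len(self.age)

    @property
    def n_households(self) -> int:
        return len(self.hh_type)

    def copy(self) -> "MicroState":
        return MicroState(
            self.age.copy(), self.sex.copy(), self.role.copy(), self.marital.copy(),
            self.partner.copy(), self.hh.copy(), self.hh_type.copy(), self.hh_area.copy(),
            self.w, self.t,
        )

    @classmethod
    def from_population(cls, pop: Population, w: int = DEFAULT_MAX_AGE) -> "MicroState":
        """Build the micro state; adults of couple households are married."""
        persons = pop.persons.reset_index(drop=True)
        households = pop.households.reset_index(drop=True)
        hh_codes, hh_order = pd.factorize(persons["household_id"])
        hh_table = households.set_index("household_id").loc[hh_order]
        age = persons["age"].to_numpy(np.int64)
        sex = persons["sex"].map(_SEX_CODE).to_numpy(np.int8)
        role = (persons["role"] == "dependent_child").to_numpy().astype(np.int8)
        marital = np.zeros(len(persons), np.int8)
        partner = np.full(len(persons), -1, np.int64)
        hh_type = hh_table["hh_type"].to_numpy()
        for h in np.flatnonzero(np.isin(hh_type, ("couple_only", "couple_with_children"))):
            members = np.flatnonzero(hh_codes == h)
            adults = members[role[members] == 0]
            fs = adults[sex[adults] == 0]
            ms = adults[sex[adults] == 1]
            if len(fs) and len(ms):
                fi, mi = int(fs[0]), int(ms[0])
                marital[fi] = marital[mi] = 1
                partner[fi], partner[mi] = mi, fi
        return cls(
            age, sex, role, marital, partner, hh_codes.astype(np.int64),
            hh_type, hh_table["area_id"].to_numpy(), w,
        )

    def to_population(self) -> Population:
        """Export as id-bearing frames (fresh sequential identifiers)."""
        hh_ids = np.array([f"H{i:07d}" for i in range(self.n_households)])
        persons = pd.DataFrame(
            {
                "person_id": [f"P{i:08d}" for i in range(self.n_persons)],
                "household_id": hh_ids[self.hh],
                "age": self.age,
                "sex": _SEX_NAME[self.sex],
                "role": _ROLE_NAME[self.role],
            }
        )
        households = pd.DataFrame(
            {"household_id": hh_ids, "area_id": self.hh_area, "hh_type": self.hh_type}
        )
        return Population(persons, households)

    def tally(self) -> PopulationState:
        """Aggregate to the deterministic state representation."""
        st = PopulationState.empty(self.w)
        st.t = self.t
        st.pf += np.bincount(self.age[self.sex == 0], minlength=self.w)[: self.w]
        st.pm += np.bincount(self.age[self.sex == 1], minlength=self.w)[: self.w]
        wives = np.flatnonzero((self.sex == 0) & (self.marital == 1))
        for fi in wives:
            mi = self.partner[fi]
            if mi >= 0:
                st.couples[self.age[fi], self.age[mi]] += 1
        st.wf += np.bincount(
            self.age[(self.sex == 0) & (self.marital == 2)], minlength=self.w
        )[: self.w]
        st.wm += np.bincount(
            self.age[(self.sex == 1) & (self.marital == 2)], minlength=self.w
        )[: self.w]
        return st

    def hh_type_counts(self) -> dict:
        from .records import HH_TYPES

        vals, counts = np.unique(self.hh_type, return_counts=True)
        table = dict(zip(vals, counts))
        return {t: int(table.get(t, 0)) for t in HH_TYPES}


def _realise_counts(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer realisation with the exact expectation: floor + Bernoulli."""
    base = np.floor(expected)
    frac = expected - base
    return (base + (rng.random(expected.shape) < frac)).astype(np.int64)


def step_micro(
    micro: MicroState,
    rates: VitalRates,
    rng: np.random.Generator,
    male_birth_fraction: float = MALE_BIRTH_FRACTION,
    ageing: bool = True,
) -> tuple[MicroState, StepLedger]:
    """One stochastic period at the person/household level.

    Event order: marriages, divorces, births recorded, deaths, leaving the
    parental home, emigration, ageing, newborns appended.  See the module
    docstring for the conventions shared with :func:`step_deterministic`.
    """
    st = micro.copy()
    w = st.w
    n0 = st.n_persons
    ledger = StepLedger()
    d_f, d_m = rates.prob("death", "F"), rates.prob("death", "M")
    mu1, mu2 = rates.pair_prob("marriage1"), rates.pair_prob("marriage2")
    nu, b = rates.pair_prob("divorce"), rates.pair_prob("birth")
    lam_f, lam_m = rates.prob("leaving_home", "F"), rates.prob("leaving_home", "M")
    emi_f, emi_m = rates.prob("emigration", "F"), rates.prob("emigration", "M")

    start_age = st.age.copy()
    alive = np.ones(n0, dtype=bool)
    wives0 = np.flatnonzero((st.sex == 0) & (st.marital == 1) & (st.partner >= 0))
    start_couples = [(int(fi), int(st.partner[fi])) for fi in wives0]

    hh_type = list(st.hh_type)
    hh_area = list(st.hh_area)
    hh = st.hh

    def new_household(area) -> int:
        hh_type.append("lone_person")  # placeholder; re-derived at the end
        hh_area.append(area)
        return len(hh_type) - 1

    # --- marriages (from start-of-period singles and widowed pools) -------
    new_pairs: list[tuple[int, int]] = []

    def realise_marriages(pool_marital: int, mu: np.ndarray) -> None:
        # Realise the expected new-couples matrix N with the exact female
        # marginal expectation: per female age the number of brides is
        # floor+Bernoulli of sum_j N_ij (which the matching caps at the
        # number available), and each bride draws a husband age from the
        # row distribution, falling back to the nearest age with an
        # available single male.
        f_mask = (st.sex == 0) & (st.marital == pool_marital)
        m_mask = (st.sex == 1) & (st.marital == pool_marital)
        sf = np.bincount(start_age[f_mask], minlength=w)[:w].astype(float)
        sm = np.bincount(start_age[m_mask], minlength=w)[:w].astype(float)
        n_exp = match_couples(sf, sm, mu)
        row_tot = n_exp.sum(axis=1)
        brides = _realise_counts(row_tot, rng)
        if brides.sum() == 0:
            return
        by_age_f: dict[int, list[int]] = {}
        by_age_m: dict[int, list[int]] = {}
        for idx in np.flatnonzero(f_mask):
            by_age_f.setdefault(int(start_age[idx]), []).append(int(idx))
        for idx in np.flatnonzero(m_mask):
            by_age_m.setdefault(int(start_age[idx]), []).append(int(idx))
        for lst in by_age_f.values():
            rng.shuffle(lst)
        for lst in by_age_m.values():
            rng.shuffle(lst)
        for i in rng.permutation(np.flatnonzero(brides)):
            i = int(i)
            q = n_exp[i] / row_tot[i]
            for _ in range(int(brides[i])):
                if not by_age_f.get(i):
                    break
                target_j = int(rng.choice(w, p=q))
                avail = [j for j, lst in by_age_m.items() if lst]
                if not avail:
                    return
                j = min(avail, key=lambda a: (abs(a - target_j), a))
                fi = by_age_f[i].pop()
                mi = by_age_m[j].pop()
                _marry(st, fi, mi, hh, hh_type, hh_area, new_household)
                new_pairs.append((fi, mi))

    realise_marriages(0, mu1)
    realise_marriages(2, mu2)

    # --- divorces and births, drawn per start-of-period couple ------------
    births: list[tuple[int, int]] = []
    if start_couples:
        fis = np.array([c[0] for c in start_couples])
        mis = np.array([c[1] for c in start_couples])
        ii, jj = start_age[fis], start_age[mis]
        div_draw = rng.random(len(fis)) < nu[ii, jj]
        birth_draw = rng.random(len(fis)) < b[ii, jj]
        for k in np.flatnonzero(div_draw):
            _divorce(st, int(fis[k]), int(mis[k]), hh, hh_type, hh_area, new_household)
        births = [(int(fis[k]), int(mis[k])) for k in np.flatnonzero(birth_draw)]

    # --- deaths (start-of-period age-specific rates) ----------------------
    p_death = np.where(st.sex == 1, d_m[start_age], d_f[start_age])
    died = rng.random(n0) < p_death
    alive &= ~died
    ledger.deaths = float(died.sum())
    for fi, mi in start_couples:
        if died[mi] and not died[fi] and st.marital[fi] != 1:
            st.marital[fi] = 2  # incl. same-period divorce: still widowed
        elif died[mi] and not died[fi] and st.partner[fi] == mi:
            st.marital[fi] = 2
            st.partner[fi] = -1
        if died[fi] and not died[mi] and st.marital[mi] != 1:
            st.marital[mi] = 2
        elif died[fi] and not died[mi] and st.partner[mi] == fi:
            st.marital[mi] = 2
            st.partner[mi] = -1
    for fi, mi in new_pairs:
        if died[mi] and not died[fi] and st.partner[fi] == mi:
            st.marital[fi] = 0  # new spouse lost: single again, not widowed
            st.partner[fi] = -1
        if died[fi] and not died[mi] and st.partner[mi] == fi:
            st.marital[mi] = 0
            st.partner[mi] = -1

    # --- leaving the parental home (dependants strictly over 15) ----------
    eligible = np.flatnonzero(alive & (st.role == 1) & (start_age > 15))
    if len(eligible):
        # eldest eligible daughter and son per household may leave
        order = np.lexsort((-start_age[eligible], st.sex[eligible], hh[eligible]))
        seen: set[tuple[int, int]] = set()
        for idx in eligible[order]:
            key = (int(hh[idx]), int(st.sex[idx]))
            if key in seen:
                continue
            seen.add(key)
            lam = lam_m if st.sex[idx] == 1 else lam_f
            if rng.random() < lam[start_age[idx]]:
                st.role[idx] = 0
                hh[idx] = new_household(hh_area[int(hh[idx])])

    # --- emigration -------------------------------------------------------
    p_emi = np.where(st.sex == 1, emi_m[start_age], emi_f[start_age])
    emigrated = alive & (rng.random(n0) < p_emi)
    alive &= ~emigrated
    ledger.emigrants = float(emigrated.sum())
    for idx in np.flatnonzero(emigrated):
        p = st.partner[idx]
        if p >= 0 and alive[p] and st.partner[p] == idx:
            st.marital[p] = 0  # emigration dissolves the couple, no widowhood
            st.partner[p] = -1

    # --- ageing and maximum-age exits -------------------------------------
    if ageing:
        st.age = st.age + 1
        exits = alive & (st.age >= w)
        ledger.exits = float(exits.sum())
        for idx in np.flatnonzero(exits):
            p = st.partner[idx]
            if p >= 0 and alive[p] and st.age[p] < w and st.partner[p] == idx:
                st.marital[p] = 2  # ageing out counts as a death
                st.partner[p] = -1
        alive &= ~exits

    # --- newborns ---------------------------------------------------------
    baby_rows = []
    for fi, mi in births:
        if alive[fi]:
            target = int(hh[fi])
        elif alive[mi]:
            target = int(hh[mi])
        else:
            target = new_household(hh_area[int(hh[fi])])
        baby_rows.append((target, 1 if rng.random() < male_birth_fraction else 0))
    ledger.births = float(len(baby_rows))

    return _compact(st, alive, hh, hh_type, hh_area, baby_rows), ledger


def _marry(st, fi, mi, hh, hh_type, hh_area, new_household) -> None:
    st.marital[fi] = st.marital[mi] = 1
    st.partner[fi], st.partner[mi] = mi, fi
    st.role[fi] = st.role[mi] = 0
    new_hh = new_household(hh_area[int(hh[fi])])
    for spouse in (fi, mi):
        old = int(hh[spouse])
        members = np.flatnonzero(hh == old)
        other_adults = [m for m in members if m != spouse and st.role[m] == 0]
        hh[spouse] = new_hh
        if not other_adults:  # a sole parent brings the children along
            for m in members:
                if st.role[m] == 1:
                    hh[m] = new_hh


def _divorce(st, fi, mi, hh, hh_type, hh_area, new_household) -> None:
    st.marital[fi] = st.marital[mi] = 0
    st.partner[fi] = st.partner[mi] = -1
    hh[mi] = new_household(hh_area[int(hh[mi])])  # children stay with the mother


def _compact(st: MicroState, alive, hh, hh_type, hh_area, baby_rows) -> MicroState:
    """Drop the dead, append newborns, renumber and re-derive hh types."""
    keep = np.flatnonzero(alive)
    remap = np.full(st.n_persons, -1, np.int64)
    remap[keep] = np.arange(len(keep))

    age = st.age[keep]
    sex = st.sex[keep]
    role = st.role[keep]
    marital = st.marital[keep]
    partner = st.partner[keep]
    ok = partner >= 0
    partner[ok] = remap[partner[ok]]
    # a partner who vanished without explicit handling leaves a single
    broken = ok & (partner < 0)
    marital[broken & (marital == 1)] = 0
    hh_new = hh[keep]

    if baby_rows:
        b_hh = np.array([r[0] for r in baby_rows], np.int64)
        b_sex = np.array([r[1] for r in baby_rows], np.int8)
        age = np.concatenate([age, np.zeros(len(baby_rows), np.int64)])
        sex = np.concatenate([sex, b_sex])
        role = np.concatenate([role, np.ones(len(baby_rows), np.int8)])
        marital = np.concatenate([marital, np.zeros(len(baby_rows), np.int8)])
        partner = np.concatenate([partner, np.full(len(baby_rows), -1, np.int64)])
        hh_new = np.concatenate([hh_new, b_hh])

    # renumber households that still have members
    used, hh_codes = np.unique(hh_new, return_inverse=True)
    area = np.array([hh_area[int(u)] for u in used], dtype=object)

    # derive household types from composition
    m = len(used)
    adult_f = np.bincount(hh_codes[(role == 0) & (sex == 0)], minlength=m)
    adult_m = np.bincount(hh_codes[(role == 0) & (sex == 1)], minlength=m)
    childs = np.bincount(hh_codes[role == 1], minlength=m)
    # a sole surviving dependent child becomes an independent adult
    orphan_hh = np.flatnonzero((adult_f + adult_m == 0) & (childs == 1))
    if len(orphan_hh):
        promote = np.isin(hh_codes, orphan_hh) & (role == 1)
        role = role.copy()
        role[promote] = 0
        adult_f = np.bincount(hh_codes[(role == 0) & (sex == 0)], minlength=m)
        adult_m = np.bincount(hh_codes[(role == 0) & (sex == 1)], minlength=m)
        childs = np.bincount(hh_codes[role == 1], minlength=m)
    types = np.array(
        [derive_hh_type(int(f), int(mm), int(c)) for f, mm, c in zip(adult_f, adult_m, childs)],
        dtype=object,
    )
    return MicroState(
        age, sex, role, marital, partner, hh_codes.astype(np.int64),
        types, area, st.w, st.t + 1,
    )


def add_immigrants(micro: MicroState, volume: int, rng: np.random.Generator) -> MicroState:
    """Append ``volume`` immigrant households cloned from the current state.

    Cloning whole households uniformly at random reproduces the empirical
    joint distribution of household type, member ages and sexes.
    """
    if volume < 0:
        raise ValueError("immigrant volume must be non-negative")
    if volume == 0:
        return micro.copy()
    if micro.n_households == 0:
        raise ValueError("cannot draw immigrants from an empty population")
    st = micro.copy()
    chosen = rng.integers(0, st.n_households, size=volume)
    new_arrays = {k: [getattr(st, k)] for k in ("age", "sex", "role", "marital", "partner", "hh")}
    next_hh = st.n_households
    next_person = st.n_persons
    types = list(st.hh_type)
    areas = list(st.hh_area)
    for h in chosen:
        members = np.flatnonzero(st.hh == h)
        remap = {int(m): next_person + k for k, m in enumerate(members)}
        new_arrays["age"].append(st.age[members])
        new_arrays["sex"].append(st.sex[members])
        new_arrays["role"].append(st.role[members])
        new_arrays["marital"].append(st.marital[members])
        new_arrays["partner"].append(
            np.array([remap.get(int(p), -1) if p >= 0 else -1 for p in st.partner[members]], np.int64)
        )
        new_arrays["hh"].append(np.full(len(members), next_hh, np.int64))
        types.append(st.hh_type[h])
        areas.append(st.hh_area[h])
        next_hh += 1
        next_person += len(members)
    return MicroState(
        np.concatenate(new_arrays["age"]),
        np.concatenate(new_arrays["sex"]),
        np.concatenate(new_arrays["role"]),
        np.concatenate(new_arrays["marital"]),
        np.concatenate(new_arrays["partner"]),
        np.concatenate(new_arrays["hh"]),
        np.array(types, dtype=object),
        np.array(areas, dtype=object),
        st.w,
        st.t,
    )


@dataclass
class Trajectory:
    """Evolution output: one state per period boundary plus step ledgers."""

    states: list
    ledgers: list[StepLedger] = field(default_factory=list)

    def totals(self) -> list[float]:
        out = []
        for s in self.states:
            out.append(s.total() if isinstance(s, PopulationState) else float(s.n_persons))
        return out


def evolve(
    baseline,
    rates: VitalRates,
    years: int,
    mode: str = "deterministic",
    seed: int = 0,
    n_periods: int = 1,
    immigrant_households_per_year: int = 0,
    male_birth_fraction: float = MALE_BIRTH_FRACTION,
) -> Trajectory:
    """Evolve a baseline population over ``years`` years.

    ``baseline`` is a :class:`Population`, :class:`MicroState` or
    :class:`PopulationState`.  Deterministic mode is bit-for-bit
    reproducible; micro mode is reproducible under a fixed seed.  Each year
    is divided into ``n_periods`` periods (annual probabilities are
    converted via q = 1 - (1-p)^(1/n)); ageing happens on the last period
    of each year, and immigrants are appended at the end of each year.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if mode not in ("deterministic", "micro"):
        raise ValueError("mode must be 'deterministic' or 'micro'")
    period_rates = rates.per_period(n_periods)

    if isinstance(baseline, Population):
        state = MicroState.from_population(baseline, w=rates.w)
    else:
        state = baseline
    if mode == "deterministic" and isinstance(state, MicroState):
        state = state.tally()
    if mode == "micro" and isinstance(state, PopulationState):
        raise TypeError("micro mode needs record-level input")

    rng_streams = np.random.SeedSequence(seed).spawn(years)
    states = [state]
    ledgers: list[StepLedger] = []
    for year in range(years):
        year_streams = rng_streams[year].spawn(n_periods + 1)
        for k in range(n_periods):
            is_last = k == n_periods - 1
            if mode == "deterministic":
                state, ledger = step_deterministic(
                    state, period_rates, male_birth_fraction, ageing=is_last
                )
            else:
                rng = np.random.default_rng(year_streams[k])
                state, ledger = step_micro(
                    state, period_rates, rng, male_birth_fraction, ageing=is_last
                )
            ledgers.append(ledger)
        if immigrant_households_per_year and mode == "micro":
            rng = np.random.default_rng(year_streams[-1])
            state = add_immigrants(state, immigrant_households_per_year, rng)
        states.append(state)
    return Trajectory(states, ledgers)
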