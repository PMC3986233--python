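"""Two-sex dynamics: reference models, deterministic step, micro step."""

import numpy as np
import pytest

import dynapop as dp
from dynapop.dynamics import (
    MALE_BIRTH_FRACTION,
    MicroState,
    PopulationState,
    StepLedger,
    add_immigrants,
    evolve,
    match_couples,
    step_deterministic,
    step_micro,
)
from dynapop.rates import rates_from_records, zero_rates


def make_state(w=100, **cells):
    st = PopulationState.empty(w)
    for key, value in cells.items():
        name, idx = key.split("_", 1)
        if name == "C":
            i, j = map(int, idx.split("_"))
            st.couples[i, j] = value
        else:
            getattr(st, name)[int(idx)] = value
    return st


class TestReferenceModels:
    def test_malthusian(self):
        assert dp.malthusian_projection(1000, 0.0, 7) == 1000
        assert dp.malthusian_projection(1000, 0.02, 2) == pytest.approx(1040.4)
        with pytest.raises(ValueError):
            dp.malthusian_projection(1000, -1.5, 1)

    def test_logistic(self):
        assert dp.logistic_growth_step(50.0, 0.1, 50.0) == 50.0  # zero growth at L
        assert dp.logistic_growth_step(0.0, 0.1, 50.0) == 0.0
        assert dp.logistic_growth_step(10.0, 0.1, 50.0) > 10.0
        assert dp.logistic_growth_step(80.0, 0.1, 50.0) < 80.0
        with pytest.raises(ValueError):
            dp.logistic_growth_step(1.0, 0.1, 0.0)


class TestMatchCouples:
    def test_no_single_males_no_couples(self):
        sf = np.full(10, 5.0)
        n = match_couples(sf, np.zeros(10), np.full((10, 10), 0.5))
        assert n.sum() == 0.0

    def test_harmonic_mean_equal_counts(self):
        sf = np.zeros(4)
        sm = np.zeros(4)
        sf[1] = sm[2] = 10.0
        mu = np.zeros((4, 4))
        mu[1, 2] = 0.1
        n = match_couples(sf, sm, mu)
        assert n[1, 2] == pytest.approx(1.0)  # 0.1 * harmonic(10, 10)

    def test_margins_never_exceed_singles(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            w = 12
            sf = rng.integers(0, 6, w).astype(float)
            sm = rng.integers(0, 6, w).astype(float)
            mu = rng.random((w, w))
            n = match_couples(sf, sm, mu)
            assert (n >= 0).all()
            assert (n.sum(axis=1) <= sf + 1e-9).all()
            assert (n.sum(axis=0) <= sm + 1e-9).all()


class TestStepDeterministic:
    def test_rates_off_pure_ageing(self):
        st = make_state(pf_10=30, pm_20=40, C_30_32=5, wf_50=3, wm_60=2)
        st.pf[30] = 5
        st.pm[32] = 5
        out, ledger = step_deterministic(st, zero_rates())
        assert out.pf[11] == 30 and out.pm[21] == 40
        assert out.couples[31, 33] == 5
        assert out.wf[51] == 3 and out.wm[61] == 2
        assert out.total() == st.total()
        assert ledger.deaths == ledger.births == ledger.exits == 0

    def test_widow_recursion_worked_example(self):
        # W' = (5 + 10 * 0.1) * 1 = 6
        rates = rates_from_records(
            [{"event": "death", "sex": "M", "age_band": "45-45", "rate": 0.1, "per": 1}]
        )
        st = make_state(pf_40=30, pm_45=20, C_40_45=10, wf_40=5)
        out, _ = step_deterministic(st, rates)
        assert out.wf[41] == pytest.approx(6.0)

    def test_couples_update_worked_example(self):
        # C' = (100 + 5 - 10) * 0.9^2 = 76.95
        rates = rates_from_records(
            [
                {"event": "death", "sex": "M", "age_band": "45-45", "rate": 0.1, "per": 1},
                {"event": "death", "sex": "F", "age_band": "40-40", "rate": 0.1, "per": 1},
                {"event": "divorce", "sex": "", "age_band": "40-40",
                 "age_band_partner": "45-45", "rate": 0.1, "per": 1},
                {"event": "marriage1", "sex": "", "age_band": "40-40",
                 "age_band_partner": "45-45", "rate": 0.05, "per": 1},
            ]
        )
        st = make_state(pf_40=200, pm_45=200, C_40_45=100)
        # singles: 100 females age 40, 100 males age 45; harmonic mean 100
        out, _ = step_deterministic(st, rates)
        assert out.couples[41, 46] == pytest.approx(76.95)

    def test_accounting_identity_random_rates(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            w = 100
            records = []
            for sex in "FM":
                for lo in range(0, w, 10):
                    band = f"{lo}-{lo + 9}"
                    records.append({"event": "death", "sex": sex, "age_band": band,
                                    "rate": rng.uniform(0, 0.3), "per": 1})
                    records.append({"event": "immigration", "sex": sex, "age_band": band,
                                    "rate": rng.uniform(0, 0.1), "per": 1})
                    records.append({"event": "emigration", "sex": sex, "age_band": band,
                                    "rate": rng.uniform(0, 0.1), "per": 1})
            records.append({"event": "birth", "sex": "F", "age_band": "15-49",
                            "rate": rng.uniform(0, 0.3), "per": 1})
            rates = rates_from_records(records)
            st = PopulationState.empty(w)
            st.pf[:] = rng.integers(0, 60, w)
            st.pm[:] = rng.integers(0, 60, w)
            for _ in range(40):
                i, j = rng.integers(15, 95, 2)
                add = min(st.pf[i], st.pm[j], 4)
                st.couples[i, j] += add
            state = st
            for _ in range(5):
                before = state.total()
                state, led = step_deterministic(state, rates)
                balance = (before + led.births + led.immigrants
                           - led.deaths - led.emigrants - led.exits)
                assert state.total() == pytest.approx(balance, abs=1e-9)

    def test_negative_mass_clamped_and_logged(self, caplog):
        # remarriage outflow exceeding the widow stock after rounding noise
        rates = rates_from_records(
            [{"event": "death", "sex": "F", "age_band": "0+", "rate": 1.5, "per": 1}]
        )
        st = make_state(pf_30=10)
        out, ledger = step_deterministic(st, rates)
        assert (out.pf >= 0).all()  # death prob clipped to 1, no negatives


class TestEvolveDeterministic:
    def test_exponential_law_reduction(self):
        records = [{"event": "immigration", "sex": s, "age_band": "0+", "rate": 0.02, "per": 1}
                   for s in "FM"]
        rates = rates_from_records(records)
        st = make_state(pf_10=500, pm_20=500)
        traj = evolve(st, rates, 10, mode="deterministic")
        expected = dp.malthusian_projection(1000, 0.02, 10)
        assert traj.totals()[-1] == pytest.approx(expected, rel=1e-12)

    def test_rates_off_totals_constant_ages_shift(self):
        st = make_state(pf_10=100, pm_12=80)
        traj = evolve(st, zero_rates(), 5, mode="deterministic")
        assert traj.totals() == [180.0] * 6
        assert traj.states[-1].pf[15] == 100
        assert traj.states[-1].pm[17] == 80


def micro_from_config(seed=5, persons=400):
    cfg = dp.RegionConfig(n_areas=1, persons_per_area=persons, seed=seed)
    return MicroState.from_population(dp.generate_true_population(cfg))


class TestStepMicro:
    def test_rates_off_identity_plus_ageing(self):
        micro = micro_from_config()
        out, ledger = step_micro(micro, zero_rates(), np.random.default_rng(0))
        assert out.n_persons == micro.n_persons
        assert (np.sort(out.age) == np.sort(micro.age + 1)).all()
        assert out.hh_type_counts() == micro.hh_type_counts()
        assert ledger.deaths == 0 and ledger.births == 0

    def test_certain_death_empties_population(self):
        micro = micro_from_config()
        rates = rates_from_records(
            [{"event": "death", "sex": s, "age_band": "0+", "rate": 1.0, "per": 1} for s in "FM"]
        )
        out, ledger = step_micro(micro, rates, np.random.default_rng(0))
        assert out.n_persons == 0
        assert ledger.deaths == micro.n_persons

    def test_seeded_reproducibility(self, full_rates):
        micro = micro_from_config()
        a, _ = step_micro(micro, full_rates, np.random.default_rng(33))
        b, _ = step_micro(micro, full_rates, np.random.default_rng(33))
        assert (a.age == b.age).all()
        assert (a.hh == b.hh).all()
        assert list(a.hh_type) == list(b.hh_type)

    def test_tally_roundtrip_and_validity(self, full_rates):
        micro = micro_from_config()
        out, _ = step_micro(micro, full_rates, np.random.default_rng(1))
        pop = out.to_population()
        pop.validate()
        st = out.tally()
        st.validate()
        assert st.total() == out.n_persons

    def test_micro_mean_matches_deterministic(self, full_rates):
        """Replicate-mean of micro steps converges on the deterministic step.

        Cells: 5-year age bands for female/male/widow/widower counts and
        10-year band pairs for couples; agreement within 3 Monte-Carlo SEs
        for at least 95% of cells (120 replicates here; the experiments
        module runs the full 500-replicate version).
        """
        micro = micro_from_config(seed=5, persons=800)
        det, _ = step_deterministic(micro.tally(), full_rates)
        runs = 120
        acc = []
        for k in range(runs):
            out, _ = step_micro(micro, full_rates, np.random.default_rng(9000 + k))
            st = out.tally()
            acc.append(_banded_cells(st))
        acc = np.array(acc)
        target = _banded_cells(det)
        mean = acc.mean(axis=0)
        se = acc.std(axis=0, ddof=1) / np.sqrt(runs)
        ok = np.where(se > 0, np.abs(mean - target) <= 3 * se, np.abs(mean - target) < 1e-9)
        assert ok.mean() >= 0.95


def _banded_cells(st: PopulationState) -> np.ndarray:
    w = st.w
    b5 = np.add.reduceat(np.eye(w), range(0, w, 5), axis=0)
    b10 = np.add.reduceat(np.eye(w), range(0, w, 10), axis=0)
    return np.concatenate([
        b5 @ st.pf, b5 @ st.pm, b5 @ st.wf, b5 @ st.wm,
        (b10 @ st.couples @ b10.T).ravel(),
    ])


class TestAddImmigrants:
    def test_volume_zero_identity(self):
        micro = micro_from_config()
        out = add_immigrants(micro, 0, np.random.default_rng(0))
        assert out.n_persons == micro.n_persons

    def test_forced_distribution(self):
        cfg = dp.RegionConfig(
            n_areas=1, households_per_area=5, hh_type_mixture={"lone_person": 1.0}, seed=1
        )
        micro = MicroState.from_population(dp.generate_true_population(cfg))
        out = add_immigrants(micro, 10, np.random.default_rng(0))
        assert out.n_households == 15
        assert all(t == "lone_person" for t in out.hh_type)

    def test_sampling_consistency_chi2(self):
        from scipy import stats

        micro = micro_from_config(persons=2000)
        out = add_immigrants(micro, 10_000, np.random.default_rng(3))
        base = micro.hh_type_counts()
        newcomers = {
            t: out.hh_type_counts()[t] - base[t] for t in base
        }
        expected_p = np.array([base[t] for t in base], float)
        expected_p /= expected_p.sum()
        observed = np.array([newcomers[t] for t in base], float)
        res = stats.chisquare(observed, expected_p * observed.sum())
        assert res.pvalue > 0.01

    def test_empty_population_rejected(self):
        micro = micro_from_config()
        empty = MicroState(
            *(a[:0] for a in (micro.age, micro.sex, micro.role, micro.marital, micro.partner, micro.hh)),
            micro.hh_type[:0], micro.hh_area[:0], micro.w,
        )
        with pytest.raises(ValueError):
            add_immigrants(empty, 5, np.random.default_rng(0))


class TestEvolveMicro:
    def test_seeded_trajectory_reproducible(self, full_rates):
        micro = micro_from_config()
        t1 = evolve(micro, full_rates, 3, mode="micro", seed=77)
        t2 = evolve(micro, full_rates, 3, mode="micro", seed=77)
        assert t1.totals() == t2.totals()
        assert (t1.states[-1].age == t2.states[-1].age).all()

    def test_rates_off_five_years(self):
        micro = micro_from_config()
        traj = evolve(micro, zero_rates(), 5, mode="micro", seed=1)
        assert traj.totals() == [float(micro.n_persons)] * 6
        assert (np.sort(traj.states[-1].age) == np.sort(micro.age + 5)).all()

    def test_immigration_grows_population(self, full_rates):
        micro = micro_from_config()
        traj = evolve(micro, zero_rates(), 2, mode="micro", seed=1,
                      immigrant_households_per_year=10)
        assert traj.states[-1].n_households == micro.n_households + 20
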