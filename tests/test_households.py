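"""Household-type transitions: event composition and the HHT matrix."""

import itertools

import numpy as np
import pytest

import dynapop.households as hh
from dynapop.rates import rates_from_records, zero_rates

B_AD = (35, 55)
COUPLE = hh.HouseholdState(B_AD, B_AD, ())
CWC1 = hh.HouseholdState(B_AD, B_AD, (("F", (0, 16)),))
LONE_F = hh.HouseholdState(B_AD, None, ())
ONE_PARENT = hh.HouseholdState(B_AD, None, (("F", (0, 16)),))


def simple_rates(**overrides):
    values = {"death": 0.05, "birth": 0.1, "marriage1": 0.05, "marriage2": 0.02,
              "divorce": 0.02, "leaving_home": 0.1}
    values.update(overrides)
    recs = [{"event": "death", "sex": s, "age_band": "0+", "rate": values["death"], "per": 1}
            for s in "FM"]
    recs += [{"event": "birth", "sex": "F", "age_band": "15-49", "rate": values["birth"], "per": 1}]
    for ev in ("marriage1", "marriage2", "divorce"):
        recs += [{"event": ev, "sex": "", "age_band": "15+", "age_band_partner": "15+",
                  "rate": values[ev], "per": 1}]
    recs += [{"event": "leaving_home", "sex": s, "age_band": "16+", "rate": values["leaving_home"],
              "per": 1} for s in "FM"]
    return rates_from_records(recs)


class TestApplyAndEnumerate:
    def test_identity_contains_all_zero_vector(self):
        assert tuple([0] * 10) in hh.enumerate_indicators(COUPLE, COUPLE)

    def test_couple_to_one_parent_requires_a_birth(self):
        # with no children present, the only route is birth + losing one adult
        cases = hh.enumerate_indicators(
            COUPLE, hh.HouseholdState(B_AD, None, (("F", (0, 16)),))
        )
        assert cases  # reachable via a compound outcome
        birth = hh.EVENTS.index("birth")
        assert all(d[birth] == 1 for d in cases)

    def test_unreachable_transition_empty(self):
        # a lone person cannot gain two children in one period
        target = hh.HouseholdState(B_AD, None, (("F", (0, 16)), ("M", (0, 16))))
        assert hh.enumerate_indicators(LONE_F, target) == []

    def test_exhaustive_oracle_couple_with_child_to_lone(self):
        # oracle: brute-force over all 2^10 outcome applications
        expected = [
            d for d in itertools.product((0, 1), repeat=10)
            if hh.apply_events(CWC1, d) == LONE_F
        ]
        assert hh.enumerate_indicators(CWC1, LONE_F) == expected
        assert len(expected) > 0


class TestCaseProbability:
    def test_zero_pi_active_component(self):
        pi = np.zeros(10)
        delta = np.zeros(10, int)
        delta[3] = 1
        assert hh.case_probability(delta, pi) == 0.0

    def test_nothing_happens(self):
        assert hh.case_probability(np.zeros(10, int), np.zeros(10)) == 1.0

    def test_product_form(self):
        pi = np.zeros(10)
        pi[0], pi[1] = 0.2, 0.5
        delta = np.zeros(10, int)
        delta[0] = delta[1] = 1
        assert hh.case_probability(delta, pi) == pytest.approx(0.1)

    def test_monte_carlo_agreement(self):
        """Closed form equals Bernoulli-simulation frequency within 3 SEs."""
        rng = np.random.default_rng(12)
        n = 200_000
        for _ in range(5):
            pi = rng.random(10)
            delta = rng.integers(0, 2, 10)
            draws = rng.random((n, 10)) < pi
            match = (draws == delta.astype(bool)).all(axis=1)
            p_hat = match.mean()
            p = hh.case_probability(delta, pi)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) <= 3 * se + 1e-12


class TestUnionProbability:
    def test_inclusion_exclusion_two_events(self):
        pi = np.zeros(10)
        pi[0], pi[1] = 0.3, 0.2
        # P(A u B) = 0.3 + 0.2 - 0.06
        assert hh.union_probability([((0,), ()), ((1,), ())], pi) == pytest.approx(0.44)

    def test_agrees_with_plain_sum_on_disjoint_full_cases(self):
        rng = np.random.default_rng(5)
        pi = rng.random(10)
        deltas = [tuple(rng.integers(0, 2, 10)) for _ in range(4)]
        deltas = list(dict.fromkeys(deltas))  # distinct full outcomes are disjoint
        cases = [
            (tuple(np.flatnonzero(d)), tuple(np.flatnonzero(1 - np.array(d))))
            for d in deltas
        ]
        plain = sum(hh.case_probability(d, pi) for d in deltas)
        assert hh.union_probability(cases, pi) == pytest.approx(plain, abs=1e-12)

    def test_contradictory_case_rejected(self):
        with pytest.raises(ValueError):
            hh.union_probability([((0,), (0,))], np.zeros(10))


class TestTransitionProbability:
    def test_sums_to_one_over_destinations(self):
        rng = np.random.default_rng(3)
        for g1 in (COUPLE, CWC1, ONE_PARENT, LONE_F):
            for _ in range(3):
                pi = rng.random(10)
                dests = {hh.apply_events(g1, d) for d in itertools.product((0, 1), repeat=10)}
                total = sum(hh.transition_probability(g1, g2, pi) for g2 in dests)
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_is_zero(self):
        target = hh.HouseholdState(B_AD, None, (("F", (0, 16)), ("M", (0, 16))))
        assert hh.transition_probability(LONE_F, target, np.full(10, 0.3)) == 0.0


@pytest.fixture(scope="module")
def small_states():
    # births can add a child up to the global tracking cap, so the state
    # list must be enumerated at that cap for closure under transitions
    return hh.enumerate_states(
        adult_bands=[(15, 55), (55, 100)], child_bands=[(0, 16), (16, 30)],
        max_children=hh.MAX_TRACKED_CHILDREN,
    )


class TestBuildMatrix:

    def test_zero_rates_identity(self, small_states):
        tm = hh.build_hht_matrix(small_states, zero_rates())
        np.testing.assert_allclose(tm.matrix[:, : len(small_states)], np.eye(len(small_states)))
        assert tm.matrix[:, -1].max() == 0.0

    def test_rows_sum_to_one(self, small_states):
        tm = hh.build_hht_matrix(small_states, simple_rates())
        np.testing.assert_allclose(tm.row_sums(), 1.0, atol=1e-12)

    def test_certain_adult_death_dissolves_couples(self, small_states):
        tm = hh.build_hht_matrix(small_states, simple_rates(death=1.0, birth=0.0,
                                                            marriage1=0.0, marriage2=0.0))
        for i, s in enumerate(small_states):
            if s.hh_type == "couple_only":
                # all mass on extinction (both adults die with certainty)
                assert tm.matrix[i, -1] == pytest.approx(1.0)

    def test_event_probabilities_inapplicable_zero(self):
        pi = hh.event_probabilities(LONE_F, simple_rates())
        assert pi[hh.EVENTS.index("birth")] == 0.0
        assert pi[hh.EVENTS.index("divorce")] == 0.0
        assert pi[hh.EVENTS.index("death_male_adult")] == 0.0
        assert pi[hh.EVENTS.index("first_marriage")] > 0.0


class TestProjectHouseholds:
    def test_identity_matrix_constant(self):
        states = hh.enumerate_states(adult_bands=[(15, 100)], child_bands=[(0, 16)],
                                     max_children=1)
        tm = hh.build_hht_matrix(states, zero_rates())
        counts = np.arange(1.0, len(states) + 1)
        traj = hh.project_households(counts, tm, 3)
        np.testing.assert_allclose(traj[-1][:-1], counts)

    def test_two_state_chain_matches_matrix_power(self):
        states = [hh.HouseholdState((15, 100), None, ()),
                  hh.HouseholdState((15, 100), (15, 100), ())]
        tm = hh.build_hht_matrix(states, simple_rates(death=0.0, birth=0.0,
                                                      divorce=0.1, marriage1=0.2,
                                                      marriage2=0.0, leaving_home=0.0))
        full = np.vstack([tm.matrix, np.eye(1, 3, 2)])
        counts = np.array([30.0, 10.0, 0.0])
        traj = hh.project_households(counts, tm, 3)
        np.testing.assert_allclose(traj[-1], counts @ np.linalg.matrix_power(full, 3))
        assert (traj >= 0).all()
        # total household mass conserved including the extinct stock
        np.testing.assert_allclose(traj.sum(axis=1), counts.sum())

    def test_dimension_mismatch_rejected(self):
        states = [COUPLE, LONE_F]
        tm = hh.build_hht_matrix(states, zero_rates())
        with pytest.raises(ValueError):
            hh.project_households(np.ones(5), tm, 2)


class TestMicroConsistency:
    def test_hh_type_transition_frequencies_match_matrix(self):
        """One micro step on many couple households vs the matrix row.

        Divorce and leaving-home are disabled so no event spawns a second
        household and every original household maps to exactly one
        destination type (or extinction); micro frequencies then estimate
        the matrix row marginalised to household types.
        """
        import dynapop as dp
        from dynapop.dynamics import MicroState, step_micro

        rates = simple_rates(divorce=0.0, leaving_home=0.0)
        n_hh = 4000
        cfg = dp.RegionConfig(
            n_areas=1, households_per_area=n_hh, seed=50,
            hh_type_mixture={"couple_only": 1.0},
            adult_age_bands=[(35, 50, 1.0)],
            age_gap_range=(0, 0),
        )
        micro = MicroState.from_population(dp.generate_true_population(cfg))
        out, _ = step_micro(micro, rates, np.random.default_rng(8))
        counts = out.hh_type_counts()
        counts["extinct"] = n_hh - out.n_households

        states = hh.enumerate_states(adult_bands=[(35, 51)], child_bands=[(0, 16)],
                                     max_children=2)
        tm = hh.build_hht_matrix(states, rates)
        src = hh.HouseholdState((35, 51), (35, 51), ())
        i = states.index(src)
        dest_types = [s.hh_type for s in states] + ["extinct"]
        p_by_type: dict[str, float] = {}
        for t, p in zip(dest_types, tm.matrix[i]):
            p_by_type[t] = p_by_type.get(t, 0.0) + p
        for t, p in p_by_type.items():
            expect = n_hh * p
            se = np.sqrt(n_hh * p * (1 - p))
            assert abs(counts.get(t, 0) - expect) <= 3 * se + 1e-9
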