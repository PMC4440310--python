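"""Simulation engine: annual-step mechanics, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest

import quotasim as q
from quotasim.errors import ValidationError

from _oracle import Group, oracle_trajectory
from conftest import degenerate_marginals, make_roster


def run_engine(roster, marginals, scenario, seed=0):
    traj = q.simulate_replicate(roster, scenario, seed, marginals)
    return traj.set_index("year")


class TestAnnualStep:
    def test_hand_traced_vacancy_chain(self, marginals):
        """Retirement frees a fixed post, the senior registrar fills it, the
        certifying trainee backfills transition, a new entrant refills training."""
        roster = make_roster([
            dict(state="FIXED", age=64.5, desired_retirement_age=65.0,
                 years_in_state=10.0),
            dict(state="TRANSITION", age=40.0, years_in_state=3.0),
            dict(state="TRAINING", age=30.0, years_in_state=4.5),
        ])
        scenario = q.PolicyScenario(quota=1, fixed_capacity=1,
                                    foreign_departure_hazard=0.0)
        after, record = q.annual_step(roster, scenario, 0, marginals)
        assert record["n_retired"] == 1
        assert record["n_training"] == record["n_transition"] == record["n_fixed"] == 1
        states = after.set_index("person_id")["state"]
        assert states[0] == "RETIRED"
        assert states[1] == "FIXED"
        assert states[2] == "TRANSITION"
        assert states[3] == "TRAINING"  # the new entrant

    def test_empty_roster_is_refilled_to_quota(self, marginals):
        scenario = q.PolicyScenario(quota=66, foreign_departure_hazard=0.0)
        after, record = q.annual_step(make_roster([]), scenario, 0, marginals)
        assert record["n_training"] == 66
        assert record["n_transition"] == record["n_fixed"] == 0
        assert record["n_retired"] == 0
        assert len(after) == 66

    def test_certifying_foreign_trainee_departs_under_return_policy(self, marginals):
        roster = make_roster([
            dict(state="TRAINING", age=30.0, years_in_state=4.5,
                 nationality="foreign"),
        ])
        scenario = q.PolicyScenario(quota=0, foreign_departure_hazard=0.0)
        after, record = q.annual_step(roster, scenario, 0, marginals)
        assert record["n_departed"] == 1
        assert record["n_transition"] == 0
        assert after.loc[0, "state"] == "DEPARTED"

    def test_certifying_foreign_trainee_stays_without_return_policy(self, marginals):
        roster = make_roster([
            dict(state="TRAINING", age=30.0, years_in_state=4.5,
                 nationality="foreign"),
        ])
        scenario = q.PolicyScenario(quota=0, fixed_capacity=0, return_policy=False,
                                    foreign_departure_hazard=0.0)
        _, record = q.annual_step(roster, scenario, 0, marginals)
        assert record["n_departed"] == 0
        assert record["n_transition"] == 1


# Degenerate scenarios where every flow is deterministic; the per-person engine
# must equal the aggregate stock-and-flow recurrence exactly.
def _s1_empty_pipeline():
    return (
        [], [],
        dict(quota=5, capacity=3, n_years=4),
        dict(quota=5, fixed_capacity=3), 0.0,
    )


def _s2_training_wave():
    rows = [dict(state="TRAINING", age=26.0, years_in_state=0.0) for _ in range(10)]
    groups = [Group("TRAINING", 10, 26.0, 0.0)]
    return (
        rows, groups,
        dict(quota=10, capacity=3, n_years=11),
        dict(quota=10, fixed_capacity=3), 0.0,
    )


def _s3_foreign_pipeline_drains():
    rows = [dict(state="TRAINING", age=28.0, years_in_state=2.0,
                 nationality="foreign") for _ in range(6)]
    groups = [Group("TRAINING", 6, 28.0, 2.0, foreign=True)]
    return (
        rows, groups,
        dict(quota=6, capacity=2, n_years=9, entrant_foreign=True),
        dict(quota=6, fixed_capacity=2), 1.0,
    )


def _s4_foreign_attrition_and_promotion():
    rows = (
        [dict(state="TRANSITION", age=40.0, years_in_state=3.0) for _ in range(4)]
        + [dict(state="TRANSITION", age=38.0, years_in_state=2.0,
                nationality="foreign") for _ in range(6)]
        + [dict(state="FIXED", age=50.0, years_in_state=5.0) for _ in range(5)]
    )
    groups = [
        Group("TRANSITION", 4, 40.0, 3.0),
        Group("TRANSITION", 6, 38.0, 2.0, foreign=True),
        Group("FIXED", 5, 50.0, 5.0),
    ]
    return (
        rows, groups,
        dict(quota=0, capacity=8, n_years=6),
        dict(quota=0, fixed_capacity=8), 1.0,
    )


def _s5_staggered_retirement_wave():
    rows = (
        [dict(state="FIXED", age=a, years_in_state=8.0) for a in (59.0, 60.0, 61.0)]
        + [dict(state="FIXED", age=45.0, years_in_state=4.0) for _ in range(3)]
        + [dict(state="TRANSITION", age=42.0, years_in_state=y)
           for y in (2.0, 1.0, 0.5)]
        + [dict(state="TRAINING", age=30.0, years_in_state=3.5),
           dict(state="TRAINING", age=29.0, years_in_state=1.5)]
    )
    groups = (
        [Group("FIXED", 1, a, 8.0) for a in (59.0, 60.0, 61.0)]
        + [Group("FIXED", 3, 45.0, 4.0)]
        + [Group("TRANSITION", 1, 42.0, y) for y in (2.0, 1.0, 0.5)]
        + [Group("TRAINING", 1, 30.0, 3.5), Group("TRAINING", 1, 29.0, 1.5)]
    )
    return (
        rows, groups,
        dict(quota=2, capacity=6, n_years=8),
        dict(quota=2, fixed_capacity=6), 0.0,
    )


def _s6_quota_shutoff():
    rows = [dict(state="TRAINING", age=27.0, years_in_state=1.0) for _ in range(5)]
    groups = [Group("TRAINING", 5, 27.0, 1.0)]
    return (
        rows, groups,
        dict(quota=0, capacity=2, n_years=7),
        dict(quota=0, fixed_capacity=2), 0.0,
    )


ORACLE_SCENARIOS = {
    "empty_pipeline": _s1_empty_pipeline,
    "training_wave": _s2_training_wave,
    "foreign_pipeline_drains": _s3_foreign_pipeline_drains,
    "foreign_attrition_and_promotion": _s4_foreign_attrition_and_promotion,
    "staggered_retirement_wave": _s5_staggered_retirement_wave,
    "quota_shutoff": _s6_quota_shutoff,
}


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", ORACLE_SCENARIOS)
    def test_engine_equals_stock_flow_recurrence(self, name):
        rows, groups, okw, skw, hazard = ORACLE_SCENARIOS[name]()
        entrant_foreign = okw.pop("entrant_foreign", False)
        marginals = degenerate_marginals(trainee_foreign=float(entrant_foreign))
        expected = pd.DataFrame(
            oracle_trajectory(groups, hazard=hazard,
                              entrant_foreign=entrant_foreign, **okw)
        )
        scenario = q.PolicyScenario(
            start_year=2014, horizon_year=2014 + okw["n_years"] - 1,
            foreign_departure_hazard=hazard, **skw,
        )
        for seed in (0, 1):
            traj = q.simulate_replicate(make_roster(rows), scenario, seed, marginals)
            got = traj[expected.columns].reset_index(drop=True)
            pd.testing.assert_frame_equal(got, expected, check_dtype=False)


@pytest.fixture(scope="module")
def small_ensemble(marginals, state_counts):
    scenario = q.PolicyScenario(foreign_departure_hazard=0.2)
    return q.run_monte_carlo(marginals, state_counts, scenario, 30, 123)


class TestInvariants:
    def test_conservation_of_persons(self, small_ensemble):
        v = small_ensemble.values
        qx = small_ensemble.quantities
        active = sum(v[:, :, qx.index(k)] for k in ("n_training", "n_transition",
                                                    "n_fixed"))
        cum = {k: np.cumsum(v[:, :, qx.index(k)], axis=1)
               for k in ("n_retired", "n_departed", "n_entrants")}
        lhs = active + cum["n_retired"] + cum["n_departed"]
        rhs = 413 + cum["n_entrants"]
        assert np.array_equal(lhs, rhs)

    def test_training_pool_pinned_at_quota(self, small_ensemble):
        assert np.all(small_ensemble.replicate_matrix("n_training") == 66)

    def test_fixed_pool_at_capacity_while_transition_nonempty(self, small_ensemble):
        n_fixed = small_ensemble.replicate_matrix("n_fixed")
        n_trans = small_ensemble.replicate_matrix("n_transition")
        assert np.all(n_fixed <= 244)
        assert np.all((n_fixed == 244) | (n_trans == 0))

    def test_percentile_ordering(self, small_ensemble):
        s = small_ensemble.summary()
        assert (s["lo95"] <= s["median"]).all()
        assert (s["median"] <= s["hi95"]).all()

    def test_no_active_person_past_retirement_age(self, marginals, state_counts):
        roster = q.sample_cohort(marginals, state_counts, seed=3)
        scenario = q.PolicyScenario(foreign_departure_hazard=0.2)
        rng = np.random.default_rng(3)
        for _ in range(5):
            roster, _ = q.annual_step(roster, scenario, rng, marginals)
        active = roster[roster["state"].isin(["TRAINING", "TRANSITION", "FIXED"])]
        assert (active["age"] < active["desired_retirement_age"]).all()

    def test_transition_pool_monotone_in_quota(self, marginals, state_counts):
        """A larger quota weakly enlarges the transition pool. The quota only
        acts once refilled entrants certify, so early years are ties up to
        Monte-Carlo noise; the horizon year must separate strictly."""
        mean = {}
        for quota in (50, 66, 80):
            sc = q.PolicyScenario(quota=quota, foreign_departure_hazard=0.2)
            ens = q.run_monte_carlo(marginals, state_counts, sc, 100, 77)
            mean[quota] = ens.replicate_matrix("n_transition").mean(axis=0)
        noise = 1.0
        assert np.all(mean[50] <= mean[66] + noise)
        assert np.all(mean[66] <= mean[80] + noise)
        assert mean[50][-1] < mean[66][-1] < mean[80][-1]

    def test_transition_pool_antitone_in_departure_hazard(self, marginals,
                                                          state_counts):
        mean = {}
        for h in (0.0, 0.2, 0.4):
            sc = q.PolicyScenario(foreign_departure_hazard=h)
            ens = q.run_monte_carlo(marginals, state_counts, sc, 100, 77)
            mean[h] = ens.replicate_matrix("n_transition").mean(axis=0)
        noise = 1.0
        assert np.all(mean[0.2] <= mean[0.0] + noise)
        assert np.all(mean[0.4] <= mean[0.2] + noise)
        assert mean[0.4][-1] < mean[0.2][-1] < mean[0.0][-1]


class TestMonteCarlo:
    def test_reproducible_given_master_seed(self, marginals, state_counts):
        sc = q.PolicyScenario(foreign_departure_hazard=0.3)
        a = q.run_monte_carlo(marginals, state_counts, sc, 10, 2024)
        b = q.run_monte_carlo(marginals, state_counts, sc, 10, 2024)
        c = q.run_monte_carlo(marginals, state_counts, sc, 10, 2025)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_replicate_minimum(self, marginals, state_counts):
        sc = q.PolicyScenario(foreign_departure_hazard=0.3)
        with pytest.raises(ValidationError, match="replicates"):
            q.run_monte_carlo(marginals, state_counts, sc, 1, 0)

    def test_unset_hazard_rejected(self, marginals, state_counts):
        with pytest.raises(ValidationError, match="hazard"):
            q.run_monte_carlo(marginals, state_counts, q.PolicyScenario(), 5, 0)

    def test_single_year_horizon(self, marginals, state_counts):
        sc = q.PolicyScenario(horizon_year=2014, foreign_departure_hazard=0.0)
        roster = q.sample_cohort(marginals, state_counts, seed=0)
        traj = q.simulate_replicate(roster, sc, 1, marginals)
        assert len(traj) == 1 and traj.loc[0, "year"] == 2014

    def test_zero_quota_empties_training(self, marginals, state_counts):
        sc = q.PolicyScenario(quota=0, foreign_departure_hazard=0.0)
        roster = q.sample_cohort(marginals, state_counts, seed=0)
        traj = q.simulate_replicate(roster, sc, 1, marginals)
        assert traj.loc[len(traj) - 1, "n_training"] == 0


class TestCalibration:
    def test_anchors_required(self, marginals, state_counts):
        with pytest.raises(ValidationError, match="anchor"):
            q.calibrate_hazard(marginals, state_counts, q.PolicyScenario(), {}, 0)

    def test_self_anchors_are_a_fixed_point(self, marginals, state_counts):
        """Calibrating against a run's own medians returns that run's hazard."""
        sc = q.PolicyScenario(foreign_departure_hazard=0.2)
        ens = q.run_monte_carlo(marginals, state_counts, sc, 60, 99)
        anchors = {
            2014: ens.median("n_transition", 2014),
            2024: ens.median("n_transition", 2024),
        }
        result = q.calibrate_hazard(
            marginals, state_counts, sc.replace(foreign_departure_hazard=None),
            anchors, master_seed=99, n_replicates=60,
            grid=[0.1, 0.15, 0.2, 0.25, 0.3],
        )
        assert result.hazard == 0.2
        assert result.sse == 0.0
        assert not result.at_boundary
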