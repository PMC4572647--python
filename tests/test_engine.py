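"""Engine behaviour: hand-computed oracles, invariants, arrival model."""

import dataclasses

import numpy as np
import pytest

import clinicflow as cf
from clinicflow import engine
from clinicflow.config import (
    AppointmentSlot,
    ScenarioConfig,
    StaffRoster,
    Template,
)
from clinicflow.errors import ConfigurationError
from conftest import const_table, deterministic_population


def run_day(scenario, day="Mon", seed=0):
    rng = np.random.default_rng(seed)
    rng_im = np.random.default_rng(seed + 1)
    return engine.simulate_day(scenario, day, rng, rng_im)


# ---------------------------------------------------------------------------
# deterministic oracles
# ---------------------------------------------------------------------------


def milestone_row(p):
    return (
        p.t_checkin_start, p.t_checkin, p.t_escort, p.t_vitals,
        p.t_provider_in, p.t_provider_out, p.t_lab_in, p.t_lab_out,
        p.t_checkout, p.t_depart,
    )


class TestMiniClinicOracle:
    """Four constant-duration patients through a one-room clinic.

    The expected milestone table below was computed by hand from the engine's
    stated rules (appointment-order escort, room held until the provider
    finishes, single check-in/check-out desks) and is frozen as the oracle.
    """

    # (checkin_start, checkin, escort, vitals, prov_in, prov_out,
    #  lab_in, lab_out, checkout, depart) per patient id
    EXPECTED = {
        2: (475, 477, 477, 480, 480, 490, 490, 495, 495, 496),   # NOB, 15 min early
        0: (480, 482, 490, 493, 493, 503, None, None, 503, 504),
        1: (482, 484, 503, 506, 506, 516, None, None, 516, 517),
        3: (500, 502, 516, 519, 519, 529, None, None, 529, 530),
    }

    def test_full_event_table_matches_hand_computation(self, mini_scenario):
        res = run_day(mini_scenario)
        assert len(res.patients) == 4
        for p in res.patients:
            assert milestone_row(p) == pytest.approx(
                self.EXPECTED[p.id]
            ), f"patient {p.id}"

    def test_waiting_room_decomposition_matches_hand_computation(self, mini_scenario):
        res = run_day(mini_scenario)
        by_id = {p.id: p for p in res.patients}
        # all waiting-room delay is room-blocked: the nurse pool (2) never empties
        assert by_id[2].room_blocked == pytest.approx(0)
        assert by_id[0].room_blocked == pytest.approx(8)
        assert by_id[1].room_blocked == pytest.approx(19)
        assert by_id[3].room_blocked == pytest.approx(14)
        assert all(p.nurse_blocked == 0 for p in res.patients)

    def test_partition_sums_to_escort_wait(self, mini_scenario):
        res = run_day(mini_scenario)
        for p in res.patients:
            assert p.room_blocked + p.nurse_blocked == pytest.approx(
                p.t_escort - p.t_checkin
            )


def test_second_patient_waits_exactly_one_provider_service():
    """Two patients ready simultaneously share one provider: the second's
    exam-room wait equals the 10-minute provider service."""
    slots = (
        AppointmentSlot(480, "ROB", "AM", "A"),
        AppointmentSlot(480, "ROB", "AM", "A"),
    )
    sc = ScenarioConfig(
        x1=1, x2=1, x3=1, days=("Mon",), n_exam_rooms=2,
        population=deterministic_population([("A", "Mon")]),
        dist_table=const_table(checkin=0.0),
        lab_processing=None,
        roster_overrides={"Mon": StaffRoster("Mon", (("A", frozenset({"AM", "PM"})),))},
        template_overrides={"A": Template("baseline", slots)},
    )
    res = run_day(sc)
    waits = sorted(p.t_provider_in - p.t_vitals for p in res.patients)
    assert waits == pytest.approx([0.0, 10.0])


def test_single_patient_timestamps_are_analytic_sums(mini_scenario):
    sc = dataclasses.replace(
        mini_scenario,
        template_overrides={
            "A": Template("baseline", (AppointmentSlot(480, "NOB", "AM", "A"),))
        },
    )
    res = run_day(sc)
    (p,) = res.patients
    # arrival 465 (15 min early), check-in 2, vitals 3, provider 10, lab 5, checkout 1
    assert milestone_row(p) == pytest.approx(
        (465, 467, 467, 470, 470, 480, 480, 485, 485, 486)
    )
    assert p.t_provider_in - p.t_vitals == 0  # no contention, no wait


# ---------------------------------------------------------------------------
# arrival model
# ---------------------------------------------------------------------------


class TestArrivals:
    def _arrivals(self, n_slots, pclass, sd=7.0, seed=0, showup=1.0):
        slots = tuple(AppointmentSlot(600, pclass, "AM", "A") for _ in range(n_slots))
        pop = dataclasses.replace(
            deterministic_population([("A", "Mon")], showup=showup),
            arrival_jitter_sd=sd,
        )
        sc = ScenarioConfig(
            days=("Mon",), population=pop, dist_table=const_table(),
            lab_processing=None,
        )
        return engine.generate_arrivals(
            Template("baseline", slots), pop, "A", "Mon",
            np.random.default_rng(seed), scenario=sc,
        )

    def test_new_patients_arrive_fifteen_minutes_early(self):
        (p,) = self._arrivals(1, "NOB", sd=0.0)
        assert p.arrival_time == 585.0

    def test_return_patients_arrive_at_slot_time_without_jitter(self):
        (p,) = self._arrivals(1, "ROB", sd=0.0)
        assert p.arrival_time == 600.0

    def test_jitter_sd_close_to_seven_minutes(self):
        ps = self._arrivals(10_000, "ROB")
        dev = np.array([p.arrival_time - p.appointment_time for p in ps])
        se = 7.0 / np.sqrt(2 * (len(dev) - 1))
        assert abs(dev.std(ddof=1) - 7.0) < 3 * se
        assert abs(dev.mean()) < 3 * 7.0 / np.sqrt(len(dev))

    def test_zero_showup_returns_empty_list(self):
        assert self._arrivals(50, "ROB", showup=0.0) == []

    def test_arrivals_sorted_by_arrival_time(self):
        ps = self._arrivals(200, "ROB", seed=3)
        times = [p.arrival_time for p in ps]
        assert times == sorted(times)

    def test_sda_slots_resolve_to_return_ob_or_gyn(self):
        slots = tuple(AppointmentSlot(600, "SDA", "PM", "A") for _ in range(400))
        pop = deterministic_population([("A", "Mon")])
        sc = ScenarioConfig(days=("Mon",), population=pop, dist_table=const_table(),
                            lab_processing=None)
        ps = engine.generate_arrivals(
            Template("baseline", slots), pop, "A", "Mon",
            np.random.default_rng(4), scenario=sc,
        )
        classes = {p.pclass for p in ps}
        assert classes == {"ROB", "RGYN"}
        frac_rob = np.mean([p.pclass == "ROB" for p in ps])
        assert abs(frac_rob - 0.5) < 3 * 0.5 / np.sqrt(len(ps))
        assert all(p.kind == "return" for p in ps)


# ---------------------------------------------------------------------------
# invariants on stochastic runs
# ---------------------------------------------------------------------------


def check_conservation_and_capacity(res):
    for p in res.patients:
        row = milestone_row(p)
        present = [t for t in row if t is not None]
        assert all(b >= a - 1e-9 for a, b in zip(present, present[1:])), (
            f"non-monotone milestones for {p.id}: {row}"
        )
        assert p.t_depart is not None           # everyone who arrives departs
        assert (p.t_lab_in is not None) == p.needs_lab
    # resource feasibility from the event log
    def capacity(resource):
        if resource.startswith("exam_room_"):
            return 1                       # a single-capacity room unit
        return res.capacities[{"nurse": "nurse_pool", "ma": "ma_pool"}.get(resource, resource)]

    in_use = {}
    for time, pid, resource, action in sorted(res.events, key=lambda e: (e[0], e[3] == "seize")):
        if resource == "clinic":
            continue
        if action == "seize":
            in_use[resource] = in_use.get(resource, 0) + 1
            assert in_use[resource] <= capacity(resource), (
                f"{resource} over capacity at t={time}"
            )
        elif action == "release":
            in_use[resource] -= 1
            assert in_use[resource] >= 0
    for resource, n in in_use.items():
        if resource != "clinic":
            assert n == 0, f"{resource} still seized at end of day"


@pytest.mark.parametrize("day", ["Mon", "Wed", "Thu"])
def test_conservation_and_capacity_hold_on_stochastic_days(default_scenario, day):
    for seed in range(5):
        res = run_day(default_scenario, day=day, seed=seed)
        check_conservation_and_capacity(res)


def test_infinite_rooms_and_nurses_remove_waiting_room_delay(default_scenario):
    sc = dataclasses.replace(default_scenario, n_exam_rooms=60, x1=4, x2=4)
    # each provider needs a dedicated room in the worst case; 60 >> patients
    for seed in range(3):
        res = run_day(sc, day="Tue", seed=seed)
        for p in res.patients:
            assert p.t_escort - p.t_checkin == pytest.approx(0.0, abs=1e-9)


def test_same_seed_reproduces_identical_metrics(default_scenario):
    a = engine.run_replications(default_scenario, n_reps=2, base_seed=42)
    b = engine.run_replications(default_scenario, n_reps=2, base_seed=42)
    assert [(r.wt, r.twt, r.tst, r.n_patients) for r in a] == [
        (r.wt, r.twt, r.tst, r.n_patients) for r in b
    ]


def test_replication_count_and_independence(default_scenario):
    reps = engine.run_replications(default_scenario, n_reps=30, base_seed=0, days=("Mon",))
    assert len(reps) == 30
    twts = [r.twt for r in reps]
    assert np.std(twts) > 0  # replications differ


def test_wider_morning_spacing_never_raises_mean_total_wait():
    """Statistical trend: t_am=16 vs t_am=10 lowers TWT (10 CRN replications)."""
    base = ScenarioConfig(template_kind="modified", t_am=10.0, t_pm=15.0)
    wide = dataclasses.replace(base, t_am=16.0)
    twt_narrow = np.mean([r.twt for r in engine.run_replications(base, 10, 5, days=("Tue",))])
    twt_wide = np.mean([r.twt for r in engine.run_replications(wide, 10, 5, days=("Tue",))])
    assert twt_wide <= twt_narrow


def test_variance_of_replication_means_shrinks_like_one_over_n(default_scenario):
    reps = engine.run_replications(default_scenario, n_reps=120, base_seed=9, days=("Mon",))
    twts = np.array([r.twt for r in reps])
    groups = twts.reshape(4, 30).mean(axis=1)
    var_of_means = groups.var(ddof=1)
    predicted = twts.var(ddof=1) / 30
    # CLT scaling within a generous factor (only 4 group means available)
    assert var_of_means < 6 * predicted
    assert predicted < 40 * var_of_means


def test_unstaffable_day_rejected_before_running(default_scenario, monkeypatch):
    """An escort pool of zero nurses is refused at validation, not mid-run."""
    empty = StaffRoster("Mon", (("D", frozenset({"AM"})),), n_rn=0, n_lpn=0)
    monkeypatch.setattr(ScenarioConfig, "roster_for", lambda self, day: empty)
    with pytest.raises(ConfigurationError):
        engine.simulate_day(default_scenario, "Mon", np.random.default_rng(0))
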