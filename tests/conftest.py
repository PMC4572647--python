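"""Shared fixtures: constant-service-time tables and hand-checkable scenarios."""

from __future__ import annotations

import pytest

from clinicflow.config import (
    AppointmentSlot,
    PatientPopulationParams,
    ScenarioConfig,
    StaffRoster,
    Template,
)
from clinicflow.distributions import DistributionSpec


def const(v: float) -> DistributionSpec:
    """Degenerate triangular: a deterministic service time of ``v`` minutes."""
    return DistributionSpec("triangular", (v, v, v))


def const_table(checkin=2.0, nurse=3.0, provider=10.0, lab=5.0, checkout=1.0):
    """Service-time table with deterministic durations for every role."""
    table = {}
    for kind in ("new", "return"):
        table[("check_in", kind)] = const(checkin)
        table[("nurse", kind)] = const(nurse)
        table[("provider", kind)] = const(provider)
        table[("lab", kind)] = const(lab)
        table[("check_out", kind)] = const(checkout)
    return table


def deterministic_population(providers_days, showup=1.0, lab_prob=None):
    """Population with no jitter/no-shows for fully deterministic runs."""
    return PatientPopulationParams(
        showup={
            (p, d, kind): showup
            for (p, d) in providers_days
            for kind in ("new", "return")
        },
        lab_prob=lab_prob or {"NOB": 1.0, "ROB": 0.0, "NGYN": 0.0, "RGYN": 0.0},
        arrival_jitter_sd=0.0,
        im_lab_rate_per_hour=0.0,
    )


@pytest.fixture
def mini_scenario():
    """Four deterministic patients, one provider, one exam room.

    Constant durations: check-in 2, vitals 3, provider 10, lab 5 (new
    patients only), check-out 1.  The full event table is hand-computed in
    the tests that use this fixture.
    """
    slots = (
        AppointmentSlot(480, "ROB", "AM", "A"),
        AppointmentSlot(480, "ROB", "AM", "A"),
        AppointmentSlot(490, "NOB", "AM", "A"),
        AppointmentSlot(500, "ROB", "AM", "A"),
    )
    return ScenarioConfig(
        x1=1, x2=1, x3=1,
        days=("Mon",),
        n_exam_rooms=1,
        population=deterministic_population([("A", "Mon")]),
        dist_table=const_table(),
        lab_processing=None,
        roster_overrides={
            "Mon": StaffRoster(day="Mon", providers=(("A", frozenset({"AM", "PM"})),))
        },
        template_overrides={"A": Template("baseline", slots)},
    )


@pytest.fixture
def default_scenario():
    return ScenarioConfig()
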