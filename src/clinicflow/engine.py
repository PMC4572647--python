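"""Event-driven simulation of one clinic day.

The model is a queueing network driven by an event calendar (a binary heap):

    arrival -> check-in (dedicated access coordinator)
            -> waiting room -> escort when an exam room AND an escorting
               staff member are simultaneously free, in appointment order
            -> vitals in the exam room (RN/LPN pool; MA as fallback escort)
            -> wait in the room for the patient's own provider
            -> provider visit (room released on exit)
            -> lab if routed (MA + single lab room, shared with a background
               internal-medicine load)
            -> check-out (second access coordinator).

Rooms are a shared pool across providers; the patient holds the room from
escort until the provider finishes, which is what makes exam rooms the
dominant bottleneck around midday.  The simulation runs until every arrived
patient has departed; departures after 5 pm are recorded as overtime rather
than truncated.

The engine is deliberately dependency-free and allocation-light: the
optimizer evaluates on the order of 10^5 simulated days.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from heapq import heapify, heappop, heappush
from typing import Sequence

import numpy as np

from .config import (
    AM_FIRST_SLOT,
    NEW_CLASSES,
    PM_FIRST_SLOT,
    ScenarioConfig,
    Template,
    WEEKDAYS,
)
from .errors import ConfigurationError

__all__ = ["Patient", "DayResult", "generate_arrivals", "simulate_day", "run_replications"]

DAY_INDEX = {d: i for i, d in enumerate(WEEKDAYS)}

# event codes
(_ARRIVAL, _CHECKIN_DONE, _VITALS_DONE, _PROVIDER_DONE, _LAB_DONE,
 _CHECKOUT_DONE, _IM_ARRIVAL, _MA_FREE) = range(8)


class Patient:
    """Mutable per-patient state; milestone attributes start as None."""

    __slots__ = (
        "id", "pclass", "kind", "provider", "appointment_time", "arrival_time",
        "needs_lab", "is_im",
        "d_checkin", "d_nurse", "d_provider", "d_lab", "d_checkout", "d_labproc",
        "t_checkin_start", "t_checkin", "t_escort", "t_vitals",
        "t_provider_in", "t_provider_out", "t_lab_in", "t_lab_out",
        "t_checkout", "t_depart",
        "room_blocked", "nurse_blocked", "escorted_by",
    )

    def __init__(self, pid, pclass, kind, provider, appt, arrival, needs_lab):
        self.id = pid
        self.pclass = pclass
        self.kind = kind
        self.provider = provider
        self.appointment_time = appt
        self.arrival_time = arrival
        self.needs_lab = needs_lab
        self.is_im = False
        self.d_checkin = self.d_nurse = self.d_provider = 0.0
        self.d_lab = self.d_checkout = self.d_labproc = 0.0
        self.t_checkin_start = self.t_checkin = self.t_escort = self.t_vitals = None
        self.t_provider_in = self.t_provider_out = None
        self.t_lab_in = self.t_lab_out = None
        self.t_checkout = self.t_depart = None
        self.room_blocked = 0.0
        self.nurse_blocked = 0.0
        self.escorted_by = None


class _ImVisit:
    __slots__ = ("id", "kind", "arrival_time", "d_lab", "d_labproc",
                 "t_lab_in", "t_lab_out", "is_im")

    def __init__(self, pid, kind, arrival, d_lab, d_labproc):
        self.id = pid
        self.kind = kind
        self.arrival_time = arrival
        self.d_lab = d_lab
        self.d_labproc = d_labproc
        self.t_lab_in = self.t_lab_out = None
        self.is_im = True


@dataclass
class DayResult:
    """Raw output of one simulated day."""

    day: str
    patients: list = field(default_factory=list)        # arrived OB/GYN patients
    im_patients: list = field(default_factory=list)
    events: list = field(default_factory=list)          # (time, pid, resource, action)
    busy: dict = field(default_factory=dict)            # resource -> contact minutes
    capacities: dict = field(default_factory=dict)
    provider_sessions: dict = field(default_factory=dict)
    n_scheduled: dict = field(default_factory=dict)     # (provider, kind) -> count
    last_depart: float = 0.0


def _sample_role(scenario: ScenarioConfig, provider: str, role: str, kind: str,
                 rng: np.random.Generator, size: int):
    """Vectorized service-time draws; per-provider laws fall back to 'provider'."""
    if role == "provider":
        try:
            spec = scenario.distribution(f"provider_{provider}", kind)
        except ConfigurationError:
            spec = scenario.distribution("provider", kind)
    else:
        spec = scenario.distribution(role, kind)
    return np.atleast_1d(spec.sample(rng, size=size)) if size else np.empty(0)


def generate_arrivals(
    template: Template,
    population,
    provider: str,
    day: str,
    rng: np.random.Generator,
    id_start: int = 0,
    horizon_start: float = 450.0,
    scenario: ScenarioConfig | None = None,
) -> list[Patient]:
    """Realize one provider-day of scheduled patients.

    Every slot consumes the same random draws whether or not the patient
    shows up, so streams stay aligned across staffing/spacing configurations
    (common random numbers).  Returns arrived patients sorted by arrival time.
    """
    slots = template.slots
    n = len(slots)
    if n == 0:
        return []
    u_show = rng.random(n)
    z = rng.standard_normal(n)
    u_sda = rng.random(n)
    u_lab = rng.random(n)

    classes = []
    kinds = []
    for i, s in enumerate(slots):
        c = s.patient_class
        if c == "SDA":
            c = "ROB" if u_sda[i] < population.sda_split else "RGYN"
        classes.append(c)
        kinds.append("new" if c in NEW_CLASSES else "return")

    # service-time draws, grouped by kind in a fixed order (CRN alignment)
    durs = {r: np.empty(n) for r in ("check_in", "nurse", "provider", "lab", "check_out")}
    labproc = np.zeros(n)
    if scenario is None:
        raise ConfigurationError("generate_arrivals requires the scenario for service laws")
    for kind in ("new", "return"):
        idx = [i for i, k in enumerate(kinds) if k == kind]
        for role in ("check_in", "nurse", "provider", "lab", "check_out"):
            draws = _sample_role(scenario, provider, role, kind, rng, len(idx))
            for j, i in enumerate(idx):
                durs[role][i] = draws[j]
        if scenario.lab_processing is not None and idx:
            draws = np.atleast_1d(scenario.lab_processing.sample(rng, size=len(idx)))
            for j, i in enumerate(idx):
                labproc[i] = draws[j]

    out = []
    for i, s in enumerate(slots):
        kind = kinds[i]
        p_show = population.get_showup(provider, day, kind)
        if u_show[i] >= p_show:
            continue
        early = population.new_patient_early if kind == "new" else 0.0
        arrival = s.clock_time + z[i] * population.arrival_jitter_sd - early
        if arrival < horizon_start:
            arrival = horizon_start
        p = Patient(
            pid=id_start + i,
            pclass=classes[i],
            kind=kind,
            provider=provider,
            appt=s.clock_time,
            arrival=arrival,
            needs_lab=bool(u_lab[i] < population.lab_prob[classes[i]]),
        )
        p.d_checkin = durs["check_in"][i]
        p.d_nurse = durs["nurse"][i]
        p.d_provider = durs["provider"][i]
        p.d_lab = durs["lab"][i]
        p.d_checkout = durs["check_out"][i]
        p.d_labproc = labproc[i]
        out.append(p)
    out.sort(key=lambda p: (p.arrival_time, p.id))
    return out


def _generate_im_visits(scenario: ScenarioConfig, rng: np.random.Generator) -> list[_ImVisit]:
    pop = scenario.population
    if pop.im_lab_rate_per_hour <= 0:
        return []
    span = scenario.horizon_end - scenario.horizon_start
    n = rng.poisson(pop.im_lab_rate_per_hour * span / 60.0)
    if n == 0:
        return []
    times = np.sort(rng.uniform(scenario.horizon_start, scenario.horizon_end, n))
    kinds = np.where(rng.random(n) < pop.im_new_frac, "new", "return")
    lab_new = scenario.distribution("lab", "new")
    lab_ret = scenario.distribution("lab", "return")
    d_new = np.atleast_1d(lab_new.sample(rng, size=int(np.sum(kinds == "new"))))
    d_ret = np.atleast_1d(lab_ret.sample(rng, size=int(np.sum(kinds == "return"))))
    if scenario.lab_processing is not None:
        d_proc = np.atleast_1d(scenario.lab_processing.sample(rng, size=n))
    else:
        d_proc = np.zeros(n)
    i_new = i_ret = 0
    out = []
    for i in range(n):
        if kinds[i] == "new":
            d = d_new[i_new]; i_new += 1
        else:
            d = d_ret[i_ret]; i_ret += 1
        out.append(_ImVisit(f"IM{i}", str(kinds[i]), float(times[i]), float(d), float(d_proc[i])))
    return out


def simulate_day(
    scenario: ScenarioConfig,
    day: str,
    rng: np.random.Generator,
    rng_im: np.random.Generator | None = None,
) -> DayResult:
    """Simulate one clinic day; deterministic given the generator states."""
    roster = scenario.roster_for(day)
    if not roster.providers:
        raise ConfigurationError(f"empty roster for {day}")
    n_nurses = roster.n_rn + roster.n_lpn
    if n_nurses < 1:
        raise ConfigurationError("at least one RN or LPN is required to escort patients")
    if roster.n_ma < 1:
        raise ConfigurationError("at least one MA is required to run the lab")

    res = DayResult(day=day)
    res.capacities = {
        "exam_rooms": scenario.n_exam_rooms,
        "nurse_pool": n_nurses,
        "ma_pool": roster.n_ma,
        "lab_room": scenario.n_lab_rooms,
        "check_in_ac": 1,
        "check_out_ac": 1,
    }
    busy = {
        "exam_rooms": 0.0, "nurse_pool": 0.0, "ma_pool": 0.0, "ma_processing": 0.0,
        "lab_room": 0.0, "check_in_ac": 0.0, "check_out_ac": 0.0,
    }

    # --- generate arrivals ------------------------------------------------
    patients: list[Patient] = []
    pid_base = 0
    for pid, sessions in roster.providers:
        template = scenario.template_for(pid, sessions)
        patients += generate_arrivals(
            template, scenario.population, pid, day, rng,
            id_start=pid_base, horizon_start=scenario.horizon_start,
            scenario=scenario,
        )
        res.n_scheduled[(pid, "new")] = template.new_count()
        res.n_scheduled[(pid, "return")] = template.n_patients - template.new_count()
        res.provider_sessions[pid] = sessions
        res.capacities[f"provider_{pid}"] = 1
        busy[f"provider_{pid}"] = 0.0
        pid_base += 100
    im_visits = _generate_im_visits(scenario, rng_im if rng_im is not None else rng)
    res.im_patients = im_visits

    # --- state ------------------------------------------------------------
    heap: list = []
    seq = itertools.count()
    for p in patients:
        heappush(heap, (p.arrival_time, next(seq), _ARRIVAL, p))
    for v in im_visits:
        heappush(heap, (v.arrival_time, next(seq), _IM_ARRIVAL, v))

    events = res.events
    free_rooms = list(range(scenario.n_exam_rooms))
    heapify(free_rooms)
    nurse_free = n_nurses
    ma_free = roster.n_ma
    lab_free = scenario.n_lab_rooms
    checkin_free = True
    checkout_free = True
    checkin_q: list = []   # FIFO via pointer
    checkin_head = 0
    checkout_q: list = []
    checkout_head = 0
    lab_q: list = []
    lab_head = 0
    waiting: list = []     # heap of (appointment, arrival, id, patient)
    room_of: dict = {}
    provider_busy = {pid: False for pid, _ in roster.providers}
    provider_avail = {
        pid: (AM_FIRST_SLOT if "AM" in sessions else PM_FIRST_SLOT)
        for pid, sessions in roster.providers
    }
    provider_q: dict = {pid: [] for pid, _ in roster.providers}
    ma_ok = scenario.ma_escort_allowed
    now = scenario.horizon_start

    def escort_capable() -> bool:
        return nurse_free > 0 or (ma_ok and ma_free > 0)

    # --- dispatch helpers ---------------------------------------------------
    def try_checkin():
        nonlocal checkin_free, checkin_head
        while checkin_free and checkin_head < len(checkin_q):
            p = checkin_q[checkin_head]
            checkin_head += 1
            checkin_free = False
            p.t_checkin_start = now
            events.append((now, p.id, "check_in_ac", "seize"))
            heappush(heap, (now + p.d_checkin, next(seq), _CHECKIN_DONE, p))
            break

    def try_escort():
        nonlocal nurse_free, ma_free
        while waiting and free_rooms and escort_capable():
            _, _, _, p = heappop(waiting)
            room = heappop(free_rooms)
            room_of[p.id] = room
            if nurse_free > 0:
                nurse_free -= 1
                p.escorted_by = "nurse"
                events.append((now, p.id, "nurse", "seize"))
            else:
                ma_free -= 1
                p.escorted_by = "ma"
                events.append((now, p.id, "ma", "seize"))
            p.t_escort = now
            events.append((now, p.id, f"exam_room_{room}", "seize"))
            heappush(heap, (now + p.d_nurse, next(seq), _VITALS_DONE, p))

    def try_provider(pid):
        q = provider_q[pid]
        if provider_busy[pid] or not q:
            return
        _, _, p = heappop(q)
        provider_busy[pid] = True
        start = now if now >= provider_avail[pid] else provider_avail[pid]
        p.t_provider_in = start
        events.append((start, p.id, f"provider_{pid}", "seize"))
        heappush(heap, (start + p.d_provider, next(seq), _PROVIDER_DONE, p))

    def try_lab():
        nonlocal ma_free, lab_free, lab_head
        while lab_head < len(lab_q) and lab_free > 0 and ma_free > 0:
            p = lab_q[lab_head]
            lab_head += 1
            lab_free -= 1
            ma_free -= 1
            p.t_lab_in = now
            events.append((now, p.id, "lab_room", "seize"))
            events.append((now, p.id, "ma", "seize"))
            heappush(heap, (now + p.d_lab, next(seq), _LAB_DONE, p))

    def try_checkout():
        nonlocal checkout_free, checkout_head
        while checkout_free and checkout_head < len(checkout_q):
            p = checkout_q[checkout_head]
            checkout_head += 1
            checkout_free = False
            p.t_checkout = now
            events.append((now, p.id, "check_out_ac", "seize"))
            heappush(heap, (now + p.d_checkout, next(seq), _CHECKOUT_DONE, p))
            break

    # --- main loop ----------------------------------------------------------
    while heap:
        t, _, code, p = heappop(heap)
        if t > now:
            if waiting:
                dt = t - now
                if not free_rooms:
                    for entry in waiting:
                        entry[3].room_blocked += dt
                elif not escort_capable():
                    for entry in waiting:
                        entry[3].nurse_blocked += dt
            now = t

        if code == _ARRIVAL:
            events.append((now, p.id, "clinic", "arrive"))
            checkin_q.append(p)
            try_checkin()
        elif code == _CHECKIN_DONE:
            checkin_free = True
            busy["check_in_ac"] += p.d_checkin
            events.append((now, p.id, "check_in_ac", "release"))
            p.t_checkin = now
            heappush(waiting, (p.appointment_time, p.arrival_time, p.id, p))
            try_checkin()
            try_escort()
        elif code == _VITALS_DONE:
            if p.escorted_by == "nurse":
                nurse_free += 1
                busy["nurse_pool"] += p.d_nurse
                events.append((now, p.id, "nurse", "release"))
            else:
                ma_free += 1
                busy["ma_pool"] += p.d_nurse
                events.append((now, p.id, "ma", "release"))
            p.t_vitals = now
            heappush(provider_q[p.provider], (now, p.id, p))
            try_provider(p.provider)
            try_escort()
            if p.escorted_by == "ma":
                try_lab()
        elif code == _PROVIDER_DONE:
            pid = p.provider
            provider_busy[pid] = False
            busy[f"provider_{pid}"] += p.d_provider
            p.t_provider_out = now
            events.append((now, p.id, f"provider_{pid}", "release"))
            room = room_of.pop(p.id)
            busy["exam_rooms"] += now - p.t_escort
            events.append((now, p.id, f"exam_room_{room}", "release"))
            heappush(free_rooms, room)
            if p.needs_lab:
                lab_q.append(p)
                try_lab()
            else:
                checkout_q.append(p)
                try_checkout()
            try_provider(pid)
            try_escort()
        elif code == _LAB_DONE:
            lab_free += 1
            busy["lab_room"] += p.d_lab
            busy["ma_pool"] += p.d_lab
            p.t_lab_out = now
            events.append((now, p.id, "lab_room", "release"))
            if not p.is_im:
                checkout_q.append(p)
                try_checkout()
            if p.d_labproc > 0:
                # MA stays busy labelling/processing the specimen
                heappush(heap, (now + p.d_labproc, next(seq), _MA_FREE, p))
            else:
                ma_free += 1
                events.append((now, p.id, "ma", "release"))
                try_escort()
            try_lab()  # the lab room is free; another MA may be idle
        elif code == _CHECKOUT_DONE:
            checkout_free = True
            busy["check_out_ac"] += p.d_checkout
            events.append((now, p.id, "check_out_ac", "release"))
            p.t_depart = now
            events.append((now, p.id, "clinic", "depart"))
            if now > res.last_depart:
                res.last_depart = now
            try_checkout()
        elif code == _IM_ARRIVAL:
            lab_q.append(p)
            try_lab()
        elif code == _MA_FREE:
            ma_free += 1
            busy["ma_processing"] += p.d_labproc
            events.append((now, p.id, "ma", "release"))
            try_lab()
            try_escort()

    res.patients = patients
    res.busy = busy
    return res


def run_replications(
    scenario: ScenarioConfig,
    n_reps: int = 30,
    base_seed: int = 0,
    days: Sequence[str] | None = None,
):
    """Run independent replications over the scenario's days.

    Replication ``r``, day ``d`` uses generators seeded from
    ``SeedSequence(base_seed, spawn_key=(r, DAY_INDEX[d], k))`` with k = 0 for
    the patient stream and k = 1 for the background lab stream, so two
    scenarios evaluated with the same ``base_seed`` share their random draws
    (common random numbers).  Returns one ``ReplicationMetrics`` per
    replication.
    """
    from . import metrics as _metrics

    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    use_days = tuple(days) if days is not None else scenario.days
    out = []
    for rep in range(n_reps):
        day_results = []
        for d in use_days:
            di = DAY_INDEX[d]
            rng_p = np.random.default_rng(
                np.random.SeedSequence(entropy=base_seed, spawn_key=(rep, di, 0))
            )
            rng_im = np.random.default_rng(
                np.random.SeedSequence(entropy=base_seed, spawn_key=(rep, di, 1))
            )
            day_results.append(simulate_day(scenario, d, rng_p, rng_im))
        out.append(_metrics.replication_metrics(day_results, scenario, rep))
    return out
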