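"""Clinic structure: appointment templates, staff rosters, population, scenarios.

Clock times are minutes past midnight throughout.  The clinic day runs from
7:30 am (450) to 5 pm (1020).  Each provider session schedules a fixed patient
mix: 16 morning patients (5 new) starting at 7:45 and 12 afternoon patients
(2 new) starting at 12:45.  The baseline template contains double bookings
(two patients in one slot); the modified template splits every double into
single slots spaced ``t_am``/``t_pm`` minutes apart while preserving the
class mix.

Patient classes: NOB/ROB new/return obstetric, NGYN/RGYN new/return
gynecology, SDA a same-day slot filled 50/50 with ROB or RGYN at simulation
time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from . import distributions as dist
from .errors import ConfigurationError, ConstraintViolationError

__all__ = [
    "AppointmentSlot",
    "Template",
    "StaffRoster",
    "PatientPopulationParams",
    "ScenarioConfig",
    "build_baseline_template",
    "build_modified_template",
    "roster",
    "default_population",
    "scheduled_count",
    "WEEKDAYS",
    "PATIENT_CLASSES",
    "NEW_CLASSES",
    "HORIZON_START",
    "HORIZON_END",
    "AM_FIRST_SLOT",
    "PM_FIRST_SLOT",
    "AM_DEADLINE",
    "DAY_DEADLINE",
]

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri")
PATIENT_CLASSES = ("NOB", "ROB", "NGYN", "RGYN", "SDA")
NEW_CLASSES = frozenset({"NOB", "NGYN"})

HORIZON_START = 450.0   # 7:30 am — clinic opens
HORIZON_END = 1020.0    # 5:00 pm — check-out target
AM_FIRST_SLOT = 465     # 7:45 am
PM_FIRST_SLOT = 765     # 12:45 pm
AM_DEADLINE = 780.0     # 1:00 pm — throughput deadline for AM-only sessions
DAY_DEADLINE = 1020.0

# Baseline template (per provider session): (clock time, class).  Double
# bookings appear as two slots with the same clock time.
_BASELINE_AM = (
    (465, "ROB"), (465, "NGYN"),
    (480, "RGYN"),
    (495, "NOB"), (495, "ROB"),
    (510, "RGYN"),
    (525, "NGYN"),
    (540, "ROB"),
    (555, "NOB"),
    (570, "RGYN"),
    (585, "ROB"),
    (600, "RGYN"),
    (615, "NOB"),
    (630, "RGYN"),
    (645, "ROB"),
    (660, "ROB"),
)
_BASELINE_PM = (
    (765, "ROB"), (765, "NGYN"),
    (780, "RGYN"),
    (795, "NOB"), (795, "ROB"),
    (810, "ROB"), (810, "RGYN"),
    (825, "ROB"),
    (840, "ROB"),
    (855, "ROB"),
    (870, "SDA"),
    (885, "SDA"),
)

# Modified template class order (all-single slots; same class mix as baseline).
_MODIFIED_AM = (
    "ROB", "NGYN", "RGYN", "NOB", "ROB", "RGYN", "NGYN", "ROB",
    "NOB", "RGYN", "ROB", "RGYN", "NOB", "RGYN", "ROB", "ROB",
)
_MODIFIED_PM = (
    "ROB", "NGYN", "RGYN", "NOB", "ROB", "ROB", "RGYN", "ROB", "ROB", "ROB",
    "SDA", "SDA",
)

T_AM_BOUNDS = (10, 16)
T_PM_BOUNDS = (10, 21)
X_BOUNDS = (1, 4)


@dataclass(frozen=True)
class AppointmentSlot:
    clock_time: float           # minutes past midnight
    patient_class: str
    session: str                # "AM" | "PM"
    provider_id: str

    def __post_init__(self) -> None:
        if self.patient_class not in PATIENT_CLASSES:
            raise ConfigurationError(f"unknown patient class {self.patient_class!r}")
        if self.session not in ("AM", "PM"):
            raise ConfigurationError(f"session must be AM or PM, got {self.session!r}")


@dataclass(frozen=True)
class Template:
    """A provider-day appointment schedule."""

    kind: str                       # "baseline" | "modified"
    slots: tuple[AppointmentSlot, ...]
    t_am: float | None = None       # modified only
    t_pm: float | None = None

    @property
    def am_slots(self) -> tuple[AppointmentSlot, ...]:
        return tuple(s for s in self.slots if s.session == "AM")

    @property
    def pm_slots(self) -> tuple[AppointmentSlot, ...]:
        return tuple(s for s in self.slots if s.session == "PM")

    @property
    def n_patients(self) -> int:
        return len(self.slots)

    def new_count(self, session: str | None = None) -> int:
        slots = self.slots if session is None else tuple(
            s for s in self.slots if s.session == session
        )
        return sum(1 for s in slots if s.patient_class in NEW_CLASSES)


def build_baseline_template(
    provider_id: str, sessions: frozenset[str] | set[str] = frozenset({"AM", "PM"})
) -> Template:
    """The current (double-booked) template restricted to the given sessions."""
    slots: list[AppointmentSlot] = []
    if "AM" in sessions:
        slots += [AppointmentSlot(t, c, "AM", provider_id) for t, c in _BASELINE_AM]
    if "PM" in sessions:
        slots += [AppointmentSlot(t, c, "PM", provider_id) for t, c in _BASELINE_PM]
    return Template("baseline", tuple(slots))


def build_modified_template(
    provider_id: str,
    t_am: float,
    t_pm: float,
    sessions: frozenset[str] | set[str] = frozenset({"AM", "PM"}),
) -> Template:
    """All-single-slot template with evenly spaced appointments.

    16 AM slots at ``465 + i*t_am`` and 12 PM slots at ``765 + j*t_pm``;
    spacings must lie within the search-space bounds (10-16 and 10-21 min).
    """
    if not (T_AM_BOUNDS[0] <= t_am <= T_AM_BOUNDS[1]):
        raise ConstraintViolationError(
            f"t_am={t_am} outside bounds [{T_AM_BOUNDS[0]}, {T_AM_BOUNDS[1]}]"
        )
    if not (T_PM_BOUNDS[0] <= t_pm <= T_PM_BOUNDS[1]):
        raise ConstraintViolationError(
            f"t_pm={t_pm} outside bounds [{T_PM_BOUNDS[0]}, {T_PM_BOUNDS[1]}]"
        )
    slots: list[AppointmentSlot] = []
    if "AM" in sessions:
        slots += [
            AppointmentSlot(AM_FIRST_SLOT + i * t_am, c, "AM", provider_id)
            for i, c in enumerate(_MODIFIED_AM)
        ]
    if "PM" in sessions:
        slots += [
            AppointmentSlot(PM_FIRST_SLOT + j * t_pm, c, "PM", provider_id)
            for j, c in enumerate(_MODIFIED_PM)
        ]
    return Template("modified", tuple(slots), t_am=t_am, t_pm=t_pm)


# ---------------------------------------------------------------------------
# Staff rosters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaffRoster:
    day: str
    providers: tuple[tuple[str, frozenset[str]], ...]  # (provider_id, sessions)
    n_rn: int = 1
    n_lpn: int = 2
    n_ma: int = 1
    n_ac: int = 2
    ust_am: bool = False

    def sessions_of(self, provider_id: str) -> frozenset[str]:
        for pid, sessions in self.providers:
            if pid == provider_id:
                return sessions
        raise ConfigurationError(f"provider {provider_id!r} not on the {self.day} roster")


# Weekly provider roster.  Half-day sessions are reconstructed from the
# working-schedule and throughput tables: Thursday runs one full-day provider
# plus one AM-only and one PM-only provider; Wednesday runs two PM half-days.
_ROSTER: dict[str, tuple[tuple[str, frozenset[str]], ...]] = {
    "Mon": (("D", frozenset({"AM", "PM"})), ("E", frozenset({"AM", "PM"}))),
    "Tue": (("A", frozenset({"AM", "PM"})), ("C", frozenset({"AM", "PM"}))),
    "Wed": (("C", frozenset({"PM"})), ("E", frozenset({"PM"}))),
    "Thu": (
        ("A", frozenset({"PM"})),
        ("B", frozenset({"AM", "PM"})),
        ("D", frozenset({"AM"})),
    ),
    "Fri": (("A", frozenset({"AM", "PM"})), ("B", frozenset({"AM", "PM"}))),
}

_UST_AM_DAYS = frozenset({"Mon", "Tue", "Wed", "Thu"})


def roster(day: str, n_rn: int = 1, n_lpn: int = 2, n_ma: int = 1) -> StaffRoster:
    if day not in WEEKDAYS:
        raise ConfigurationError(f"unknown weekday {day!r}; expected one of {WEEKDAYS}")
    return StaffRoster(
        day=day,
        providers=_ROSTER[day],
        n_rn=n_rn,
        n_lpn=n_lpn,
        n_ma=n_ma,
        ust_am=day in _UST_AM_DAYS,
    )


def scheduled_count(day: str) -> int:
    """Total patients scheduled across all providers on ``day``."""
    if day not in _ROSTER:
        raise ConfigurationError(f"unknown weekday {day!r}")
    return sum(
        16 * ("AM" in sessions) + 12 * ("PM" in sessions)
        for _, sessions in _ROSTER[day]
    )


# ---------------------------------------------------------------------------
# Patient population parameters
# ---------------------------------------------------------------------------

# Show-up probabilities by (provider, day, kind).  The published table lists
# one value per provider working day in roster order.
_SHOWUP: dict[tuple[str, str, str], float] = {
    ("A", "Tue", "new"): 0.80, ("A", "Tue", "return"): 0.75,
    ("A", "Thu", "new"): 0.70, ("A", "Thu", "return"): 0.75,
    ("A", "Fri", "new"): 0.90, ("A", "Fri", "return"): 0.78,
    ("B", "Thu", "new"): 0.71, ("B", "Thu", "return"): 0.50,
    ("B", "Fri", "new"): 0.75, ("B", "Fri", "return"): 0.66,
    ("C", "Tue", "new"): 0.90, ("C", "Tue", "return"): 0.83,
    ("C", "Wed", "new"): 1.00, ("C", "Wed", "return"): 0.94,
    ("D", "Mon", "new"): 0.93, ("D", "Mon", "return"): 0.80,
    ("D", "Thu", "new"): 0.55, ("D", "Thu", "return"): 1.00,
    ("E", "Mon", "new"): 0.56, ("E", "Mon", "return"): 0.80,
    ("E", "Wed", "new"): 1.00, ("E", "Wed", "return"): 0.95,
}

_LAB_PROB = {"NOB": 1.0, "ROB": 0.3, "NGYN": 0.6, "RGYN": 0.6}


@dataclass(frozen=True)
class PatientPopulationParams:
    """Arrival behaviour, no-shows, and lab routing of the patient population.

    ``im_lab_rate_per_hour`` is the Poisson rate of internal-medicine lab
    visits sharing the single lab room (the IM clinic itself is not modelled;
    its only coupling to the OB/GYN flow is this background load).
    """

    showup: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(_SHOWUP)
    )
    lab_prob: Mapping[str, float] = field(default_factory=lambda: dict(_LAB_PROB))
    arrival_jitter_sd: float = 7.0      # minutes, Normal(0, sd) around appointment
    new_patient_early: float = 15.0     # new patients arrive this much earlier
    sda_split: float = 0.5              # P(SDA slot resolves to ROB)
    im_lab_rate_per_hour: float = 2.0
    im_new_frac: float = 0.5

    def __post_init__(self) -> None:
        for k, p in self.showup.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"show-up probability {k} = {p} outside [0, 1]")
        for c, p in self.lab_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"lab probability {c} = {p} outside [0, 1]")
        if not 0.0 <= self.sda_split <= 1.0:
            raise ConfigurationError(f"sda_split = {self.sda_split} outside [0, 1]")
        if self.im_lab_rate_per_hour < 0:
            raise ConfigurationError("im_lab_rate_per_hour must be >= 0")

    def get_showup(self, provider: str, day: str, kind: str) -> float:
        key = (provider, day, kind)
        if key in self.showup:
            return self.showup[key]
        raise ConfigurationError(f"no show-up probability configured for {key}")


def default_population(**overrides) -> PatientPopulationParams:
    return PatientPopulationParams(**overrides)


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified simulation scenario.

    x1/x2/x3 are the LPN/RN/MA head-counts; ``t_am``/``t_pm`` are the slot
    spacings of the modified template (ignored for the baseline template).
    """

    x1: int = 2                         # LPNs
    x2: int = 1                         # RNs
    x3: int = 1                         # MAs
    template_kind: str = "baseline"
    t_am: float | None = None
    t_pm: float | None = None
    days: tuple[str, ...] = ("Mon", "Tue", "Thu", "Fri")
    population: PatientPopulationParams = field(default_factory=PatientPopulationParams)
    dist_table: Mapping[tuple[str, str], dist.DistributionSpec] | None = None
    horizon_start: float = HORIZON_START
    horizon_end: float = HORIZON_END
    n_exam_rooms: int = 7
    n_lab_rooms: int = 1
    ma_escort_allowed: bool = True      # MA escorts only when no RN/LPN is free
    lab_after_provider: bool = True
    # MA specimen handling after each draw (occupies the MA, not the lab room)
    lab_processing: dist.DistributionSpec | None = field(
        default_factory=lambda: dist.DistributionSpec("triangular", (2, 4, 6))
    )
    roster_overrides: Mapping[str, StaffRoster] | None = None
    template_overrides: Mapping[str, Template] | None = None

    def __post_init__(self) -> None:
        for name, v in (("x1", self.x1), ("x2", self.x2), ("x3", self.x3)):
            if not (X_BOUNDS[0] <= v <= X_BOUNDS[1]):
                raise ConstraintViolationError(
                    f"{name}={v} outside bounds [{X_BOUNDS[0]}, {X_BOUNDS[1]}]"
                )
        if self.template_kind not in ("baseline", "modified"):
            raise ConfigurationError(
                f"template_kind must be baseline or modified, got {self.template_kind!r}"
            )
        if self.template_kind == "modified":
            if self.t_am is None or self.t_pm is None:
                raise ConfigurationError("modified template requires t_am and t_pm")
            # bound check delegated (raises ConstraintViolationError)
            build_modified_template("_check", self.t_am, self.t_pm)
        for d in self.days:
            if d not in WEEKDAYS:
                raise ConfigurationError(f"unknown weekday {d!r} in days")
        if self.n_exam_rooms < 1 or self.n_lab_rooms < 1:
            raise ConfigurationError("need at least one exam room and one lab room")
        if not self.lab_after_provider:
            raise ConfigurationError(
                "lab-before-provider routing is not implemented; "
                "lab_after_provider must be True"
            )

    # -- accessors used by the engine --------------------------------------

    def distribution(self, role: str, kind: str) -> dist.DistributionSpec:
        table = self.dist_table if self.dist_table is not None else _default_table()
        try:
            return table[(role, kind)]
        except KeyError:
            raise ConfigurationError(
                f"no service-time law configured for role={role!r} kind={kind!r}"
            ) from None

    def roster_for(self, day: str) -> StaffRoster:
        if self.roster_overrides and day in self.roster_overrides:
            r = self.roster_overrides[day]
        else:
            r = roster(day)
        return dataclasses.replace(r, n_lpn=self.x1, n_rn=self.x2, n_ma=self.x3)

    def template_for(self, provider_id: str, sessions) -> Template:
        if self.template_overrides and provider_id in self.template_overrides:
            return self.template_overrides[provider_id]
        if self.template_kind == "baseline":
            return build_baseline_template(provider_id, sessions)
        return build_modified_template(provider_id, self.t_am, self.t_pm, sessions)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "staffing": {"x1": self.x1, "x2": self.x2, "x3": self.x3},
            "template": self.template_kind,
            "spacings": {"t_am": self.t_am, "t_pm": self.t_pm},
            "days": list(self.days),
            "rooms": {"exam": self.n_exam_rooms, "lab": self.n_lab_rooms},
            "ma_escort_allowed": self.ma_escort_allowed,
            "lab_processing": None
            if self.lab_processing is None
            else {
                "family": self.lab_processing.family,
                "params": list(self.lab_processing.params),
                "time_divisor": self.lab_processing.time_divisor,
            },
            "population": {
                "arrival_jitter_sd": self.population.arrival_jitter_sd,
                "new_patient_early": self.population.new_patient_early,
                "sda_split": self.population.sda_split,
                "im_lab_rate_per_hour": self.population.im_lab_rate_per_hour,
                "im_new_frac": self.population.im_new_frac,
                "lab_prob": dict(self.population.lab_prob),
                "showup": {
                    f"{p}/{day}/{kind}": v
                    for (p, day, kind), v in self.population.showup.items()
                },
            },
        }
        if self.dist_table is not None:
            d["distributions"] = {
                f"{role}/{kind}": {
                    "family": s.family,
                    "params": list(s.params),
                    "time_divisor": s.time_divisor,
                }
                for (role, kind), s in self.dist_table.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        try:
            staffing = d.get("staffing", {})
            pop_d = d.get("population", {})
            pop_kwargs = {}
            for k in (
                "arrival_jitter_sd",
                "new_patient_early",
                "sda_split",
                "im_lab_rate_per_hour",
                "im_new_frac",
            ):
                if k in pop_d:
                    pop_kwargs[k] = float(pop_d[k])
            if "lab_prob" in pop_d:
                pop_kwargs["lab_prob"] = {k: float(v) for k, v in pop_d["lab_prob"].items()}
            if "showup" in pop_d:
                showup = {}
                for key, v in pop_d["showup"].items():
                    p, day, kind = key.split("/")
                    showup[(p, day, kind)] = float(v)
                pop_kwargs["showup"] = showup
            table = None
            if "distributions" in d:
                table = {}
                for key, sd in d["distributions"].items():
                    role, kind = key.split("/")
                    table[(role, kind)] = dist.DistributionSpec(
                        sd["family"], tuple(sd["params"]), sd.get("time_divisor", 1)
                    )
            spacings = d.get("spacings", {}) or {}
            rooms = d.get("rooms", {}) or {}
            lp = d.get("lab_processing", "default")
            if lp == "default":
                lab_processing = dist.DistributionSpec("triangular", (2, 4, 6))
            elif lp is None:
                lab_processing = None
            else:
                lab_processing = dist.DistributionSpec(
                    lp["family"], tuple(lp["params"]), lp.get("time_divisor", 1)
                )
            return cls(
                x1=int(staffing.get("x1", 2)),
                x2=int(staffing.get("x2", 1)),
                x3=int(staffing.get("x3", 1)),
                template_kind=d.get("template", "baseline"),
                t_am=None if spacings.get("t_am") is None else float(spacings["t_am"]),
                t_pm=None if spacings.get("t_pm") is None else float(spacings["t_pm"]),
                days=tuple(d.get("days", ("Mon", "Tue", "Thu", "Fri"))),
                population=PatientPopulationParams(**pop_kwargs),
                dist_table=table,
                n_exam_rooms=int(rooms.get("exam", 7)),
                n_lab_rooms=int(rooms.get("lab", 1)),
                ma_escort_allowed=bool(d.get("ma_escort_allowed", True)),
                lab_processing=lab_processing,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed scenario: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        try:
            d = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid scenario YAML: {exc}") from exc
        if not isinstance(d, Mapping):
            raise ConfigurationError("scenario YAML must be a mapping")
        return cls.from_dict(d)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_yaml(fh.read())


_TABLE_CACHE: dict | None = None


def _default_table():
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = dist.load_default_table()
    return _TABLE_CACHE
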