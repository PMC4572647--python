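"""Synthetic patient-tracker (PT) log: format, generator, extractors.

The PT log emulates timestamp ("milestone") data captured by clinic staff at
each patient interaction.  One row per arrived patient, one column per
milestone, empty cells for milestones that did not occur (e.g. lab stamps for
patients not routed to the lab).  Times are minutes past midnight as
decimals; files are UTF-8 CSV with a header row.

Milestones, in flow order:

    check_in_start, check_in, escorted, vitals_done, provider_in,
    provider_out, [lab_in, lab_out], check_out, check_out_done

``check_in`` is stamped when check-in processing finishes and ``check_out``
when the patient reaches the check-out desk, so every gap between consecutive
stamps of different stations is pure waiting and ``check_out - check_in`` is
the total spent time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import engine as _engine
from .config import ScenarioConfig
from .metrics import patient_times

__all__ = [
    "MILESTONES",
    "TrackerRecord",
    "generate_tracker_log",
    "records_from_day",
    "write_csv",
    "read_csv",
    "extract_service_samples",
    "extract_patient_times",
    "estimate_showup",
]

MILESTONES = (
    "check_in_start",
    "check_in",
    "escorted",
    "vitals_done",
    "provider_in",
    "provider_out",
    "lab_in",
    "lab_out",
    "check_out",
    "check_out_done",
)

# milestone pairs bracketing each staff role's service
_SERVICE_BRACKETS = {
    "check_in": ("check_in_start", "check_in"),
    "nurse": ("escorted", "vitals_done"),
    "lab": ("lab_in", "lab_out"),
    "check_out": ("check_out", "check_out_done"),
    "provider": ("provider_in", "provider_out"),
}


@dataclass(frozen=True)
class TrackerRecord:
    """One arrived patient's milestone row."""

    patient_id: str
    patient_class: str
    kind: str                       # "new" | "return"
    provider_id: str
    day: str
    day_index: int
    appointment_time: float
    milestones: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev = None
        for m in MILESTONES:
            t = self.milestones.get(m)
            if t is None:
                continue
            if prev is not None and t < prev - 1e-9:
                raise ValueError(
                    f"record {self.patient_id}: milestone {m} at {t} precedes "
                    f"an earlier milestone at {prev}"
                )
            prev = t

    @property
    def routed_to_lab(self) -> bool:
        return "lab_in" in self.milestones

    # duck-type the attributes metrics.patient_times expects
    @property
    def t_checkin(self):
        return self.milestones.get("check_in")

    @property
    def t_escort(self):
        return self.milestones.get("escorted")

    @property
    def t_vitals(self):
        return self.milestones.get("vitals_done")

    @property
    def t_provider_in(self):
        return self.milestones.get("provider_in")

    @property
    def t_provider_out(self):
        return self.milestones.get("provider_out")

    @property
    def t_lab_in(self):
        return self.milestones.get("lab_in")

    @property
    def t_lab_out(self):
        return self.milestones.get("lab_out")

    @property
    def t_checkout(self):
        return self.milestones.get("check_out")

    @property
    def needs_lab(self):
        return self.routed_to_lab

    @property
    def id(self):
        return self.patient_id

    @property
    def provider(self):
        return self.provider_id


def records_from_day(day_result, day_index: int = 0) -> list[TrackerRecord]:
    """Convert one simulated day's patients into PT records."""
    out = []
    for p in day_result.patients:
        ms = {
            "check_in_start": p.t_checkin_start,
            "check_in": p.t_checkin,
            "escorted": p.t_escort,
            "vitals_done": p.t_vitals,
            "provider_in": p.t_provider_in,
            "provider_out": p.t_provider_out,
            "lab_in": p.t_lab_in,
            "lab_out": p.t_lab_out,
            "check_out": p.t_checkout,
            "check_out_done": p.t_depart,
        }
        out.append(
            TrackerRecord(
                patient_id=f"{day_result.day}{day_index}-{p.id}",
                patient_class=p.pclass,
                kind=p.kind,
                provider_id=p.provider,
                day=day_result.day,
                day_index=day_index,
                appointment_time=p.appointment_time,
                milestones={k: float(v) for k, v in ms.items() if v is not None},
            )
        )
    return out


def generate_tracker_log(
    scenario: ScenarioConfig, n_days: int, seed: int
) -> list[TrackerRecord]:
    """Simulate ``n_days`` clinic days (cycling over the scenario's weekdays)
    and return their PT records.  Deterministic given the seed."""
    records: list[TrackerRecord] = []
    for i in range(n_days):
        day = scenario.days[i % len(scenario.days)]
        rng_p = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i, 0))
        )
        rng_im = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i, 1))
        )
        dr = _engine.simulate_day(scenario, day, rng_p, rng_im)
        records += records_from_day(dr, day_index=i)
    return records


def write_csv(records: Sequence[TrackerRecord], path) -> None:
    df = to_frame(records)
    df.to_csv(path, index=False)


def to_frame(records: Sequence[TrackerRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "patient_class": r.patient_class,
            "kind": r.kind,
            "provider_id": r.provider_id,
            "day": r.day,
            "day_index": r.day_index,
            "appointment_time": r.appointment_time,
        }
        for m in MILESTONES:
            row[m] = r.milestones.get(m, np.nan)
        rows.append(row)
    cols = ["patient_id", "patient_class", "kind", "provider_id", "day",
            "day_index", "appointment_time", *MILESTONES]
    return pd.DataFrame(rows, columns=cols)


def read_csv(path) -> list[TrackerRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        ms = {m: float(row[m]) for m in MILESTONES if m in row and pd.notna(row[m])}
        out.append(
            TrackerRecord(
                patient_id=str(row["patient_id"]),
                patient_class=str(row["patient_class"]),
                kind=str(row["kind"]),
                provider_id=str(row["provider_id"]),
                day=str(row["day"]),
                day_index=int(row["day_index"]),
                appointment_time=float(row["appointment_time"]),
                milestones=ms,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Extractors
# ---------------------------------------------------------------------------


def extract_service_samples(
    records: Sequence[TrackerRecord], role: str, kind: str | None = None
) -> np.ndarray:
    """Service durations of one staff role from bracketing milestones.

    ``role`` is one of check_in, nurse, lab, check_out, or ``provider_<id>``
    (e.g. ``provider_A``).  Records missing either bracketing milestone are
    excluded; an empty result triggers a warning.
    """
    provider_filter = None
    lookup = role
    if role.startswith("provider_"):
        provider_filter = role.split("_", 1)[1]
        lookup = "provider"
    if lookup not in _SERVICE_BRACKETS:
        raise ValueError(
            f"unknown role {role!r}; expected check_in, nurse, lab, check_out "
            f"or provider_<id>"
        )
    start_m, end_m = _SERVICE_BRACKETS[lookup]
    out = []
    for r in records:
        if kind is not None and r.kind != kind:
            continue
        if provider_filter is not None and r.provider_id != provider_filter:
            continue
        t0, t1 = r.milestones.get(start_m), r.milestones.get(end_m)
        if t0 is None or t1 is None:
            continue
        out.append(t1 - t0)
    if not out:
        warnings.warn(
            f"no service samples for role={role!r} kind={kind!r}", stacklevel=2
        )
    return np.asarray(out, dtype=float)


def extract_patient_times(records: Sequence[TrackerRecord]) -> pd.DataFrame:
    """Per-patient WT, total wait, and total spent time from the PT log.

    Records missing core milestones are skipped with a warning naming them
    (the diagnostics); monotonicity is already enforced at record
    construction.
    """
    core = ("check_in", "escorted", "vitals_done", "provider_in", "provider_out", "check_out")
    rows, bad = [], []
    for r in records:
        if any(m not in r.milestones for m in core):
            bad.append(r.patient_id)
            continue
        if r.routed_to_lab and "lab_out" not in r.milestones:
            bad.append(r.patient_id)
            continue
        t = patient_times(r)
        t["patient_id"] = r.patient_id
        t["day"] = r.day
        t["day_index"] = r.day_index
        rows.append(t)
    if bad:
        warnings.warn(f"skipped {len(bad)} incomplete records: {bad[:10]}", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=["patient_id", "provider", "kind", "day", "day_index",
                 "escort_wait", "wt", "lab_wait", "checkout_wait", "twt", "tst"],
    )


def estimate_showup(
    records: Sequence[TrackerRecord], scenario: ScenarioConfig
) -> dict[tuple[str, str, str], float]:
    """Arrived / scheduled ratio per (provider, day, kind) across the log."""
    day_indices: dict[str, set[int]] = {}
    arrived: dict[tuple[str, str, str], int] = {}
    for r in records:
        day_indices.setdefault(r.day, set()).add(r.day_index)
        key = (r.provider_id, r.day, r.kind)
        arrived[key] = arrived.get(key, 0) + 1

    out: dict[tuple[str, str, str], float] = {}
    for day, indices in day_indices.items():
        n_days = len(indices)
        roster = scenario.roster_for(day)
        for pid, sessions in roster.providers:
            template = scenario.template_for(pid, sessions)
            for kind in ("new", "return"):
                n_new = template.new_count()
                scheduled = (n_new if kind == "new" else template.n_patients - n_new) * n_days
                key = (pid, day, kind)
                if scheduled == 0:
                    warnings.warn(f"zero scheduled patients for {key}", stacklevel=2)
                    continue
                ratio = arrived.get(key, 0) / scheduled
                if ratio == 0.0:
                    warnings.warn(f"no arrivals observed for {key}", stacklevel=2)
                out[key] = ratio
    return out
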