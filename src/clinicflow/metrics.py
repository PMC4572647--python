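"""Micro and macro performance measures, comparisons, and validation tests.

Per-patient quantities (minutes):

* ``wt`` — wait for the provider inside the exam room, ``provider_in -
  vitals_done`` (the micro measure WT averages this).
* ``twt`` — total wait: waiting-room wait (``escorted - check_in``) + exam-room
  wait + lab queue wait (``lab_in - provider_out`` when routed) + check-out
  queue wait.
* ``tst`` — total spent time, ``check_out - check_in``.

Staff utilization is patient-contact time over scheduled minutes (570 for a
full day, 330 for an AM-only session, 255 for PM-only); exam-room and lab
utilization divide occupied time by the 570-minute clinic day.  Scenario
comparisons use Welch two-sample t tests on replication means; an "Overall"
row aggregates per-key results by unweighted means, with the overall
improvement defined as the mean of the per-key improvement percentages (not
the improvement of the means).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AM_DEADLINE, DAY_DEADLINE, HORIZON_END, HORIZON_START

__all__ = [
    "DayMetrics",
    "ReplicationMetrics",
    "ComparisonResult",
    "patient_times",
    "compute_metrics",
    "replication_metrics",
    "wait_decomposition",
    "timeseries",
    "compare_scenarios",
    "validate_against_actual",
]

_FULL_DAY_MIN = HORIZON_END - HORIZON_START  # 570


def patient_times(p) -> dict:
    """Wait/spent decomposition for one completed patient (engine or tracker)."""
    escort_wait = p.t_escort - p.t_checkin
    wt = p.t_provider_in - p.t_vitals
    lab_wait = (p.t_lab_in - p.t_provider_out) if p.needs_lab else 0.0
    pre_checkout = p.t_checkout - (p.t_lab_out if p.needs_lab else p.t_provider_out)
    twt = escort_wait + wt + lab_wait + pre_checkout
    tst = p.t_checkout - p.t_checkin
    return {
        "patient_id": p.id,
        "provider": p.provider,
        "kind": p.kind,
        "escort_wait": escort_wait,
        "wt": wt,
        "lab_wait": lab_wait,
        "checkout_wait": pre_checkout,
        "twt": twt,
        "tst": tst,
    }


@dataclass
class DayMetrics:
    """Performance measures of one simulated day."""

    day: str
    n_scheduled: int
    n_arrived: int
    wt: float
    twt: float
    tst: float
    throughput: dict                 # provider -> checked out by deadline
    utilization: dict                # resource -> fraction of scheduled time
    per_provider: dict               # provider -> {wt, twt, tst, n, throughput}
    last_depart: float
    empty: bool = False


def _scheduled_minutes(sessions) -> float:
    has_am = "AM" in sessions
    has_pm = "PM" in sessions
    if has_am and has_pm:
        return _FULL_DAY_MIN
    if has_am:
        return AM_DEADLINE - HORIZON_START      # 330
    return HORIZON_END - 765.0                   # 255


def compute_metrics(day_result, scenario) -> DayMetrics:
    """Reduce one day's raw simulation output to its performance measures."""
    patients = day_result.patients
    n_sched = sum(day_result.n_scheduled.values())
    caps = day_result.capacities

    util = {}
    for pid, sessions in day_result.provider_sessions.items():
        util[f"provider_{pid}"] = day_result.busy[f"provider_{pid}"] / _scheduled_minutes(sessions)
    util["nurse"] = day_result.busy["nurse_pool"] / (caps["nurse_pool"] * _FULL_DAY_MIN)
    util["ma"] = day_result.busy["ma_pool"] / (caps["ma_pool"] * _FULL_DAY_MIN)
    util["exam_room"] = day_result.busy["exam_rooms"] / (caps["exam_rooms"] * _FULL_DAY_MIN)
    util["lab_room"] = day_result.busy["lab_room"] / (caps["lab_room"] * _FULL_DAY_MIN)
    util["check_in_ac"] = day_result.busy["check_in_ac"] / _FULL_DAY_MIN
    util["check_out_ac"] = day_result.busy["check_out_ac"] / _FULL_DAY_MIN

    if not patients:
        return DayMetrics(
            day=day_result.day, n_scheduled=n_sched, n_arrived=0,
            wt=0.0, twt=0.0, tst=0.0,
            throughput={pid: 0 for pid in day_result.provider_sessions},
            utilization=util,
            per_provider={},
            last_depart=day_result.last_depart,
            empty=True,
        )

    rows = [patient_times(p) for p in patients]
    per_provider = {}
    throughput = {}
    for pid, sessions in day_result.provider_sessions.items():
        deadline = AM_DEADLINE if sessions == frozenset({"AM"}) else DAY_DEADLINE
        own = [p for p in patients if p.provider == pid]
        tput = sum(1 for p in own if p.t_depart is not None and p.t_depart <= deadline)
        throughput[pid] = tput
        own_rows = [r for r in rows if r["provider"] == pid]
        if own_rows:
            per_provider[pid] = {
                "wt": float(np.mean([r["wt"] for r in own_rows])),
                "twt": float(np.mean([r["twt"] for r in own_rows])),
                "tst": float(np.mean([r["tst"] for r in own_rows])),
                "n": len(own_rows),
                "throughput": tput,
            }

    return DayMetrics(
        day=day_result.day,
        n_scheduled=n_sched,
        n_arrived=len(patients),
        wt=float(np.mean([r["wt"] for r in rows])),
        twt=float(np.mean([r["twt"] for r in rows])),
        tst=float(np.mean([r["tst"] for r in rows])),
        throughput=throughput,
        utilization=util,
        per_provider=per_provider,
        last_depart=day_result.last_depart,
    )


@dataclass
class ReplicationMetrics:
    """Pooled measures of one replication (one pass over the scenario's days)."""

    rep: int
    days: tuple
    day_metrics: list
    wt: float                        # patient-weighted pooled means
    twt: float
    tst: float
    n_patients: int
    last_depart: float
    per_provider_day: dict = field(default_factory=dict)  # (day, provider) -> dict


def replication_metrics(day_results, scenario, rep: int) -> ReplicationMetrics:
    dms = [compute_metrics(dr, scenario) for dr in day_results]
    n = sum(dm.n_arrived for dm in dms)
    if n:
        wt = sum(dm.wt * dm.n_arrived for dm in dms) / n
        twt = sum(dm.twt * dm.n_arrived for dm in dms) / n
        tst = sum(dm.tst * dm.n_arrived for dm in dms) / n
    else:
        wt = twt = tst = 0.0
    ppd = {}
    for dm in dms:
        for pid, vals in dm.per_provider.items():
            ppd[(dm.day, pid)] = vals
    return ReplicationMetrics(
        rep=rep,
        days=tuple(dm.day for dm in dms),
        day_metrics=dms,
        wt=wt, twt=twt, tst=tst,
        n_patients=n,
        last_depart=max((dm.last_depart for dm in dms), default=0.0),
        per_provider_day=ppd,
    )


# ---------------------------------------------------------------------------
# Wait-cause decomposition and time series
# ---------------------------------------------------------------------------


def wait_decomposition(day_result, bin_width: float = 30.0):
    """Split each patient's waiting-room wait into room-blocked and
    staff-blocked minutes.

    At every instant a patient sits in the waiting room, either no exam room
    is free (``room_blocked``) or a room is free but no escorting staff is
    (``nurse_blocked``); the two parts sum exactly to the escort wait.
    Returns ``(per_patient, binned)`` DataFrames, with patients binned by
    waiting-room entry time.
    """
    rows = []
    for p in day_result.patients:
        rows.append({
            "patient_id": p.id,
            "ready": p.t_checkin,
            "escort_wait": p.t_escort - p.t_checkin,
            "room_blocked": p.room_blocked,
            "nurse_blocked": p.nurse_blocked,
        })
    per_patient = pd.DataFrame(
        rows, columns=["patient_id", "ready", "escort_wait", "room_blocked", "nurse_blocked"]
    )
    if per_patient.empty:
        binned = pd.DataFrame(columns=["bin", "room_blocked", "nurse_blocked", "escort_wait", "n"])
        return per_patient, binned
    bins = (per_patient["ready"] // bin_width) * bin_width
    grouped = per_patient.groupby(bins)
    binned = grouped[["room_blocked", "nurse_blocked", "escort_wait"]].mean()
    binned["n"] = grouped.size()
    binned = binned.reset_index().rename(columns={"ready": "bin"})
    return per_patient, binned


def timeseries(
    replication_day_results: Sequence[Sequence],
    value: str = "escort_wait",
    bin_width: float = 30.0,
) -> pd.DataFrame:
    """Mean wait vs clock time with a 95 % CI over replications.

    ``replication_day_results`` is one sequence of ``DayResult`` per
    replication.  Patients are binned by escort time (waiting-room measures)
    or provider service start (``wt``/``twt``/``tst``).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    per_rep_bins: list[dict] = []
    for day_results in replication_day_results:
        acc: dict[float, list] = {}
        for dr in day_results:
            for p in dr.patients:
                times = patient_times(p)
                anchor = p.t_escort if value in ("escort_wait", "room_blocked", "nurse_blocked") else p.t_provider_in
                v = {
                    "room_blocked": p.room_blocked,
                    "nurse_blocked": p.nurse_blocked,
                }.get(value, times.get(value))
                if v is None:
                    raise ValueError(f"unknown time-series value {value!r}")
                b = math.floor(anchor / bin_width) * bin_width
                acc.setdefault(b, []).append(v)
        per_rep_bins.append({b: (float(np.mean(vs)), len(vs)) for b, vs in acc.items()})
    all_bins = sorted({b for d in per_rep_bins for b in d})
    rows = []
    for b in all_bins:
        vals = np.array([d[b][0] for d in per_rep_bins if b in d])
        n_patients = sum(d[b][1] for d in per_rep_bins if b in d)
        mean = float(vals.mean())
        if len(vals) > 1:
            half = float(stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / math.sqrt(len(vals)))
        else:
            half = float("nan")
        rows.append({"bin": b, "mean": mean, "ci_low": mean - half,
                     "ci_high": mean + half, "n_reps": len(vals),
                     "n_patients": n_patients})
    return pd.DataFrame(
        rows, columns=["bin", "mean", "ci_low", "ci_high", "n_reps", "n_patients"]
    )


# ---------------------------------------------------------------------------
# Scenario comparison and validation
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    table: pd.DataFrame              # per-key rows
    overall: dict                    # unweighted aggregation across keys

    def round(self, ndigits: int = 2) -> pd.DataFrame:
        """Report-style view with values rounded for table parity."""
        out = self.table.copy()
        for c in ("baseline", "best", "improvement_pct"):
            out[c] = out[c].round(ndigits)
        overall = {
            k: (round(v, ndigits) if isinstance(v, float) else v)
            for k, v in self.overall.items()
        }
        out.loc["Overall"] = [
            overall.get("baseline"), overall.get("best"),
            overall.get("improvement_pct"), overall.get("p"),
        ]
        return out


def _as_array(v) -> np.ndarray:
    return np.atleast_1d(np.asarray(v, dtype=float))


def compare_scenarios(
    baseline: Mapping[object, Sequence[float] | float],
    best: Mapping[object, Sequence[float] | float],
    keys: Sequence | None = None,
) -> ComparisonResult:
    """Compare two scenarios key by key (keys are e.g. provider-days).

    Values may be replication vectors (Welch t test per key) or plain means
    (no test).  Improvement % per key is ``100 * (baseline - best) /
    baseline``; the overall row takes unweighted means of the per-key means
    and of the per-key improvement percentages.
    """
    if keys is None:
        keys = list(baseline.keys())
    missing = [k for k in keys if k not in baseline or k not in best]
    if missing:
        raise KeyError(f"keys missing from one side of the comparison: {missing}")

    rows = {}
    base_vectors, best_vectors = [], []
    for k in keys:
        b = _as_array(baseline[k])
        s = _as_array(best[k])
        b_mean, s_mean = float(b.mean()), float(s.mean())
        imp = 100.0 * (b_mean - s_mean) / b_mean if b_mean != 0 else float("nan")
        if len(b) >= 2 and len(s) >= 2:
            p = float(stats.ttest_ind(b, s, equal_var=False).pvalue)
            if math.isnan(p) and np.allclose(b, s):
                p = 1.0
            base_vectors.append(b)
            best_vectors.append(s)
        else:
            p = float("nan")
        rows[k] = {"baseline": b_mean, "best": s_mean, "improvement_pct": imp, "p": p}

    table = pd.DataFrame.from_dict(rows, orient="index")
    overall = {
        "baseline": float(table["baseline"].mean()),
        "best": float(table["best"].mean()),
        "improvement_pct": float(table["improvement_pct"].mean()),
        "p": float("nan"),
    }
    if base_vectors and len({len(v) for v in base_vectors}) == 1 and len({len(v) for v in best_vectors}) == 1:
        overall_base = np.mean(np.vstack(base_vectors), axis=0)
        overall_best = np.mean(np.vstack(best_vectors), axis=0)
        p = float(stats.ttest_ind(overall_base, overall_best, equal_var=False).pvalue)
        if math.isnan(p) and np.allclose(overall_base, overall_best):
            p = 1.0
        overall["p"] = p
    return ComparisonResult(table=table, overall=overall)


def validate_against_actual(
    sim_reps: Mapping[object, Sequence[float]],
    actual: Mapping[object, float],
) -> dict:
    """Two-sided one-sample t test of simulated replication means against the
    observed value, per key.  Returns key -> p-value."""
    out = {}
    for k, target in actual.items():
        v = _as_array(sim_reps[k])
        if len(v) < 2:
            raise ValueError(f"need >= 2 replications for key {k!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # near-constant data
            res = stats.ttest_1samp(v, float(target))
        p = float(res.pvalue)
        if math.isnan(p) and np.allclose(v, target):
            p = 1.0
        out[k] = p
    return out
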