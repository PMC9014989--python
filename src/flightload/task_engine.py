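"""Discrete-time simulator of the four-subtask flight multitasking paradigm.

The paradigm consists of four concurrent subtasks shown on one display:

* **tracking** — keep a circular cursor on a moving aircraft target with a
  joystick; performance is the cursor-target distance (mm), and excursions
  beyond an alarm threshold (30 mm) are logged as alarms.
* **meter** — four dashboards whose pointers rise clockwise at different
  speeds; a key press while the pointer is inside its red warning arc resets
  it, otherwise it falls back by itself after passing the arc.
* **emergency** — groups of 10–20 red dots appear sporadically; the operator
  counts them and presses the matching number key within a 30-s window; the
  next group appears 30 s after the current one resolves.
* **residual** — a numeral is always on screen; a correct key press makes the
  next appear immediately. Response throughput indexes spare capacity.

Load conditions activate subsets: low = {tracking, residual}, medium adds the
meters, high adds the emergencies.

The synthetic operator is a limited-capacity resource allocator: each subtask
requests a share of a fixed resource pool, primary tasks are filled greedily in
priority order, and the residual-capacity task receives only what is left.
Tracking error follows a 2-D Ornstein–Uhlenbeck process whose mean-reversion
rate is ``tracking_gain`` times the allocated tracking share, so resource
competition degrades tracking; the residual task's response rate scales with
its allocated share, so competition throttles numeral throughput.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from ._streams import rng_from
from .errors import ConfigurationError, MetricError, ValidationError

__all__ = [
    "CONDITIONS", "CONDITION_TASKS", "TaskConfig", "OperatorProfile",
    "MeterEvent", "EmergencyEvent", "NumeralEvent", "BehaviorLog",
    "PerformanceSummary", "allocate_resources", "simulate_session",
    "score_performance", "write_behavior_log", "read_behavior_log",
]

CONDITIONS = ("low", "medium", "high")

CONDITION_TASKS = {
    "low": frozenset({"tracking", "residual"}),
    "medium": frozenset({"tracking", "residual", "meter"}),
    "high": frozenset({"tracking", "residual", "meter", "emergency"}),
}

# Fraction of the mean response latency that is an irreducible motor/perceptual
# floor; the remainder is exponentially distributed.
_LATENCY_SHIFT_FRAC = 0.4


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one 180-s multitasking run."""

    condition: str = "low"
    duration_s: float = 180.0
    tick_hz: float = 20.0
    alarm_threshold_mm: float = 30.0
    alarm_check_hz: float = 1.0
    alarm_mode: str = "onset"  # "onset" | "per_check"
    dot_count_range: tuple = (10, 20)
    emergency_window_s: float = 30.0
    emergency_gap_s: float = 30.0
    emergency_first_onset_range_s: tuple = (5.0, 15.0)
    meter_count: int = 4
    meter_speeds_deg_s: tuple = (9.0, 12.0, 15.0, 18.0)
    warning_arc_deg: float = 30.0
    warning_arc_start_deg: tuple = (190.0, 230.0, 270.0, 310.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITION_TASKS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.tick_hz <= 0:
            raise ConfigurationError("tick_hz must be > 0")
        if self.alarm_check_hz <= 0:
            raise ConfigurationError("alarm_check_hz must be > 0")
        if self.alarm_mode not in ("onset", "per_check"):
            raise ConfigurationError("alarm_mode must be 'onset' or 'per_check'")
        lo, hi = self.dot_count_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer)) and lo <= hi):
            raise ConfigurationError("dot_count_range must be an integer interval with low <= high")
        if self.meter_count != len(self.meter_speeds_deg_s) or self.meter_count != len(self.warning_arc_start_deg):
            raise ConfigurationError("need one speed and one warning-arc position per meter")
        speeds = tuple(self.meter_speeds_deg_s)
        if any(s <= 0 for s in speeds) or len(set(speeds)) != len(speeds):
            raise ConfigurationError("meter speeds must be positive and pairwise distinct")
        if not (0 < self.warning_arc_deg < 360):
            raise ConfigurationError("warning_arc_deg must be in (0, 360)")

    @property
    def active_tasks(self) -> frozenset:
        return CONDITION_TASKS[self.condition]


@dataclass(frozen=True)
class OperatorProfile:
    """Limited-capacity synthetic operator.

    ``demands`` is the resource share each subtask requests when it has a
    pending event (tracking and the residual numeral are always pending; each
    pending meter warning requests one meter share). ``priority_order`` fills
    requests greedily; the residual-capacity task must rank last.
    """

    capacity: float = 1.0
    priority_order: tuple = ("meter", "emergency", "tracking", "residual")
    demands: dict = field(default_factory=lambda: {
        "tracking": 0.85, "meter": 0.30, "emergency": 0.35, "residual": 0.6,
    })
    tracking_noise_sd: float = 30.0   # mm / sqrt(s) diffusion of the error process
    tracking_gain: float = 2.0        # 1/s error-correction rate per unit share
    meter_latency_s: float = 1.0
    emergency_latency_s: float = 15.0
    numeral_latency_s: float = 0.5
    accuracy_probs: dict = field(default_factory=lambda: {
        "meter": 0.90, "emergency": 0.85, "numeral": 0.95,
    })

    def __post_init__(self):
        if self.capacity < 0:
            raise ConfigurationError("capacity must be >= 0")
        known = {"tracking", "meter", "emergency", "residual"}
        if set(self.priority_order) - known or set(self.demands) - known:
            raise ConfigurationError(f"unknown task identifier in profile (known: {sorted(known)})")
        if self.priority_order and self.priority_order[-1] != "residual" and "residual" in self.priority_order:
            raise ConfigurationError("residual-capacity task must rank last in priority_order")
        if min(self.meter_latency_s, self.emergency_latency_s, self.numeral_latency_s) <= 0:
            raise ConfigurationError("latencies must be > 0")
        if any(not 0 <= p <= 1 for p in self.accuracy_probs.values()):
            raise ConfigurationError("accuracy probabilities must be in [0, 1]")
        if any(d < 0 for d in self.demands.values()):
            raise ConfigurationError("demands must be >= 0")
        if self.tracking_noise_sd < 0 or self.tracking_gain < 0:
            raise ConfigurationError("tracking parameters must be >= 0")


class MeterEvent(NamedTuple):
    onset_s: float                 # pointer enters the warning arc
    response_s: Optional[float]    # key press, or None if missed
    correct: bool


class EmergencyEvent(NamedTuple):
    onset_s: float
    dot_count: int
    response_s: Optional[float]
    correct: bool


class NumeralEvent(NamedTuple):
    shown_s: float
    response_s: float
    correct: bool


@dataclass(frozen=True)
class BehaviorLog:
    """Timestamped record of one run; all times are run-relative seconds."""

    condition: str
    tracking_t_s: np.ndarray
    tracking_distance_mm: np.ndarray
    alarm_events: tuple
    meter_events: tuple
    emergency_events: tuple
    numeral_events: tuple
    seed: int
    duration_s: float

    def __post_init__(self):
        t = np.asarray(self.tracking_t_s, dtype=float)
        d = np.asarray(self.tracking_distance_mm, dtype=float)
        object.__setattr__(self, "tracking_t_s", t)
        object.__setattr__(self, "tracking_distance_mm", d)
        if t.shape != d.shape:
            raise ValidationError("tracking times and distances must match")
        if d.size and (d.min() < 0):
            raise ValidationError("tracking distances must be >= 0")
        for ev in self.emergency_events:
            if ev.response_s is not None and not (0 <= ev.response_s - ev.onset_s):
                raise ValidationError("emergency response before onset")


@dataclass(frozen=True)
class PerformanceSummary:
    """The behavioral metrics of one run (None where a subtask was inactive)."""

    condition: str
    avg_distance_mm: float
    n_alarms: int
    n_numeral_responses: int
    meter_rt_s: Optional[float]
    meter_accuracy_pct: Optional[float]
    emergency_rt_s: Optional[float]
    emergency_accuracy_pct: Optional[float]


def allocate_resources(profile: OperatorProfile, active_tasks, pending_demands) -> dict:
    """Greedy priority fill of the operator's resource pool.

    ``pending_demands`` maps task name -> requested share (0 for no pending
    demand). Tasks are filled in ``priority_order``; each receives
    ``min(request, remaining pool)``, so a primary task with a pending demand
    is fully served before anything lower-ranked — in particular before the
    residual-capacity task — receives resources.
    """
    active = set(active_tasks)
    if not active:
        raise ConfigurationError("active task set must be non-empty")
    known = {"tracking", "meter", "emergency", "residual"}
    for name in list(active) + list(pending_demands):
        if name not in known:
            raise ConfigurationError(f"unknown task identifier {name!r}")
    for name in pending_demands:
        if name not in active and pending_demands[name] > 0:
            raise ConfigurationError(f"demand requested for inactive task {name!r}")
    remaining = profile.capacity
    shares = {name: 0.0 for name in active}
    for name in profile.priority_order:
        if name not in active:
            continue
        req = float(pending_demands.get(name, 0.0))
        give = min(req, remaining)
        shares[name] = give
        remaining -= give
    return shares


def _shifted_exp(rng: np.random.Generator, mean: float) -> float:
    shift = _LATENCY_SHIFT_FRAC * mean
    return shift + rng.exponential((1.0 - _LATENCY_SHIFT_FRAC) * mean)


def _simulate_meters(config: TaskConfig, profile: OperatorProfile, seed: int):
    """Per-meter warning cycles; returns (events, demand intervals)."""
    events, intervals = [], []
    acc = profile.accuracy_probs["meter"]
    for m in range(config.meter_count):
        rng = rng_from(seed, 11, m)
        speed = config.meter_speeds_deg_s[m]
        rise_s = config.warning_arc_start_deg[m] / speed
        window = config.warning_arc_deg / speed
        cycle_start = 0.0
        while True:
            onset = cycle_start + rise_s
            if onset >= config.duration_s:
                break
            latency = _shifted_exp(rng, profile.meter_latency_s)
            correct = bool(rng.random() < acc)
            if latency < window:
                resp = onset + latency
                cycle_start = resp if correct else onset + window
            else:
                resp, correct = None, False
                cycle_start = onset + window
            end = min(resp if resp is not None else onset + window, config.duration_s)
            if resp is not None and resp > config.duration_s:
                resp, correct = None, False
            events.append(MeterEvent(onset, resp, correct))
            intervals.append((onset, end))
    events.sort(key=lambda e: e.onset_s)
    return tuple(events), intervals


def _simulate_emergencies(config: TaskConfig, profile: OperatorProfile, seed: int):
    rng = rng_from(seed, 12)
    acc = profile.accuracy_probs["emergency"]
    lo, hi = config.dot_count_range
    window = config.emergency_window_s
    events, intervals = [], []
    onset = float(rng.uniform(*config.emergency_first_onset_range_s))
    while onset < config.duration_s:
        dots = int(rng.integers(lo, hi + 1))
        latency = _shifted_exp(rng, profile.emergency_latency_s)
        correct = bool(rng.random() < acc)
        if latency < window:
            resp = onset + latency
            resolved = resp if correct else onset + window
        else:
            resp, correct = None, False
            resolved = onset + window
        if resp is not None and resp > config.duration_s:
            resp, correct = None, False
        events.append(EmergencyEvent(onset, dots, resp, correct))
        intervals.append((onset, min(resolved, config.duration_s)))
        onset = resolved + config.emergency_gap_s
    return tuple(events), intervals


def _demand_segments(config: TaskConfig, profile: OperatorProfile,
                     meter_intervals, emergency_intervals):
    """Piecewise-constant resource shares over the run.

    Returns (edges, share_tracking, share_residual) with edges of length
    n_segments + 1.
    """
    edges = {0.0, config.duration_s}
    for a, b in meter_intervals + emergency_intervals:
        edges.add(min(max(a, 0.0), config.duration_s))
        edges.add(min(max(b, 0.0), config.duration_s))
    edges = np.array(sorted(edges))
    active = config.active_tasks
    tr, res = [], []
    m_iv = np.array(meter_intervals).reshape(-1, 2)
    e_iv = np.array(emergency_intervals).reshape(-1, 2)
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        n_meters = int(np.sum((m_iv[:, 0] <= mid) & (mid < m_iv[:, 1]))) if m_iv.size else 0
        em = bool(np.any((e_iv[:, 0] <= mid) & (mid < e_iv[:, 1]))) if e_iv.size else False
        demands = {
            "tracking": profile.demands["tracking"],
            "residual": profile.demands["residual"],
            "meter": n_meters * profile.demands["meter"] if "meter" in active else 0.0,
            "emergency": profile.demands["emergency"] if ("emergency" in active and em) else 0.0,
        }
        demands = {k: v for k, v in demands.items() if k in active}
        shares = allocate_resources(profile, active, demands)
        tr.append(shares.get("tracking", 0.0))
        res.append(shares.get("residual", 0.0))
    return edges, np.array(tr), np.array(res)


def _simulate_numerals(config: TaskConfig, profile: OperatorProfile, seed: int,
                       edges, share_res):
    """Renewal process of numeral responses with share-scaled rate.

    Within a segment the inter-attempt time is exponential with mean
    ``numeral_latency_s * demand / share``; segments with zero share produce no
    attempts. Crossing a segment boundary discards the pending draw and
    redraws, which is exact for a piecewise-constant-rate Poisson process.
    """
    rng = rng_from(seed, 13)
    acc = profile.accuracy_probs["numeral"]
    demand = profile.demands["residual"]
    events = []
    shown = 0.0
    for (a, b), share in zip(zip(edges[:-1], edges[1:]), share_res):
        if share <= 0 or demand <= 0:
            continue
        mean_gap = profile.numeral_latency_s * demand / share
        t = a
        while True:
            t = t + rng.exponential(mean_gap)
            if t >= b:
                break
            correct = bool(rng.random() < acc)
            events.append(NumeralEvent(shown, t, correct))
            if correct:
                shown = t
    return tuple(events)


def _ou_tracking(config: TaskConfig, profile: OperatorProfile, seed: int,
                 edges, share_tr):
    """2-D Ornstein–Uhlenbeck tracking-error path sampled at tick_hz.

    Euler–Maruyama with per-tick reversion rate θ_i = gain · share(t_i); runs
    of constant θ are advanced with a vectorized exact recursion.
    """
    n = int(round(config.duration_s * config.tick_hz))
    dt = 1.0 / config.tick_hz
    tick_t = np.arange(n) * dt
    seg_idx = np.clip(np.searchsorted(edges, tick_t, side="right") - 1, 0, len(share_tr) - 1)
    theta = profile.tracking_gain * share_tr[seg_idx]
    if np.any(theta * dt >= 1.0):
        raise ConfigurationError("tick_hz too low for the configured tracking gain (theta*dt >= 1)")
    rng = rng_from(seed, 14)
    sigma = profile.tracking_noise_sd
    eps = rng.standard_normal((n, 2)) * (sigma * np.sqrt(dt))
    pos = np.empty((n, 2))
    x = np.zeros(2)
    changes = np.flatnonzero(np.diff(theta)) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [n]))
    for s, e in zip(starts, ends):
        a = 1.0 - theta[s] * dt
        for c0 in range(s, e, 1024):
            c1 = min(c0 + 1024, e)
            m = c1 - c0
            j = np.arange(1, m + 1)
            w = eps[c0:c1] / (a ** np.arange(m))[:, None]
            cs = np.cumsum(w, axis=0)
            xs = (a ** j)[:, None] * x[None, :] + (a ** (j - 1))[:, None] * cs
            pos[c0:c1] = xs
            x = xs[-1]
    # sample at tick times: state at t_i is the value before the i-th update
    path = np.vstack([np.zeros((1, 2)), pos[:-1]])
    dist = np.hypot(path[:, 0], path[:, 1])
    return tick_t, dist


def _alarm_times(t_s: np.ndarray, dist: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Alarm check on a 1-Hz (configurable) grid; onset or per-check counting."""
    n_checks = int(np.floor(config.duration_s * config.alarm_check_hz))
    check_t = (np.arange(1, n_checks + 1)) / config.alarm_check_hz
    idx = np.clip(np.round(check_t * config.tick_hz).astype(int), 0, len(dist) - 1)
    above = dist[idx] > config.alarm_threshold_mm
    if config.alarm_mode == "per_check":
        hit = above
    else:
        prev = np.concatenate(([False], above[:-1]))
        hit = above & ~prev
    return check_t[hit]


def simulate_session(config: TaskConfig, profile: OperatorProfile) -> BehaviorLog:
    """Run one multitasking session; deterministic in (config, profile)."""
    seed = config.rng_seed
    active = config.active_tasks
    if "meter" in active:
        meter_events, meter_iv = _simulate_meters(config, profile, seed)
    else:
        meter_events, meter_iv = (), []
    if "emergency" in active:
        emergency_events, emergency_iv = _simulate_emergencies(config, profile, seed)
    else:
        emergency_events, emergency_iv = (), []
    edges, share_tr, share_res = _demand_segments(config, profile, meter_iv, emergency_iv)
    numeral_events = _simulate_numerals(config, profile, seed, edges, share_res)
    t_s, dist = _ou_tracking(config, profile, seed, edges, share_tr)
    alarms = _alarm_times(t_s, dist, config)
    return BehaviorLog(
        condition=config.condition,
        tracking_t_s=t_s,
        tracking_distance_mm=dist,
        alarm_events=tuple(float(t) for t in alarms),
        meter_events=meter_events,
        emergency_events=emergency_events,
        numeral_events=numeral_events,
        seed=seed,
        duration_s=config.duration_s,
    )


def score_performance(log: BehaviorLog, config: TaskConfig) -> PerformanceSummary:
    """Behavioral metrics of one run (tracking, alarms, RTs, accuracies)."""
    if log.tracking_distance_mm.size == 0:
        raise MetricError("empty tracking samples: average distance undefined")
    avg_distance = float(np.mean(log.tracking_distance_mm))
    n_alarms = int(_alarm_times(log.tracking_t_s, log.tracking_distance_mm, config).size)
    n_numeral = sum(1 for ev in log.numeral_events if ev.correct)

    def _rt_acc(events):
        if not events:
            return None, None
        rts = [ev.response_s - ev.onset_s for ev in events if ev.response_s is not None]
        rt = float(np.mean(rts)) if rts else None
        acc = 100.0 * sum(1 for ev in events if ev.correct) / len(events)
        return rt, acc

    active = config.active_tasks
    meter_rt, meter_acc = _rt_acc(log.meter_events) if "meter" in active else (None, None)
    em_rt, em_acc = _rt_acc(log.emergency_events) if "emergency" in active else (None, None)
    return PerformanceSummary(
        condition=log.condition,
        avg_distance_mm=avg_distance,
        n_alarms=n_alarms,
        n_numeral_responses=n_numeral,
        meter_rt_s=meter_rt,
        meter_accuracy_pct=meter_acc,
        emergency_rt_s=em_rt,
        emergency_accuracy_pct=em_acc,
    )


# ---------------------------------------------------------------------------
# serialization: JSON Lines for events, CSV for the tracking samples

def write_behavior_log(log: BehaviorLog, events_path, tracking_csv_path=None) -> None:
    with open(events_path, "w") as fh:
        header = {"stream": "meta", "condition": log.condition, "seed": log.seed,
                  "duration_s": log.duration_s}
        fh.write(json.dumps(header) + "\n")
        for t in log.alarm_events:
            fh.write(json.dumps({"stream": "alarm", "t": t}) + "\n")
        for ev in log.meter_events:
            fh.write(json.dumps({"stream": "meter", "t": ev.onset_s,
                                 "response_s": ev.response_s, "correct": ev.correct}) + "\n")
        for ev in log.emergency_events:
            fh.write(json.dumps({"stream": "emergency", "t": ev.onset_s, "dot_count": ev.dot_count,
                                 "response_s": ev.response_s, "correct": ev.correct}) + "\n")
        for ev in log.numeral_events:
            fh.write(json.dumps({"stream": "numeral", "t": ev.shown_s,
                                 "response_s": ev.response_s, "correct": ev.correct}) + "\n")
    if tracking_csv_path is not None:
        with open(tracking_csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_s", "distance_mm"])
            for t, d in zip(log.tracking_t_s, log.tracking_distance_mm):
                w.writerow([f"{t:.6g}", f"{d:.17g}"])


def read_behavior_log(events_path, tracking_csv_path=None) -> BehaviorLog:
    meta = None
    alarms, meters, emergencies, numerals = [], [], [], []
    with open(events_path) as fh:
        for line in fh:
            rec = json.loads(line)
            stream = rec.get("stream")
            if stream == "meta":
                meta = rec
            elif stream == "alarm":
                alarms.append(rec["t"])
            elif stream == "meter":
                meters.append(MeterEvent(rec["t"], rec["response_s"], rec["correct"]))
            elif stream == "emergency":
                emergencies.append(EmergencyEvent(rec["t"], rec["dot_count"],
                                                  rec["response_s"], rec["correct"]))
            elif stream == "numeral":
                numerals.append(NumeralEvent(rec["t"], rec["response_s"], rec["correct"]))
            else:
                raise ValidationError(f"unknown event stream {stream!r}")
    if meta is None:
        raise ValidationError("behavior log has no meta record")
    if tracking_csv_path is not None:
        rows = np.genfromtxt(tracking_csv_path, delimiter=",", names=True)
        t_s = np.atleast_1d(rows["t_s"]).astype(float)
        dist = np.atleast_1d(rows["distance_mm"]).astype(float)
    else:
        t_s = np.array([])
        dist = np.array([])
    return BehaviorLog(
        condition=meta["condition"], tracking_t_s=t_s, tracking_distance_mm=dist,
        alarm_events=tuple(alarms), meter_events=tuple(meters),
        emergency_events=tuple(emergencies), numeral_events=tuple(numerals),
        seed=meta["seed"], duration_s=meta["duration_s"],
    )
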