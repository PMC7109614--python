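"""Executable diagnostic-process state machine with full task traceability.

The redesigned pathway is run as an explicit state machine: one state per
clinical task, each with a responsible actor (patient, doctor, nurse or
system).  Every instance keeps an ordered task log with entry/exit
timestamps, so per-task durations — the raw material for detecting which
tasks dilate the process — fall out of the trace.  The clock is always an
explicit parameter; the engine never reads wall time.

Guards are pure, named predicates over the instance payload.  Dispatch for
an event evaluates its transitions in definition order and takes the first
whose guard holds; ``always`` is the unconditional fallback and must be the
last transition of its (state, event) group.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .config import EngineConfig
from .records import Notification
from .screening import is_eligible_for_screening

Actor = str
Guard = Callable[[Mapping[str, Any]], bool]


class ProcessModelError(ValueError):
    pass


class RejectedEvent(RuntimeError):
    """Event not valid (or no guard true) in the current state."""


class TerminalInstance(RuntimeError):
    """The instance already reached a terminal state."""


def _payload_flag(key: str) -> Guard:
    return lambda p: bool(p.get(key))


#: registered pure predicates over the instance payload
GUARDS: dict[str, Guard] = {
    "always": lambda p: True,
    "eligible": _payload_flag("eligible"),
    "screening_positive": _payload_flag("screening_positive"),
    "copd_suspected": _payload_flag("suspected"),
    "calibrated": _payload_flag("calibrated"),
    "session_invalid": lambda p: not p.get("session_valid", False),
    "session_obstructed": lambda p: bool(p.get("session_valid")) and bool(p.get("obstructed")),
    "copd_confirmed": _payload_flag("copd_confirmed"),
    "refer": _payload_flag("refer"),
}


@dataclass(frozen=True)
class NotificationSpec:
    recipient: str
    kind: str
    payload_key: str


@dataclass(frozen=True)
class Transition:
    source: str
    event: str
    guard: str
    target: str
    notify: tuple[NotificationSpec, ...] = ()


@dataclass(frozen=True)
class ProcessModel:
    """Validated process graph: states, actors, transitions, terminals."""

    initial: str
    actors: Mapping[str, Actor]
    terminals: frozenset[str]
    transitions: tuple[Transition, ...]
    _by_source_event: Mapping[tuple[str, str], tuple[Transition, ...]] = field(hash=False, default=None)  # type: ignore[assignment]

    @property
    def states(self) -> frozenset[str]:
        return frozenset(self.actors)

    def transitions_for(self, state: str, event: str) -> tuple[Transition, ...]:
        return self._by_source_event.get((state, event), ())


def load_process_model(definition: str | Path | Mapping[str, Any]) -> ProcessModel:
    """Load and validate a process definition (YAML/JSON document or dict).

    Validation enforces: known guard names; no transition out of a terminal
    state; at least one outgoing transition from every non-terminal state;
    every state reachable from the initial state; ``always`` fallbacks last
    within their (state, event) group and guard names unique within it.
    """
    if isinstance(definition, (str, Path)):
        definition = yaml.safe_load(Path(definition).read_text())
    states = definition["states"]
    initial = definition.get("initial")
    if initial not in states:
        raise ProcessModelError(f"initial state {initial!r} is not a defined state")
    actors = {name: (meta or {}).get("actor", "system") for name, meta in states.items()}
    terminals = frozenset(name for name, meta in states.items() if (meta or {}).get("terminal"))
    transitions: list[Transition] = []
    for t in definition.get("transitions", []):
        guard = t.get("guard", "always")
        if guard not in GUARDS:
            raise ProcessModelError(f"unknown guard {guard!r} on {t['from']} --{t['event']}-->")
        for s in (t["from"], t["to"]):
            if s not in states:
                raise ProcessModelError(f"transition references unknown state {s!r}")
        if t["from"] in terminals:
            raise ProcessModelError(f"terminal state {t['from']!r} has an outgoing transition")
        notify = tuple(
            NotificationSpec(n["recipient"], n["kind"], n.get("payload_key", n["kind"]))
            for n in t.get("notify", [])
        )
        transitions.append(Transition(t["from"], t["event"], guard, t["to"], notify))

    by_se: dict[tuple[str, str], list[Transition]] = {}
    for tr in transitions:
        by_se.setdefault((tr.source, tr.event), []).append(tr)
    for (src, ev), group in by_se.items():
        guards = [g.guard for g in group]
        if len(set(guards)) != len(guards):
            raise ProcessModelError(f"duplicate guard within ({src}, {ev})")
        if "always" in guards and guards.index("always") != len(guards) - 1:
            raise ProcessModelError(f"'always' fallback must be last in ({src}, {ev})")

    non_terminal = set(states) - terminals
    without_exit = non_terminal - {tr.source for tr in transitions}
    if without_exit:
        raise ProcessModelError(f"non-terminal states without outgoing transitions: {sorted(without_exit)}")

    # reachability from the initial state
    adjacency: dict[str, set[str]] = {}
    for tr in transitions:
        adjacency.setdefault(tr.source, set()).add(tr.target)
    seen = {initial}
    queue = deque([initial])
    while queue:
        for nxt in adjacency.get(queue.popleft(), ()):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    unreachable = set(states) - seen
    if unreachable:
        raise ProcessModelError(f"unreachable states: {sorted(unreachable)}")

    return ProcessModel(
        initial=initial,
        actors=actors,
        terminals=terminals,
        transitions=tuple(transitions),
        _by_source_event={k: tuple(v) for k, v in by_se.items()},
    )


def default_model(config: Optional[EngineConfig] = None) -> ProcessModel:
    return load_process_model((config or EngineConfig()).process_model_path)


class TaskLogEntry(BaseModel):
    state: str
    event: str  # the event that entered this state ('start' for the initial one)
    actor: str
    entry: dt.datetime
    exit: Optional[dt.datetime] = None


class ProcessInstance(BaseModel):
    """One patient's journey through the process, with its full trace."""

    instance_id: str
    patient_id: str
    current_state: str
    payload: dict[str, Any] = Field(default_factory=dict)
    log: list[TaskLogEntry] = Field(default_factory=list)
    notifications: list[Notification] = Field(default_factory=list)

    def is_terminal(self, model: ProcessModel) -> bool:
        return self.current_state in model.terminals


def start_instance(model: ProcessModel, instance_id: str, patient_id: str, clock: dt.datetime) -> ProcessInstance:
    inst = ProcessInstance(instance_id=instance_id, patient_id=patient_id, current_state=model.initial)
    inst.log.append(TaskLogEntry(state=model.initial, event="start", actor=model.actors[model.initial], entry=clock))
    return inst


def advance(
    instance: ProcessInstance,
    event: str,
    clock: dt.datetime,
    model: Optional[ProcessModel] = None,
    payload: Optional[Mapping[str, Any]] = None,
    config: Optional[EngineConfig] = None,
) -> ProcessInstance:
    """Apply an event to an instance (in place) and return it.

    The event payload is merged into the instance payload *before* guard
    evaluation.  The previous task's exit timestamp is stamped with the
    clock, which must not run backwards relative to the log.
    """
    model = model or default_model(config)
    cfg = config or EngineConfig()
    if instance.current_state in model.terminals:
        raise TerminalInstance(f"instance {instance.instance_id} is terminal at {instance.current_state}")
    if instance.log and clock < instance.log[-1].entry:
        raise ValueError("clock runs backwards relative to the task log")
    merged = dict(instance.payload)
    if payload:
        merged.update(payload)
    candidates = model.transitions_for(instance.current_state, event)
    if not candidates:
        raise RejectedEvent(f"event {event!r} not valid in state {instance.current_state!r}")
    taken = next((tr for tr in candidates if GUARDS[tr.guard](merged)), None)
    if taken is None:
        raise RejectedEvent(f"no guard satisfied for event {event!r} in state {instance.current_state!r}")
    # commit only after dispatch succeeded, so a rejected event leaves the instance unchanged
    instance.payload = merged
    instance.log[-1].exit = clock
    instance.current_state = taken.target
    instance.log.append(
        TaskLogEntry(state=taken.target, event=event, actor=model.actors[taken.target], entry=clock)
    )
    for spec in taken.notify:
        when = clock
        if spec.kind == "appointment_reminder" and "appointment_time" in merged:
            when = merged["appointment_time"] - cfg.reminder_lead
        instance.notifications.append(
            Notification(
                recipient_role=spec.recipient,  # type: ignore[arg-type]
                kind=spec.kind,  # type: ignore[arg-type]
                scheduled_time=when,
                payload_key=spec.payload_key,
                patient_id=instance.patient_id,
            )
        )
    return instance


def schedule_reminder(
    patient_id: str, appointment_time: dt.datetime, config: Optional[EngineConfig] = None
) -> Notification:
    """Appointment reminder, scheduled exactly lead-time before the visit."""
    cfg = config or EngineConfig()
    return Notification(
        recipient_role="patient",
        kind="appointment_reminder",
        scheduled_time=appointment_time - cfg.reminder_lead,
        payload_key="appointment_reminder",
        patient_id=patient_id,
    )


def replay(model: ProcessModel, log: Sequence[TaskLogEntry]) -> str:
    """Replay a task log against the model; returns the final state.

    Raises if the logged (state, event) sequence is not a walk in the model
    graph — the soundness oracle for the engine's traces.
    """
    if not log:
        raise ValueError("empty log")
    if log[0].state != model.initial or log[0].event != "start":
        raise ValueError("log does not begin at the initial state")
    state = model.initial
    for entry in log[1:]:
        targets = {tr.target for tr in model.transitions_for(state, entry.event)}
        if entry.state not in targets:
            raise ValueError(f"log step {state!r} --{entry.event}--> {entry.state!r} is not in the model")
        state = entry.state
    return state


class Appointment(BaseModel):
    patient_id: str
    age: Optional[int] = None
    appointment_time: dt.datetime


@dataclass
class SweepResult:
    invites: list[Notification]
    instances: list[ProcessInstance]
    skipped: list[str]  # patient ids skipped (missing age)


def nightly_appointment_sweep(
    appointments: Iterable[Appointment | Mapping[str, Any]],
    screening_history: Mapping[str, dt.date],
    clock: dt.datetime,
    invited_history: Optional[dict[str, dt.date]] = None,
    model: Optional[ProcessModel] = None,
    config: Optional[EngineConfig] = None,
) -> SweepResult:
    """End-of-day sweep over newly made appointments.

    For every appointment whose patient passes the opportunistic-screening
    gate (strictly over the age cut, not screened — nor already invited —
    within the revalidation window), a process instance is opened and a
    screening invite issued.  At most one invite per patient per sweep; an
    appointment without an age is skipped and reported.  Passing the same
    ``invited_history`` dict across sweeps makes the sweep idempotent.
    """
    cfg = config or EngineConfig()
    model = model or default_model(cfg)
    invited_history = invited_history if invited_history is not None else {}
    invites: list[Notification] = []
    instances: list[ProcessInstance] = []
    skipped: list[str] = []
    seen: set[str] = set()
    for i, appt in enumerate(appointments):
        if not isinstance(appt, Appointment):
            appt = Appointment(**appt)
        if appt.patient_id in seen:
            continue
        if appt.age is None:
            skipped.append(appt.patient_id)
            continue
        last = screening_history.get(appt.patient_id)
        last_invite = invited_history.get(appt.patient_id)
        if last_invite is not None and (last is None or last_invite > last):
            last = last_invite
        decision = is_eligible_for_screening(None, clock.date(), last, cfg, age=appt.age)
        if not decision.eligible:
            continue
        seen.add(appt.patient_id)
        inst = start_instance(model, f"sweep-{clock.date().isoformat()}-{i}", appt.patient_id, clock)
        advance(inst, "appointment_registered", clock, model, config=cfg)
        advance(
            inst,
            "eligibility_checked",
            clock,
            model,
            payload={"eligible": True, "appointment_time": appt.appointment_time},
            config=cfg,
        )
        invites.extend(n for n in inst.notifications if n.kind == "screening_invite")
        instances.append(inst)
        invited_history[appt.patient_id] = clock.date()
    return SweepResult(invites=invites, instances=instances, skipped=skipped)


def task_duration_report(instances: Iterable[ProcessInstance]) -> pd.DataFrame:
    """Per-task duration summary over closed log entries.

    Columns: count, mean_s, median_s, max_s, open_count; one row per state
    that appears in any log.  Open (no-exit) entries are excluded from the
    duration statistics and counted separately.
    """
    rows = []
    for inst in instances:
        for entry in inst.log:
            rows.append(
                {
                    "state": entry.state,
                    "duration_s": (entry.exit - entry.entry).total_seconds() if entry.exit else None,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["count", "mean_s", "median_s", "max_s", "open_count"])
    df = pd.DataFrame(rows)
    closed = df.dropna(subset=["duration_s"])
    agg = closed.groupby("state")["duration_s"].agg(count="count", mean_s="mean", median_s="median", max_s="max")
    open_counts = df[df["duration_s"].isna()].groupby("state").size().rename("open_count")
    report = agg.join(open_counts, how="outer").fillna({"open_count": 0, "count": 0})
    report["open_count"] = report["open_count"].astype(int)
    report["count"] = report["count"].astype(int)
    return report.sort_index()


def export_task_log(instances: Iterable[ProcessInstance]) -> str:
    """Task logs as JSON Lines: one record per log entry."""
    lines = []
    for inst in instances:
        for entry in inst.log:
            lines.append(
                json.dumps(
                    {
                        "instance_id": inst.instance_id,
                        "patient_id": inst.patient_id,
                        "state": entry.state,
                        "event": entry.event,
                        "actor": entry.actor,
                        "entry": entry.entry.isoformat(),
                        "exit": entry.exit.isoformat() if entry.exit else None,
                    }
                )
            )
    return "\n".join(lines)
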