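"""Process engine: model validation, event dispatch, traceability, sweep."""

import datetime as dt

import pytest
import yaml

from copdflow.process import (
    Appointment,
    ProcessModelError,
    RejectedEvent,
    TerminalInstance,
    advance,
    load_process_model,
    nightly_appointment_sweep,
    replay,
    schedule_reminder,
    start_instance,
    task_duration_report,
)

T0 = dt.datetime(2026, 3, 2, 8, 0)


def minutes(n):
    return T0 + dt.timedelta(minutes=n)


class TestModelValidation:
    def test_bundled_model_loads_with_expected_shape(self, model):
        assert len(model.states) == 19
        assert model.initial == "appointment_requested"
        assert model.terminals == {"not_copd", "copd_diagnosed_primary_care", "referred_to_specialist", "no_show"}

    def test_transition_out_of_terminal_rejected(self, cfg):
        doc = yaml.safe_load(cfg.process_model_path.read_text())
        doc["transitions"].append({"from": "not_copd", "event": "oops", "guard": "always", "to": "no_show"})
        with pytest.raises(ProcessModelError, match="not_copd"):
            load_process_model(doc)

    def test_unreachable_state_rejected(self, cfg):
        doc = yaml.safe_load(cfg.process_model_path.read_text())
        doc["states"]["orphan"] = {"actor": "system"}
        doc["transitions"].append({"from": "orphan", "event": "x", "guard": "always", "to": "not_copd"})
        with pytest.raises(ProcessModelError, match="orphan"):
            load_process_model(doc)

    def test_missing_initial_state_rejected(self, cfg):
        doc = yaml.safe_load(cfg.process_model_path.read_text())
        doc["initial"] = "nowhere"
        with pytest.raises(ProcessModelError, match="nowhere"):
            load_process_model(doc)

    def test_unknown_guard_rejected(self, cfg):
        doc = yaml.safe_load(cfg.process_model_path.read_text())
        doc["transitions"][0]["guard"] = "mystery"
        with pytest.raises(ProcessModelError, match="mystery"):
            load_process_model(doc)


class TestAdvance:
    def test_eligible_patient_gets_screening_invite(self, model, cfg):
        inst = start_instance(model, "i1", "p1", T0)
        advance(inst, "appointment_registered", minutes(1), model, config=cfg)
        advance(inst, "eligibility_checked", minutes(2), model, payload={"eligible": True}, config=cfg)
        assert inst.current_state == "screening_invited"
        assert [n.kind for n in inst.notifications] == ["screening_invite"]

    def test_positive_screening_notifies_patient_and_doctor(self, model, cfg):
        inst = start_instance(model, "i1", "p1", T0)
        advance(inst, "appointment_registered", minutes(1), model, config=cfg)
        advance(inst, "eligibility_checked", minutes(2), model, payload={"eligible": True}, config=cfg)
        advance(inst, "screening_done", minutes(10), model, payload={"screening_positive": True}, config=cfg)
        assert inst.current_state == "suspicion_recorded"
        alerts = [n for n in inst.notifications if n.kind == "screening_positive_alert"]
        assert {n.recipient_role for n in alerts} == {"patient", "doctor"}

    def test_event_on_terminal_instance_raises(self, model, cfg):
        inst = start_instance(model, "i1", "p1", T0)
        advance(inst, "appointment_registered", minutes(1), model, config=cfg)
        advance(inst, "eligibility_checked", minutes(2), model, payload={"eligible": False}, config=cfg)
        advance(inst, "no_show_timeout", minutes(3), model, config=cfg)
        assert inst.current_state == "no_show"
        with pytest.raises(TerminalInstance):
            advance(inst, "consultation_started", minutes(4), model, config=cfg)

    def test_invalid_event_leaves_instance_unchanged(self, model, cfg):
        inst = start_instance(model, "i1", "p1", T0)
        before = inst.model_copy(deep=True)
        with pytest.raises(RejectedEvent):
            advance(inst, "treatment_defined", minutes(1), model, config=cfg)
        assert inst == before

    def test_clock_must_not_run_backwards(self, model, cfg):
        inst = start_instance(model, "i1", "p1", T0)
        with pytest.raises(ValueError, match="backwards"):
            advance(inst, "appointment_registered", T0 - dt.timedelta(minutes=5), model, config=cfg)

    def test_log_is_a_walk_and_replay_recovers_final_state(self, model, cfg):
        inst = start_instance(model, "i1", "p1", T0)
        advance(inst, "appointment_registered", minutes(1), model, config=cfg)
        advance(inst, "eligibility_checked", minutes(2), model, payload={"eligible": True}, config=cfg)
        advance(inst, "screening_done", minutes(9), model, payload={"screening_positive": False}, config=cfg)
        advance(inst, "consultation_started", minutes(60), model, config=cfg)
        advance(inst, "evaluation_done", minutes(70), model, payload={"suspected": False}, config=cfg)
        assert inst.current_state == "not_copd"
        assert replay(model, inst.log) == "not_copd"
        # exactly one open entry per non-terminal instance; terminal has open terminal entry
        assert sum(1 for e in inst.log if e.exit is None) == 1
        entries = [e.entry for e in inst.log]
        assert entries == sorted(entries)


class TestReminder:
    def test_reminder_scheduled_exactly_lead_before(self, cfg):
        appt = dt.datetime(2026, 4, 1, 9, 30)
        n = schedule_reminder("p1", appt, cfg)
        assert n.scheduled_time == appt - dt.timedelta(hours=24)
        assert n.kind == "appointment_reminder"


class TestSweep:
    def appointments(self):
        return [
            Appointment(patient_id="a", age=38, appointment_time=minutes(600)),
            Appointment(patient_id="b", age=41, appointment_time=minutes(600)),
            Appointment(patient_id="c", age=70, appointment_time=minutes(660)),
        ]

    def test_over_40_rule_limits_invites(self, model, cfg):
        res = nightly_appointment_sweep(self.appointments(), {}, T0, model=model, config=cfg)
        assert len(res.invites) == 2
        assert {n.patient_id for n in res.invites} == {"b", "c"}
        assert all(i.current_state == "screening_invited" for i in res.instances)

    def test_recently_screened_patient_not_reinvited(self, model, cfg):
        history = {"c": (T0 - dt.timedelta(days=548)).date()}
        res = nightly_appointment_sweep(self.appointments(), history, T0, model=model, config=cfg)
        assert {n.patient_id for n in res.invites} == {"b"}

    def test_empty_appointment_list(self, model, cfg):
        res = nightly_appointment_sweep([], {}, T0, model=model, config=cfg)
        assert res.invites == [] and res.instances == []

    def test_missing_age_skipped_and_logged(self, model, cfg):
        appts = [Appointment(patient_id="x", appointment_time=minutes(600))]
        res = nightly_appointment_sweep(appts, {}, T0, model=model, config=cfg)
        assert res.invites == [] and res.skipped == ["x"]

    def test_sweep_is_idempotent_across_reruns(self, model, cfg):
        invited = {}
        first = nightly_appointment_sweep(self.appointments(), {}, T0, invited, model=model, config=cfg)
        second = nightly_appointment_sweep(self.appointments(), {}, T0, invited, model=model, config=cfg)
        assert len(first.invites) == 2 and second.invites == []

    def test_duplicate_appointments_one_invite(self, model, cfg):
        appts = self.appointments() + [Appointment(patient_id="b", age=41, appointment_time=minutes(700))]
        res = nightly_appointment_sweep(appts, {}, T0, model=model, config=cfg)
        assert sum(1 for n in res.invites if n.patient_id == "b") == 1


class TestDurationReport:
    def _closed_instance(self, model, cfg, durations):
        inst = start_instance(model, "i", "p", T0)
        t = T0
        advance(inst, "appointment_registered", t := t + dt.timedelta(seconds=durations[0]), model, config=cfg)
        advance(inst, "eligibility_checked", t := t + dt.timedelta(seconds=durations[1]), model,
                payload={"eligible": False}, config=cfg)
        return inst

    def test_single_instance_durations(self, model, cfg):
        inst = self._closed_instance(model, cfg, [300, 900])
        rep = task_duration_report([inst])
        assert rep.loc["appointment_requested", "mean_s"] == 300
        assert rep.loc["eligibility_check", "mean_s"] == 900

    def test_mean_across_instances(self, model, cfg):
        a = self._closed_instance(model, cfg, [100, 50])
        b = self._closed_instance(model, cfg, [300, 50])
        rep = task_duration_report([a, b])
        assert rep.loc["appointment_requested", "count"] == 2
        assert rep.loc["appointment_requested", "mean_s"] == 200
        assert rep.loc["appointment_requested", "max_s"] == 300

    def test_open_tasks_counted_separately(self, model, cfg):
        inst = start_instance(model, "i", "p", T0)
        rep = task_duration_report([inst])
        assert rep.loc["appointment_requested", "open_count"] == 1
        assert rep.loc["appointment_requested", "count"] == 0

    def test_empty_input_empty_report(self):
        assert task_duration_report([]).empty
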