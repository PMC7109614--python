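"""Spirometry QC and interpretation: calibration, acceptability,
reproducibility, best-value selection, LLN, obstruction calls."""

import datetime as dt
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from copdflow.config import EngineConfig
from copdflow.records import SpirometryAttempt, SpirometrySession
from copdflow.spirometry import (
    MappingError,
    RangeError,
    SpirometryError,
    check_calibration,
    check_reproducibility,
    classify_obstruction,
    compute_lln,
    flag_attempt_quality,
    interpret_session,
    select_best,
)

T0 = dt.datetime(2026, 3, 1, 10, 0)


def att(fvc, fev1, **kw):
    return SpirometryAttempt(fvc_l=fvc, fev1_l=fev1, **kw)


class TestCalibration:
    def test_recent_calibration_passes(self):
        assert check_calibration(T0 - dt.timedelta(hours=2), T0)

    def test_stale_calibration_fails(self):
        assert not check_calibration(T0 - dt.timedelta(hours=25), T0)

    def test_exactly_24h_is_inclusive(self):
        assert check_calibration(T0 - dt.timedelta(hours=24), T0)

    def test_future_calibration_is_a_data_error(self):
        with pytest.raises(SpirometryError):
            check_calibration(T0 + dt.timedelta(hours=1), T0)


class TestAttemptQuality:
    def test_short_fet_sets_early_termination(self, cfg):
        assert flag_attempt_quality(att(3.0, 2.0, fet_s=4.0), cfg).early_termination

    def test_adequate_fet_leaves_flags_clear(self, cfg):
        a = flag_attempt_quality(att(3.0, 2.0, fet_s=8.0), cfg)
        assert not a.flagged

    def test_operator_glottis_closure_excludes_attempt(self, cfg):
        rep = check_reproducibility(
            [att(3.3, 2.2, glottis_closure=True), att(3.2, 2.1), att(3.1, 2.05)], cfg
        )
        assert not rep.reproducible and rep.reason == "insufficient_attempts"


class TestReproducibility:
    def test_tight_session_passes(self, cfg):
        rep = check_reproducibility([att(3.30, 2.20), att(3.20, 2.10), att(3.10, 2.05)], cfg)
        assert rep.reproducible
        assert rep.delta_fvc_l == pytest.approx(0.10)
        assert rep.delta_fev1_l == pytest.approx(0.10)

    def test_spread_fvc_fails(self, cfg):
        rep = check_reproducibility([att(3.50, 2.0), att(3.30, 2.0), att(3.00, 2.0)], cfg)
        assert not rep.reproducible and rep.delta_fvc_l == pytest.approx(0.20)

    def test_boundary_delta_exactly_015_passes(self, cfg):
        """The rule is inclusive: a 0.15 L difference still validates."""
        rep = check_reproducibility([att(3.30, 2.20), att(3.15, 2.05), att(3.00, 2.00)], cfg)
        assert rep.reproducible
        assert rep.delta_fvc_l == pytest.approx(0.15) and rep.delta_fev1_l == pytest.approx(0.15)

    def test_fewer_than_three_acceptable_attempts(self, cfg):
        rep = check_reproducibility([att(3.3, 2.2), att(3.2, 2.1)], cfg)
        assert not rep.reproducible and rep.reason == "insufficient_attempts"

    def test_extra_attempts_use_two_best_rule(self, cfg):
        # 4 attempts: two best FVC are 3.30/3.28 even though the worst pair is wide
        rep = check_reproducibility([att(3.30, 2.2), att(3.28, 2.18), att(3.0, 2.1), att(2.9, 2.05)], cfg)
        assert rep.reproducible

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(280, 360), st.integers(180, 250)),  # centiliters
            min_size=3,
            max_size=5,
        )
    )
    def test_matches_pairwise_oracle_on_lattice(self, raw):
        """Two-best rule equals brute-force pair enumeration (integer cL oracle)."""
        cfg = EngineConfig()
        attempts = [att(f / 100, e / 100) for f, e in raw]
        rep = check_reproducibility(attempts, cfg)
        thr = round(cfg.reproducibility_threshold_l * 100)

        def best_pair_delta(vals):
            pairs = itertools.combinations(vals, 2)
            a, b = max(pairs, key=lambda p: p[0] + p[1])
            return abs(a - b)

        expected = (
            best_pair_delta([f for f, _ in raw]) <= thr
            and best_pair_delta([e for _, e in raw]) <= thr
        )
        assert rep.reproducible == expected


class TestSelectBest:
    def test_best_values_may_come_from_different_attempts(self):
        assert select_best([att(3.1, 2.2), att(3.3, 2.0)]) == (3.3, 2.2)

    def test_single_attempt_is_its_own_best(self):
        assert select_best([att(3.1, 2.2)]) == (3.1, 2.2)

    def test_empty_set_is_an_error(self):
        with pytest.raises(SpirometryError, match="no_acceptable_attempts"):
            select_best([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(100, 600), st.integers(80, 400)), min_size=1, max_size=6))
    def test_best_dominates_every_attempt(self, raw):
        attempts = [att(max(f, e) / 100, min(f, e) / 100) for f, e in raw]
        bf, be = select_best(attempts)
        assert all(bf >= a.fvc_l and be >= a.fev1_l for a in attempts)


class TestLln:
    def test_reference_male_60y_value(self, patient_factory, equations):
        """Frozen regression value from the bundled coefficient row."""
        lln, pred_fev1 = compute_lln(patient_factory(age=60), equations)
        assert 0.55 < lln < 0.75
        assert lln == pytest.approx(0.65992, abs=1e-6)
        assert pred_fev1 == pytest.approx(3.4701, abs=1e-3)

    def test_lln_decreases_with_age(self, patient_factory, equations):
        lln60, _ = compute_lln(patient_factory(age=60), equations)
        lln80, _ = compute_lln(patient_factory(age=80), equations)
        assert lln80 < lln60

    def test_lln_below_predicted_for_all_groups(self, patient_factory, equations):
        for sex in ("male", "female"):
            for group in equations.groups:
                p = patient_factory(sex=sex, ethnic_group=group, age=50)
                pred, lln, fev1 = equations.evaluate(p)
                assert 0 < lln < pred and fev1 > 0

    def test_height_range_boundary_inclusive(self, patient_factory, equations):
        compute_lln(patient_factory(height_cm=200.0), equations)  # boundary computes
        with pytest.raises(RangeError):
            compute_lln(patient_factory(height_cm=201.0), equations)

    def test_unmapped_group_lists_available(self, patient_factory, equations):
        with pytest.raises(MappingError, match="caucasian"):
            compute_lln(patient_factory(ethnic_group="martian"), equations)


class TestObstructionCall:
    def test_fixed_mode_below_cut(self):
        call = classify_obstruction(2.0, 3.0, mode="fixed")
        assert call.obstructed and call.ratio == pytest.approx(2 / 3)

    def test_ratio_exactly_070_is_not_obstructed(self):
        assert not classify_obstruction(0.70, 1.00, mode="fixed").obstructed

    def test_lln_mode_uses_the_lln_threshold(self):
        assert not classify_obstruction(0.67, 1.00, mode="lln", lln=0.65).obstructed
        assert classify_obstruction(0.64, 1.00, mode="lln", lln=0.65).obstructed

    def test_lln_mode_without_lln_is_a_config_error(self):
        with pytest.raises(SpirometryError):
            classify_obstruction(2.0, 3.0, mode="lln")


class TestSessionPipeline:
    def _session(self, attempts, calibrated=True):
        return SpirometrySession(
            session_id="s1", patient_id="p1", session_time=T0,
            last_calibration=T0 - dt.timedelta(hours=2 if calibrated else 48),
            attempts=attempts,
        )

    def test_valid_obstructed_session(self, patient_factory, equations, cfg):
        s = self._session([att(4.00, 2.40), att(3.95, 2.35), att(3.90, 2.30)])
        v = interpret_session(s, patient_factory(age=60), equations, cfg)
        assert v.valid and v.best_fvc_l == 4.00 and v.best_fev1_l == 2.40
        assert v.obstruction is True and v.threshold_mode == "lln"

    def test_uncalibrated_session_is_invalid(self, patient_factory, equations, cfg):
        s = self._session([att(4.00, 2.40)] * 3, calibrated=False)
        v = interpret_session(s, patient_factory(), equations, cfg)
        assert not v.valid and not v.calibrated and v.obstruction is None

    def test_irreproducible_session_gives_no_call(self, patient_factory, equations, cfg):
        s = self._session([att(4.00, 2.40), att(3.70, 2.35), att(3.40, 2.30)])
        v = interpret_session(s, patient_factory(), equations, cfg)
        assert not v.valid and v.obstruction is None
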