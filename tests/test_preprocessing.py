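"""Phase splitting, loss rates, exclusion filters, standardized difference."""

import numpy as np
import pytest

import pulsedx as px
from pulsedx.preprocessing import evaluation_phase_signals
from conftest import make_phase_signal


def _make_eval(pid="P0", visit="V2", wd=360, mmrc=2, hr_mask=None, spo2_mask=None):
    n = wd + px.RECOVERY_DURATION
    rng = np.random.default_rng(0)
    return px.EvaluationRecord(
        patient_id=pid,
        visit=visit,
        state="decompensated" if visit == "V1" else "compensated",
        hr=80 + rng.normal(0, 2, n),
        spo2=95 + rng.normal(0, 0.5, n),
        hr_mask=np.zeros(n, bool) if hr_mask is None else hr_mask,
        spo2_mask=np.zeros(n, bool) if spo2_mask is None else spo2_mask,
        mmrc=mmrc,
        nyha=2,
        walk_duration=wd,
    )


class TestSplitPhases:
    @pytest.mark.parametrize("wd", [360, 300, 181])
    def test_phase_lengths(self, wd):
        hr_w, hr_r, ox_w, ox_r = px.split_phases(_make_eval(wd=wd))
        assert len(hr_w) == len(ox_w) == wd
        assert len(hr_r) == len(ox_r) == px.RECOVERY_DURATION

    def test_no_sample_in_both_phases(self):
        ev = _make_eval(wd=300)
        hr_w, hr_r, _, _ = px.split_phases(ev)
        recombined = np.concatenate([hr_w.samples, hr_r.samples])
        assert np.array_equal(recombined, ev.hr[:540])

    def test_boundary_outside_recording_rejected(self):
        ev = _make_eval(wd=300)
        ev.walk_duration = 700  # tamper past construction-time validation
        with pytest.raises(ValueError):
            px.split_phases(ev)


class TestLossRate:
    def test_no_missing(self):
        assert px.loss_rate(make_phase_signal(np.ones(240))) == 0.0

    @pytest.mark.parametrize("n_masked,n,expected", [(36, 360, 0.10), (37, 360, 37 / 360)])
    def test_counts(self, n_masked, n, expected):
        mask = np.zeros(n, bool)
        mask[:n_masked] = True
        sig = make_phase_signal(np.ones(n), phase="walk", mask=mask)
        assert px.loss_rate(sig) == pytest.approx(expected)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            px.loss_rate(make_phase_signal(np.array([])))


def _patient(pid, evals, age=70.0):
    return px.PatientRecord(patient_id=pid, age=age, sex="male", disease="HF", evaluations=evals)


class TestApplyFilters:
    def test_clean_patient_fully_retained(self):
        patient = _patient(
            "A", [_make_eval("A", "V1", mmrc=4), _make_eval("A", "V2", mmrc=2)]
        )
        filtered, log = px.apply_filters([patient])
        assert len(filtered) == 1 and len(filtered[0].evaluations) == 2
        assert log == []

    def test_loss_above_ten_percent_excludes_evaluation(self):
        # 11% loss confined to the recovery HR phase
        wd = 360
        mask = np.zeros(wd + 240, bool)
        mask[wd : wd + 27] = True  # 27/240 = 11.25%
        bad = _make_eval("A", "V3", wd=wd, mmrc=2, hr_mask=mask)
        patient = _patient(
            "A", [_make_eval("A", "V1", mmrc=4), _make_eval("A", "V2", mmrc=2), bad]
        )
        filtered, log = px.apply_filters([patient])
        assert [e.visit for e in filtered[0].evaluations] == ["V1", "V2"]
        assert [(e.visit, e.rule) for e in log] == [("V3", "loss_rate")]

    def test_loss_exactly_ten_percent_retained(self):
        wd = 360
        mask = np.zeros(wd + 240, bool)
        mask[wd : wd + 24] = True  # 24/240 = 10% exactly: strict rule keeps it
        ev = _make_eval("A", "V2", wd=wd, mmrc=2, hr_mask=mask)
        patient = _patient("A", [_make_eval("A", "V1", mmrc=4), ev])
        filtered, log = px.apply_filters([patient])
        assert len(filtered[0].evaluations) == 2 and log == []

    def test_no_mmrc_improvement_removes_patient(self):
        # both home visits show zero improvement -> no valid home evaluation
        patient = _patient(
            "B",
            [
                _make_eval("B", "V1", mmrc=3),
                _make_eval("B", "V2", mmrc=3),
                _make_eval("B", "V3", mmrc=4),
            ],
        )
        filtered, log = px.apply_filters([patient])
        assert filtered == []
        rules = [e.rule for e in log]
        assert rules.count("mmrc_no_improvement") == 2
        assert "no_home_visit" in rules

    def test_v1_loss_removes_patient(self):
        wd = 360
        mask = np.zeros(wd + 240, bool)
        mask[:120] = True  # 33% walk loss
        patient = _patient(
            "C", [_make_eval("C", "V1", wd=wd, mmrc=4, spo2_mask=mask), _make_eval("C", "V2", mmrc=2)]
        )
        filtered, log = px.apply_filters([patient])
        assert filtered == []
        assert any(e.rule == "no_valid_v1" for e in log)

    def test_idempotent(self, small_cohort):
        once, _ = px.apply_filters(small_cohort)
        twice, log = px.apply_filters(once)
        assert log == []
        assert [p.patient_id for p in twice] == [p.patient_id for p in once]
        assert [len(p.evaluations) for p in twice] == [len(p.evaluations) for p in once]


class TestStandardizedDifference:
    def test_identical_series_give_zero(self):
        x = np.sin(np.linspace(0, 6, 240)) + 5
        hr = make_phase_signal(x, kind="HR")
        ox = make_phase_signal(x, kind="Ox")
        out = px.standardized_difference(hr, ox)
        assert out.kind == "HRminusOx"
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_constant_inputs_flagged_degenerate(self):
        hr = make_phase_signal(np.full(240, 80.0), kind="HR")
        ox = make_phase_signal(np.full(240, 95.0), kind="Ox")
        out = px.standardized_difference(hr, ox)
        assert out.degenerate
        assert np.all(out.samples == 0.0)

    def test_opposite_trends_with_evaluation_scope(self):
        """HR rising and Ox falling: with the standardization fitted across
        both phases, the walk-phase difference mean is positive and the
        recovery-phase mean negative."""
        n = 10
        hr_all = np.arange(2 * n, dtype=float)  # rising across the evaluation
        ox_all = -np.arange(2 * n, dtype=float)  # falling
        hr_stats = (hr_all.mean(), hr_all.std())
        ox_stats = (ox_all.mean(), ox_all.std())
        hr_w = make_phase_signal(hr_all[n:], kind="HR", phase="walk")
        ox_w = make_phase_signal(ox_all[n:], kind="Ox", phase="walk")
        hr_r = make_phase_signal(hr_all[:n], kind="HR", phase="recovery")
        ox_r = make_phase_signal(ox_all[:n], kind="Ox", phase="recovery")
        walk = px.standardized_difference(hr_w, ox_w, hr_stats, ox_stats)
        rec = px.standardized_difference(hr_r, ox_r, hr_stats, ox_stats)
        assert walk.samples.mean() > 0
        assert rec.samples.mean() < 0

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        hr = make_phase_signal(80 + rng.normal(0, 3, 240), kind="HR")
        ox = make_phase_signal(95 + rng.normal(0, 1, 240), kind="Ox")
        base = px.standardized_difference(hr, ox)
        hr10 = make_phase_signal(hr.samples * 10 + 7, kind="HR")
        scaled = px.standardized_difference(hr10, ox)
        np.testing.assert_allclose(scaled.samples, base.samples, atol=1e-10)

    def test_mask_union(self):
        m1 = np.zeros(240, bool)
        m2 = np.zeros(240, bool)
        m1[:10] = True
        m2[230:] = True
        rng = np.random.default_rng(0)
        hr = make_phase_signal(80 + rng.normal(0, 2, 240), kind="HR", mask=m1)
        ox = make_phase_signal(95 + rng.normal(0, 1, 240), kind="Ox", mask=m2)
        out = px.standardized_difference(hr, ox)
        assert np.array_equal(out.missing_mask, m1 | m2)


def test_evaluation_phase_signals_structure():
    signals = evaluation_phase_signals(_make_eval(wd=300))
    assert set(signals) == {
        (kind, phase) for kind in ("HR", "Ox", "HRminusOx") for phase in ("walk", "recovery")
    }
    assert len(signals[("HRminusOx", "walk")]) == 300
    # evaluation-scope standardization keeps phase means informative:
    # the difference is not forced to zero mean within each phase
    assert abs(signals[("HRminusOx", "walk")].unmasked.mean()) >= 0.0
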