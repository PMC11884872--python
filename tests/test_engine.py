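"""Closed-loop engine: displacement, smoothing, trial FSM, latency."""

from __future__ import annotations

import numpy as np
import pytest

from sonoreach.engine import (
    DisplacementComputer,
    KinematicSample,
    MovingAverage,
    StageDelays,
    TrialConfig,
    TrialFSM,
    measure_latency,
    run_stream,
    smooth,
)
from sonoreach.pose import Calibration

from tests.conftest import run_displacement, stream_from_displacement
from tests.oracles import count_successes_oracle, random_displacement_sequence


def fsm_events(disp, cfg=None, fps=70.0):
    cfg = cfg or TrialConfig()
    fsm = TrialFSM(cfg)
    events = []
    for i, d in enumerate(disp):
        events.extend(fsm.step(KinematicSample(i / fps, float(d), 0.0, True, True)))
    return events


class TestDisplacement:
    def test_at_rest_gives_zero(self, calibration, trial_cfg):
        stream = stream_from_displacement(np.zeros(3), calibration=calibration)
        comp = DisplacementComputer(calibration, trial_cfg)
        s = comp.step(stream.frame(0))
        assert s.disp_left == 0.0 and s.disp_right == 0.0
        assert s.valid_left and s.valid_right

    def test_pixels_to_mm(self, calibration, trial_cfg):
        # left digits 150 px above rest at 0.1 mm/px -> 15 mm
        stream = stream_from_displacement(np.array([15.0]), calibration=calibration)
        comp = DisplacementComputer(calibration, trial_cfg)
        assert comp.step(stream.frame(0)).disp_left == pytest.approx(15.0)

    def test_low_likelihood_holds_last_value(self, calibration, trial_cfg):
        stream = stream_from_displacement(np.array([7.0, 9.0]), calibration=calibration)
        comp = DisplacementComputer(calibration, trial_cfg)
        first = comp.step(stream.frame(0))
        assert first.disp_left == pytest.approx(7.0)
        frame = stream.frame(1)
        gated = np.where(
            [n.startswith("left") for n in frame.names], 0.2, frame.likelihood
        )
        frame.likelihood = gated
        second = comp.step(frame)
        assert not second.valid_left
        assert second.disp_left == pytest.approx(7.0)  # held, not 9.0
        assert second.valid_right

    def test_partial_gating_uses_passing_digits_only(self, calibration, trial_cfg):
        stream = stream_from_displacement(np.array([10.0]), calibration=calibration)
        frame = stream.frame(0)
        lik = frame.likelihood.copy()
        y = frame.y.copy()
        left = [i for i, n in enumerate(frame.names) if n.startswith("left")]
        lik[left[0]] = 0.1  # failed digit pulled far away must be ignored
        y[left[0]] = 0.0
        frame.likelihood, frame.y = lik, y
        s = DisplacementComputer(calibration, trial_cfg).step(frame)
        assert s.disp_left == pytest.approx(10.0)

    def test_missing_calibration_rejected(self, trial_cfg):
        with pytest.raises(ValueError):
            DisplacementComputer(None, trial_cfg)


class TestSmoothing:
    def test_window_one_is_identity(self):
        x = np.array([1.0, -2.0, 3.5, 0.0])
        np.testing.assert_array_equal(smooth(x, 1), x)

    def test_constant_signal_unchanged(self):
        np.testing.assert_allclose(smooth(np.full(10, 4.2), 5), np.full(10, 4.2))

    def test_step_response_hand_computed(self):
        out = smooth([0.0, 0.0, 0.0, 10.0, 10.0, 10.0], 3)
        np.testing.assert_allclose(out[3:], [10 / 3, 20 / 3, 10.0])

    def test_matches_convolution_oracle_in_steady_state(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        w = 7
        expected = np.convolve(x, np.ones(w) / w, mode="valid")
        np.testing.assert_allclose(smooth(x, w)[w - 1 :], expected, atol=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            MovingAverage(0)


class TestTrialFSM:
    def test_hand_traced_toy_sequence(self):
        # 10 samples at 10 Hz; second ramp falls inside the 0.5 s refractory
        disp = [0, 5, 16, 10, 1, 0, 8, 20, 3, 1]
        events = fsm_events(disp, fps=10.0)
        assert [(e.kind, e.timestamp) for e in events] == [
            ("reach_start", 0.1),
            ("target_entry", 0.2),
            ("success", 0.2),
            ("reward", 0.2),
            ("trial_reset", 0.9),
        ]
        assert events[3].payload == {"volume_ul": 5.0}

    def test_subthreshold_ramp_no_success(self):
        events = fsm_events([0, 4, 10, 4, 0])
        assert [e.kind for e in events] == ["reach_start", "trial_reset"]

    def test_two_ramps_within_refractory_one_success(self):
        # full ramps separated by less than 0.5 s at 70 fps
        ramp = [0, 8, 16, 8, 0]
        events = fsm_events(ramp + ramp + [0] * 80)
        assert sum(e.kind == "success" for e in events) == 1
        # after the refractory elapses at rest, the trial resets
        assert events[-1].kind == "trial_reset"

    def test_invalid_sample_freezes_state(self):
        cfg = TrialConfig()
        fsm = TrialFSM(cfg)
        fsm.step(KinematicSample(0.0, 5.0, 0.0, True, True))
        assert fsm.step(KinematicSample(0.1, 0.0, 0.0, False, True)) == []
        assert fsm.state.value == "reaching"

    def test_agrees_with_excursion_scan_oracle(self):
        cfg = TrialConfig()
        rng = np.random.default_rng(2024)
        for _ in range(300):
            d = random_displacement_sequence(rng)
            t = np.arange(d.size) / 70.0
            got = sum(e.kind == "success" for e in fsm_events(d))
            assert got == count_successes_oracle(t, d, cfg)


class TestRunSession:
    def test_success_count_matches_planted_reaches(self):
        from sonoreach.simulate import CohortDesign, LearningParams, simulate_session

        params = LearningParams(noise_sd=0.0)
        cfg = TrialConfig(smooth_window=1)
        stream, truth = simulate_session(
            "f0", 2, "feedback", params, CohortDesign(session_length=120.0), seed=5
        )
        rec = run_stream(stream, Calibration(), cfg)
        assert rec.success_count == truth.success_count
        assert rec.reach_start_count == truth.left_count

    def test_control_mode_differs_only_in_tone_log(self):
        disp = np.concatenate([np.zeros(20), np.linspace(0, 18, 30), np.zeros(50)])
        fb = run_displacement(disp, mode="feedback")
        ctrl = run_displacement(disp, mode="control")
        assert len(fb.tone_log) == disp.size and ctrl.tone_log == []
        assert [(e.kind, e.timestamp) for e in fb.events] == [
            (e.kind, e.timestamp) for e in ctrl.events
        ]
        assert fb.kinematics == ctrl.kinematics

    def test_session_is_deterministic(self):
        disp = np.concatenate([np.zeros(10), np.linspace(0, 16, 20), np.zeros(30)])
        a = run_displacement(disp)
        b = run_displacement(disp)
        assert a.events == b.events
        assert a.tone_log == b.tone_log
        assert a.timings == b.timings

    def test_event_grammar(self):
        rng = np.random.default_rng(7)
        d = random_displacement_sequence(rng, max_len=200)
        rec = run_displacement(d, cfg=TrialConfig(smooth_window=1))
        kinds = [e.kind for e in rec.events]
        assert kinds[0] == "session_start" and kinds[-1] == "session_end"
        # every success immediately followed by exactly one reward
        for i, k in enumerate(kinds):
            if k == "success":
                assert kinds[i + 1] == "reward"
        assert kinds.count("success") == kinds.count("reward")
        # events time-ordered
        times = [e.timestamp for e in rec.events]
        assert times == sorted(times)

    def test_save_load_round_trip(self, tmp_path):
        disp = np.concatenate([np.zeros(10), np.linspace(0, 16, 20), np.zeros(30)])
        rec = run_displacement(disp, mouse="f3", day=2)
        from sonoreach.engine import SessionRecord

        rec.save(tmp_path / "s")
        back = SessionRecord.load(tmp_path / "s")
        assert back.mouse == "f3" and back.day == 2
        assert back.events == rec.events
        assert back.kinematics == rec.kinematics
        assert back.tone_log == rec.tone_log


class TestLatency:
    def test_injected_stage_delays_sum_exactly(self):
        disp = np.zeros(20)
        rec = run_displacement(disp, stage_delays=StageDelays(5.0, 10.0, 15.0, 0.0))
        m = measure_latency(rec)
        assert m.mean_latency_ms == pytest.approx(30.0, abs=1e-6)
        assert m.max_latency_ms == pytest.approx(30.0, abs=1e-6)

    def test_zero_delay_zero_latency(self):
        m = measure_latency(run_displacement(np.zeros(10)))
        assert m.mean_latency_ms == pytest.approx(0.0, abs=1e-9)
        assert m.loop_rate_hz == pytest.approx(70.0)

    def test_random_delays_mean_matches_bookkeeping(self):
        rng = np.random.default_rng(11)
        means = []
        for _ in range(5):
            delays = StageDelays(*rng.uniform(0.5, 20.0, 4))
            rec = run_displacement(np.zeros(15), stage_delays=delays)
            m = measure_latency(rec)
            means.append((m.mean_latency_ms, delays.total_ms))
        for got, want in means:
            assert got == pytest.approx(want, abs=1e-6)

    def test_missing_timings_rejected(self):
        from sonoreach.engine import SessionRecord

        with pytest.raises(ValueError):
            measure_latency(SessionRecord())
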