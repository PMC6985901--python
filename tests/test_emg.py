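"""EMG event detection, trial rejection, behaviour summaries and MVF."""

import numpy as np
import pandas as pd
import pytest

from betadyn import (
    SensorRecording,
    SessionConfig,
    TrialEvents,
    compute_mvf,
    detect_contraction_bounds,
    summarize_trials,
    synthesize_session,
)

from conftest import make_schedule

FS = 600.0


def step_emg(schedule, n_samples, amplitude=1.0):
    """Noiseless rectangular EMG bursts spanning each contraction."""
    data = np.zeros((2, n_samples))
    for _, row in schedule.table.iterrows():
        i0 = int(round(row["contract_on_s"] * FS))
        i1 = int(round(row["contract_off_s"] * FS))
        data[:, i0:i1] = amplitude
    return SensorRecording(data, FS, ["ext", "flex"], kind="emg")


@pytest.fixture(scope="module")
def noiseless_fixture():
    sched = make_schedule([2.0, 5.0, 10.0])
    n = int(round((sched.table["rest_end_s"].iloc[-1] + 5) * FS))
    return sched, step_emg(sched, n)


class TestDetection:
    def test_noiseless_step_onset_exact(self, noiseless_fixture):
        sched, emg = noiseless_fixture
        ev = detect_contraction_bounds(emg, sched, filter_band=None)
        assert not ev.table["rejected"].any()
        for _, row in ev.table.merge(sched.table, on="trial_id").iterrows():
            i_true = int(round(row["contract_on_s"] * FS))
            assert int(round(row["onset_s"] * FS)) == i_true
            i_off_true = int(round(row["contract_off_s"] * FS)) - 1
            assert int(round(row["offset_s"] * FS)) == i_off_true

    def test_noisy_recovery_within_50ms(self):
        # contraction-to-baseline SD ratio 10, ~50 trials
        cfg = SessionConfig(n_channels=8, n_sources=3,
                            n_trials_per_condition=17, lead_in_s=40.0,
                            tail_s=40.0)
        s = synthesize_session(cfg, seed=21)
        ev = detect_contraction_bounds(s.emg, s.schedule)
        merged = ev.kept.merge(s.schedule.table, on="trial_id")
        assert len(merged) >= 45
        err_on = (merged["onset_s"] - merged["contract_on_s"]).abs()
        err_off = (merged["offset_s"] - merged["contract_off_s"]).abs()
        assert (err_on <= 0.050).all()
        assert (err_off <= 0.050).all()

    def test_rest_movement_injection_rejected(self, small_session):
        s = small_session
        data = s.emg.data.copy()
        sd = s.config.emg_baseline_sd
        row = s.schedule.table.iloc[2]
        t_burst = row["contract_off_s"] + 10.0
        i0 = int(round(t_burst * s.emg.fs))
        i1 = i0 + int(round(0.3 * s.emg.fs))
        rng = np.random.default_rng(0)
        data[:, i0:i1] = rng.standard_normal((2, i1 - i0)) * 10 * sd
        emg = SensorRecording(data, s.emg.fs, s.emg.channel_labels, kind="emg")
        ev = detect_contraction_bounds(emg, s.schedule)
        bad = ev.table[ev.table["trial_id"] == row["trial_id"]].iloc[0]
        assert bad["rejected"] and bad["reason"] == "rest_movement"

    def test_threshold_scale_invariance(self, small_session, small_events):
        s = small_session
        scaled = SensorRecording(s.emg.data * 3.7, s.emg.fs,
                                 s.emg.channel_labels, kind="emg")
        ev2 = detect_contraction_bounds(scaled, s.schedule)
        pd.testing.assert_frame_equal(ev2.table, small_events.table)

    def test_raising_k_sd_never_creates_no_onset_on_noiseless_steps(
            self, noiseless_fixture):
        sched, emg = noiseless_fixture
        counts = []
        for k in (1.0, 3.0, 10.0):
            ev = detect_contraction_bounds(emg, sched, k_sd=k,
                                           filter_band=None)
            counts.append((ev.table["reason"] == "no_onset").sum())
        assert counts == sorted(counts)
        assert counts[-1] == 0

    def test_all_zero_channel_rejected(self):
        sched = make_schedule([2.0])
        n = int(round((sched.table["rest_end_s"].iloc[0] + 5) * FS))
        emg = SensorRecording(np.zeros((2, n)) + 1e-12 * np.eye(2, n), FS,
                              ["a", "b"], kind="emg")
        emg.data[1, :] = 0.0
        with pytest.raises(ValueError, match="identically zero"):
            detect_contraction_bounds(emg, sched, filter_band=None)

    def test_baseline_window_outside_recording(self):
        sched = make_schedule([2.0], rest_s=30.0)
        n = int(round((sched.table["contract_off_s"].iloc[0] + 5) * FS))
        emg = step_emg(sched, n)
        with pytest.raises(ValueError, match="baseline window"):
            detect_contraction_bounds(emg, sched, filter_band=None)


class TestBehaviour:
    def _events(self, schedule):
        tab = schedule.table[["trial_id", "condition_s"]].copy()
        tab["onset_s"] = schedule.table["contract_on_s"]
        tab["offset_s"] = schedule.table["contract_off_s"]
        tab["rejected"] = False
        tab["reason"] = ""
        return TrialEvents(tab)

    def test_constant_force_mean_exact(self):
        sched = make_schedule([5.0])
        n = int(round((sched.table["rest_end_s"].iloc[0] + 5) * FS))
        force = np.zeros((1, n))
        i0 = int(round(sched.table["contract_on_s"].iloc[0] * FS))
        i1 = int(round(sched.table["contract_off_s"].iloc[0] * FS))
        force[0, i0:i1] = 30.0
        emg = step_emg(sched, n)
        summ = summarize_trials(SensorRecording(force, FS, ["f"], kind="force"),
                                emg, self._events(sched))
        assert summ.trials["force_pct_mvf"].iloc[0] == pytest.approx(30.0)

    def test_linear_ramp_mean_is_central_mean(self):
        sched = make_schedule([3.0])
        n = int(round((sched.table["rest_end_s"].iloc[0] + 5) * FS))
        force = np.zeros((1, n))
        i0 = int(round(sched.table["contract_on_s"].iloc[0] * FS))
        i1 = int(round(sched.table["contract_off_s"].iloc[0] * FS))
        force[0, i0:i1] = np.linspace(0, 1, i1 - i0)
        summ = summarize_trials(SensorRecording(force, FS, ["f"], kind="force"),
                                step_emg(sched, n), self._events(sched))
        # mean of the central 2 s of a 0->1 ramp over 3 s
        assert summ.trials["force_pct_mvf"].iloc[0] == pytest.approx(0.5, abs=1e-3)

    def test_force_variability_ordering_recovered(self):
        cfg = SessionConfig(n_channels=8, n_sources=3,
                            n_trials_per_condition=15, lead_in_s=40.0,
                            tail_s=40.0,
                            force_sd_pct={2.0: 1.0, 5.0: 0.8, 10.0: 0.6})
        s = synthesize_session(cfg, seed=5)
        ev = detect_contraction_bounds(s.emg, s.schedule)
        summ = summarize_trials(s.force, s.emg, ev)
        sds = summ.trials.groupby("condition_s")["force_pct_mvf"].std()
        assert sds[2.0] > sds[10.0]

    def test_short_contraction_skipped(self):
        sched = make_schedule([2.0])
        tab = self._events(sched).table
        tab["offset_s"] = tab["onset_s"] + 0.8  # < 2 x 0.5 s edges
        n = int(round((sched.table["rest_end_s"].iloc[0] + 5) * FS))
        force = SensorRecording(np.ones((1, n)), FS, ["f"], kind="force")
        with pytest.raises(ValueError, match="shorter"):
            summarize_trials(force, step_emg(sched, n), TrialEvents(tab))


class TestMVF:
    def test_flat_trace_gives_zero(self):
        assert compute_mvf(np.ones(1200) * 4.2, FS) == pytest.approx(0.0)

    def test_rectangular_pulse(self):
        x = np.zeros(3000)
        x[600:780] = 1.0  # 300-ms pulse
        assert compute_mvf(x, FS) == pytest.approx(1.0)

    def test_triangular_pulse(self):
        x = np.zeros(3000)
        n = 120  # 200-ms triangle
        x[600:600 + n] = 1.0 - np.abs(np.linspace(-1, 1, n))
        assert compute_mvf(x, FS) == pytest.approx(0.5, abs=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_mvf(np.ones(300), FS)
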