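"""Band-pass filtering, Hilbert envelopes, time-frequency spectrograms and
trial-averaged beta-band envelope timecourses.

Epoching conventions follow the two segmentations used for movement-locked
beta analysis: onset-aligned epochs start 3 s before contraction onset (to
capture preparatory suppression); offset-aligned epochs of 31/34/39 s start
5/8/13 s before contraction offset for the 2/5/10-s conditions. The TFS is a
relative-change measure (baseline subtracted, then divided); the beta
timecourse keeps absolute source units with the baseline mean subtracted.
The common baseline window is 2-10 s before the end of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .synth import TaskSchedule

__all__ = [
    "EnvelopeSpectrogram",
    "BetaTimecourse",
    "bandpass_filter",
    "hilbert_envelope",
    "default_bands",
    "compute_tfs",
    "beta_envelope",
    "epoch_bounds",
]

# offset-aligned epochs: (start before offset, total length) per condition
OFFSET_EPOCHS = {2.0: (5.0, 31.0), 5.0: (8.0, 34.0), 10.0: (13.0, 39.0)}
ONSET_PRE_S = 3.0
BASELINE_BEFORE_TRIAL_END_S = (2.0, 10.0)
BETA_BAND = (15.0, 30.0)


@dataclass
class EnvelopeSpectrogram:
    """bands x time relative-amplitude spectrogram, one per condition."""

    bands: np.ndarray               # n_bands x 2 (lo, hi) Hz
    times: dict                     # condition -> time axis (s re alignment)
    values: dict                    # condition -> bands x time
    alignment: str = "offset"
    baseline_window: tuple = BASELINE_BEFORE_TRIAL_END_S


@dataclass
class BetaTimecourse:
    """Absolute-unit, baseline-subtracted, trial-averaged beta envelope."""

    times: dict                     # condition -> time axis (s re alignment)
    values: dict                    # condition -> mean envelope
    sem: dict = field(default_factory=dict)
    alignment: str = "offset"
    band: tuple = BETA_BAND
    n_trials: dict = field(default_factory=dict)


def bandpass_filter(x: np.ndarray, lo: float, hi: float, fs: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs = {fs} Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to hilbert_envelope")
    if x.shape[-1] <= 10:
        raise ValueError("input too short for a meaningful envelope")
    return np.abs(hilbert(x, axis=-1))


def default_bands(n_bands: int = 31, f_lo: float = 2.0, f_hi: float = 148.0,
                  width: float = 8.0) -> np.ndarray:
    """31 overlapping bands: centres linearly spaced 2-148 Hz, 8 Hz wide."""
    centres = np.linspace(f_lo, f_hi, n_bands)
    lo = np.maximum(centres - width / 2, 0.5)
    return np.column_stack([lo, centres + width / 2])


def epoch_bounds(row, alignment: str, cue_lead_s: float = 2.0):
    """(start_s, stop_s, t0_s) of one trial's epoch in recording time.

    ``t0_s`` is the alignment event (detected onset or offset). The epoch end
    in both alignments is the end of the trial's rest period.
    """
    if alignment == "offset":
        pre, length = OFFSET_EPOCHS[float(row["condition_s"])]
        start = row["offset_s"] - pre
        return start, start + length, row["offset_s"]
    elif alignment == "onset":
        start = row["onset_s"] - ONSET_PRE_S
        stop = row["rest_end_s"] - cue_lead_s
        return start, stop, row["onset_s"]
    raise ValueError(f"unknown alignment {alignment!r}")


def _epoch_matrix(x: np.ndarray, fs: float, events_tab, alignment: str,
                  cue_lead_s: float, condition: float):
    """Stack same-condition epochs of x (1-D), aligned on the event sample."""
    rows = events_tab[events_tab["condition_s"] == condition]
    if len(rows) == 0:
        raise ValueError(f"no kept trials for condition {condition}")
    segs, t_axis = [], None
    for _, row in rows.iterrows():
        start, stop, t0 = epoch_bounds(row, alignment, cue_lead_s)
        i0, i1 = int(round(start * fs)), int(round(stop * fs))
        if i0 < 0 or i1 > x.shape[-1]:
            raise ValueError("epoch extends beyond the recording")
        ia = int(round(t0 * fs))
        segs.append((i0, i1, ia))
    pre = min(ia - i0 for i0, i1, ia in segs)
    post = min(i1 - ia for i0, i1, ia in segs)
    mat = np.stack([x[ia - pre:ia + post] for _, _, ia in segs])
    t_axis = np.arange(-pre, post) / fs
    return mat, t_axis


def _baseline_slice(times: np.ndarray, trial_end_t: float,
                    baseline: tuple) -> np.ndarray:
    b0 = trial_end_t - baseline[1]
    b1 = trial_end_t - baseline[0]
    mask = (times >= b0) & (times < b1)
    if not mask.any():
        raise ValueError("baseline window empty for this epoch")
    return mask


def _trial_end_time(events_tab, condition: float, alignment: str,
                    cue_lead_s: float) -> float:
    """Epoch-relative time of the end of the trial (start of next cue)."""
    rows = events_tab[events_tab["condition_s"] == condition]
    if alignment == "offset":
        rests = rows["rest_end_s"] - cue_lead_s - rows["offset_s"]
    else:
        rests = rows["rest_end_s"] - cue_lead_s - rows["onset_s"]
    return float(rests.min())


def _merged_events(events, schedule: TaskSchedule):
    """Kept-trial table with rest_end_s merged in from the schedule."""
    tab = events.kept.copy()
    if len(tab) == 0:
        raise ValueError("no kept trials")
    if "rest_end_s" in tab.columns:
        return tab
    sched = schedule.table[["trial_id", "rest_end_s"]]
    return tab.merge(sched, on="trial_id", how="left")


def compute_tfs(source_tc: np.ndarray, events, schedule: TaskSchedule, fs: float,
                bands: np.ndarray | None = None, alignment: str = "offset",
                baseline: tuple = BASELINE_BEFORE_TRIAL_END_S) -> EnvelopeSpectrogram:
    """Time-frequency spectrogram of relative amplitude change.

    Per band: filter, Hilbert envelope, average over same-condition trials,
    subtract the baseline mean, divide by the baseline mean. Filtering and the
    Hilbert transform run on the continuous timecourse (equivalently: epochs
    padded well beyond the filter transient), so epoch edges are clean.
    """
    if bands is None:
        bands = default_bands()
    x = np.asarray(source_tc, dtype=float).ravel()
    tab = _merged_events(events, schedule)
    conditions = sorted(tab["condition_s"].unique())

    env_bands = []
    for lo, hi in bands:
        env_bands.append(hilbert_envelope(bandpass_filter(x, lo, hi, fs)))

    values, times = {}, {}
    for cond in conditions:
        t_end = _trial_end_time(tab, cond, alignment, schedule.cue_lead_s)
        mats = []
        for env in env_bands:
            mat, t_axis = _epoch_matrix(env, fs, tab, alignment,
                                        schedule.cue_lead_s, cond)
            avg = mat.mean(axis=0)
            bmask = _baseline_slice(t_axis, t_end, baseline)
            mu = avg[bmask].mean()
            mats.append((avg - mu) / mu)
        values[cond] = np.vstack(mats)
        times[cond] = t_axis
    return EnvelopeSpectrogram(bands=np.asarray(bands), times=times,
                               values=values, alignment=alignment,
                               baseline_window=baseline)


def beta_envelope(source_tc: np.ndarray, events, schedule: TaskSchedule, fs: float,
                  band: tuple = BETA_BAND, alignment: str = "offset",
                  baseline: tuple = BASELINE_BEFORE_TRIAL_END_S) -> BetaTimecourse:
    """Absolute beta-band envelope, baseline-subtracted, averaged per condition."""
    x = np.asarray(source_tc, dtype=float).ravel()
    env = hilbert_envelope(bandpass_filter(x, band[0], band[1], fs))
    tab = _merged_events(events, schedule)
    conditions = sorted(tab["condition_s"].unique())

    times, values, sems, counts = {}, {}, {}, {}
    for cond in conditions:
        mat, t_axis = _epoch_matrix(env, fs, tab, alignment,
                                    schedule.cue_lead_s, cond)
        avg = mat.mean(axis=0)
        t_end = _trial_end_time(tab, cond, alignment, schedule.cue_lead_s)
        bmask = _baseline_slice(t_axis, t_end, baseline)
        avg = avg - avg[bmask].mean()
        times[cond] = t_axis
        values[cond] = avg
        sems[cond] = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) \
            if mat.shape[0] > 1 else np.zeros_like(avg)
        counts[cond] = mat.shape[0]
    return BetaTimecourse(times=times, values=values, sem=sems,
                          alignment=alignment, band=tuple(band), n_trials=counts)
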