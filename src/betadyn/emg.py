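"""EMG contraction-bound detection, trial rejection and behavioural summaries.

Onset/offset detection follows the classical rectified-EMG threshold rule:
EMG is band-pass filtered 1-150 Hz and rectified; the noise threshold is
``k_sd`` (default 3) times the standard deviation of the rectified signal over
pooled per-trial baseline windows (13-23 s after the contraction-offset cue).
The contraction onset is the first supra-threshold sample within +-0.5 s of
the contraction cue, the offset the last supra-threshold sample within
+-0.5 s of the end cue. A short forward/backward moving-average gate makes
the raw-sample search robust to isolated noise excursions while remaining
exact on noiseless steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import bandpass_filter
from .synth import SensorRecording, TaskSchedule

__all__ = [
    "TrialEvents",
    "BehaviourSummary",
    "detect_contraction_bounds",
    "flag_meg_artifacts",
    "summarize_trials",
    "compute_mvf",
]

REJECT_REASONS = ("no_onset", "no_offset", "rest_movement", "artifact")


@dataclass
class TrialEvents:
    """Detected contraction bounds and rejection flags, one row per trial."""

    table: pd.DataFrame  # trial_id, condition_s, onset_s, offset_s, rejected, reason
    threshold: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[~self.table["rejected"]]

    @property
    def n_rejected(self) -> int:
        return int(self.table["rejected"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialEvents":
        return cls(pd.read_csv(path))


@dataclass
class BehaviourSummary:
    """Steady-state per-trial force/EMG means and run-level aggregates."""

    trials: pd.DataFrame      # per kept trial: condition, mean force, mean EMG/channel
    by_condition: pd.DataFrame
    edge_exclusion_s: float = 0.5


def _rectified_smoothed(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average of |x| with window n (odd)."""
    kernel = np.ones(n) / n
    return np.convolve(np.abs(x), kernel, mode="same")


def _first_supra(rect: np.ndarray, smooth: np.ndarray, thr: float,
                 i0: int, i1: int, run_n: int = 1) -> int | None:
    """First sample in [i0, i1) that is supra-threshold, gated by a
    *sustained* excursion of the smoothed trace (robust to isolated noise
    samples and to brief smoothed-noise bumps)."""
    seg = smooth[i0:i1] > thr
    gate = None
    for start, stop in _supra_runs(seg):
        if stop - start >= run_n:
            gate = start
            break
    if gate is None:
        return None
    raw = np.nonzero(rect[i0 + gate:i1] > thr)[0]
    if len(raw) == 0:
        return None
    return i0 + gate + raw[0]


def _last_supra(rect: np.ndarray, smooth: np.ndarray, thr: float,
                i0: int, i1: int, run_n: int = 1) -> int | None:
    seg = smooth[i0:i1] > thr
    gate = None
    for start, stop in reversed(_supra_runs(seg)):
        if stop - start >= run_n:
            gate = stop - 1
            break
    if gate is None:
        return None
    raw = np.nonzero(rect[i0:i0 + gate + 1] > thr)[0]
    if len(raw) == 0:
        return None
    return i0 + raw[-1]


def _supra_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def detect_contraction_bounds(
    emg: SensorRecording,
    schedule: TaskSchedule,
    k_sd: float = 3.0,
    search_halfwidth_s: float = 0.5,
    baseline_window_s: tuple = (13.0, 23.0),
    rest_min_run_s: float = 0.05,
    smooth_s: float = 0.025,
    filter_band: tuple | None = (1.0, 150.0),
) -> TrialEvents:
    """Detect per-trial contraction onset/offset from EMG; reject bad trials.

    Rejection reasons: ``no_onset``/``no_offset`` when the threshold search
    fails within the +-0.5-s cue windows; ``rest_movement`` when both EMG
    channels show a supra-threshold run of at least ``rest_min_run_s`` during
    the trial's rest period.
    """
    fs = emg.fs
    if filter_band is not None:
        lo, hi = filter_band
        filt = bandpass_filter(emg.data, lo, min(hi, 0.45 * fs), fs)
    else:
        # already-conditioned input (e.g. clean synthetic fixtures)
        filt = emg.data
    rect = np.abs(filt)
    n_smooth = max(int(round(smooth_s * fs)) | 1, 3)
    smooth = np.vstack([_rectified_smoothed(f, n_smooth) for f in filt])
    n_samples = emg.n_samples

    tab = schedule.table
    # pooled baseline windows: 13-23 s after the contraction-offset cue
    base_idx = []
    for _, row in tab.iterrows():
        cue_off = row["cue_on_s"] + schedule.cue_lead_s + row["condition_s"]
        i0 = int(round((cue_off + baseline_window_s[0]) * fs))
        i1 = int(round((cue_off + baseline_window_s[1]) * fs))
        if i0 < 0 or i1 > n_samples:
            raise ValueError(
                f"baseline window [{baseline_window_s[0]}, {baseline_window_s[1]}] s "
                f"after offset cue extends beyond the recording for trial "
                f"{int(row['trial_id'])}"
            )
        base_idx.append(np.arange(i0, i1))
    base_idx = np.concatenate(base_idx)

    for ch in range(rect.shape[0]):
        if np.all(emg.data[ch] == 0):
            raise ValueError(f"EMG channel {ch} is identically zero (SD = 0)")
    thr = k_sd * rect[:, base_idx].std(axis=1)

    rows = []
    half = int(round(search_halfwidth_s * fs))
    min_run = max(int(round(rest_min_run_s * fs)), 1)
    for _, row in tab.iterrows():
        cue_on = row["cue_on_s"] + schedule.cue_lead_s
        cue_off = cue_on + row["condition_s"]
        onset = offset = np.nan
        rejected, reason = False, ""

        c = int(round(cue_on * fs))
        i_on = _first_supra(rect[0], smooth[0], thr[0],
                            max(c - half, 0), min(c + half, n_samples),
                            run_n=n_smooth)
        if i_on is None:
            rejected, reason = True, "no_onset"
        else:
            onset = i_on / fs
            c2 = int(round(cue_off * fs))
            i_off = _last_supra(rect[0], smooth[0], thr[0],
                                max(c2 - half, 0), min(c2 + half, n_samples),
                                run_n=n_smooth)
            if i_off is None or (not np.isnan(onset) and i_off / fs <= onset):
                rejected, reason = True, "no_offset"
            else:
                offset = i_off / fs

        if not rejected:
            # rest window: 1 s after contraction-offset cue until next cue - 1 s
            r0 = int(round((cue_off + 1.0) * fs))
            r1 = int(round((row["rest_end_s"] - schedule.cue_lead_s - 1.0) * fs))
            r1 = min(r1, n_samples)
            if r1 > r0:
                both = np.ones(r1 - r0, dtype=bool)
                for ch in range(rect.shape[0]):
                    both &= smooth[ch, r0:r1] > thr[ch]
                if any(stop - start >= min_run for start, stop in _supra_runs(both)):
                    rejected, reason = True, "rest_movement"

        rows.append((int(row["trial_id"]), row["condition_s"], onset, offset,
                     rejected, reason))

    table = pd.DataFrame(rows, columns=["trial_id", "condition_s", "onset_s",
                                        "offset_s", "rejected", "reason"])
    return TrialEvents(table=table, threshold=thr)


def flag_meg_artifacts(meg: SensorRecording, schedule: TaskSchedule,
                       events: TrialEvents, z_thresh: float = 5.0) -> TrialEvents:
    """Automated stand-in for visual MEG trial inspection.

    Trials whose broadband sensor power is a ``z_thresh``-sigma outlier across
    trials are flagged with reason ``artifact``.
    """
    fs = meg.fs
    power = []
    for _, row in schedule.table.iterrows():
        i0 = int(round(row["cue_on_s"] * fs))
        i1 = min(int(round(row["rest_end_s"] * fs)), meg.n_samples)
        power.append(float(np.mean(meg.data[:, i0:i1] ** 2)))
    power = np.asarray(power)
    mu, sd = power.mean(), power.std()
    table = events.table.copy()
    if sd > 0:
        z = (power - mu) / sd
        bad = z > z_thresh
        table.loc[bad & ~table["rejected"], "reason"] = "artifact"
        table.loc[bad, "rejected"] = True
    return TrialEvents(table=table, threshold=events.threshold)


def summarize_trials(force: SensorRecording, emg: SensorRecording,
                     events: TrialEvents, edge_exclusion_s: float = 0.5,
                     mvf: float | None = None) -> BehaviourSummary:
    """Per-trial steady-state means of force (%MVF) and rectified EMG.

    The first and last ``edge_exclusion_s`` (default 0.5 s) of each kept
    contraction are excluded so only steady output is summarised. Contractions
    too short to leave a steady segment are skipped.
    """
    kept = events.kept
    if len(kept) == 0:
        raise ValueError("no kept trials to summarise")
    fs = force.fs
    rect_emg = np.abs(emg.data)
    scale = 100.0 / mvf if mvf else 1.0

    rows = []
    for _, row in kept.iterrows():
        i0 = int(round((row["onset_s"] + edge_exclusion_s) * fs))
        i1 = int(round((row["offset_s"] - edge_exclusion_s) * fs))
        if i1 - i0 < 1:
            continue  # contraction shorter than the excluded edges
        rec = {"trial_id": int(row["trial_id"]),
               "condition_s": row["condition_s"],
               "force_pct_mvf": float(force.data[0, i0:i1].mean()) * scale}
        for ch in range(emg.n_channels):
            rec[f"emg_mean_ch{ch}"] = float(rect_emg[ch, i0:i1].mean())
        rows.append(rec)
    if not rows:
        raise ValueError("all kept contractions shorter than the edge exclusion")
    trials = pd.DataFrame(rows)
    by_condition = trials.drop(columns="trial_id").groupby("condition_s").agg(
        ["mean", "std"]
    )
    return BehaviourSummary(trials=trials, by_condition=by_condition,
                            edge_exclusion_s=edge_exclusion_s)


def compute_mvf(force_trace: SensorRecording | np.ndarray, fs: float | None = None,
                peak_window_s: float = 0.2, baseline_window_s: float = 0.4) -> float:
    """Maximum voluntary force from a probe trace.

    Peak of the sliding 200-ms-window mean, minus the mean over the final
    400 ms of the recording (the force bar's baseline reading).
    """
    if isinstance(force_trace, SensorRecording):
        x, fs = force_trace.data[0], force_trace.fs
    else:
        if fs is None:
            raise ValueError("fs required for array input")
        x = np.asarray(force_trace, dtype=float).ravel()
    n_peak = int(round(peak_window_s * fs))
    n_base = int(round(baseline_window_s * fs))
    if len(x) < n_peak + n_base:
        raise ValueError("trace too short for MVF estimation (< 600 ms)")
    csum = np.cumsum(np.insert(x, 0, 0.0))
    window_means = (csum[n_peak:] - csum[:-n_peak]) / n_peak
    return float(window_means.max() - x[-n_base:].mean())
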