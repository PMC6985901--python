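"""Synthetic grip-force MEG sessions with known ground truth.

Emulates the statistical structure of a cued isometric grip-force experiment:
subjects hold 30 %MVF for 2, 5 or 10 s (15 trials per duration per run, 30-s
rests), while a beta-band (15-30 Hz) source in "sensorimotor cortex" emits
transient bursts whose *probability* -- not amplitude -- is suppressed during
contraction (MRBD) and transiently elevated after contraction offset (PMBR),
with a post-offset rate profile shaped like a Weibull density whose scale
grows, and whose total burst surplus shrinks, with task duration.

Sensor data are a lead-field projection of the sources plus white and 1/f
background noise; EMG-like and force-like channels are generated on the same
clock, so the downstream event detection, beamforming, curve fitting and HMM
stages can be exercised end-to-end against the generator's annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskSchedule",
    "LeadField",
    "SourceActivity",
    "SensorRecording",
    "BurstConfig",
    "SessionConfig",
    "Session",
    "build_geometry",
    "build_schedule",
    "simulate_bursts",
    "synthesize_session",
    "weibull_pdf",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = [
    "trial_id",
    "condition_s",
    "cue_on_s",
    "contract_on_s",
    "contract_off_s",
    "rest_end_s",
]


@dataclass
class TaskSchedule:
    """Cue/contraction timing and condition labels for every trial.

    ``contract_on_s``/``contract_off_s`` are the *actual* (ground-truth)
    contraction bounds, jittered around the cued times; the cued contraction
    start is ``cue_on_s + cue_lead_s`` (the target profile appears 2 s before
    the contraction period).
    """

    table: pd.DataFrame
    cue_lead_s: float = 2.0

    def __post_init__(self) -> None:
        missing = [c for c in SCHEDULE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"schedule table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def conditions(self) -> np.ndarray:
        return self.table["condition_s"].to_numpy()

    @property
    def cued_on(self) -> np.ndarray:
        """Cued contraction start (visual cue for force onset)."""
        return self.table["cue_on_s"].to_numpy() + self.cue_lead_s

    @property
    def cued_off(self) -> np.ndarray:
        """Cued contraction end."""
        return self.cued_on + self.conditions

    def validate(self) -> None:
        t = self.table
        dur = t["contract_off_s"] - t["contract_on_s"]
        if not np.all(np.abs(dur - t["condition_s"]) <= 0.5):
            raise ValueError("contraction length deviates >0.5 s from condition")
        if not np.all(t["contract_on_s"] < t["contract_off_s"]):
            raise ValueError("contract_on must precede contract_off")

    def to_csv(self, path) -> None:
        self.table[SCHEDULE_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cue_lead_s: float = 2.0) -> "TaskSchedule":
        return cls(pd.read_csv(path), cue_lead_s=cue_lead_s)


@dataclass
class LeadField:
    """Forward model: sensor gain of each (fixed-orientation) source."""

    gain: np.ndarray          # channels x sources
    source_coords: np.ndarray  # sources x 3
    channel_coords: np.ndarray  # channels x 3

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms <= 0):
            raise ValueError("lead field has a zero-norm column")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class SourceActivity:
    """Source timecourses plus the burst annotations that generated them."""

    timecourses: np.ndarray                 # sources x samples
    fs: float
    burst_onsets: list                      # per source: int sample indices
    burst_offsets: list                     # per source: int sample indices
    burst_rate_profile: dict = field(default_factory=dict)

    @property
    def n_sources(self) -> int:
        return self.timecourses.shape[0]

    def burst_count(self, source: int = 0) -> int:
        return len(self.burst_onsets[source])


@dataclass
class SensorRecording:
    """channels x samples multichannel recording (MEG, EMG or force)."""

    data: np.ndarray
    fs: float
    channel_labels: list
    kind: str = "meg"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.kind == "emg" and self.data.shape[0] < 2:
            raise ValueError("EMG recordings need >=2 channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class BurstConfig:
    """Parameters of the phase-dependent beta-burst renewal process.

    Rates are unconditional burst rates (bursts/s); the post-offset surplus is
    a Weibull-density profile so that the generator and the PMBR fit share a
    parametric family: lambda(t) = rate_rest + extra_d * f(t - offset; a_d, b).
    """

    rate_rest: float = 1.8
    rate_move: float = 0.3
    post_extra: dict = field(default_factory=lambda: {2.0: 8.0, 5.0: 5.0, 10.0: 2.5})
    post_scale: dict = field(default_factory=lambda: {2.0: 2.0, 5.0: 2.75, 10.0: 3.5})
    post_shape: float = 1.8
    duration_median_s: float = 0.10
    duration_sigma: float = 0.35
    min_gap_s: float = 0.02
    amp_median: float = 1.0
    amp_sigma: float = 0.2
    carrier_hz: float = 21.5
    carrier_jitter_hz: float = 1.0
    background_rate: float = 1.2
    n_background_networks: int = 3

    @property
    def mean_duration_s(self) -> float:
        return float(np.exp(np.log(self.duration_median_s) + 0.5 * self.duration_sigma**2))


@dataclass
class SessionConfig:
    """One experimental run's worth of synthetic data."""

    fs: float = 600.0
    n_channels: int = 24
    n_sources: int = 10
    n_trials_per_condition: int = 15
    conditions: tuple = (2.0, 5.0, 10.0)
    rest_s: float = 30.0
    cue_lead_s: float = 2.0
    lead_in_s: float = 75.0
    tail_s: float = 75.0
    onset_jitter_sd: float = 0.08
    offset_jitter_sd: float = 0.08
    noise_sd: float = 0.05
    pink_amplitude: float = 0.10
    emg_baseline_sd: float = 10.0
    emg_contraction_gain: tuple = (10.0, 6.0)
    force_target_pct: float = 30.0
    force_sd_pct: dict = field(default_factory=lambda: {2.0: 1.0, 5.0: 0.8, 10.0: 0.6})
    force_noise_pct: float = 0.3
    force_ramp_s: float = 0.3
    mvf_probe_pct: float = 100.0
    mvf_probe_duration_s: float = 3.0
    geometry_model: str = "orthonormal"
    burst: BurstConfig = field(default_factory=BurstConfig)

    def validate(self) -> None:
        if self.n_trials_per_condition < 0:
            raise ValueError("n_trials_per_condition must be >= 0")
        if self.n_trials_per_condition == 0:
            raise ValueError("config requests an empty session (n_trials = 0)")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if any(c not in (self.burst.post_extra) for c in self.conditions):
            raise ValueError(
                f"burst config lacks post-offset parameters for conditions {self.conditions}"
            )
        if self.n_sources > self.n_channels:
            raise ValueError("default geometry requires n_channels >= n_sources")

    def replace(self, **kw) -> "SessionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Session:
    """Bundle returned by :func:`synthesize_session` (one run)."""

    meg: SensorRecording
    emg: SensorRecording
    force: SensorRecording
    schedule: TaskSchedule
    sources: SourceActivity
    leadfield: LeadField
    config: SessionConfig
    seed: int
    task_source: int = 0
    probe_times: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def build_geometry(n_channels: int, n_sources: int, seed: int,
                   model: str = "orthonormal") -> LeadField:
    """Deterministic seeded forward model.

    ``orthonormal``: gain = Q from the QR decomposition of a seeded Gaussian
    matrix (well-conditioned, unit-norm columns). ``sphere``: point magnetic
    dipoles in a conducting sphere sampled by radial-ish sensors -- a crude but
    physically-flavoured alternative.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    if n_sources > n_channels:
        raise ValueError(
            f"n_sources ({n_sources}) exceeds n_channels ({n_channels}); "
            "localization would be ill-posed for the default model"
        )
    rng = np.random.default_rng(seed)
    # sensors on an upper hemisphere (radius 12 cm), sources in a ball (8 cm)
    phi = rng.uniform(0, 2 * np.pi, n_channels)
    costh = rng.uniform(0.15, 1.0, n_channels)
    sinth = np.sqrt(1 - costh**2)
    channel_coords = 0.12 * np.column_stack(
        [sinth * np.cos(phi), sinth * np.sin(phi), costh]
    )
    u = rng.normal(size=(n_sources, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = 0.08 * rng.uniform(0.3, 0.9, n_sources) ** (1 / 3)
    source_coords = u * radii[:, None]

    if model == "orthonormal":
        g = rng.standard_normal((n_channels, n_sources))
        q, _ = np.linalg.qr(g)
        gain = q[:, :n_sources]
        # fix column signs for bitwise determinism across LAPACK conventions
        signs = np.sign(gain[np.argmax(np.abs(gain), axis=0), np.arange(n_sources)])
        gain = gain * signs
    elif model == "sphere":
        m = rng.normal(size=(n_sources, 3))
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        gain = np.empty((n_channels, n_sources))
        for j in range(n_sources):
            r = channel_coords - source_coords[j]
            d = np.linalg.norm(r, axis=1)
            b = np.cross(np.broadcast_to(m[j], r.shape), r) / d[:, None] ** 3
            # radial sensor orientation
            orient = channel_coords / np.linalg.norm(channel_coords, axis=1, keepdims=True)
            gain[:, j] = np.einsum("ij,ij->i", b, orient)
        gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown geometry model {model!r}")
    return LeadField(gain=gain, source_coords=source_coords,
                     channel_coords=channel_coords)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def build_schedule(config: SessionConfig, rng: np.random.Generator) -> TaskSchedule:
    """Pseudo-random trial order: 15 trials per duration, 30-s rests."""
    conds = np.repeat(np.asarray(config.conditions, dtype=float),
                      config.n_trials_per_condition)
    order = rng.permutation(len(conds))
    conds = conds[order]

    rows = []
    t = config.lead_in_s  # first cued contraction onset
    for i, d in enumerate(conds):
        cue_on = t - config.cue_lead_s
        on = t + np.clip(rng.normal(0, config.onset_jitter_sd), -0.4, 0.4)
        off = t + d + np.clip(rng.normal(0, config.offset_jitter_sd), -0.4, 0.4)
        rest_end = t + d + config.rest_s
        rows.append((i, d, cue_on, on, off, rest_end))
        t = rest_end  # next cued onset
    table = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    sched = TaskSchedule(table, cue_lead_s=config.cue_lead_s)
    sched.validate()
    return sched


def session_duration(config: SessionConfig) -> float:
    total = config.lead_in_s + config.tail_s
    total += config.n_trials_per_condition * sum(
        d + config.rest_s for d in config.conditions
    )
    return total


# ---------------------------------------------------------------------------
# burst process
# ---------------------------------------------------------------------------


def weibull_pdf(t, a: float, b: float):
    """Weibull density f(t) = (b/a) (t/a)^(b-1) exp(-(t/a)^b), zero for t <= 0."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / a
    out[pos] = (b / a) * x ** (b - 1) * np.exp(-(x**b))
    return out[0] if scalar else out


def _task_rate_profile(schedule: TaskSchedule, burst: BurstConfig, t_grid: np.ndarray):
    """Burst rate lambda(t) of the task-modulated source on a time grid."""
    lam = np.full_like(t_grid, burst.rate_rest)
    tab = schedule.table
    for _, row in tab.iterrows():
        cue = row["cue_on_s"]
        off = row["contract_off_s"]
        d = row["condition_s"]
        move = (t_grid >= cue) & (t_grid < off)
        lam[move] = burst.rate_move
        post = (t_grid >= off) & (t_grid < row["rest_end_s"] - schedule.cue_lead_s)
        lam[post] = burst.rate_rest + burst.post_extra[d] * weibull_pdf(
            t_grid[post] - off, burst.post_scale[d], burst.post_shape
        )
    return lam


def _draw_bursts(lam_grid: np.ndarray, t_grid: np.ndarray, burst: BurstConfig,
                 rng: np.random.Generator, duration_s: float):
    """Renewal process with refractory dead time and compensated hazard.

    The waiting hazard beyond the refractory period is lambda' =
    lambda/(1 - lambda*dbar) with dbar the mean burst-plus-gap length, which
    makes the configured lambda the *unconditional* burst rate (expected count
    = integral of lambda dt).
    """
    dbar = burst.mean_duration_s + burst.min_gap_s
    lam_max = float(lam_grid.max(initial=0.0))
    if lam_max <= 0:
        return [], [], []
    if lam_max * dbar >= 0.85:
        raise ValueError(
            f"burst rate {lam_max:.2f}/s too high for disjoint bursts of mean "
            f"length {dbar * 1e3:.0f} ms; reduce rates or burst duration"
        )
    hmax = lam_max / (1.0 - lam_max * dbar)

    def hazard(t):
        lam = np.interp(t, t_grid, lam_grid)
        return lam / (1.0 - lam * dbar)

    onsets, offsets, amps = [], [], []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / hmax)
        if t >= duration_s:
            break
        if rng.uniform() * hmax <= hazard(t):
            dur = rng.lognormal(np.log(burst.duration_median_s), burst.duration_sigma)
            if t + dur >= duration_s:
                break
            onsets.append(t)
            offsets.append(t + dur)
            amps.append(rng.lognormal(np.log(burst.amp_median), burst.amp_sigma))
            t += dur + burst.min_gap_s
    return onsets, offsets, amps


def _render_bursts(n_samples: int, fs: float, onsets, offsets, amps,
                   burst: BurstConfig, rng: np.random.Generator):
    from scipy.signal import windows

    x = np.zeros(n_samples)
    on_idx, off_idx = [], []
    for t0, t1, a in zip(onsets, offsets, amps):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        i1 = max(i1, i0 + 2)
        if i1 > n_samples:
            break
        n = i1 - i0
        f = burst.carrier_hz + burst.carrier_jitter_hz * rng.standard_normal()
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n) / fs
        x[i0:i1] += a * windows.tukey(n, 0.5) * np.sin(2 * np.pi * f * tt + phase)
        on_idx.append(i0)
        off_idx.append(i1)
    return x, np.asarray(on_idx, dtype=int), np.asarray(off_idx, dtype=int)


def simulate_bursts(schedule: TaskSchedule, burst: BurstConfig, seed: int,
                    fs: float = 600.0, duration_s: float | None = None,
                    n_sources: int = 1) -> SourceActivity:
    """Draw phase-dependent beta bursts and render source timecourses.

    Source 0 is task-modulated (rate suppressed during cue+contraction,
    Weibull-shaped surplus after offset). The remaining sources form
    ``n_background_networks`` networks that burst as units at the stationary
    ``background_rate`` — network members share burst times (with
    independent phases and mild amplitude jitter), mirroring the
    network-state organisation of ongoing activity that the mutually
    exclusive state model downstream presumes. Burst amplitudes are drawn
    from one distribution regardless of phase (the burst hypothesis: task
    modulation acts on burst *probability*, not amplitude).
    """
    if len(schedule) == 0 and duration_s is None:
        raise ValueError("zero-length schedule and no explicit duration")
    if duration_s is None:
        duration_s = float(schedule.table["rest_end_s"].iloc[-1]) + 5.0
    n_samples = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)

    t_grid = np.arange(0.0, duration_s + 0.01, 0.01)
    if len(schedule):
        lam_task = _task_rate_profile(schedule, burst, t_grid)
    else:
        lam_task = np.full_like(t_grid, burst.rate_rest)

    tcs = np.zeros((n_sources, n_samples))
    all_on = [None] * n_sources
    all_off = [None] * n_sources

    on, off, amp = _draw_bursts(lam_task, t_grid, burst, rng, duration_s)
    tcs[0], all_on[0], all_off[0] = _render_bursts(n_samples, fs, on, off,
                                                   amp, burst, rng)

    n_net = max(min(burst.n_background_networks, n_sources - 1), 1)
    lam_bg = np.full_like(t_grid, burst.background_rate)
    for net in range(n_net):
        members = [s for s in range(1, n_sources) if (s - 1) % n_net == net]
        if not members:
            continue
        on, off, amp = _draw_bursts(lam_bg, t_grid, burst, rng, duration_s)
        for s in members:
            jitter = np.asarray(amp) * rng.uniform(0.8, 1.2, len(amp)) \
                if len(amp) else amp
            tcs[s], all_on[s], all_off[s] = _render_bursts(
                n_samples, fs, on, off, jitter, burst, rng
            )

    profile = {
        "rate_rest": burst.rate_rest,
        "rate_move": burst.rate_move,
        "post_extra": dict(burst.post_extra),
        "post_scale": dict(burst.post_scale),
        "post_shape": burst.post_shape,
    }
    return SourceActivity(timecourses=tcs, fs=fs, burst_onsets=all_on,
                          burst_offsets=all_off, burst_rate_profile=profile)


# ---------------------------------------------------------------------------
# noise + peripheral channels
# ---------------------------------------------------------------------------


def one_over_f_noise(n_channels: int, n_samples: int, fs: float,
                     rng: np.random.Generator, f_min: float = 1.0) -> np.ndarray:
    """Seeded 1/f (power) background via spectral shaping of white noise."""
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], f_min))
    w = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(w, axis=1) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    # unit variance per channel before user scaling
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _emg_channels(schedule: TaskSchedule, config: SessionConfig, n_samples: int,
                  rng: np.random.Generator) -> np.ndarray:
    fs = config.fs
    sd = config.emg_baseline_sd
    data = rng.standard_normal((2, n_samples)) * sd
    for _, row in schedule.table.iterrows():
        i0 = int(round(row["contract_on_s"] * fs))
        i1 = int(round(row["contract_off_s"] * fs))
        for ch, gain in enumerate(config.emg_contraction_gain):
            data[ch, i0:i1] *= gain
    return data


def _force_channel(schedule: TaskSchedule, config: SessionConfig, n_samples: int,
                   rng: np.random.Generator):
    """Force in %MVF: 30 % plateaus with per-condition trial SD, 100 % probes."""
    fs = config.fs
    ramp_n = max(int(round(config.force_ramp_s * fs)), 1)
    ramp = np.linspace(0, 1, ramp_n, endpoint=False)
    x = np.zeros(n_samples)

    def add_plateau(i0, i1, level):
        i0, i1 = max(i0, 0), min(i1, n_samples)
        if i1 <= i0:
            return
        seg = np.full(i1 - i0, float(level))
        m = min(ramp_n, len(seg))
        seg[:m] *= ramp[:m]
        seg[-m:] *= ramp[:m][::-1]
        x[i0:i1] += seg

    # two 100 %MVF probes in the lead-in and two in the tail
    probe_n = int(round(config.mvf_probe_duration_s * fs))
    t_end = n_samples / fs
    probes = [5.0, 38.0, t_end - config.tail_s + 5.0, t_end - config.tail_s + 38.0]
    for tp in probes:
        i0 = int(round(tp * fs))
        add_plateau(i0, i0 + probe_n, config.mvf_probe_pct)

    for _, row in schedule.table.iterrows():
        i0 = int(round(row["contract_on_s"] * fs))
        i1 = int(round(row["contract_off_s"] * fs))
        level = config.force_target_pct + rng.normal(
            0, config.force_sd_pct[row["condition_s"]]
        )
        add_plateau(i0, i1, level)

    x += rng.standard_normal(n_samples) * config.force_noise_pct
    return x, np.asarray(probes)


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------


def synthesize_session(config: SessionConfig | None = None, seed=0,
                       leadfield: LeadField | None = None) -> Session:
    """Generate one seeded run: MEG + EMG + force + schedule + ground truth.

    ``leadfield`` may be supplied to share one head geometry across the runs
    of a subject; otherwise it is drawn from the seed.
    """
    config = config or SessionConfig()
    config.validate()
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seed_label = int(root.entropy) if np.isscalar(root.entropy) else 0
    s_geom, s_sched, s_burst, s_noise, s_emg, s_force = root.spawn(6)

    if leadfield is None:
        leadfield = build_geometry(config.n_channels, config.n_sources,
                                   seed=s_geom, model=config.geometry_model)
    elif leadfield.n_channels != config.n_channels \
            or leadfield.n_sources != config.n_sources:
        raise ValueError("supplied lead field does not match config dimensions")
    rng_sched = np.random.default_rng(s_sched)
    schedule = build_schedule(config, rng_sched)
    total_s = session_duration(config)
    n_samples = int(round(total_s * config.fs))

    sources = simulate_bursts(schedule, config.burst, seed=s_burst, fs=config.fs,
                              duration_s=total_s, n_sources=config.n_sources)

    rng_noise = np.random.default_rng(s_noise)
    meg_data = leadfield.gain @ sources.timecourses
    if config.noise_sd > 0:
        meg_data = meg_data + rng_noise.standard_normal(meg_data.shape) * config.noise_sd
    if config.pink_amplitude > 0:
        meg_data = meg_data + config.pink_amplitude * one_over_f_noise(
            config.n_channels, n_samples, config.fs, rng_noise
        )

    emg_data = _emg_channels(schedule, config, n_samples, np.random.default_rng(s_emg))
    force_data, probes = _force_channel(schedule, config, n_samples,
                                        np.random.default_rng(s_force))

    meg = SensorRecording(meg_data, config.fs,
                          [f"MEG{i:03d}" for i in range(config.n_channels)], kind="meg")
    emg = SensorRecording(emg_data, config.fs, ["EMG_ext", "EMG_flex"], kind="emg")
    force = SensorRecording(force_data, config.fs, ["force"], kind="force")
    return Session(meg=meg, emg=emg, force=force, schedule=schedule,
                   sources=sources, leadfield=leadfield, config=config,
                   seed=seed_label, task_source=0, probe_times=probes)
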