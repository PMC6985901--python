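"""Scalar LCMV beamforming: covariance estimation, pseudo-T contrasts,
virtual electrodes, and symmetric orthogonalization for leakage reduction.

The spatial filter for a source with (fixed-orientation) lead-field column l
is w = C^-1 l / (l^T C^-1 l), the linearly-constrained minimum-variance
solution with unit gain at the source. Active/control window power is
contrasted with the Vrba-Robinson pseudo-T statistic

    T = (P_active - P_control) / (2 * eps * w^T w),

where eps, the sensor-noise power proxy, is the smallest eigenvalue of the
unregularised combined covariance. Weights are computed from the Tikhonov-
regularised covariance (mu = 5% of the largest eigenvalue by default); power
terms use the unregularised window covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import bandpass_filter
from .synth import LeadField, SensorRecording, TaskSchedule

__all__ = [
    "CovarianceSet",
    "BeamformerResult",
    "LCMVBeamformer",
    "band_covariances",
    "tikhonov_regularize",
    "lcmv_weights",
    "pseudo_t_map",
    "virtual_electrodes",
    "symmetric_orthogonalize",
]

# active/control window rules (seconds, relative to detected events)
PMBR_ACTIVE_S = 8.0
PMBR_CONTROL_S = (16.0, 24.0)
MRBD_CONTROL_START_S = 24.0


@dataclass
class CovarianceSet:
    """Active/control/combined sensor covariances for one contrast."""

    active_cov: np.ndarray
    control_cov: np.ndarray
    combined_cov: np.ndarray
    band: tuple
    window_spec: str
    n_active: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        for name in ("active_cov", "control_cov", "combined_cov"):
            c = getattr(self, name)
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")


@dataclass
class BeamformerResult:
    """Fitted spatial filters and the pseudo-T contrast map."""

    weights: np.ndarray            # sources x channels
    tmap: np.ndarray               # pseudo-T per source
    peak_source: int
    contrast: str
    band: tuple
    covariances: CovarianceSet | None = None
    noise_eps: float = float("nan")
    source_coords: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            f"LCMV beamformer ({self.contrast.upper()} contrast, "
            f"{self.band[0]:g}-{self.band[1]:g} Hz)",
            f"  sources:      {len(self.tmap)}",
            f"  peak source:  {self.peak_source} (T = {self.tmap[self.peak_source]:+.3f})",
            f"  T range:      [{self.tmap.min():+.3f}, {self.tmap.max():+.3f}]",
            f"  noise eps:    {self.noise_eps:.3e}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"source_id": np.arange(len(self.tmap)),
                           "tstat": self.tmap})
        if self.source_coords is not None:
            df[["x", "y", "z"]] = self.source_coords
        return df


def _window_samples(events, schedule: TaskSchedule, spec: str, fs: float,
                    n_samples: int):
    """(active, control) lists of (i0, i1) sample windows for kept trials."""
    tab = events.kept
    active, control = [], []
    for _, row in tab.iterrows():
        if spec == "pmbr":
            a0, a1 = row["offset_s"], row["offset_s"] + PMBR_ACTIVE_S
            c0 = row["offset_s"] + PMBR_CONTROL_S[0]
            c1 = row["offset_s"] + PMBR_CONTROL_S[1]
        elif spec == "mrbd":
            a0, a1 = row["onset_s"], row["onset_s"] + row["condition_s"]
            c0 = row["onset_s"] + MRBD_CONTROL_START_S
            c1 = c0 + row["condition_s"]
        else:
            raise ValueError(f"unknown window spec {spec!r}")
        for (t0, t1), dest in (((a0, a1), active), ((c0, c1), control)):
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            if i0 < 0 or i1 > n_samples:
                raise ValueError(
                    f"{spec} window [{t0:.2f}, {t1:.2f}] s outside recording"
                )
            dest.append((i0, i1))
    return active, control


def _cov_of_windows(x: np.ndarray, windows) -> tuple[np.ndarray, int]:
    n_ch = x.shape[0]
    acc = np.zeros((n_ch, n_ch))
    n = 0
    for i0, i1 in windows:
        seg = x[:, i0:i1]
        acc += seg @ seg.T
        n += seg.shape[1]
    if n < n_ch + 1:
        raise ValueError(
            f"only {n} samples for a {n_ch}-channel covariance; estimate would "
            "be singular -- provide more windows or regularize"
        )
    cov = acc / n
    return 0.5 * (cov + cov.T), n


def band_covariances(meg: SensorRecording, events, schedule: TaskSchedule,
                     band: tuple = (15.0, 30.0),
                     window_spec: str = "pmbr") -> CovarianceSet:
    """Sample covariances over concatenated active/control windows.

    Windows of all three durations are concatenated (the underlying source is
    assumed common across durations, maximising covariance samples); the
    combined covariance pools active and control samples and is the one used
    for weight computation.
    """
    if not (0 < band[0] < band[1] < meg.fs / 2):
        raise ValueError("band outside Nyquist range")
    x = bandpass_filter(meg.data, band[0], band[1], meg.fs)
    active, control = _window_samples(events, schedule, window_spec, meg.fs,
                                      meg.n_samples)
    a_cov, n_a = _cov_of_windows(x, active)
    c_cov, n_c = _cov_of_windows(x, control)
    comb, _ = _cov_of_windows(x, active + control)
    return CovarianceSet(active_cov=a_cov, control_cov=c_cov, combined_cov=comb,
                         band=tuple(band), window_spec=window_spec,
                         n_active=n_a, n_control=n_c)


def tikhonov_regularize(cov: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """cov + fraction * lambda_max * I."""
    if fraction < 0:
        raise ValueError("regularization fraction must be >= 0")
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if fraction == 0:
        return cov
    lam_max = float(np.linalg.eigvalsh(cov)[-1])
    return cov + fraction * lam_max * np.eye(cov.shape[0])


def lcmv_weights(leadfield: LeadField | np.ndarray, cov_inv: np.ndarray,
                 source: int | None = None) -> np.ndarray:
    """Unit-gain LCMV weights w = C^-1 l / (l^T C^-1 l).

    With ``source`` given, returns that source's weight vector; otherwise a
    sources x channels matrix.
    """
    gain = leadfield.gain if isinstance(leadfield, LeadField) else np.asarray(leadfield)
    cols = gain if source is None else gain[:, [source]]
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm lead-field column")
    cl = cov_inv @ cols                      # channels x sources
    denom = np.einsum("cs,cs->s", cols, cl)
    w = (cl / denom).T                       # sources x channels
    return w[0] if source is not None else w


def pseudo_t_map(leadfield: LeadField, covset: CovarianceSet,
                 regularization: float = 0.05) -> BeamformerResult:
    """Pseudo-T contrast image over all sources, with peak identification.

    The peak is the extremum matching the contrast sign: maximum for the PMBR
    (power increase), minimum for the MRBD (power decrease).
    """
    reg = tikhonov_regularize(covset.combined_cov, regularization)
    cov_inv = np.linalg.inv(reg)
    w = lcmv_weights(leadfield, cov_inv)     # sources x channels
    p_act = np.einsum("sc,cd,sd->s", w, covset.active_cov, w)
    p_ctl = np.einsum("sc,cd,sd->s", w, covset.control_cov, w)
    eps = float(np.linalg.eigvalsh(covset.combined_cov)[0])
    tmap = (p_act - p_ctl) / (2.0 * eps * np.einsum("sc,sc->s", w, w))
    if not np.all(np.isfinite(tmap)):
        raise ValueError("non-finite pseudo-T values (singular weights?)")
    peak = int(np.argmin(tmap)) if covset.window_spec == "mrbd" else int(np.argmax(tmap))
    return BeamformerResult(weights=w, tmap=tmap, peak_source=peak,
                            contrast=covset.window_spec, band=covset.band,
                            covariances=covset, noise_eps=eps,
                            source_coords=leadfield.source_coords)


def virtual_electrodes(meg: SensorRecording, leadfield: LeadField,
                       parcel_sources: np.ndarray | None = None,
                       band: tuple = (1.0, 150.0),
                       regularization: float = 0.05,
                       combined_cov: np.ndarray | None = None) -> np.ndarray:
    """Beamformed timecourse for one representative source per parcel.

    The covariance window spans the whole experiment in the wide (1-150 Hz)
    band. Returns a parcels x samples matrix.
    """
    if parcel_sources is None:
        parcel_sources = np.arange(leadfield.n_sources)
    parcel_sources = np.asarray(parcel_sources, dtype=int)
    if np.any(parcel_sources < 0) or np.any(parcel_sources >= leadfield.n_sources):
        raise ValueError("parcel with no mapped source")
    hi = min(band[1], 0.45 * meg.fs)
    x = bandpass_filter(meg.data, band[0], hi, meg.fs)
    if combined_cov is None:
        combined_cov = (x @ x.T) / x.shape[1]
    cov_inv = np.linalg.inv(tikhonov_regularize(combined_cov, regularization))
    w = lcmv_weights(LeadField(leadfield.gain[:, parcel_sources],
                               leadfield.source_coords[parcel_sources],
                               leadfield.channel_coords), cov_inv)
    return w @ x


def symmetric_orthogonalize(timecourses: np.ndarray, tol: float = 1e-6,
                            max_iter: int = 50) -> np.ndarray:
    """Closest-orthogonal-matrix leakage correction (parcels x samples).

    Iterates Loewdin symmetric orthonormalization (the orthogonal polar
    factor) with per-row magnitude restoration by regression, treating all
    rows equivalently; converges to the closest set of mutually orthogonal
    timecourses in the least-squares sense. Deterministic.
    """
    X = np.asarray(timecourses, dtype=float)
    p, n = X.shape
    if n <= p:
        raise ValueError("need more samples than parcels")
    A = X.T                                   # n x p
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] <= 1e-10 * s[0]:
        corr = np.corrcoef(X)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient input: rows {i} and {j} are collinear "
            f"(|r| = {abs(corr[i, j]):.4f})"
        )
    d = np.linalg.norm(A, axis=0)
    prev = None
    for _ in range(max_iter):
        U, _, Vt = np.linalg.svd(A * d[None, :], full_matrices=False)
        O = U @ Vt                            # orthonormal columns
        d = np.einsum("np,np->p", A, O)       # magnitude regression
        ssr = float(np.sum((A - O * d[None, :]) ** 2))
        if prev is not None and abs(prev - ssr) <= tol * max(prev, 1e-300):
            break
        prev = ssr
    return (O * d[None, :]).T


class LCMVBeamformer:
    """Scalar LCMV beamformer model over a session's MEG data.

    Parameters
    ----------
    meg : SensorRecording
    leadfield : LeadField
    events : TrialEvents
        Detected contraction bounds (kept trials define the windows).
    schedule : TaskSchedule
    regularization : float
        Tikhonov fraction of the largest covariance eigenvalue (0 disables).
    """

    def __init__(self, meg: SensorRecording, leadfield: LeadField, events,
                 schedule: TaskSchedule, regularization: float = 0.05):
        if leadfield.n_channels != meg.n_channels:
            raise ValueError("lead field/channel count mismatch")
        self.meg = meg
        self.leadfield = leadfield
        self.events = events
        self.schedule = schedule
        self.regularization = regularization

    def fit(self, contrast: str = "pmbr", band: tuple = (15.0, 30.0)) -> BeamformerResult:
        covset = band_covariances(self.meg, self.events, self.schedule,
                                  band=band, window_spec=contrast)
        return pseudo_t_map(self.leadfield, covset, self.regularization)

    def virtual_electrodes(self, parcel_sources=None,
                           band: tuple = (1.0, 150.0)) -> np.ndarray:
        return virtual_electrodes(self.meg, self.leadfield, parcel_sources,
                                  band=band, regularization=self.regularization)
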