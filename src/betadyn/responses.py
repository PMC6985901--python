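"""Parametric quantification of the post-movement beta rebound (PMBR) and the
movement-related beta decrease (MRBD).

PMBR: a Weibull-density curve

    f(t) = (b/a) (t/a)^(b-1) exp(-(t/a)^b),    t > 0,

scaled by a linear amplitude coefficient, is fitted to the trial-averaged
beta envelope from the rebound start t0 (the first zero up-crossing after the
MRBD trough) onward. For each candidate (a, b) the amplitude enters linearly
and is solved by ordinary least squares; (a, b) are optimised by multi-start
Nelder-Mead in log space (the SSR surface is multimodal). Derived metrics:
peak amplitude, time-to-peak (the density mode t0 + a((b-1)/b)^(1/b) for
b > 1) and return-to-baseline time (first post-peak time at which the fitted
curve's |gradient| falls below a threshold, default 1e-4 per second).

MRBD: a trapezoid (0 -> h over [t1,t2], h over [t2,t3], h -> 0 over [t3,t4],
h < 0) fitted by SSR minimisation with the vertex ordering enforced through a
positive-increment reparameterisation. Amplitude |h|, duration t3-t2, and
integral |h|((t4-t1)+(t3-t2))/2 follow from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .synth import weibull_pdf

__all__ = [
    "WeibullFit",
    "TrapezoidFit",
    "WeibullRebound",
    "TrapezoidDepression",
    "find_rebound_start",
    "fit_weibull_glm",
    "weibull_metrics",
    "fit_trapezoid",
    "trapezoid_metrics",
    "weibull_gradient",
]


def weibull_gradient(t, a: float, b: float):
    """d f(t; a, b) / dt of the Weibull density (zero for t <= 0)."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / a
    xb = x**b
    out[pos] = (b / a**2) * x ** (b - 2) * np.exp(-xb) * ((b - 1) - b * xb)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Weibull rebound
# ---------------------------------------------------------------------------


@dataclass
class WeibullFit:
    """Weibull PMBR fit results."""

    a: float              # scale (s)
    b: float              # shape
    beta_amp: float       # linear amplitude coefficient (source units)
    t0: float             # rebound start, s relative to alignment event
    ssr: float
    n_obs: int = 0
    converged: bool = True

    @property
    def time_to_peak(self) -> float:
        """Time of the curve's maximum (s, same reference as t0)."""
        if self.b > 1:
            return self.t0 + self.a * ((self.b - 1) / self.b) ** (1 / self.b)
        return self.t0

    @property
    def peak_amplitude(self) -> float:
        if self.b > 1:
            return self.beta_amp * float(weibull_pdf(self.time_to_peak - self.t0,
                                                     self.a, self.b))
        if self.b == 1:
            return self.beta_amp / self.a
        return self.beta_amp * float(weibull_pdf(1e-3, self.a, self.b))

    def return_time(self, grad_threshold: float = 1e-4,
                    t_max: float = 60.0, dt: float = 1e-3) -> float:
        """First post-peak time where |d(beta*f)/dt| < grad_threshold.

        The search starts at the point of steepest descent after the peak
        (the gradient is zero *at* the peak itself).
        """
        if grad_threshold <= 0:
            raise ValueError("gradient threshold must be positive")
        rel = np.arange(max(self.time_to_peak - self.t0, dt), t_max, dt)
        g = np.abs(self.beta_amp * weibull_gradient(rel, self.a, self.b))
        steepest = int(np.argmax(g))
        below = np.nonzero(g[steepest:] < grad_threshold)[0]
        if len(below) == 0:
            return float("nan")
        return float(self.t0 + rel[steepest + below[0]])

    def predict(self, times) -> np.ndarray:
        return self.beta_amp * weibull_pdf(np.asarray(times) - self.t0,
                                           self.a, self.b)

    def summary(self) -> str:
        return "\n".join([
            "Weibull rebound fit",
            f"  scale a:        {self.a:.4f} s",
            f"  shape b:        {self.b:.4f}",
            f"  amplitude:      {self.beta_amp:.4f}",
            f"  t0:             {self.t0:.4f} s",
            f"  peak amplitude: {self.peak_amplitude:.4f}",
            f"  time to peak:   {self.time_to_peak:.4f} s",
            f"  return time:    {self.return_time():.3f} s",
            f"  SSR:            {self.ssr:.6g}  (n = {self.n_obs})",
        ])


def find_rebound_start(times: np.ndarray, values: np.ndarray, fs: float,
                       smooth_s: float = 0.2,
                       anchor_time: float | None = None) -> float:
    """First zero up-crossing of the (lightly smoothed) envelope after the
    MRBD. Smoothing applies to t0 detection only.

    ``anchor_time`` places the start of the crossing search at a known point
    inside the suppression (normally the movement offset, where the MRBD is
    still ongoing); without it the search starts at the envelope trough.
    Anchoring makes t0 immune to brief positive wobbles earlier in a long
    movement period.
    """
    n = max(int(round(smooth_s * fs)) | 1, 1)
    kernel = np.ones(n) / n
    sm = np.convolve(values, kernel, mode="same")
    if anchor_time is None:
        anchor = int(np.argmin(sm))
    else:
        anchor = int(np.searchsorted(times, anchor_time))
        anchor = min(anchor, len(sm) - 1)
    up = np.nonzero(sm[anchor:] >= 0)[0]
    if len(up) == 0:
        raise ValueError("envelope never returns to zero after the MRBD")
    return float(times[anchor + up[0]])


class WeibullRebound:
    """Model: trial-averaged beta envelope ~ beta_amp * Weibull(t - t0; a, b).

    Parameters
    ----------
    times, values : 1-D arrays
        Envelope timecourse (s relative to contraction offset; absolute,
        baseline-subtracted units).
    t0 : float, optional
        Rebound start. Detected from the data when omitted.
    fs : float
        Sampling rate of ``times`` (used only for t0 smoothing).
    """

    def __init__(self, times, values, t0: float | None = None,
                 fs: float | None = None, anchor_time: float | None = 0.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values shape mismatch")
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(self.times)))
        self.fs = fs
        if t0 is None:
            # times are relative to contraction offset; anchor the zero-
            # crossing search there (the MRBD is still ongoing at offset)
            anchor = anchor_time if self.times[0] <= (anchor_time or 0.0) else None
            t0 = find_rebound_start(self.times, self.values, fs,
                                    anchor_time=anchor)
        self.t0 = float(t0)
        mask = self.times >= self.t0
        if not mask.any():
            raise ValueError("no samples after rebound start t0")
        self._t = self.times[mask] - self.t0
        self._y = self.values[mask]

    def _ols(self, a: float, b: float):
        g = weibull_pdf(self._t, a, b)
        gg = float(g @ g)
        if gg <= 0 or not np.isfinite(gg):
            return 0.0, float(self._y @ self._y)
        beta = float(g @ self._y) / gg
        r = self._y - beta * g
        return beta, float(r @ r)

    def ssr(self, a: float, b: float) -> float:
        return self._ols(a, b)[1]

    def fit(self, n_starts: int = 9, a_range: tuple = (0.1, 20.0),
            b_range: tuple = (0.5, 10.0), xatol: float = 1e-8,
            fatol: float = 1e-12, max_iter: int = 400) -> WeibullFit:
        """Multi-start Nelder-Mead over (log a, log b), OLS amplitude inside."""
        k = max(int(round(np.sqrt(n_starts))), 1)
        a0s = np.exp(np.linspace(np.log(a_range[0]), np.log(a_range[1]), k + 2))[1:-1]
        b0s = np.exp(np.linspace(np.log(b_range[0]), np.log(b_range[1]), k + 2))[1:-1]

        la_lo, la_hi = np.log(a_range[0]), np.log(a_range[1])
        lb_lo, lb_hi = np.log(b_range[0]), np.log(b_range[1])
        y2 = float(self._y @ self._y)

        def objective(p):
            # soft box constraint keeping (a, b) inside the admissible ranges
            excess = (max(la_lo - p[0], 0.0) + max(p[0] - la_hi, 0.0)
                      + max(lb_lo - p[1], 0.0) + max(p[1] - lb_hi, 0.0))
            pen = y2 * excess**2 if excess > 0 else 0.0
            return self._ols(np.exp(p[0]), np.exp(p[1]))[1] + pen

        best = None
        any_converged = False
        for a0 in a0s:
            for b0 in b0s:
                res = minimize(objective, x0=[np.log(a0), np.log(b0)],
                               method="Nelder-Mead",
                               options={"xatol": xatol, "fatol": fatol,
                                        "maxiter": max_iter})
                any_converged |= bool(res.success)
                if best is None or res.fun < best.fun:
                    best = res
        if best is None or not any_converged:
            raise RuntimeError("Weibull optimizer failed to converge from any start")
        a, b = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
        beta, ssr = self._ols(a, b)
        return WeibullFit(a=a, b=b, beta_amp=beta, t0=self.t0, ssr=ssr,
                          n_obs=len(self._y), converged=any_converged)


def fit_weibull_glm(times, values, t0: float | None = None,
                    fs: float | None = None, **fit_kw) -> WeibullFit:
    """Functional wrapper around :class:`WeibullRebound`."""
    return WeibullRebound(times, values, t0=t0, fs=fs).fit(**fit_kw)


def weibull_metrics(fit: WeibullFit, grad_threshold: float = 1e-4):
    """(peak_amplitude, time_to_peak, return_time) of a fitted curve."""
    return fit.peak_amplitude, fit.time_to_peak, fit.return_time(grad_threshold)


# ---------------------------------------------------------------------------
# trapezoid MRBD
# ---------------------------------------------------------------------------


@dataclass
class TrapezoidFit:
    """Trapezoid MRBD fit: vertices t1 < t2 < t3 < t4, height h (< 0)."""

    t1: float
    t2: float
    t3: float
    t4: float
    h: float
    ssr: float
    n_obs: int = 0
    degenerate: bool = False

    @property
    def amplitude(self) -> float:
        return abs(self.h)

    @property
    def duration(self) -> float:
        return self.t3 - self.t2

    @property
    def integral(self) -> float:
        """Trapezoid area |h| * ((t4 - t1) + (t3 - t2)) / 2."""
        return abs(self.h) * ((self.t4 - self.t1) + (self.t3 - self.t2)) / 2.0

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.h * np.interp(t, [self.t1, self.t2, self.t3, self.t4],
                                  [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)

    def summary(self) -> str:
        flag = "  [degenerate: |h| ~ 0, duration unreliable]" if self.degenerate else ""
        return "\n".join([
            "Trapezoid MRBD fit" + flag,
            f"  vertices:  t1={self.t1:.3f}, t2={self.t2:.3f}, "
            f"t3={self.t3:.3f}, t4={self.t4:.3f} s",
            f"  height h:  {self.h:.4f}",
            f"  amplitude: {self.amplitude:.4f}   duration: {self.duration:.3f} s"
            f"   integral: {self.integral:.4f}",
            f"  SSR:       {self.ssr:.6g}  (n = {self.n_obs})",
        ])


class TrapezoidDepression:
    """Model: beta envelope ~ trapezoid(t; t1..t4, h) over the MRBD window."""

    def __init__(self, times, values):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if len(self.times) < 4:
            raise ValueError("window shorter than 4 samples")

    def _ssr(self, params) -> float:
        t1, ld1, ld2, ld3, h = params
        t2 = t1 + np.exp(ld1)
        t3 = t2 + np.exp(ld2)
        t4 = t3 + np.exp(ld3)
        model = h * np.interp(self.times, [t1, t2, t3, t4], [0, 1, 1, 0],
                              left=0.0, right=0.0)
        r = self.values - model
        return float(r @ r)

    def _initial_guesses(self):
        t, y = self.times, self.values
        n = max(int(0.05 * len(y)) | 1, 3)
        sm = np.convolve(y, np.ones(n) / n, mode="same")
        h0 = float(np.percentile(sm, 2))
        if h0 >= 0:
            h0 = float(sm.min()) or -1e-3
        deep = sm <= 0.5 * h0
        if deep.any():
            ta, tb = float(t[deep][0]), float(t[deep][-1])
        else:
            ta, tb = float(t[len(t) // 3]), float(t[2 * len(t) // 3])
        span = max(tb - ta, 4.0 / len(t) * (t[-1] - t[0]))
        guesses = []
        for edge in (0.25, 0.75):
            for base_frac in (0.8, 0.5):
                d1 = max(edge * span * 0.3, 1e-2)
                d2 = max(base_frac * span, 1e-2)
                guesses.append([ta - d1, np.log(d1), np.log(d2), np.log(d1), h0])
        guesses.append([ta - 0.5, np.log(0.5), np.log(max(span, 0.1)),
                        np.log(0.5), h0])
        return guesses

    def fit(self, n_starts: int = 5, xatol: float = 1e-8, fatol: float = 1e-12,
            max_iter: int = 2000) -> TrapezoidFit:
        best = None
        any_ok = False
        for x0 in self._initial_guesses()[:max(n_starts, 1)]:
            res = minimize(self._ssr, x0=np.asarray(x0, dtype=float),
                           method="Nelder-Mead",
                           options={"xatol": xatol, "fatol": fatol,
                                    "maxiter": max_iter, "maxfev": max_iter})
            any_ok |= bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("trapezoid optimizer failed")
        t1, ld1, ld2, ld3, h = best.x
        t2 = t1 + np.exp(ld1)
        t3 = t2 + np.exp(ld2)
        t4 = t3 + np.exp(ld3)
        scale = float(np.max(np.abs(self.values))) or 1.0
        return TrapezoidFit(t1=float(t1), t2=float(t2), t3=float(t3),
                            t4=float(t4), h=float(h), ssr=float(best.fun),
                            n_obs=len(self.values),
                            degenerate=abs(h) < 1e-3 * scale)


def fit_trapezoid(times, values, **fit_kw) -> TrapezoidFit:
    """Functional wrapper around :class:`TrapezoidDepression`."""
    return TrapezoidDepression(times, values).fit(**fit_kw)


def trapezoid_metrics(fit: TrapezoidFit):
    """(amplitude, duration, integral) of a fitted trapezoid."""
    return fit.amplitude, fit.duration, fit.integral
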