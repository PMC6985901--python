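"""Amplitude-envelope Hidden Markov Model with variational-Bayes inference.

Parcel beta/broadband envelopes (downsampled to 100 Hz, 1-40 Hz filtered,
standardised) are modelled by K mutually exclusive states, each a
multivariate normal over parcels; the latent state sequence is Markovian.
Inference uses a structured mean-field variational posterior: Dirichlet rows
for the transition matrix, a Dirichlet initial distribution, Normal-Wishart
observation parameters, and an exact chain posterior (forward-backward) for
the states. The negative evidence lower bound ("free energy", lower is
better) is monitored every iteration and used to select the best of
``n_inits`` restarts. Decoding uses Viterbi with posterior-mean parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linear_sum_assignment
from scipy.signal import decimate
from scipy.special import digamma, gammaln

from ._chain import forward_backward, viterbi_path
from .spectral import bandpass_filter, hilbert_envelope
from .synth import TaskSchedule

__all__ = [
    "HMMResults",
    "StatePath",
    "EnvelopeHMM",
    "prepare_hmm_input",
    "fit_hmm",
    "viterbi_decode",
    "state_metrics",
    "scan_states",
    "align_states",
    "DEFAULT_EPOCHS",
]

DEFAULT_EPOCHS = {"post": (1.0, 5.0), "movement": (-4.0, 0.0), "rest": (20.0, 24.0)}


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------


def prepare_hmm_input(parcel_tcs, fs: float = 600.0, target_fs: float = 100.0,
                      band: tuple = (1.0, 40.0), standardize: bool = True):
    """Downsample, band-filter and envelope parcel timecourses.

    ``parcel_tcs``: one parcels x samples matrix or a list of them (sessions).
    Returns (X, boundaries): X is samples x parcels concatenated across
    sessions; ``boundaries`` holds each session's start index so the chain
    recursions never bridge sessions.
    """
    if isinstance(parcel_tcs, np.ndarray):
        parcel_tcs = [parcel_tcs]
    q = fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"fs/target_fs = {q} must be an integer decimation factor")
    q = int(round(q))

    segments, boundaries, start = [], [], 0
    for tc in parcel_tcs:
        tc = np.atleast_2d(np.asarray(tc, dtype=float))
        if tc.shape[1] < 24 * q:
            raise ValueError("session too short for decimation filtering")
        v = tc.var(axis=1)
        if np.any(v == 0):
            raise ValueError(f"parcel(s) {np.nonzero(v == 0)[0]} have zero variance")
        low = decimate(tc, q, ftype="fir", zero_phase=True) if q > 1 else tc
        filt = bandpass_filter(low, band[0], min(band[1], 0.45 * target_fs),
                               target_fs)
        env = hilbert_envelope(filt)
        segments.append(env.T)                 # samples x parcels
        boundaries.append(start)
        start += env.shape[1]
    X = np.concatenate(segments, axis=0)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X, boundaries


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class StatePath:
    """Per-sample most-likely state with per-state binary timecourses."""

    states: np.ndarray            # int per sample
    n_states: int
    fs: float = 100.0
    boundaries: list = field(default_factory=lambda: [0])

    def binary(self) -> np.ndarray:
        """states x samples one-hot matrix (mutually exclusive by construction)."""
        out = np.zeros((self.n_states, len(self.states)), dtype=np.int8)
        out[self.states, np.arange(len(self.states))] = 1
        return out


@dataclass
class HMMResults:
    """Posterior summary of a fitted envelope HMM."""

    n_states: int
    means: np.ndarray             # K x P (posterior mean)
    covariances: np.ndarray       # K x P x P (posterior expected covariance)
    transitions: np.ndarray       # K x K row-stochastic (posterior mean)
    initial_probs: np.ndarray
    free_energy: float
    free_energy_trace: np.ndarray
    init_free_energies: np.ndarray
    init_index: int
    seed: int
    n_iter: int
    converged: bool
    all_traces: list = field(default_factory=list)   # per-init FE trajectories
    boundaries: list = field(default_factory=lambda: [0])
    # raw variational parameters (needed to resume/decode exactly)
    _post: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        rows = self.transitions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")

    def decode(self, X: np.ndarray, boundaries=None) -> StatePath:
        return viterbi_decode(self, X, boundaries)

    def summary(self) -> str:
        occ = np.bincount(np.argmax(self.means, axis=1), minlength=self.means.shape[1])
        lines = [
            f"Envelope HMM ({self.n_states} states, {self.means.shape[1]} parcels)",
            f"  free energy:   {self.free_energy:.2f} "
            f"(best of {len(self.init_free_energies)} inits, init {self.init_index})",
            f"  iterations:    {self.n_iter} (converged: {self.converged})",
            f"  diag(A):       {np.round(np.diag(self.transitions), 3)}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# variational Bayes machinery
# ---------------------------------------------------------------------------


def _kl_dirichlet(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    aq0, ap0 = alpha_q.sum(), alpha_p.sum()
    return float(
        gammaln(aq0) - gammaln(alpha_q).sum()
        - gammaln(ap0) + gammaln(alpha_p).sum()
        + ((alpha_q - alpha_p) * (digamma(alpha_q) - digamma(aq0))).sum()
    )


def _ln_wishart_B(W: np.ndarray, nu: float) -> float:
    P = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(
        -0.5 * nu * logdet - 0.5 * nu * P * np.log(2.0)
        - 0.25 * P * (P - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu - np.arange(P))).sum()
    )


def _e_ln_det_lambda(W: np.ndarray, nu: float) -> float:
    P = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(digamma(0.5 * (nu - np.arange(P))).sum()
                 + P * np.log(2.0) + logdet)


def _kl_normal_wishart(m, beta, W, nu, m0, beta0, W0, nu0) -> float:
    P = len(m)
    e_lndet = _e_ln_det_lambda(W, nu)
    e_lam = nu * W
    dm = m - m0
    kl_normal = 0.5 * (P * beta0 / beta + beta0 * float(dm @ e_lam @ dm)
                       - P + P * np.log(beta / beta0))
    W0_inv = np.linalg.inv(W0)
    kl_wishart = (
        0.5 * (nu - nu0) * e_lndet
        - 0.5 * nu * P                     # tr(W^-1 E[Lambda]) = nu * P
        + 0.5 * float(np.trace(W0_inv @ e_lam))
        + _ln_wishart_B(W, nu) - _ln_wishart_B(W0, nu0)
    )
    return float(kl_normal + kl_wishart)


class EnvelopeHMM:
    """Variational-Bayes multivariate-normal HMM over parcel envelopes.

    Parameters
    ----------
    X : (samples, parcels) array
        Prepared envelopes (see :func:`prepare_hmm_input`).
    n_states : int
    boundaries : list of int
        Session start indices; the chain never bridges sessions.
    trans_prior_diag, trans_prior_offdiag : float
        Dirichlet pseudo-counts on transition rows (the diagonal excess
        encourages temporal persistence).
    """

    def __init__(self, X: np.ndarray, n_states: int, boundaries=None,
                 trans_prior_diag: float = 10.0,
                 trans_prior_offdiag: float = 1.0):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x parcels")
        if n_states < 1:
            raise ValueError("need at least one state")
        T, P = X.shape
        if T < 2 * n_states * P:
            raise ValueError("too few samples for the requested model size")
        self.X = X
        self.K = n_states
        self.boundaries = list(boundaries) if boundaries else [0]
        K = n_states
        self.alpha_A0 = np.full((K, K), trans_prior_offdiag) \
            + (trans_prior_diag - trans_prior_offdiag) * np.eye(K)
        self.alpha_pi0 = np.ones(K)
        # Normal-Wishart prior: empirical-mean centring, P+2 dof
        self.m0 = X.mean(axis=0)
        self.beta0 = 1.0
        self.nu0 = float(P + 2)
        S = np.cov(X.T) if P > 1 else np.atleast_2d(np.var(X))
        S = S + 1e-6 * np.eye(P)
        self.W0 = np.linalg.inv(S * self.nu0)   # so prior E[Lambda] = S^-1

    # -- single-init VB ----------------------------------------------------
    def _m_step(self, gamma, xi_sum, first_counts):
        X = self.X
        K, P = self.K, X.shape[1]
        Nk = gamma.sum(axis=0) + 1e-12
        xbar = (gamma.T @ X) / Nk[:, None]
        beta = self.beta0 + Nk
        nu = self.nu0 + Nk
        m = (self.beta0 * self.m0 + Nk[:, None] * xbar) / beta[:, None]
        W = np.empty((K, P, P))
        W0_inv = np.linalg.inv(self.W0)
        for k in range(K):
            d = X - xbar[k]
            Sk = (gamma[:, k][:, None] * d).T @ d
            dm = (xbar[k] - self.m0)[:, None]
            Winv = W0_inv + Sk + (self.beta0 * Nk[k] / beta[k]) * (dm @ dm.T)
            Winv = 0.5 * (Winv + Winv.T)
            W[k] = np.linalg.inv(Winv)
            # symmetrize for numerical hygiene
            W[k] = 0.5 * (W[k] + W[k].T)
        alpha_A = self.alpha_A0 + xi_sum
        alpha_pi = self.alpha_pi0 + first_counts
        return {"m": m, "beta": beta, "W": W, "nu": nu,
                "alpha_A": alpha_A, "alpha_pi": alpha_pi}

    def _expected_loglik(self, post):
        X = self.X
        K, P = self.K, X.shape[1]
        T = X.shape[0]
        ll = np.empty((T, K))
        for k in range(K):
            W, nu, beta, m = post["W"][k], post["nu"][k], post["beta"][k], post["m"][k]
            e_lndet = _e_ln_det_lambda(W, nu)
            L = np.linalg.cholesky(W)
            proj = (X - m) @ L
            quad = nu * np.einsum("tp,tp->t", proj, proj)
            ll[:, k] = 0.5 * (e_lndet - P / beta - quad - P * np.log(2 * np.pi))
        return ll

    def _expected_ln_trans(self, post):
        aA = post["alpha_A"]
        lnA = digamma(aA) - digamma(aA.sum(axis=1, keepdims=True))
        api = post["alpha_pi"]
        lnpi = digamma(api) - digamma(api.sum())
        return lnA, lnpi

    def _kl_terms(self, post) -> float:
        kl = _kl_dirichlet(post["alpha_pi"], self.alpha_pi0)
        for k in range(self.K):
            kl += _kl_dirichlet(post["alpha_A"][k], self.alpha_A0[k])
            kl += _kl_normal_wishart(post["m"][k], post["beta"][k],
                                     post["W"][k], post["nu"][k],
                                     self.m0, self.beta0, self.W0, self.nu0)
        return kl

    def _init_responsibilities(self, rng: np.random.Generator) -> np.ndarray:
        """Seeded random perturbation of a k-means partition."""
        from scipy.cluster.vq import kmeans2

        T = self.X.shape[0]
        if self.K == 1:
            return np.ones((T, 1))
        sub = self.X[:: max(T // 20000, 1)]
        _, labels_sub = kmeans2(sub, self.K, minit="++",
                                seed=int(rng.integers(2**31)))
        # assign all samples to the nearest k-means centroid
        centroids = np.stack([
            sub[labels_sub == k].mean(axis=0) if np.any(labels_sub == k)
            else sub[rng.integers(len(sub))]
            for k in range(self.K)
        ])
        d2 = ((self.X[:, None, :] - centroids[None]) ** 2).sum(axis=2) \
            if self.X.shape[1] * self.K * T < 5e8 else None
        if d2 is None:
            d2 = np.empty((T, self.K))
            for k in range(self.K):
                d2[:, k] = ((self.X - centroids[k]) ** 2).sum(axis=1)
        labels = np.argmin(d2, axis=1)
        gamma = np.full((T, self.K), 0.25 / max(self.K - 1, 1))
        gamma[np.arange(T), labels] = 0.75
        gamma *= rng.uniform(0.8, 1.2, size=gamma.shape)
        return gamma / gamma.sum(axis=1, keepdims=True)

    def _fit_single(self, seed: int, init_index: int, tol: float,
                    max_iter: int):
        rng = np.random.default_rng(seed + init_index)
        gamma = self._init_responsibilities(rng)
        xi0 = gamma[:-1].T @ gamma[1:]
        first = gamma[np.asarray(self.boundaries, dtype=int)].sum(axis=0)
        post = self._m_step(gamma, xi0, first)

        trace = []
        converged = False
        for it in range(max_iter):
            ll = self._expected_loglik(post)
            lnA, lnpi = self._expected_ln_trans(post)
            gamma, xi_sum, lnZ, first = forward_backward(
                ll, lnA, lnpi, self.boundaries
            )
            fe = -(lnZ - self._kl_terms(post))
            trace.append(fe)
            if len(trace) > 1:
                rel = (trace[-2] - trace[-1]) / max(abs(trace[-2]), 1e-300)
                if abs(rel) < tol:
                    converged = True
                    break
            post = self._m_step(gamma, xi_sum, first)
        return post, np.asarray(trace), converged

    def fit(self, n_inits: int = 10, seed: int = 0, tol: float = 1e-6,
            max_iter: int = 100) -> HMMResults:
        """Run ``n_inits`` VB restarts, return the lowest-free-energy model."""
        results = []
        errors = []
        for i in range(n_inits):
            try:
                post, trace, conv = self._fit_single(seed, i, tol, max_iter)
                results.append((trace[-1], i, post, trace, conv))
            except np.linalg.LinAlgError as exc:  # non-PSD during updates
                errors.append(f"init {i}: {exc}")
        if not results:
            raise RuntimeError("all HMM inits failed: " + "; ".join(errors))
        by_init = sorted(results, key=lambda r: r[1])
        init_fes = np.array([r[0] for r in by_init])
        all_traces = [np.asarray(r[3]) for r in by_init]
        fe_best, idx, post, trace, conv = min(results, key=lambda r: r[0])

        K, P = self.K, self.X.shape[1]
        covs = np.empty((K, P, P))
        for k in range(K):
            denom = post["nu"][k] - P - 1
            covs[k] = np.linalg.inv(post["W"][k]) / max(denom, 1e-6)
        A = post["alpha_A"] / post["alpha_A"].sum(axis=1, keepdims=True)
        pi = post["alpha_pi"] / post["alpha_pi"].sum()
        return HMMResults(
            n_states=K, means=post["m"].copy(), covariances=covs,
            transitions=A, initial_probs=pi, free_energy=float(fe_best),
            free_energy_trace=trace, init_free_energies=init_fes,
            init_index=idx, seed=seed, n_iter=len(trace), converged=conv,
            all_traces=all_traces, boundaries=self.boundaries, _post=post,
        )


def fit_hmm(X: np.ndarray, n_states: int, n_inits: int = 10, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 100, boundaries=None,
            **model_kw) -> HMMResults:
    """Functional wrapper around :class:`EnvelopeHMM`."""
    model = EnvelopeHMM(X, n_states, boundaries=boundaries, **model_kw)
    return model.fit(n_inits=n_inits, seed=seed, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# decoding and metrics
# ---------------------------------------------------------------------------


def viterbi_decode(model: HMMResults, X: np.ndarray,
                   boundaries=None) -> StatePath:
    """Most probable state sequence under posterior-mean parameters."""
    X = np.asarray(X, dtype=float)
    K, P = model.n_states, model.means.shape[1]
    if X.ndim != 2 or X.shape[1] != P:
        raise ValueError(f"expected samples x {P} envelope matrix")
    boundaries = list(boundaries) if boundaries is not None else model.boundaries
    ll = np.empty((X.shape[0], K))
    for k in range(K):
        cov = model.covariances[k]
        cf = cho_factor(cov, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        d = X - model.means[k]
        sol = cho_solve(cf, d.T)
        quad = np.einsum("pt,pt->t", d.T, sol)
        ll[:, k] = -0.5 * (quad + logdet + P * np.log(2 * np.pi))
    with np.errstate(divide="ignore"):
        lnA = np.log(model.transitions)
        lnpi = np.log(model.initial_probs)
    path = viterbi_path(ll, lnA, lnpi, boundaries)
    return StatePath(states=path, n_states=K, boundaries=boundaries)


def align_states(means_est: np.ndarray, means_ref: np.ndarray) -> np.ndarray:
    """Label alignment: ``perm[k]`` is the reference state matched to
    estimated state k (Hungarian assignment on squared mean distance)."""
    cost = ((means_est[:, None, :] - means_ref[None]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def _visits(binary: np.ndarray):
    """(onsets, offsets) sample indices of True runs (offsets exclusive)."""
    d = np.diff(binary.astype(np.int8), prepend=0, append=0)
    return np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]


METRIC_NAMES = ["fractional_occupancy", "n_occurrences", "mean_lifetime_ms",
                "mean_interval_ms", "mean_beta_amplitude"]


def state_metrics(path: StatePath, schedule: TaskSchedule, events,
                  beta_env: np.ndarray | None = None,
                  beta_fs: float = 600.0,
                  epochs: dict | None = None,
                  per_trial: bool = False) -> pd.DataFrame:
    """Five summary statistics per state x epoch x condition.

    Epoch windows are defined relative to each kept trial's detected
    contraction offset (seconds). Per trial and state: fractional occupancy;
    number of occurrences (visits whose onset falls inside the window); mean
    lifetime of those visits (unclipped); mean interval between consecutive
    in-window visits; mean beta amplitude over active samples (the
    conventional beta envelope multiplied by the binary state timecourse,
    sample-and-hold upsampled to the envelope grid). Trial-averaged unless
    ``per_trial``; lifetime and interval are absent (NaN) when no visits
    occur, never coerced to zero.
    """
    epochs = epochs or DEFAULT_EPOCHS
    fs = path.fs
    dt_ms = 1000.0 / fs
    binaries = path.binary()
    n_samples = len(path.states)
    factor = int(round(beta_fs / fs)) if beta_env is not None else 1

    kept = events.kept
    trial_rows = []
    for state in range(path.n_states):
        b = binaries[state]
        onsets, offsets = _visits(b)
        for epoch, (w0, w1) in epochs.items():
            if w1 <= w0:
                raise ValueError(f"epoch {epoch!r} window has zero length")
            for _, trial in kept.iterrows():
                t_off = trial["offset_s"]
                i0 = int(round((t_off + w0) * fs))
                i1 = int(round((t_off + w1) * fs))
                if i0 < 0 or i1 > n_samples or i1 <= i0:
                    continue
                occ = float(b[i0:i1].mean())
                in_win = (onsets >= i0) & (onsets < i1)
                n_occ = int(in_win.sum())
                lifetimes = (offsets[in_win] - onsets[in_win]) * dt_ms
                life = float(lifetimes.mean()) if n_occ else np.nan
                if n_occ >= 2:
                    on_w, off_w = onsets[in_win], offsets[in_win]
                    interval = float(np.mean(on_w[1:] - off_w[:-1]) * dt_ms)
                else:
                    interval = np.nan
                if beta_env is not None:
                    j0, j1 = i0 * factor, i1 * factor
                    mask = np.repeat(b[i0:i1], factor).astype(bool)
                    seg = beta_env[j0:j1]
                    amp = float(seg[mask[:len(seg)]].mean()) if mask.any() else np.nan
                else:
                    amp = np.nan
                trial_rows.append({
                    "state": state, "epoch": epoch,
                    "condition_s": trial["condition_s"],
                    "trial_id": int(trial["trial_id"]),
                    "fractional_occupancy": occ, "n_occurrences": n_occ,
                    "mean_lifetime_ms": life, "mean_interval_ms": interval,
                    "mean_beta_amplitude": amp,
                })
    trials = pd.DataFrame(trial_rows)
    if per_trial:
        return trials
    rows = []
    for (state, epoch, cond), grp in trials.groupby(
            ["state", "epoch", "condition_s"], sort=True):
        for name in METRIC_NAMES:
            rows.append({"state": state, "epoch": epoch, "condition_s": cond,
                         "metric": name, "value": float(grp[name].mean()),
                         "n_trials": len(grp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-order scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    models: dict                    # K -> HMMResults
    free_energies: dict             # K -> float
    sensorimotor_state: dict        # K -> int (template match), if template given
    template: np.ndarray | None = None

    def report(self) -> pd.DataFrame:
        rows = []
        for K, fe in self.free_energies.items():
            rows.append({"n_states": K, "free_energy": fe,
                         "sensorimotor_state": self.sensorimotor_state.get(K)})
        return pd.DataFrame(rows)


def scan_states(X: np.ndarray, K_list=(4, 6, 8, 10), template=None,
                boundaries=None, n_inits: int = 10, seed: int = 0,
                tol: float = 1e-6, max_iter: int = 100, **model_kw) -> ScanResult:
    """Fit an HMM per candidate state count; optionally identify the
    sensorimotor-like state by spatial correlation with a template map."""
    models, fes, sm = {}, {}, {}
    for K in K_list:
        res = fit_hmm(X, K, n_inits=n_inits, seed=seed, tol=tol,
                      max_iter=max_iter, boundaries=boundaries, **model_kw)
        models[K] = res
        fes[K] = res.free_energy
        if template is not None:
            t = np.asarray(template, dtype=float)
            corrs = [abs(np.corrcoef(m, t)[0, 1]) for m in res.means]
            sm[K] = int(np.argmax(corrs))
    return ScanResult(models=models, free_energies=fes, sensorimotor_state=sm,
                      template=np.asarray(template) if template is not None else None)
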