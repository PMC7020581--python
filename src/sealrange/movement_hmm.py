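"""Two-state hidden Markov model of travel rate.

Movement is summarised as the speed between consecutive fixes and modelled
as switching between two latent states: slow movement (area-restricted
search, ARS — tortuous search or resting inside a prey patch) and fast
movement (directed travel).  Emissions are gamma distributed per state —
the standard positive-support choice for speeds — and fitting is by
Baum–Welch EM with forward–backward smoothing restarted at every burst
(tracks are split into bursts wherever the inter-fix gap exceeds a
threshold, so haul-out gaps contribute no spurious speeds).

The quantity consumed downstream is p(ARS): the smoothed posterior
probability of the slow state at each fix.  High p(ARS) marks apparent
foraging; low p(ARS) marks travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma

from .track_io import Track

__all__ = [
    "StepSeries",
    "HMMFit",
    "DegenerateDataError",
    "compute_speeds",
    "fit_hmm2",
    "posterior_pars",
    "viterbi_states",
]


class DegenerateDataError(ValueError):
    """The speed data cannot identify two emission distributions."""


@dataclass
class StepSeries:
    """Per-fix speeds grouped into bursts of contiguous sampling.

    ``speeds[i]`` is the speed (km/h) from fix ``fix_index[i]-1`` to fix
    ``fix_index[i]``; a new ``burst`` id starts wherever the gap between
    consecutive fixes exceeded the gap threshold.
    """

    speeds: np.ndarray
    burst: np.ndarray
    fix_index: np.ndarray

    def __len__(self) -> int:
        return len(self.speeds)

    def burst_slices(self) -> list[slice]:
        out = []
        if len(self.speeds) == 0:
            return out
        ids = self.burst
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append(slice(start, i))
                start = i
        return out


@dataclass
class HMMFit:
    """Fitted 2-state gamma HMM; state 0 is the slow state by convention."""

    shapes: np.ndarray          # gamma shape per state, > 0
    rates: np.ndarray           # gamma rate per state, > 0
    transition: np.ndarray      # 2x2, rows sum to 1
    initial: np.ndarray         # length 2, sums to 1
    log_likelihood: float
    converged: bool
    n_iter: int
    history: list = field(default_factory=list, repr=False)

    @property
    def state_means(self) -> np.ndarray:
        return self.shapes / self.rates

    def to_dict(self) -> dict:
        return {
            "states": ["slow (ARS)", "fast (travel)"],
            "gamma_shape": [float(v) for v in self.shapes],
            "gamma_rate": [float(v) for v in self.rates],
            "state_mean_kmh": [float(v) for v in self.state_means],
            "transition": [[float(v) for v in row] for row in self.transition],
            "initial": [float(v) for v in self.initial],
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


# ---------------------------------------------------------------------------
# speeds


def compute_speeds(track: Track, gap_threshold_h: float = 2.0) -> StepSeries:
    """Speeds between consecutive projected fixes, split into bursts.

    A burst breaks wherever the time gap exceeds ``gap_threshold_h`` hours
    (default 2 h, i.e. eight missed 15-min fixes — typical of GPS
    suspension during haul-out).  Bursts of fewer than 2 fixes contribute
    no speeds.
    """
    if not track.is_projected:
        raise ValueError("track must be projected before computing speeds")
    fx = track.fixes
    if len(fx) < 2:
        return StepSeries(np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int))
    x = fx["x"].to_numpy(dtype=float) / 1000.0
    y = fx["y"].to_numpy(dtype=float) / 1000.0
    t = fx["timestamp"].astype("int64").to_numpy() / 3.6e12
    dt = np.diff(t)
    d = np.hypot(np.diff(x), np.diff(y))
    ok = (dt > 0) & (dt <= gap_threshold_h)
    speeds = d[ok] / dt[ok]
    fix_index = np.arange(1, len(fx))[ok]
    # a new burst wherever the retained steps are not consecutive fixes
    burst = np.zeros(len(fix_index), dtype=int)
    if len(fix_index) > 1:
        burst[1:] = np.cumsum(np.diff(fix_index) != 1)
    return StepSeries(speeds=speeds, burst=burst, fix_index=fix_index)


# ---------------------------------------------------------------------------
# gamma weighted MLE (M-step)


def _gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted ML gamma (shape, rate) via Newton on the shape equation."""
    wsum = float(np.sum(w))
    mean = float(np.sum(w * x) / wsum)
    meanlog = float(np.sum(w * np.log(x)) / wsum)
    s = np.log(mean) - meanlog  # >= 0 by Jensen
    s = max(s, 1e-12)
    k = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)  # standard initialiser
    for _ in range(50):
        f = np.log(k) - digamma(k) - s
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    k = float(np.clip(k, 1e-6, 1e6))
    return k, k / mean


def _gamma_logpdf(x: np.ndarray, shape: float, rate: float) -> np.ndarray:
    return shape * np.log(rate) + (shape - 1) * np.log(x) - rate * x - gammaln(shape)


# ---------------------------------------------------------------------------
# forward-backward


@numba.njit(cache=True)
def _forward_backward_kernel(b: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward on pre-shifted emission densities.

    Returns (gamma, xi_sum, log_scale_sum): smoothed state posteriors
    (T, S), summed pairwise transition posteriors (S, S) and the sum of
    log scaling factors.
    """
    T, S = b.shape
    alpha = np.empty((T, S))
    scale = np.empty(T)
    tot = 0.0
    for s in range(S):
        alpha[0, s] = pi[s] * b[0, s]
        tot += alpha[0, s]
    scale[0] = tot
    for s in range(S):
        alpha[0, s] /= tot
    for t in range(1, T):
        tot = 0.0
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += alpha[t - 1, r] * A[r, s]
            alpha[t, s] = acc * b[t, s]
            tot += alpha[t, s]
        scale[t] = tot
        for s in range(S):
            alpha[t, s] /= tot
    beta = np.empty((T, S))
    for s in range(S):
        beta[T - 1, s] = 1.0
    for t in range(T - 2, -1, -1):
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += A[s, r] * b[t + 1, r] * beta[t + 1, r]
            beta[t, s] = acc / scale[t + 1]
    gamma = np.empty((T, S))
    for t in range(T):
        tot = 0.0
        for s in range(S):
            gamma[t, s] = alpha[t, s] * beta[t, s]
            tot += gamma[t, s]
        for s in range(S):
            gamma[t, s] /= tot
    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        tot = 0.0
        for r in range(S):
            for s in range(S):
                tot += alpha[t, r] * A[r, s] * b[t + 1, s] * beta[t + 1, s]
        for r in range(S):
            for s in range(S):
                xi_sum[r, s] += alpha[t, r] * A[r, s] * b[t + 1, s] * beta[t + 1, s] / tot
    log_scale = 0.0
    for t in range(T):
        log_scale += np.log(scale[t])
    return gamma, xi_sum, log_scale


def _forward_backward(logb: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward for one burst.

    Returns (gamma, xi_sum, loglik): smoothed state posteriors (T, 2),
    summed pairwise transition posteriors (2, 2) and the log-likelihood.
    """
    shift = logb.max(axis=1)
    b = np.exp(logb - shift[:, None])
    gamma, xi_sum, log_scale = _forward_backward_kernel(
        np.ascontiguousarray(b), np.ascontiguousarray(A), np.ascontiguousarray(pi)
    )
    # add back the per-row max shift applied for numerical stability
    return gamma, xi_sum, float(log_scale + shift.sum())


def _prepare_speeds(speeds: np.ndarray) -> np.ndarray:
    """Nudge zero speeds to half the smallest positive speed (gamma support)."""
    x = np.asarray(speeds, dtype=float).copy()
    pos = x[x > 0]
    if len(pos) == 0:
        raise DegenerateDataError("all speeds are zero")
    x[x <= 0] = pos.min() / 2.0
    return x


def _init_means(x: np.ndarray, seed: int | None) -> np.ndarray:
    """2-means (Lloyd) on speeds, initialised at the 25th/75th percentiles."""
    centers = np.percentile(x, [25, 75]).astype(float)
    if centers[0] == centers[1]:
        centers[1] = centers[0] * 1.5 + 1e-6
    for _ in range(100):
        assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == j].mean() if np.any(assign == j) else centers[j] for j in (0, 1)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def fit_hmm2(
    series: StepSeries,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> HMMFit:
    """Fit the 2-state gamma HMM to a speed series by Baum–Welch EM.

    The forward pass restarts at each burst.  The log-likelihood is
    non-decreasing over iterations (up to numerical noise); convergence is
    declared when it improves by less than ``tol``.  States are reordered
    slow-first after fitting, so label switching cannot leak out.
    """
    if len(series) < 50:
        raise ValueError(f"need >= 50 speed observations, got {len(series)}")
    x = _prepare_speeds(series.speeds)
    if np.ptp(x) < 1e-12:
        raise DegenerateDataError("all speeds identical; two states unidentifiable")

    means = _init_means(x, seed)
    cv2 = max(np.var(x) / np.mean(x) ** 2, 0.05)
    shapes = np.full(2, 1.0 / cv2)
    rates = shapes / means
    A = np.array([[0.9, 0.1], [0.1, 0.9]])
    pi = np.array([0.5, 0.5])
    slices = series.burst_slices()

    ll_prev = -np.inf
    converged = False
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        logb = np.column_stack([_gamma_logpdf(x, shapes[s], rates[s]) for s in (0, 1)])
        post = np.empty((len(x), 2))
        xi_tot = np.zeros((2, 2))
        pi_acc = np.zeros(2)
        ll = 0.0
        for sl in slices:
            g, xi, l = _forward_backward(logb[sl], A, pi)
            post[sl] = g
            xi_tot += xi
            pi_acc += g[0]
            ll += l
        history.append(ll)
        # M-step
        A = xi_tot / xi_tot.sum(axis=1, keepdims=True)
        pi = pi_acc / pi_acc.sum()
        for s in (0, 1):
            shapes[s], rates[s] = _gamma_mle(x, np.maximum(post[:, s], 1e-300))
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

    # slow state first
    order = np.argsort(shapes / rates)
    fit = HMMFit(
        shapes=shapes[order],
        rates=rates[order],
        transition=A[np.ix_(order, order)],
        initial=pi[order],
        log_likelihood=history[-1],
        converged=converged,
        n_iter=it,
        history=history,
    )
    return fit


def posterior_pars(fit: HMMFit, series: StepSeries, accept_unconverged: bool = False) -> np.ndarray:
    """Smoothed posterior probability of the slow (ARS) state per step.

    Returns an array aligned with ``series.speeds``; p(slow) + p(fast) = 1
    at every step.
    """
    if not fit.converged and not accept_unconverged:
        raise ValueError("fit did not converge; pass accept_unconverged=True to proceed")
    x = _prepare_speeds(series.speeds)
    if len(x) == 0:
        return np.empty(0)
    logb = np.column_stack([_gamma_logpdf(x, fit.shapes[s], fit.rates[s]) for s in (0, 1)])
    out = np.empty(len(x))
    for sl in series.burst_slices():
        g, _, _ = _forward_backward(logb[sl], fit.transition, fit.initial)
        out[sl] = g[:, 0]
    return out


def viterbi_states(fit: HMMFit, series: StepSeries) -> np.ndarray:
    """Most likely state path (0 = slow, 1 = fast) per step, per burst."""
    x = _prepare_speeds(series.speeds)
    logb = np.column_stack([_gamma_logpdf(x, fit.shapes[s], fit.rates[s]) for s in (0, 1)])
    logA = np.log(fit.transition)
    logpi = np.log(fit.initial)
    out = np.empty(len(x), dtype=int)
    for sl in series.burst_slices():
        lb = logb[sl]
        T = lb.shape[0]
        delta = np.empty((T, 2))
        back = np.zeros((T, 2), dtype=int)
        delta[0] = logpi + lb[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            back[t] = cand.argmax(axis=0)
            delta[t] = cand.max(axis=0) + lb[t]
        path = np.empty(T, dtype=int)
        path[-1] = delta[-1].argmax()
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        out[sl] = path
    return out


def attach_pars(track: Track, series: StepSeries, pars: np.ndarray) -> Track:
    """Write p(ARS) back onto the fix table as a ``pars`` column.

    Steps carry the speed *into* each fix; the first fix of each burst has
    no step and inherits the first step's value within its burst.  Fixes
    outside any burst get NaN.
    """
    out = track.copy()
    col = np.full(len(out.fixes), np.nan)
    col[series.fix_index] = pars
    # backfill the fix that starts each burst
    for sl in series.burst_slices():
        first_fix = series.fix_index[sl.start] - 1
        if first_fix >= 0 and np.isnan(col[first_fix]):
            col[first_fix] = pars[sl.start]
    out.fixes["pars"] = col
    return out
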