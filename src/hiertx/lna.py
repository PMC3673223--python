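"""Linear-noise-approximation likelihood for single-cell onset curves.

Under the LNA the joint law of (mRNA, protein) is Gaussian: the mean obeys
the deterministic rate equations and the covariance the Lyapunov ODE

    dphi/dt   = A·phi + b(t)
    dSigma/dt = A·Sigma + Sigma·Aᵀ + D(t)

with A = [[-delta_M, 0], [alpha, -delta_P]], b(t) = (c·tau(t), 0) and
D = diag(c·tau + delta_M·m_M, alpha·m_M + delta_P·m_P).  Observations
y = kappa·P + eps are linear-Gaussian, so the likelihood of a whole time
series is computed exactly (within the LNA) by a Kalman-style sequential
filter: propagate moments between observation times, condition on each
signal, and accumulate the log predictive densities *including their full
normalization constants* — series of different lengths must remain
comparable when summed across cells.

The mean has a closed form per phase (constant-coefficient affine system on
either side of the transcription switch); the covariance is integrated by
fixed-substep RK4 against that mean.  By default D is evaluated along the
unconditional (deterministic) mean, which makes the sequential filter
reproduce the dense joint Gaussian of the linear SDE exactly; setting
``noise_mean="filtered"`` evaluates D along the filtered mean restarted
after each update (a closely-agreeing variant retained for comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .kinetics import CellKinetics, CellTimeSeries

__all__ = [
    "MomentState",
    "propagate_moments",
    "observe_update",
    "loglik_cell",
    "loglik_arrays",
    "loglik_dataset",
    "DEFAULT_SUBSTEPS",
]

DEFAULT_SUBSTEPS = 20
_EIG_TOL = 1e-10  # relative negative-eigenvalue clip, per covariance trace


@dataclass
class MomentState:
    """LNA moments of (mRNA, protein) at one instant.

    ``mean`` is the filtered (conditional) mean; ``ref_mean`` is the
    unconditional deterministic mean along which the process noise D is
    evaluated in the default variant.  ``cov`` is symmetric PSD up to a
    small numerical tolerance.
    """

    t: float
    mean: np.ndarray
    cov: np.ndarray
    ref_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if self.ref_mean is None:
            self.ref_mean = self.mean.copy()
        else:
            self.ref_mean = np.asarray(self.ref_mean, dtype=float).reshape(2)
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@njit(cache=True)
def _mean_at(mM0, mP0, u, alpha, dM, dP, h):
    """Closed-form affine-system mean at offset h from (mM0, mP0).

    Handles the degenerate zero-rate limits so pure birth/death special
    cases evaluate exactly.
    """
    tiny = 1e-12
    if dM > tiny:
        A0 = u / dM
        B0 = mM0 - A0
        edM = math.exp(-dM * h)
        mM = A0 + B0 * edM
        if dP > tiny:
            edP = math.exp(-dP * h)
            if abs(dP - dM) > 1e-9 * (dP + dM):
                f = (edM - edP) / (dP - dM)
            else:
                f = h * edM
            mP = mP0 * edP + alpha * A0 / dP * (1.0 - edP) + alpha * B0 * f
        else:
            intM = A0 * h + B0 * (1.0 - edM) / dM
            mP = mP0 + alpha * intM
    else:
        mM = mM0 + u * h
        if dP > tiny:
            edP = math.exp(-dP * h)
            # ∫_0^h s·e^{-dP(h-s)} ds = h/dP − (1−e^{-dP h})/dP²
            int_s = h / dP - (1.0 - edP) / (dP * dP)
            mP = mP0 * edP + alpha * (mM0 * (1.0 - edP) / dP + u * int_s)
        else:
            mP = mP0 + alpha * (mM0 * h + 0.5 * u * h * h)
    return mM, mP


@njit(cache=True)
def _cov_rhs(S11, S12, S22, mMr, mPr, u, alpha, dM, dP):
    d1 = -2.0 * dM * S11 + (u + dM * mMr)
    d2 = alpha * S11 - (dM + dP) * S12
    d3 = 2.0 * alpha * S12 - 2.0 * dP * S22 + (alpha * mMr + dP * mPr)
    return d1, d2, d3


@njit(cache=True)
def _prop_segment(mM, mP, refM, refP, S11, S12, S22,
                  h_total, u, alpha, dM, dP, n_sub):
    """Propagate moments across one constant-tau segment of length h_total.

    Filtered mean and reference (noise) mean advance by the exact closed
    form; the covariance by RK4 with ``n_sub`` fixed substeps, D evaluated
    along the reference mean.
    """
    if h_total <= 0.0:
        return mM, mP, refM, refP, S11, S12, S22
    # keep RK4 well inside its stability/accuracy region for stiff spans:
    # the fastest covariance eigenrate is 2·max(dM, dP)
    n_min = int(h_total * 2.0 * max(dM, dP) / 0.5) + 1
    if n_min > n_sub:
        n_sub = n_min
    dt = h_total / n_sub
    refM0, refP0 = refM, refP
    for i in range(n_sub):
        h0 = dt * i
        mA, pA = _mean_at(refM0, refP0, u, alpha, dM, dP, h0)
        mB, pB = _mean_at(refM0, refP0, u, alpha, dM, dP, h0 + 0.5 * dt)
        mC, pC = _mean_at(refM0, refP0, u, alpha, dM, dP, h0 + dt)
        k1a, k1b, k1c = _cov_rhs(S11, S12, S22, mA, pA, u, alpha, dM, dP)
        k2a, k2b, k2c = _cov_rhs(S11 + 0.5 * dt * k1a, S12 + 0.5 * dt * k1b,
                                 S22 + 0.5 * dt * k1c, mB, pB, u, alpha, dM, dP)
        k3a, k3b, k3c = _cov_rhs(S11 + 0.5 * dt * k2a, S12 + 0.5 * dt * k2b,
                                 S22 + 0.5 * dt * k2c, mB, pB, u, alpha, dM, dP)
        k4a, k4b, k4c = _cov_rhs(S11 + dt * k3a, S12 + dt * k3b,
                                 S22 + dt * k3c, mC, pC, u, alpha, dM, dP)
        S11 += dt / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        S12 += dt / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        S22 += dt / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
    mM, mP = _mean_at(mM, mP, u, alpha, dM, dP, h_total)
    refM, refP = _mean_at(refM0, refP0, u, alpha, dM, dP, h_total)
    return mM, mP, refM, refP, S11, S12, S22


@njit(cache=True)
def _prop_interval(mM, mP, refM, refP, S11, S12, S22,
                   t0, t1, s, tau_off, tau_on, c, alpha, dM, dP, n_sub):
    """Propagate from t0 to t1, splitting at the transcription switch s."""
    if t0 < s < t1:
        mM, mP, refM, refP, S11, S12, S22 = _prop_segment(
            mM, mP, refM, refP, S11, S12, S22,
            s - t0, c * tau_off, alpha, dM, dP, n_sub)
        mM, mP, refM, refP, S11, S12, S22 = _prop_segment(
            mM, mP, refM, refP, S11, S12, S22,
            t1 - s, c * tau_on, alpha, dM, dP, n_sub)
    else:
        u = c * tau_on if t0 >= s else c * tau_off
        mM, mP, refM, refP, S11, S12, S22 = _prop_segment(
            mM, mP, refM, refP, S11, S12, S22,
            t1 - t0, u, alpha, dM, dP, n_sub)
    return mM, mP, refM, refP, S11, S12, S22


@njit(cache=True)
def _psd_guard(S11, S12, S22):
    """Clip a tiny negative eigenvalue; flag a genuinely indefinite matrix.

    Returns (S11, S12, S22, ok): ok=False when the minimum eigenvalue is
    below -1e-10·max(trace, 1), which the caller treats as a numerical
    failure rather than silently repairing.
    """
    tr = S11 + S22
    disc = math.sqrt((S11 - S22) ** 2 + 4.0 * S12 * S12)
    emin = 0.5 * (tr - disc)
    if emin >= 0.0:
        return S11, S12, S22, True
    if emin < -_EIG_TOL * max(tr, 1.0):
        return S11, S12, S22, False
    # project: Sigma -= emin * v vᵀ with v the unit eigenvector of emin
    if abs(S12) > 0.0:
        vx = emin - S22
        vy = S12
        nrm = math.sqrt(vx * vx + vy * vy)
        vx /= nrm
        vy /= nrm
    elif S11 <= S22:
        vx, vy = 1.0, 0.0
    else:
        vx, vy = 0.0, 1.0
    S11 -= emin * vx * vx
    S12 -= emin * vx * vy
    S22 -= emin * vy * vy
    return S11, S12, S22, True


@njit(cache=True)
def _loglik_kernel(times, signals, tau_off, tau_on, s, alpha, dM, dP,
                   c, kappa, sig2, n_sub, filtered_noise):
    """Sequential-filter log-likelihood of one cell; NaN signals failure."""
    mM = 0.0
    mP = 0.0
    refM = 0.0
    refP = 0.0
    S11 = 0.0
    S12 = 0.0
    S22 = 0.0
    t_prev = 0.0
    ll = 0.0
    for i in range(times.shape[0]):
        t = times[i]
        if t > t_prev:
            mM, mP, refM, refP, S11, S12, S22 = _prop_interval(
                mM, mP, refM, refP, S11, S12, S22,
                t_prev, t, s, tau_off, tau_on, c, alpha, dM, dP, n_sub)
        S11, S12, S22, ok = _psd_guard(S11, S12, S22)
        if not ok:
            return np.nan
        S = kappa * kappa * S22 + sig2
        if S <= 0.0:
            return np.nan
        resid = signals[i] - kappa * mP
        ll += -0.5 * math.log(2.0 * math.pi * S) - 0.5 * resid * resid / S
        g1 = kappa * S12 / S
        g2 = kappa * S22 / S
        mM += g1 * resid
        mP += g2 * resid
        c12 = kappa * S12
        c22 = kappa * S22
        S11 -= c12 * c12 / S
        S12 -= c12 * c22 / S
        S22 -= c22 * c22 / S
        if filtered_noise:
            refM = mM
            refP = mP
        t_prev = t
    return ll


def _unpack(k: CellKinetics):
    tr = k.transcription
    return (tr.tau_off, tr.tau_on, tr.switch_time, k.alpha, k.delta_M,
            k.delta_P, k.copy_number, k.kappa, k.sigma_eps2)


def propagate_moments(
    state: MomentState,
    t1: float,
    k: CellKinetics,
    n_substeps: int = DEFAULT_SUBSTEPS,
    noise_mean: str = "deterministic",
) -> MomentState:
    """Propagate LNA moments from ``state.t`` to ``t1 > state.t``.

    Integration is split at the transcription switch when it lies inside
    the interval.  ``noise_mean`` selects the mean along which the process
    noise D is evaluated ("deterministic": the unconditional ``ref_mean``;
    "filtered": the conditional mean).
    """
    if not t1 > state.t:
        raise ValueError(f"t1 must exceed state.t ({t1} <= {state.t})")
    tau_off, tau_on, s, alpha, dM, dP, c, _, _ = _unpack(k)
    ref = state.mean if noise_mean == "filtered" else state.ref_mean
    mM, mP, refM, refP, S11, S12, S22 = _prop_interval(
        state.mean[0], state.mean[1], ref[0], ref[1],
        state.cov[0, 0], state.cov[0, 1], state.cov[1, 1],
        state.t, t1, s, tau_off, tau_on, c, alpha, dM, dP, n_substeps)
    if not (math.isfinite(S11) and math.isfinite(S22) and math.isfinite(mM)):
        raise FloatingPointError("moment propagation produced non-finite values")
    return MomentState(
        t=t1,
        mean=np.array([mM, mP]),
        cov=np.array([[S11, S12], [S12, S22]]),
        ref_mean=np.array([refM, refP]),
    )


def observe_update(
    state: MomentState, y: float, kappa: float, sigma_eps2: float
) -> tuple[MomentState, float]:
    """Condition the moments on one observation ``y = kappa·P + eps``.

    Returns the updated state and the log predictive density increment
    ``log N(y | kappa·m_P, kappa²·Sigma_PP + sigma_eps2)`` with its full
    normalization constant.
    """
    if not sigma_eps2 > 0:
        raise ValueError("sigma_eps2 must be > 0 for an observation update")
    S11, S12, S22, ok = _psd_guard(
        state.cov[0, 0], state.cov[0, 1], state.cov[1, 1])
    if not ok:
        raise FloatingPointError("covariance is indefinite beyond tolerance")
    S = kappa * kappa * S22 + sigma_eps2
    if S <= 0:
        raise FloatingPointError("non-positive predictive variance")
    resid = y - kappa * state.mean[1]
    inc = -0.5 * math.log(2.0 * math.pi * S) - 0.5 * resid * resid / S
    gain = np.array([kappa * S12, kappa * S22]) / S
    mean = state.mean + gain * resid
    cvec = np.array([kappa * S12, kappa * S22])
    cov = np.array([[S11, S12], [S12, S22]]) - np.outer(cvec, cvec) / S
    return MomentState(t=state.t, mean=mean, cov=cov, ref_mean=state.ref_mean), inc


def loglik_arrays(
    times: np.ndarray,
    signals: np.ndarray,
    k: CellKinetics,
    n_substeps: int = DEFAULT_SUBSTEPS,
    noise_mean: str = "deterministic",
) -> float:
    """Log-likelihood from raw time/signal arrays (empty arrays give 0.0)."""
    times = np.ascontiguousarray(times, dtype=np.float64)
    signals = np.ascontiguousarray(signals, dtype=np.float64)
    if times.shape != signals.shape:
        raise ValueError("times and signals must have matching shapes")
    ll = _loglik_kernel(
        times, signals, *_unpack(k), int(n_substeps),
        noise_mean == "filtered")
    if math.isnan(ll):
        raise FloatingPointError("likelihood evaluation failed (degenerate covariance)")
    return float(ll)


def loglik_cell(
    ts: CellTimeSeries,
    k: CellKinetics,
    n_substeps: int = DEFAULT_SUBSTEPS,
    noise_mean: str = "deterministic",
) -> float:
    """LNA log-likelihood of one cell's onset curve.

    The filter starts from M(0)=P(0)=0 with zero covariance at transfection
    (t=0) and alternates moment propagation with observation updates over
    the whole series.
    """
    try:
        return loglik_arrays(ts.times, ts.signals, k, n_substeps, noise_mean)
    except FloatingPointError as exc:
        raise FloatingPointError(f"cell {ts.cell_id!r}: {exc}") from exc


def loglik_dataset(
    dataset: list[CellTimeSeries],
    params: dict,
    n_substeps: int = DEFAULT_SUBSTEPS,
    noise_mean: str = "deterministic",
) -> np.ndarray:
    """Per-cell log-likelihood vector; ``params`` maps cell_id → CellKinetics.

    Cells are conditionally independent given their parameters, so the sum
    of this vector is the joint log-likelihood.
    """
    missing = [ts.cell_id for ts in dataset if ts.cell_id not in params]
    if missing:
        raise KeyError(f"no parameters for cells: {missing}")
    return np.array(
        [loglik_cell(ts, params[ts.cell_id], n_substeps, noise_mean) for ts in dataset]
    )
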