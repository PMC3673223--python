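"""Exact stochastic simulation and the synthetic population benchmark.

Single cells are simulated with the Gillespie algorithm over four reactions
— mRNA birth at rate ``c·tau(t)``, mRNA death at ``delta_M·M``, protein
birth at ``alpha·M``, protein death at ``delta_P·P`` — starting from
M = P = 0 at transfection (t = 0).  The single off→on step in ``tau`` is
handled exactly: when a proposed event would cross the switch time the
waiting time is re-drawn from the switch with on-phase propensities, which
is valid because the rate is piecewise constant (memorylessness).

The population generator draws per-cell kinetics from the hierarchical
benchmark design: lognormal per-copy transcription and translation rates
(parameterized by mean and Fano factor, with Fano = 1 for the on-rates:
variance equal to the mean), inverse-gamma measurement error variance,
zero-truncated integer Poisson copy number, and uniform switch times.
Degradation rates and the fluorescence constant are generator constants,
assumed known during inference.  Three construct groups A/B/C carry
on-rate means in ratio 1:2:5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit

from .kinetics import CellKinetics, CellTimeSeries, ChangepointTranscription

__all__ = [
    "PopulationSpec",
    "Benchmark",
    "lognormal_params_from_mean_fano",
    "sample_population",
    "simulate_ssa",
    "gillespie_cell",
    "sample_trajectory",
    "measure",
    "make_benchmark",
]


def _default_obs_times() -> np.ndarray:
    return np.arange(0.0, 51.0, 1.0)


@dataclass
class PopulationSpec:
    """Design of a synthetic benchmark population.

    Defaults are the package's benchmark conditions: 15 cells per construct
    group, 51 hourly observations, on-rate means 2/4/10 (ratios 1:2:5) with
    Fano factor 1, mean copy number 3, and signal levels in the hundreds to
    thousands so mRNA ≥ 5 and protein ≥ 100 molecules (the regime where the
    LNA likelihood is accurate).  Time unit: hours; signal units arbitrary.
    """

    n_cells_per_group: dict = field(default_factory=lambda: {"A": 15, "B": 15, "C": 15})
    group_tau_on_means: dict = field(default_factory=lambda: {"A": 2.0, "B": 4.0, "C": 10.0})
    fano: float = 1.0
    tau_off_mean: float = 0.2
    tau_off_fano: float = 0.05
    alpha_mean: float = 2.0
    alpha_fano: float = 0.5
    copy_lambda: float = 3.0
    meas_var_shape: float = 3.0
    meas_var_scale: float = 1800.0
    switch_window: tuple = (5.0, 20.0)
    obs_times: np.ndarray = field(default_factory=_default_obs_times)
    delta_M: float = 0.2
    delta_P: float = 0.05
    kappa: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        for name in ("fano", "tau_off_mean", "tau_off_fano", "alpha_mean",
                     "alpha_fano", "copy_lambda", "meas_var_shape",
                     "meas_var_scale", "delta_M", "delta_P", "kappa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for g, m in self.group_tau_on_means.items():
            if not m > 0:
                raise ValueError(f"group_tau_on_means[{g!r}] must be > 0")
        if set(self.n_cells_per_group) != set(self.group_tau_on_means):
            raise ValueError("group labels of sizes and means must match")
        lo, hi = self.switch_window
        t = self.obs_times
        if not (t[0] <= lo < hi <= t[-1]):
            raise ValueError("switch_window must lie within the observation span")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["obs_times"] = self.obs_times.tolist()
        d["switch_window"] = list(self.switch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        if "switch_window" in d:
            d["switch_window"] = tuple(d["switch_window"])
        return cls(**d)


def lognormal_params_from_mean_fano(mean: float, fano: float) -> tuple[float, float]:
    """(mu, sigma) of the normal underlying a lognormal with given mean and Fano.

    Solves exp(mu + sigma²/2) = mean and variance = fano·mean, giving
    sigma² = ln(1 + fano/mean) and mu = ln(mean) − sigma²/2.
    """
    if not (mean > 0 and fano > 0):
        raise ValueError("mean and fano must be > 0")
    sigma2 = math.log1p(fano / mean)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _trunc_poisson_int(lam: float, rng: np.random.Generator, max_tries: int = 10000) -> int:
    """Zero-truncated integer Poisson draw by rejection (resample until > 0)."""
    for _ in range(max_tries):
        c = int(rng.poisson(lam))
        if c > 0:
            return c
    raise RuntimeError(
        f"zero-truncated Poisson rejection exceeded {max_tries} tries at lambda={lam}"
    )


def sample_population(
    spec: PopulationSpec, rng: np.random.Generator
) -> tuple[list[CellKinetics], list[str]]:
    """Draw per-cell kinetics for every cell of the population design."""
    mu_off, sd_off = lognormal_params_from_mean_fano(spec.tau_off_mean, spec.tau_off_fano)
    mu_a, sd_a = lognormal_params_from_mean_fano(spec.alpha_mean, spec.alpha_fano)
    lo, hi = spec.switch_window
    kinetics: list[CellKinetics] = []
    groups: list[str] = []
    for g in sorted(spec.n_cells_per_group):
        mu_on, sd_on = lognormal_params_from_mean_fano(spec.group_tau_on_means[g], spec.fano)
        for _ in range(spec.n_cells_per_group[g]):
            tau_on = float(rng.lognormal(mu_on, sd_on))
            tau_off = float(rng.lognormal(mu_off, sd_off))
            alpha = float(rng.lognormal(mu_a, sd_a))
            # inverse-gamma(shape, scale) = scale / Gamma(shape, 1)
            sig2 = spec.meas_var_scale / float(rng.gamma(spec.meas_var_shape, 1.0))
            c = _trunc_poisson_int(spec.copy_lambda, rng)
            s = float(rng.uniform(lo, hi))
            kinetics.append(
                CellKinetics(
                    transcription=ChangepointTranscription(tau_off, tau_on, s),
                    alpha=alpha,
                    delta_M=spec.delta_M,
                    delta_P=spec.delta_P,
                    copy_number=float(c),
                    kappa=spec.kappa,
                    sigma_eps2=sig2,
                )
            )
            groups.append(g)
    return kinetics, groups


@njit(cache=True)
def _ssa_kernel(tau_off, tau_on, s, alpha, dM, dP, c, t_end, seed, max_events):
    np.random.seed(seed)
    times = np.empty(max_events)
    Ms = np.empty(max_events, np.int64)
    Ps = np.empty(max_events, np.int64)
    t = 0.0
    M = 0
    P = 0
    times[0] = 0.0
    Ms[0] = 0
    Ps[0] = 0
    n = 1
    while True:
        tau = tau_on if t >= s else tau_off
        a1 = c * tau
        a2 = dM * M
        a3 = alpha * M
        a4 = dP * P
        atot = a1 + a2 + a3 + a4
        if atot <= 0.0:
            if t < s:
                t = s  # nothing can fire in the off-phase; jump to the switch
                continue
            break
        dt = -math.log(np.random.random()) / atot
        if t < s and t + dt >= s:
            # the proposed event crosses the switch: restart the exponential
            # clock at s with on-phase propensities (exact for piecewise-
            # constant rates by memorylessness)
            t = s
            continue
        if t + dt > t_end:
            break
        t += dt
        r = np.random.random() * atot
        if r < a1:
            M += 1
        elif r < a1 + a2:
            M -= 1
        elif r < a1 + a2 + a3:
            P += 1
        else:
            P -= 1
        if n >= max_events:
            return times, Ms, Ps, -1
        times[n] = t
        Ms[n] = M
        Ps[n] = P
        n += 1
    return times, Ms, Ps, n


def simulate_ssa(
    tau_off: float,
    tau_on: float,
    switch_time: float,
    alpha: float,
    delta_M: float,
    delta_P: float,
    copy_number: float,
    t_end: float,
    seed: int,
    max_events: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact SSA trajectory from raw rate constants (rates may be zero here).

    Returns event times and the integer (M, P) state after each event,
    including the initial (0, 0, 0) record.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    times, Ms, Ps, n = _ssa_kernel(
        float(tau_off), float(tau_on), float(switch_time), float(alpha),
        float(delta_M), float(delta_P), float(copy_number), float(t_end),
        int(seed) % (2**31), int(max_events))
    if n < 0:
        raise RuntimeError(f"trajectory exceeded the event cap ({max_events})")
    return times[:n].copy(), Ms[:n].copy(), Ps[:n].copy()


def gillespie_cell(
    k: CellKinetics, t_end: float, rng: np.random.Generator,
    max_events: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact SSA trajectory of one cell (integer copy number required)."""
    c = k.copy_number
    if abs(c - round(c)) > 1e-9:
        raise ValueError(f"simulation requires an integer copy number, got {c}")
    tr = k.transcription
    seed = int(rng.integers(2**31))
    return simulate_ssa(tr.tau_off, tr.tau_on, tr.switch_time, k.alpha,
                        k.delta_M, k.delta_P, round(c), t_end, seed, max_events)


def sample_trajectory(
    obs_times: np.ndarray, event_times: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Sample a right-continuous piecewise-constant trajectory at obs_times."""
    idx = np.searchsorted(event_times, obs_times, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("observation before the first event record")
    return np.asarray(values)[idx]


def measure(
    obs_times: np.ndarray,
    protein: np.ndarray,
    kappa: float,
    sigma_eps2: float,
    rng: np.random.Generator,
    cell_id: str = "cell",
    group: str = "-",
) -> CellTimeSeries:
    """Apply the measurement equation y = kappa·P + eps to a sampled trajectory."""
    if sigma_eps2 < 0:
        raise ValueError("sigma_eps2 must be >= 0")
    noise = rng.normal(0.0, math.sqrt(sigma_eps2), size=len(obs_times)) \
        if sigma_eps2 > 0 else np.zeros(len(obs_times))
    signals = kappa * np.asarray(protein, dtype=float) + noise
    return CellTimeSeries(cell_id=cell_id, group=group,
                          times=np.asarray(obs_times, dtype=float), signals=signals)


@dataclass
class Benchmark:
    """A simulated dataset with its retained ground truth."""

    dataset: list
    truth: pd.DataFrame
    spec: PopulationSpec
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ts in self.dataset:
            rows.append(pd.DataFrame({
                "cell_id": ts.cell_id, "group": ts.group,
                "time": ts.times, "signal": ts.signals,
            }))
        return pd.concat(rows, ignore_index=True)


def make_benchmark(spec: PopulationSpec | None = None, seed: int = 0) -> Benchmark:
    """Generate the three-group A/B/C validation dataset with ground truth.

    Per-cell kinetics are drawn from the population design, each cell is
    simulated exactly by SSA, sampled on the observation grid and observed
    through the measurement equation.  The returned truth table keeps every
    per-cell parameter for recovery tests.  Deterministic given ``seed``.
    """
    if spec is None:
        spec = PopulationSpec()
    rng = np.random.default_rng(seed if spec.seed is None else spec.seed)
    kinetics, groups = sample_population(spec, rng)
    counts: dict = {}
    dataset = []
    rows = []
    t_end = float(spec.obs_times[-1]) + 1e-9
    for k, g in zip(kinetics, groups):
        counts[g] = counts.get(g, 0) + 1
        cell_id = f"{g}{counts[g]:02d}"
        ev_t, _, ev_P = gillespie_cell(k, t_end, rng)
        P_obs = sample_trajectory(spec.obs_times, ev_t, ev_P)
        ts = measure(spec.obs_times, P_obs, spec.kappa, k.sigma_eps2, rng,
                     cell_id=cell_id, group=g)
        dataset.append(ts)
        tr = k.transcription
        rows.append({
            "cell_id": cell_id, "group": g,
            "tau_off": tr.tau_off, "tau_on": tr.tau_on,
            "switch_time": tr.switch_time, "alpha": k.alpha,
            "copy_number": k.copy_number, "sigma_eps2": k.sigma_eps2,
            "delta_M": k.delta_M, "delta_P": k.delta_P, "kappa": k.kappa,
        })
    return Benchmark(dataset=dataset, truth=pd.DataFrame(rows), spec=spec,
                     seed=int(seed if spec.seed is None else spec.seed))
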