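"""Kinetic model of reporter gene expression in a single transfected cell.

The cell carries ``c`` plasmid copies of a reporter construct.  Each copy
transcribes mRNA at a per-copy rate ``tau(t)`` that switches once, at time
``s``, from a basal off-phase level to an active on-phase level.  mRNA is
translated into fluorescent protein and both species degrade linearly:

    dM = (c*tau(t) - delta_M*M) dt + sqrt(c*tau(t) + delta_M*M) dW_1
    dP = (alpha*M  - delta_P*P) dt + sqrt(alpha*M  + delta_P*P) dW_2

with the diffusion terms arising from the central-limit treatment of the
underlying birth/death events (molecule-number semantics).  Fluorescence is
observed as ``y = kappa*P + eps`` with additive Gaussian measurement error.

Only the product ``c*tau`` enters the dynamics, which is the identifiability
degeneracy the hierarchical layer resolves up to a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChangepointTranscription",
    "CellKinetics",
    "CellTimeSeries",
    "transcription_rate_at",
    "drift",
    "diffusion_variances",
]


def _require_positive_finite(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ChangepointTranscription:
    """Per-copy transcription rate with a single off→on changepoint.

    Parameters
    ----------
    tau_off : float
        Basal per-copy transcription rate before the switch
        (molecules · time⁻¹ · copy⁻¹, > 0).
    tau_on : float
        Active per-copy transcription rate from the switch onwards (> 0).
    switch_time : float
        Time ``s`` of the single off→on transition (≥ 0).  The boundary
        instant belongs to the on-phase.

    Notes
    -----
    Phases are labelled by time order, not magnitude: ``tau_on < tau_off`` is
    permitted and simply describes a downward step.
    """

    tau_off: float
    tau_on: float
    switch_time: float

    def __post_init__(self) -> None:
        _require_positive_finite("tau_off", self.tau_off)
        _require_positive_finite("tau_on", self.tau_on)
        if not (math.isfinite(self.switch_time) and self.switch_time >= 0):
            raise ValueError(
                f"switch_time must be finite and >= 0, got {self.switch_time!r}"
            )

    def rate_at(self, t: float) -> float:
        return transcription_rate_at(t, self)


@dataclass(frozen=True)
class CellKinetics:
    """All kinetic parameters of one cell.

    Parameters
    ----------
    transcription : ChangepointTranscription
        Per-copy transcription rate function.
    alpha : float
        Translation rate per mRNA molecule (time⁻¹).
    delta_M, delta_P : float
        First-order degradation rates of mRNA and protein (time⁻¹).
    copy_number : float
        Plasmid count ``c``.  A positive integer when simulating; treated as
        a positive real during inference (continuous relaxation).
    kappa : float
        Fluorescence per mole of protein (signal units per molecule).
    sigma_eps2 : float
        Variance of the additive Gaussian measurement error (signal units²).
    """

    transcription: ChangepointTranscription
    alpha: float
    delta_M: float
    delta_P: float
    copy_number: float
    kappa: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        for name in ("alpha", "delta_M", "delta_P", "copy_number", "kappa", "sigma_eps2"):
            _require_positive_finite(name, getattr(self, name))


@dataclass(frozen=True)
class CellTimeSeries:
    """One cell's observed fluorescence onset curve.

    ``times`` must be strictly increasing and the same length as ``signals``
    (length ≥ 2).  Signals may be negative after background subtraction.
    Different cells may have different lengths; the likelihood keeps its full
    normalization constants so values remain comparable across lengths.
    """

    cell_id: str
    group: str
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signals = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signals", signals)
        if times.ndim != 1 or signals.ndim != 1 or len(times) != len(signals):
            raise ValueError("times and signals must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError(f"cell {self.cell_id!r}: need at least 2 observations")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(signals)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite times or signals")
        if np.any(times < 0):
            raise ValueError(f"cell {self.cell_id!r}: negative observation times")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"cell {self.cell_id!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def transcription_rate_at(t: float, f: ChangepointTranscription) -> float:
    """Evaluate the per-copy transcription rate at time ``t``.

    Returns exactly ``tau_off`` for ``t < switch_time`` and exactly ``tau_on``
    for ``t >= switch_time`` (the boundary belongs to the on-phase).
    """
    if not math.isfinite(t):
        raise ValueError(f"time must be finite, got {t!r}")
    return f.tau_on if t >= f.switch_time else f.tau_off


def drift(state, t: float, k: CellKinetics) -> np.ndarray:
    """Deterministic drift ``(c·tau(t) − δ_M·M, α·M − δ_P·P)`` at ``state=(M, P)``."""
    M, P = float(state[0]), float(state[1])
    tau = transcription_rate_at(t, k.transcription)
    return np.array(
        [k.copy_number * tau - k.delta_M * M, k.alpha * M - k.delta_P * P]
    )


def diffusion_variances(state, t: float, k: CellKinetics) -> np.ndarray:
    """Instantaneous variance rates ``(c·tau(t) + δ_M·M, α·M + δ_P·P)``.

    Sums (not differences) of birth and death propensities, per the
    birth/death central-limit construction; always nonnegative on the
    admissible state space ``M, P ≥ 0``.
    """
    M, P = float(state[0]), float(state[1])
    if M < 0 or P < 0:
        raise ValueError(f"negative state ({M}, {P}) is outside the model support")
    tau = transcription_rate_at(t, k.transcription)
    return np.array(
        [k.copy_number * tau + k.delta_M * M, k.alpha * M + k.delta_P * P]
    )
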