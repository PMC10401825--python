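"""Single-compartment respiratory mechanics and decremental-PEEP selection.

Each breath is fitted with the unicompartmental equation of motion of the
respiratory system,

    P(t) = V(t)/C + R * V'(t) + P0,

by ordinary least squares over the full cycle, yielding compliance C
(ml/cmH2O), resistance R (cmH2O/l/s) and the end-expiratory pressure
offset P0 (cmH2O). During a decremental PEEP trial the selected PEEP is
the level with maximal fitted compliance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BreathWaveform",
    "PEEPTrialRecord",
    "EOMFit",
    "fit_equation_of_motion",
    "select_peep_max_compliance",
    "synthetic_breath",
]


@dataclass
class BreathWaveform:
    """Sampled airway pressure/flow/volume over one respiratory cycle.

    Units: time s, pressure cmH2O, flow l/s, volume l (above the
    end-expiratory volume of the breath).
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        if any(a.size != n for a in (self.pressure, self.flow, self.volume)):
            raise ValueError("waveform channels must have equal length")
        if n >= 2:
            integrated = np.concatenate(
                ([0.0], np.cumsum(np.diff(self.time) * 0.5 * (self.flow[1:] + self.flow[:-1])))
            )
            scale = max(np.abs(self.volume).max(), 1e-12)
            if np.max(np.abs(integrated - (self.volume - self.volume[0]))) > 0.02 * scale:
                raise ValueError("volume is inconsistent with integrated flow (> 2 %)")


@dataclass
class PEEPTrialRecord:
    """Fitted mechanics along a decremental PEEP sequence."""

    peep: np.ndarray  # cmH2O, strictly decreasing
    compliance: np.ndarray  # ml/cmH2O
    resistance: np.ndarray | None = None  # cmH2O/l/s

    def __post_init__(self) -> None:
        self.peep = np.asarray(self.peep, dtype=float)
        self.compliance = np.asarray(self.compliance, dtype=float)
        if self.peep.size != self.compliance.size:
            raise ValueError("PEEP and compliance must have equal length")
        if self.peep.size and np.any(np.diff(self.peep) >= 0):
            raise ValueError("decremental trial requires strictly decreasing PEEP")
        if np.any(self.compliance <= 0):
            raise ValueError("compliances must be positive")


@dataclass
class EOMFit:
    compliance_ml_per_cmH2O: float
    resistance_cmH2O_per_l_s: float
    p0_cmH2O: float
    residual_rms_cmH2O: float


def fit_equation_of_motion(breath: BreathWaveform) -> EOMFit:
    """Least-squares fit of P = V/C + R*V' + P0 over one cycle."""
    if breath.time.size < 10:
        raise ValueError("need at least 10 samples per breath")
    if np.ptp(breath.volume) == 0:
        raise ValueError("constant volume; elastance not identifiable")
    design = np.column_stack(
        [breath.volume, breath.flow, np.ones_like(breath.volume)]
    )
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (volume proportional to flow?)")
    coef, *_ = np.linalg.lstsq(design, breath.pressure, rcond=None)
    elastance, resistance, p0 = coef  # cmH2O/l, cmH2O/l/s, cmH2O
    if elastance <= 0:
        raise ValueError("non-positive fitted elastance")
    resid = breath.pressure - design @ coef
    return EOMFit(
        compliance_ml_per_cmH2O=1000.0 / elastance,
        resistance_cmH2O_per_l_s=float(resistance),
        p0_cmH2O=float(p0),
        residual_rms_cmH2O=float(np.sqrt(np.mean(resid**2))),
    )


def select_peep_max_compliance(trial: PEEPTrialRecord) -> float:
    """PEEP of maximal fitted compliance; ties go to the higher PEEP."""
    if trial.peep.size == 0:
        raise ValueError("empty PEEP trial record")
    best = trial.compliance.max()
    # ties broken toward the higher (more recruitment-preserving) PEEP
    return float(trial.peep[trial.compliance >= best - 1e-12].max())


def synthetic_breath(
    compliance_ml_per_cmH2O: float = 9.0,
    resistance_cmH2O_per_l_s: float = 14.0,
    peep_cmH2O: float = 7.0,
    tidal_volume_l: float = 0.17,
    resp_rate_per_min: float = 26.0,
    i_to_e: float = 0.5,
    fs_hz: float = 100.0,
    pressure_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BreathWaveform:
    """Volume-controlled breath (constant inspiratory flow, passive
    exponential expiration) obeying the single-compartment model.

    Defaults mirror a surfactant-depleted, moderately injured lung on
    volume-control ventilation: C = 9 ml/cmH2O, R = 14 cmH2O/l/s, tidal
    volume 0.17 l, rate 26/min, I:E = 1:2.
    """
    t_total = 60.0 / resp_rate_per_min
    t_insp = t_total * i_to_e / (1.0 + i_to_e)
    t = np.arange(0.0, t_total, 1.0 / fs_hz)
    c_l = compliance_ml_per_cmH2O / 1000.0  # l/cmH2O
    tau = resistance_cmH2O_per_l_s * c_l
    flow = np.where(t < t_insp, tidal_volume_l / t_insp, 0.0)
    exp_t = t[t >= t_insp] - t_insp
    flow[t >= t_insp] = -tidal_volume_l / tau * np.exp(-exp_t / tau)
    # volume by trapezoidal integration of flow, so the two channels are
    # discretely consistent at any sampling rate
    volume = np.concatenate(
        ([0.0], np.cumsum(np.diff(t) * 0.5 * (flow[1:] + flow[:-1])))
    )
    pressure = volume / c_l + resistance_cmH2O_per_l_s * flow + peep_cmH2O
    if pressure_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        pressure = pressure + rng.normal(0.0, pressure_noise_sd, size=t.size)
    return BreathWaveform(time=t, pressure=pressure, flow=flow, volume=volume)
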