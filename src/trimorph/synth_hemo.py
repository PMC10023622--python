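"""Synthetic mock-loop waveforms: pump flow, valve flows, Windkessel pressure.

The waveform model treats the ventricle as a pass-through at cycle scale:
per cycle, forward tricuspid volume minus tricuspid backflow equals forward
pulmonary volume minus pulmonary regurgitant volume.  Regurgitant lobes are
placed in systole (tricuspid) and early diastole (pulmonary).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InvalidParameterError

__all__ = [
    "WindkesselParams",
    "PumpSettings",
    "FlowWaveformSet",
    "OrificeModel",
    "make_pump_flow",
    "split_flows",
    "simulate_windkessel",
    "steady_backflow",
    "calibrate_eroa",
    "add_noise",
    "make_flow_set",
]

MMHG_TO_PA = 133.322387415


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: characteristic resistance, compliance,
    adjustable peripheral resistance."""

    Rc: float = 0.029  # mmHg s / mL
    C: float = 16.5  # mL / mmHg
    Rp: float = 1.0  # mmHg s / mL, adjustable in [0.22, 1.18]

    def __post_init__(self):
        if min(self.Rc, self.C, self.Rp) <= 0:
            raise InvalidParameterError("Windkessel parameters must be positive")


@dataclass(frozen=True)
class PumpSettings:
    heart_rate: float = 60.0  # bpm
    stroke_volume: float = 70.0  # mL
    systolic_fraction: float = 0.35
    fs: float = 200.0  # Hz

    def __post_init__(self):
        if min(self.heart_rate, self.fs) <= 0 or self.stroke_volume < 0:
            raise InvalidParameterError("pump settings must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise InvalidParameterError("systolic_fraction must be in (0, 1)")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.fs * self.period))


@dataclass
class FlowWaveformSet:
    """Synchronized pressure/flow records at a fixed sampling rate.

    Sign conventions: ``q_pulm`` positive forward through the pulmonary
    valve; ``q_tv`` positive atrium -> ventricle, negative regurgitant.
    """

    t: np.ndarray  # s
    q_pulm: np.ndarray  # mL/s
    q_tv: np.ndarray  # mL/s
    pap: np.ndarray  # mmHg
    fs: float
    heart_rate: float
    n_cycles: int

    def __post_init__(self):
        lengths = {len(self.t), len(self.q_pulm), len(self.q_tv), len(self.pap)}
        if len(lengths) != 1:
            raise InvalidParameterError("waveform channels must have equal length")
        dt = np.diff(self.t)
        if dt.size and (np.abs(dt - 1.0 / self.fs) > 1e-9).any():
            raise InvalidParameterError("time base must be uniform at 1/fs")
        per_cycle = self.fs * 60.0 / self.heart_rate
        expected = int(round(self.n_cycles * per_cycle))
        # n_cycles counts the *complete* cycles; a trailing partial cycle
        # (acquisition stopped mid-beat) is tolerated and later discarded
        if not expected - 1 <= len(self.t) < expected + per_cycle:
            raise InvalidParameterError(
                "record length inconsistent with n_cycles * (60 / heart_rate)"
            )


@dataclass(frozen=True)
class OrificeModel:
    """Lumped regurgitant orifice for the steady backflow bench."""

    eroa: float  # mm^2
    cd: float = 0.7
    rho: float = 1000.0  # kg/m^3 (saline)

    def __post_init__(self):
        if self.eroa < 0:
            raise InvalidParameterError("eroa must be >= 0")
        if not 0.0 < self.cd <= 1.0:
            raise InvalidParameterError("cd must be in (0, 1]")
        if self.rho <= 0:
            raise InvalidParameterError("rho must be > 0")


# ---------------------------------------------------------------------------
# waveform construction
# ---------------------------------------------------------------------------


def _lobe(t_cycle: np.ndarray, start: float, width: float, volume: float) -> np.ndarray:
    """Half-sinusoid lobe on [start, start+width] with exact discrete volume.

    The lobe is normalized so its trapezoidal integral over the sampled grid
    equals ``volume`` (mL) exactly, which keeps the downstream integral
    contracts tight at any sampling rate.
    """
    shape = np.zeros_like(t_cycle)
    in_win = (t_cycle >= start) & (t_cycle <= start + width)
    shape[in_win] = np.sin(np.pi * (t_cycle[in_win] - start) / width)
    integral = np.trapezoid(shape, t_cycle)
    if integral <= 0:
        if volume != 0:
            raise InvalidParameterError("lobe window contains no samples")
        return shape
    return shape * (volume / integral)


def make_pump_flow(settings: PumpSettings, n_cycles: int = 1) -> np.ndarray:
    """Pump outflow (mL/s): half-sinusoid ejection over the systolic fraction
    of each cycle, per-cycle ejected volume equal to the stroke volume."""
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    n = settings.samples_per_cycle
    t_cycle = np.arange(n) / settings.fs
    cycle = _lobe(t_cycle, 0.0, settings.systolic_fraction * settings.period,
                  settings.stroke_volume)
    return np.tile(cycle, n_cycles)


def split_flows(
    pump_flow: np.ndarray,
    trf_target: float,
    prv_target: float,
    settings: PumpSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the pump stroke into pulmonary and tricuspid flow waveforms with
    prescribed regurgitation indexes.

    Per cycle: the tricuspid channel carries a systolic negative lobe of
    volume ``trf_target/100 * SV`` and a diastolic filling lobe; the
    pulmonary channel carries the complementary forward volume plus an
    early-diastolic negative lobe of volume ``prv_target``.
    """
    if not 0.0 <= trf_target < 100.0:
        raise InvalidParameterError("trf_target must be in [0, 100)")
    if prv_target < 0:
        raise InvalidParameterError("prv_target must be >= 0")
    n = settings.samples_per_cycle
    if len(pump_flow) % n:
        raise InvalidParameterError("pump flow length is not a whole number of cycles")
    n_cycles = len(pump_flow) // n
    t_cycle = np.arange(n) / settings.fs
    T = settings.period
    Ts = settings.systolic_fraction * T
    sv = settings.stroke_volume

    v_backflow = trf_target / 100.0 * sv
    v_forward_pulm = sv - v_backflow + prv_target
    v_forward_tv = v_forward_pulm - prv_target + v_backflow  # pass-through closure

    q_pulm = (
        _lobe(t_cycle, 0.0, Ts, v_forward_pulm)
        - _lobe(t_cycle, Ts, 0.15 * T, prv_target)
    )
    q_tv = (
        -_lobe(t_cycle, 0.0, Ts, v_backflow)
        + _lobe(t_cycle, Ts, T - Ts - 1.0 / settings.fs, v_forward_tv)
    )
    return np.tile(q_pulm, n_cycles), np.tile(q_tv, n_cycles)


# ---------------------------------------------------------------------------
# Windkessel
# ---------------------------------------------------------------------------


def simulate_windkessel(
    params: WindkesselParams,
    q_pulm: np.ndarray,
    p0: float = 0.0,
    fs: float = 200.0,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Pulmonary artery pressure (mmHg) from the three-element Windkessel.

    Integrates ``C dPc/dt = q - Pc/Rp`` with fixed-step RK4 (cubic
    interpolation of the sampled inflow at half steps) and returns
    ``pap = Rc q + Pc``.
    """
    q = np.asarray(q_pulm, dtype=float)
    if t is not None:
        dt_all = np.diff(t)
        if dt_all.size and np.ptp(dt_all) > 1e-9:
            raise InvalidParameterError("time base must be uniformly sampled")
        dt = float(dt_all[0]) if dt_all.size else 1.0 / fs
    else:
        dt = 1.0 / fs
    tt = np.arange(len(q)) * dt
    if len(q) >= 4:
        q_of_t = CubicSpline(tt, q)
    else:  # pragma: no cover - degenerate records
        q_of_t = lambda x: np.interp(x, tt, q)

    pc = np.empty(len(q))
    pc[0] = p0
    q_half = np.asarray(q_of_t(tt[:-1] + dt / 2), dtype=float)
    inv_rp_c = 1.0 / (params.Rp * params.C)
    inv_c = 1.0 / params.C

    for i in range(len(q) - 1):
        p = pc[i]
        k1 = q[i] * inv_c - p * inv_rp_c
        k2 = q_half[i] * inv_c - (p + dt / 2 * k1) * inv_rp_c
        k3 = q_half[i] * inv_c - (p + dt / 2 * k2) * inv_rp_c
        k4 = q[i + 1] * inv_c - (p + dt * k3) * inv_rp_c
        pc[i + 1] = p + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    return params.Rc * q + pc


# ---------------------------------------------------------------------------
# steady orifice backflow
# ---------------------------------------------------------------------------


def steady_backflow(model: OrificeModel, delta_p: float) -> float:
    """Orifice-law steady backflow (L/min): Q = cd * EROA * sqrt(2 dp / rho)."""
    if delta_p < 0:
        raise InvalidParameterError("delta_p must be >= 0")
    area_m2 = model.eroa * 1e-6
    v = np.sqrt(2.0 * delta_p * MMHG_TO_PA / model.rho)  # m/s
    return float(model.cd * area_m2 * v * 60_000.0)  # m^3/s -> L/min


def calibrate_eroa(
    target_lmin: float, delta_p: float, cd: float = 0.7, rho: float = 1000.0
) -> OrificeModel:
    """Orifice model whose steady backflow at ``delta_p`` equals the target."""
    if delta_p <= 0:
        raise InvalidParameterError("delta_p must be > 0 for calibration")
    if target_lmin < 0:
        raise InvalidParameterError("target backflow must be >= 0")
    v = np.sqrt(2.0 * delta_p * MMHG_TO_PA / rho)
    eroa = target_lmin / (cd * v * 60_000.0) / 1e-6
    return OrificeModel(eroa=float(eroa), cd=cd, rho=rho)


# ---------------------------------------------------------------------------
# noise and the composite generator
# ---------------------------------------------------------------------------


def add_noise(wf: FlowWaveformSet, snr_db: float, seed: int = 0) -> FlowWaveformSet:
    """Additive Gaussian noise at the requested per-channel SNR (dB).

    ``snr_db = inf`` returns the waveforms unchanged.  SNR is defined on
    signal power (mean square), per channel.
    """
    if not (np.isfinite(snr_db) or np.isposinf(snr_db)):
        raise InvalidParameterError("snr_db must be finite or +inf")
    if np.isposinf(snr_db):
        return replace(
            wf,
            t=wf.t.copy(),
            q_pulm=wf.q_pulm.copy(),
            q_tv=wf.q_tv.copy(),
            pap=wf.pap.copy(),
        )
    rng = np.random.default_rng(seed)
    out = {}
    for name in ("q_pulm", "q_tv", "pap"):
        x = getattr(wf, name)
        power = np.mean(x**2)
        sd = np.sqrt(power / 10.0 ** (snr_db / 10.0))
        out[name] = x + rng.normal(0.0, sd, size=x.shape)
    return replace(wf, t=wf.t.copy(), **out)


def make_flow_set(
    settings: PumpSettings = PumpSettings(),
    wk: WindkesselParams = WindkesselParams(),
    trf_target: float = 0.0,
    prv_target: float = 0.0,
    n_cycles: int = 10,
    snr_db: float = np.inf,
    seed: int = 0,
) -> FlowWaveformSet:
    """Compose pump -> flow split -> Windkessel -> noise into one record.

    The Windkessel state starts at its DC operating point (mean inflow times
    peripheral resistance) so the record is quasi-periodic from the first
    cycle.
    """
    pump = make_pump_flow(settings, n_cycles)
    q_pulm, q_tv = split_flows(pump, trf_target, prv_target, settings)
    p0 = float(np.mean(q_pulm) * wk.Rp)
    pap = simulate_windkessel(wk, q_pulm, p0=p0, fs=settings.fs)
    n = len(pump)
    wf = FlowWaveformSet(
        t=np.arange(n) / settings.fs,
        q_pulm=q_pulm,
        q_tv=q_tv,
        pap=pap,
        fs=settings.fs,
        heart_rate=settings.heart_rate,
        n_cycles=n_cycles,
    )
    return add_noise(wf, snr_db, seed=seed)
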