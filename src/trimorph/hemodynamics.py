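"""Fluid-dynamic indexes from waveform records.

All integrals are trapezoidal on the averaged cycle; cycle segmentation is
by the nominal pump period (the platform is paced, so no peak detection is
needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .synth_hemo import FlowWaveformSet

__all__ = [
    "AveragedCycle",
    "HemoIndexes",
    "SteadyBackflowReading",
    "ensemble_average",
    "compute_trf",
    "compute_co",
    "compute_prv",
    "compute_indexes",
    "measure_steady_backflow",
]


@dataclass
class AveragedCycle:
    """Pointwise mean of pap / q_pulm / q_tv over full cardiac cycles."""

    t: np.ndarray  # s, one cycle
    pap: np.ndarray
    q_pulm: np.ndarray
    q_tv: np.ndarray
    n_cycles_used: int
    fs: float


@dataclass
class HemoIndexes:
    TRF: float  # %
    CO: float  # L/min
    PRV: float  # mL

    def as_dict(self) -> dict[str, float]:
        return {"TRF": self.TRF, "CO": self.CO, "PRV": self.PRV}


@dataclass
class SteadyBackflowReading:
    value_lmin: float
    settled: bool


def ensemble_average(
    wf: FlowWaveformSet, heart_rate: float | None = None, n_cycles: int = 10
) -> AveragedCycle:
    """Average the record over ``n_cycles`` cycles of the nominal period.

    Cycles are segmented at fixed period from the record start; a partial
    trailing cycle is discarded.
    """
    hr = heart_rate if heart_rate is not None else wf.heart_rate
    n = int(round(wf.fs * 60.0 / hr))
    available = len(wf.t) // n
    if available < n_cycles:
        raise InvalidParameterError(
            f"record holds {available} full cycles, {n_cycles} requested"
        )
    def avg(x):
        return x[: n_cycles * n].reshape(n_cycles, n).mean(axis=0)

    return AveragedCycle(
        t=np.arange(n) / wf.fs,
        pap=avg(wf.pap),
        q_pulm=avg(wf.q_pulm),
        q_tv=avg(wf.q_tv),
        n_cycles_used=n_cycles,
        fs=wf.fs,
    )


def compute_trf(cycle: AveragedCycle, stroke_volume: float) -> float:
    """Tricuspid regurgitant fraction (%): backflow volume over stroke volume."""
    if stroke_volume <= 0:
        raise InvalidParameterError("stroke_volume must be > 0")
    backflow = np.trapezoid(np.clip(-cycle.q_tv, 0.0, None), cycle.t)
    return float(100.0 * backflow / stroke_volume)


def compute_co(cycle: AveragedCycle) -> float:
    """Cardiac output (L/min): mean pulmonary flow, mL/s -> L/min."""
    return float(np.mean(cycle.q_pulm) * 0.06)


def compute_prv(cycle: AveragedCycle) -> float:
    """Pulmonary regurgitant volume (mL): integral of retrograde pulmonary flow."""
    return float(np.trapezoid(np.clip(-cycle.q_pulm, 0.0, None), cycle.t))


def compute_indexes(cycle: AveragedCycle, stroke_volume: float) -> HemoIndexes:
    return HemoIndexes(
        TRF=compute_trf(cycle, stroke_volume),
        CO=compute_co(cycle),
        PRV=compute_prv(cycle),
    )


def measure_steady_backflow(
    record: np.ndarray,
    fs: float = 200.0,
    settle_fraction: float = 0.5,
) -> SteadyBackflowReading:
    """Steady-state backflow (L/min): mean of the trailing part of the record.

    The reading is flagged unsettled when the trailing-window linear trend
    exceeds 1%/s of the mean.
    """
    record = np.asarray(record, dtype=float)
    if record.size == 0:
        raise InvalidParameterError("record is empty")
    if not 0.0 < settle_fraction <= 1.0:
        raise InvalidParameterError("settle_fraction must be in (0, 1]")
    n_tail = max(int(np.ceil(record.size * settle_fraction)), 2)
    tail = record[-n_tail:]
    t = np.arange(tail.size) / fs
    value = float(tail.mean())
    slope = float(np.polyfit(t, tail, 1)[0]) if tail.size >= 2 else 0.0
    scale = abs(value) if value != 0 else 1.0
    settled = abs(slope) < 0.01 * scale
    return SteadyBackflowReading(value_lmin=value, settled=settled)
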