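"""Pressure-driven flow networks, flow programs and QC event detection.

A single pressure source feeding several eye models in parallel behaves
like an electrical network of conductances: the pressure is common to all
branches and the flow divides as Q_i = P / R_i. Flow-rate control, by
contrast, can only regulate one branch at a time, which mirrors the
physical constraint of the bench (one flow setpoint per controller).

The module also generates the diurnal ("circadian") aqueous-flow program —
a sinusoid between the nocturnal and morning secretion rates — and scans
pressure/flow telemetry for the two QC signatures of a failed run: a leak
(pressure collapses toward zero while flow is unchanged) and a blockage
(pressure spikes above its running baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import constants as c
from .errors import (
    AlignmentError,
    ConfigurationError,
    InvalidParameterError,
    ModeError,
)
from .telemetry_io import child_rng

log = logging.getLogger("pkeye.network")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class HydraulicBranch:
    """Lumped hydraulic resistance of one model plus its tubing."""

    label: str
    resistance: float  # mmHg per (µL/min)

    def __post_init__(self):
        if not self.resistance > 0:
            raise InvalidParameterError("resistance must be > 0")


@dataclass(frozen=True)
class FlowProgram:
    """A sinusoidal time-varying inflow waveform.

    ``phase_reference`` is the clock hour (0–24) at which the flow is
    maximal; t = 0 of any trace is taken as midnight.
    """

    baseline: float        # µL/min (midline)
    amplitude: float       # µL/min
    period: float          # s
    phase_reference: float = c.CIRCADIAN_DEFAULT_PEAK_HOUR  # clock hour of max
    sample_rate: float = c.DEFAULT_RECORDING_HZ             # Hz
    duration: float = c.SECONDS_PER_DAY                     # s

    def __post_init__(self):
        if self.baseline - self.amplitude < 0:
            raise InvalidParameterError("program flow would go negative")
        if not self.period > 0:
            raise InvalidParameterError("period must be > 0")
        if not self.sample_rate > 0:
            raise InvalidParameterError("sample_rate must be > 0")

    def flow_at(self, t) -> np.ndarray:
        """Instantaneous flow (µL/min) at time(s) ``t`` seconds."""
        t_max = self.phase_reference * 3600.0
        return self.baseline + self.amplitude * np.cos(
            2 * np.pi * (np.asarray(t, dtype=float) - t_max) / self.period
        )


@dataclass(frozen=True)
class QCEvent:
    """One detected anomaly in pressure/flow telemetry."""

    kind: Literal["leak", "blockage"]
    time: float                       # s, onset
    evidence: tuple[float, float]     # (pressure mmHg, flow µL/min) at onset


# ---------------------------------------------------------------------------
# Parallel network solve
# ---------------------------------------------------------------------------
def solve_parallel(
    source_pressure: float, branches: Sequence[HydraulicBranch]
) -> pd.Series:
    """Per-branch flows (µL/min) for a common source pressure (mmHg).

    Pressure is identical across parallel branches; each draws
    Q_i = P / R_i and the source supplies the sum.
    """
    if len(branches) == 0:
        raise ConfigurationError("need at least one branch")
    flows = {b.label: source_pressure / b.resistance for b in branches}
    return pd.Series(flows, name="flow_uL_min")


# ---------------------------------------------------------------------------
# Controller simulation
# ---------------------------------------------------------------------------
def simulate_controller(
    mode: Literal["pressure", "flow"],
    setpoint: float,
    branches: Sequence[HydraulicBranch],
    duration: float,
    sample_rate: float = c.DEFAULT_RECORDING_HZ,
    pressure_noise: float = 0.0,
    flow_noise: float = 0.0,
    time_constant: float = c.DEFAULT_CONTROLLER_TIME_CONSTANT_S,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate pressure- or flow-controlled operation.

    In pressure mode the source holds ``setpoint`` mmHg and every branch
    flows per :func:`solve_parallel`. In flow mode — admissible only for a
    single branch — the controller adjusts pressure with first-order
    settling (time constant ``time_constant`` s) until the branch flow
    equals the ``setpoint`` µL/min. Sensor noise is Gaussian per channel.

    Returns a wide DataFrame: ``time_s``, ``pressure_mmHg`` and one
    ``flow_<label>`` column per branch (µL/min).
    """
    if len(branches) == 0:
        raise ConfigurationError("need at least one branch")
    if mode == "flow" and len(branches) != 1:
        raise ModeError(
            "flow control regulates a single branch; use pressure mode for "
            "parallel networks"
        )
    if mode not in ("pressure", "flow"):
        raise ModeError(f"unknown mode {mode!r}")
    if pressure_noise < 0 or flow_noise < 0:
        raise InvalidParameterError("noise sigma must be >= 0")

    rng = child_rng(seed, "network.controller")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    if mode == "pressure":
        p_true = np.full(n, float(setpoint))
    else:
        p_target = setpoint * branches[0].resistance
        p_true = p_target * (1.0 - np.exp(-t / time_constant))

    out = {"time_s": t}
    out["pressure_mmHg"] = p_true + (
        rng.normal(0.0, pressure_noise, n) if pressure_noise else 0.0
    )
    for b in branches:
        q_true = p_true / b.resistance
        out[f"flow_{b.label}"] = q_true + (
            rng.normal(0.0, flow_noise, n) if flow_noise else 0.0
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Circadian program
# ---------------------------------------------------------------------------
def circadian_program(
    min_flow: float = c.AQUEOUS_FLOW_RANGE_ULMIN[0],
    max_flow: float = c.AQUEOUS_FLOW_RANGE_ULMIN[1],
    period: float = c.SECONDS_PER_DAY,
    phase_reference: float = c.CIRCADIAN_DEFAULT_PEAK_HOUR,
    sample_rate: float = c.DEFAULT_RECORDING_HZ,
    duration: float = c.SECONDS_PER_DAY,
) -> pd.DataFrame:
    """Sampled diurnal flow program (sinusoid between min and max flow).

    Mimics aqueous-humour secretion: maximal in the morning, minimal at
    night. Returns ``time_s`` / ``flow_uL_min`` columns; over an integer
    number of periods the mean equals (min+max)/2.
    """
    if not (max_flow > min_flow > 0) and not (max_flow == min_flow > 0):
        raise InvalidParameterError("need max_flow >= min_flow > 0")
    n = int(round(duration * sample_rate))
    if n < 1:
        raise InvalidParameterError("duration shorter than one sample")
    prog = FlowProgram(
        baseline=(min_flow + max_flow) / 2,
        amplitude=(max_flow - min_flow) / 2,
        period=period,
        phase_reference=phase_reference,
        sample_rate=sample_rate,
        duration=duration,
    )
    t = np.arange(n) / sample_rate
    return pd.DataFrame({"time_s": t, "flow_uL_min": prog.flow_at(t)})


# ---------------------------------------------------------------------------
# QC detection
# ---------------------------------------------------------------------------
def _as_series(trace) -> pd.Series:
    if isinstance(trace, pd.Series):
        return trace
    df = pd.DataFrame(trace)
    if "time_s" in df.columns:
        value_col = [col for col in df.columns if col != "time_s"][0]
        return pd.Series(df[value_col].to_numpy(), index=df["time_s"].to_numpy())
    raise AlignmentError("trace must be a Series indexed by time or have time_s")


def detect_qc_events(
    pressure_trace,
    flow_trace,
    leak_pressure_threshold: float = c.DEFAULT_LEAK_PRESSURE_THRESHOLD_MMHG,
    spike_factor: float = c.DEFAULT_SPIKE_FACTOR,
    window: float = c.DEFAULT_QC_WINDOW_S,
) -> list[QCEvent]:
    """Scan aligned pressure (mmHg) and flow (µL/min) traces for anomalies.

    Leak: the windowed median pressure falls below
    ``leak_pressure_threshold`` while the windowed median flow stays within
    ±20 % of its running baseline (an open circuit loses pressure but the
    controller keeps pushing flow). Blockage: the windowed median pressure
    exceeds ``spike_factor`` times its running baseline. Running baselines
    are expanding medians lagged by one window so an emerging fault does
    not contaminate its own reference. Contiguous flagged samples collapse
    into a single event stamped at onset.
    """
    p = _as_series(pressure_trace)
    q = _as_series(flow_trace)
    if len(p) != len(q) or not np.array_equal(p.index, q.index):
        raise AlignmentError("pressure and flow traces must share timestamps")
    times = np.asarray(p.index, dtype=float)
    if len(times) < 2:
        return []
    dt = float(np.median(np.diff(times)))
    w = max(1, int(round(window / dt)))

    p_med = p.reset_index(drop=True).rolling(w, center=True, min_periods=1).median()
    q_med = q.reset_index(drop=True).rolling(w, center=True, min_periods=1).median()
    p_base = p.reset_index(drop=True).expanding(min_periods=w).median().shift(w)
    q_base = q.reset_index(drop=True).expanding(min_periods=w).median().shift(w)

    valid = p_base.notna() & q_base.notna()
    leak = valid & (p_med < leak_pressure_threshold) & (
        (q_med - q_base).abs() <= 0.2 * q_base.abs()
    )
    block = valid & (p_med > spike_factor * p_base)

    events: list[QCEvent] = []
    for kind, mask in (("leak", leak), ("blockage", block)):
        arr = mask.to_numpy()
        onsets = np.flatnonzero(arr & ~np.roll(arr, 1))
        if arr.any() and arr[0]:
            onsets = np.union1d(onsets, [0])
        for i in onsets:
            ev = QCEvent(kind, float(times[i]), (float(p.iloc[i]), float(q.iloc[i])))
            log.info("QC %s event at t=%.1f s (p=%.3g mmHg, q=%.3g uL/min)",
                     kind, ev.time, *ev.evidence)
            events.append(ev)
    events.sort(key=lambda e: e.time)
    return events
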