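"""Shared telemetry infrastructure: typed frames, CSV/JSON round trips,
run-configuration validation, seeded RNG streams and the fixture registry.

Telemetry uses a single long-format CSV dialect — ``time_s,channel,value,
unit`` — so channels recorded at different rates coexist in one file. Values
are rendered with 9 significant digits; any value already representable at
that precision round-trips bit-exactly.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import constants as c
from .errors import SchemaError, ValidationError

log = logging.getLogger("pkeye")

#: Units accepted in telemetry files.
REGISTERED_UNITS: frozenset[str] = frozenset(
    {"mmHg", "uL_min", "degC", "m_s2", "deg", "deg_s", "ug_mL"}
)

TELEMETRY_COLUMNS = ("time_s", "channel", "value", "unit")


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TelemetryFrame:
    """One timestamped sample of one named channel."""

    time: float
    channel: str
    value: float
    unit: str

    def __post_init__(self):
        if self.unit not in REGISTERED_UNITS:
            raise SchemaError(f"unknown unit {self.unit!r}")
        if self.time < 0:
            raise SchemaError(f"negative time {self.time}")


def frames_to_dataframe(frames: Iterable[TelemetryFrame]) -> pd.DataFrame:
    rows = [(f.time, f.channel, f.value, f.unit) for f in frames]
    return pd.DataFrame(rows, columns=TELEMETRY_COLUMNS)


def dataframe_to_frames(df: pd.DataFrame) -> list[TelemetryFrame]:
    return [
        TelemetryFrame(float(t), str(ch), float(v), str(u))
        for t, ch, v, u in df.itertuples(index=False)
    ]


def write_telemetry(frames, path) -> None:
    """Write frames (iterable of TelemetryFrame or a long-format DataFrame)
    to CSV, rendering values at 9 significant digits."""
    if isinstance(frames, pd.DataFrame):
        df = frames[list(TELEMETRY_COLUMNS)]
        bad = set(df["unit"]) - REGISTERED_UNITS
        if bad:
            raise SchemaError(f"unknown unit(s) {sorted(bad)}")
    else:
        df = frames_to_dataframe(frames)
    out = df.copy()
    out["time_s"] = [f"{t:.9g}" for t in out["time_s"]]
    out["value"] = [f"{v:.9g}" for v in out["value"]]
    out.to_csv(path, index=False)


def read_telemetry(path) -> pd.DataFrame:
    """Read a telemetry CSV, validating units row by row.

    Raises
    ------
    SchemaError
        If a row carries an unregistered unit (message names the line).
    """
    df = pd.read_csv(path, dtype={"channel": str, "unit": str},
                     float_precision="round_trip")
    missing = set(TELEMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s) {sorted(missing)}")
    for i, unit in enumerate(df["unit"]):
        if unit not in REGISTERED_UNITS:
            # +2: header line plus 1-based indexing
            raise SchemaError(f"unknown unit {unit!r} at line {i + 2}")
    df["time_s"] = df["time_s"].astype(float)
    df["value"] = df["value"].astype(float)
    return df


def wide_to_frames(df: pd.DataFrame, units: Mapping[str, str]) -> pd.DataFrame:
    """Convert a wide table (time_s + one column per channel) to the long
    telemetry dialect. ``units`` maps channel column -> registered unit."""
    records = []
    for ch, unit in units.items():
        if unit not in REGISTERED_UNITS:
            raise SchemaError(f"unknown unit {unit!r}")
        records.append(
            pd.DataFrame(
                {
                    "time_s": df["time_s"],
                    "channel": ch,
                    "value": df[ch],
                    "unit": unit,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Seeded RNG streams
# ---------------------------------------------------------------------------
def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-module RNG stream.

    Streams are derived from (run seed, stable text label), so adding a new
    consumer never perturbs the draws of an existing one.
    """
    entropy = [int(seed) & 0x7FFFFFFF, *label.encode("utf-8")]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------
@dataclass
class RunConfig:
    """Top-level run configuration with platform throughput validation."""

    seed: int = 0
    recording_rate_hz: float = c.DEFAULT_RECORDING_HZ
    controllers: int = 1
    sensors_per_controller: int = 1
    sections: dict = field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self):
        if self.recording_rate_hz <= 0:
            raise ValidationError("recording rate must be positive")
        if self.recording_rate_hz > c.MAX_RECORDING_HZ:
            raise ValidationError(
                f"recording rate {self.recording_rate_hz} Hz exceeds the "
                f"{c.MAX_RECORDING_HZ} Hz platform cap"
            )
        if not 1 <= self.controllers <= c.MAX_CONTROLLERS:
            raise ValidationError(
                f"controllers must be 1..{c.MAX_CONTROLLERS}"
            )
        if not 1 <= self.sensors_per_controller <= c.MAX_SENSORS_PER_CONTROLLER:
            raise ValidationError(
                f"sensors per controller must be 1..{c.MAX_SENSORS_PER_CONTROLLER}"
            )


def max_throughput(config: RunConfig) -> float:
    """Aggregate data points per second of a telemetry plan.

    Fully populated (50 Hz × 6 controllers × 6 sensors) this is 1800
    points/s, the acquisition chain's ceiling.
    """
    return (
        config.recording_rate_hz
        * config.controllers
        * config.sensors_per_controller
    )


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {
        k: data[k]
        for k in (
            "seed",
            "recording_rate_hz",
            "controllers",
            "sensors_per_controller",
            "output_dir",
        )
        if k in data
    }
    sections = {
        k: v
        for k, v in data.items()
        if k in ("membrane", "network", "pk", "motion", "probe")
    }
    return RunConfig(sections=sections, **known)


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------
def _load_pressure_flow_csv() -> pd.DataFrame:
    with resources.files("pkeye.data").joinpath(
        "pressure_flow_fixture.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _load_motion_presets() -> dict:
    with resources.files("pkeye.data").joinpath("motion_presets.json").open() as fh:
        return json.load(fh)


def fixture_registry() -> dict[str, pd.DataFrame]:
    """Named tables transcribing the platform's printed bench measurements.

    Keys
    ----
    ``pursing_12_14kDa``
        Flow through a 12–14 kDa membrane at 150 mmHg for the three clamp
        diameters (20/15/5 mm -> 0.66/0.54/0.05 µL/min).
    ``pursing_mwco_at_2uLmin``
        Pressure drop needed for ~2.0 µL/min through a 20 mm clamp for each
        MWCO (12–14 kDa -> 361 mmHg, 50 kDa -> 342, 300 kDa -> 7).
    ``pressure_flow_all``
        Union of the above in the fixture CSV schema.
    ``calibration_standards``
        Two-fold serial dilution standards, 3.90625–62.5 µg/mL.
    """
    table = _load_pressure_flow_csv()
    reg: dict[str, pd.DataFrame] = {}
    reg["pressure_flow_all"] = table
    reg["pursing_12_14kDa"] = table[
        table["experiment"] == "area_sweep_150mmHg"
    ].reset_index(drop=True)
    reg["pursing_mwco_at_2uLmin"] = table[
        table["experiment"] == "mwco_sweep_2uLmin"
    ].reset_index(drop=True)
    reg["calibration_standards"] = pd.DataFrame(
        {
            "concentration_ug_mL": list(c.DEFAULT_CALIBRATION_STANDARDS_UGML),
            "source": ["2-fold serial dilution of 250 ug/mL stock"] * 5,
        }
    )
    return reg


def get_fixture(name: str) -> pd.DataFrame:
    """Look up one fixture table by name (KeyError if unknown).

    Returned frames are copies; the registry itself is immutable.
    """
    return fixture_registry()[name].copy()
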