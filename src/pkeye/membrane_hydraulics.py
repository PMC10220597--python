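"""Porous-membrane pressure–flow hydraulics.

The pressure drop across a thin porous membrane is modelled per pore as the
sum of a Poiseuille channel term and a Sampson orifice term,

    Δp = 8 µ T Q / (π R⁴)  +  3 µ Q / R³ ,

with µ the shear viscosity of the fluid (Pa·s), T the membrane thickness
(m), R the pore radius (m) and Q the volumetric flow through one pore
(m³/s). The relation is linear in Q, so it inverts analytically; the total
flow through a clamped circular area is the per-pore flow times the number
of pores in that area.

The module also simulates the bench's stepped pressure-sweep protocol
(pressure raised and then lowered in a staircase while flow is recorded)
and fits an effective pore radius to measured pressure–flow pairs. Because
the membranes' microstructure (thickness, porosity, true pore radius) is
not independently known, the fitted radius is an *effective* parameter:
only orderings across membranes at a common assumed thickness/porosity are
physically meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import constants as c
from .errors import (
    ConfigurationError,
    FittingError,
    InvalidParameterError,
    MembraneRuptureError,
)
from .telemetry_io import child_rng


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FluidSpec:
    """A Newtonian working fluid."""

    name: str
    viscosity: float  # dynamic (shear) viscosity, Pa·s

    def __post_init__(self):
        if not self.viscosity > 0:
            raise InvalidParameterError("viscosity must be > 0")


#: Phosphate-buffered saline at bench temperature.
PBS = FluidSpec("PBS", c.PBS_VISCOSITY_PAS)
#: Simulated vitreous fluid (hyaluronate solution), mid-range viscosity.
SVF = FluidSpec("SVF", sum(c.SVF_VISCOSITY_RANGE_PAS) / 2)


@dataclass(frozen=True)
class MembraneSpec:
    """A dialysis membrane clamped over a circular flow area.

    ``burst_pressure`` (Pa) optionally models the loss of integrity seen at
    high applied pressure; when set, sweeps that exceed it raise
    :class:`MembraneRuptureError`. Default off.
    """

    mwco: str                 # molecular-weight cut-off label, kDa
    pore_radius: float        # single-pore radius, m
    thickness: float          # membrane thickness, m
    exposed_diameter: float   # clamped circular flow area diameter, m
    pore_density: float       # pores per unit area, 1/m²
    burst_pressure: float | None = None

    def __post_init__(self):
        if not self.pore_radius > 0:
            raise InvalidParameterError("pore_radius must be > 0")
        if self.thickness < 0:
            raise InvalidParameterError("thickness must be >= 0")
        if not self.exposed_diameter > 0:
            raise InvalidParameterError("exposed_diameter must be > 0")
        if not self.pore_density > 0:
            raise InvalidParameterError("pore_density must be > 0")
        if not self.pore_radius < self.exposed_diameter / 2:
            raise InvalidParameterError(
                "pore_radius must be smaller than the exposed radius"
            )

    @property
    def exposed_area(self) -> float:
        """Clamped flow area, m²."""
        return math.pi * (self.exposed_diameter / 2) ** 2

    @property
    def pore_count(self) -> int:
        return int(round(self.pore_density * self.exposed_area))


def membrane_from_mwco(
    mwco: str,
    exposed_diameter: float,
    thickness: float = c.DEFAULT_MEMBRANE_THICKNESS_M,
    pore_density: float = c.DEFAULT_PORE_DENSITY_PER_M2,
    burst_pressure: float | None = None,
) -> MembraneSpec:
    """Build a membrane from its MWCO label using the seed pore radii."""
    try:
        radius = c.DEFAULT_PORE_RADIUS_BY_MWCO_M[mwco]
    except KeyError as exc:
        raise ConfigurationError(
            f"no seed pore radius for MWCO {mwco!r}; "
            f"known: {sorted(c.DEFAULT_PORE_RADIUS_BY_MWCO_M)}"
        ) from exc
    return MembraneSpec(mwco, radius, thickness, exposed_diameter,
                        pore_density, burst_pressure)


@dataclass(frozen=True)
class PressureFlowPoint:
    """One measured (Δp, Q) operating point in bench units."""

    pressure_drop: float  # mmHg
    flow: float           # µL/min

    def __post_init__(self):
        if self.pressure_drop < 0 or self.flow < 0:
            raise InvalidParameterError(
                "pressure_drop and flow must be non-negative"
            )


# ---------------------------------------------------------------------------
# Forward model and inversion (SI)
# ---------------------------------------------------------------------------
def pore_resistance(fluid: FluidSpec, membrane: MembraneSpec) -> float:
    """Hydraulic resistance of one pore, Pa per (m³/s)."""
    r = membrane.pore_radius
    channel = 8.0 * fluid.viscosity * membrane.thickness / (math.pi * r**4)
    orifice = 3.0 * fluid.viscosity / r**3
    return channel + orifice


def pore_pressure_drop(
    fluid: FluidSpec, membrane: MembraneSpec, pore_flow: float
) -> float:
    """Pressure drop (Pa) across one pore carrying ``pore_flow`` m³/s."""
    if pore_flow < 0:
        raise InvalidParameterError("pore_flow must be >= 0")
    return pore_resistance(fluid, membrane) * pore_flow


def membrane_flow(
    fluid: FluidSpec, membrane: MembraneSpec, pressure_drop: float
) -> float:
    """Total flow (m³/s) through the clamped area at ``pressure_drop`` Pa."""
    if pressure_drop < 0:
        raise InvalidParameterError("pressure_drop must be >= 0")
    n = membrane.pore_count
    if n < 1:
        raise ConfigurationError(
            "exposed area contains no pores at this pore density"
        )
    return n * pressure_drop / pore_resistance(fluid, membrane)


def membrane_flow_ulmin(
    fluid: FluidSpec, membrane: MembraneSpec, pressure_drop_mmhg: float
) -> float:
    """Bench-unit convenience wrapper: mmHg in, µL/min out."""
    q = membrane_flow(fluid, membrane, pressure_drop_mmhg * c.MMHG_TO_PA)
    return q * c.M3S_TO_ULMIN


# ---------------------------------------------------------------------------
# Effective-pore-radius fitting
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PoreRadiusFit:
    """Result of an effective pore-radius fit."""

    pore_radius: float            # m
    residuals: pd.DataFrame       # per-point relative flow residuals
    sse: float                    # sum of squared relative errors


def fit_effective_pore_radius(
    points: Sequence[PressureFlowPoint],
    fluid: FluidSpec,
    thickness: float,
    exposed_diameter: float,
    pore_density: float = c.DEFAULT_PORE_DENSITY_PER_M2,
) -> PoreRadiusFit:
    """Fit the pore radius minimising squared *relative* flow error.

    The model flow at a given radius is ``Q_i = Δp_i · N / k(R)`` with
    ``k(R)`` the per-pore resistance, so the least-squares optimum over the
    relative errors ``(Q_model/Q_obs − 1)`` has a closed form in the pore
    conductance ``x = N/k(R)``; the radius is then recovered from the
    strictly monotone ``k(R)`` by bracketed root finding.
    """
    usable = [p for p in points if p.flow > 0]
    if not usable:
        raise FittingError("need at least one point with positive flow")

    # a_i = Δp_i / Q_i in SI; optimum of sum (a_i x - 1)^2 is x* = Σa/Σa².
    a = np.array(
        [p.pressure_drop * c.MMHG_TO_PA / (p.flow * c.ULMIN_TO_M3S)
         for p in usable]
    )
    x_star = a.sum() / (a**2).sum()   # total conductance, (m³/s)/Pa

    n_pores = int(round(pore_density * math.pi * (exposed_diameter / 2) ** 2))
    if n_pores < 1:
        raise FittingError("exposed area contains no pores")
    k_target = n_pores / x_star       # required per-pore resistance

    def k_of_r(r: float) -> float:
        return (8.0 * fluid.viscosity * thickness / (math.pi * r**4)
                + 3.0 * fluid.viscosity / r**3)

    # k(R) is strictly decreasing; bracket geometrically.
    lo, hi = 1e-12, exposed_diameter / 4
    if not (k_of_r(lo) > k_target > k_of_r(hi)):
        # widen the lower bracket if the membrane is extremely tight
        while k_of_r(lo) < k_target and lo > 1e-15:
            lo /= 10
        if not (k_of_r(lo) > k_target > k_of_r(hi)):
            raise FittingError("target conductance outside bracketable range")
    radius = brentq(lambda r: k_of_r(r) - k_target, lo, hi,
                    xtol=1e-18, rtol=1e-14)

    fitted = MembraneSpec("fitted", radius, thickness, exposed_diameter,
                          pore_density)
    rows = []
    for p in usable:
        q_model = membrane_flow_ulmin(fluid, fitted, p.pressure_drop)
        rows.append(
            {
                "pressure_mmHg": p.pressure_drop,
                "flow_obs_uL_min": p.flow,
                "flow_model_uL_min": q_model,
                "rel_residual": q_model / p.flow - 1.0,
            }
        )
    resid = pd.DataFrame(rows)
    sse = float((resid["rel_residual"] ** 2).sum())
    return PoreRadiusFit(radius, resid, sse)


def fit_fixture_radii(
    fixture: pd.DataFrame,
    fluid: FluidSpec = PBS,
    thickness: float = c.DEFAULT_MEMBRANE_THICKNESS_M,
    pore_density: float = c.DEFAULT_PORE_DENSITY_PER_M2,
) -> pd.DataFrame:
    """Fit one effective radius per membrane id in a fixture table."""
    out = []
    for mid, grp in fixture.groupby("membrane_id", sort=False):
        pts = [
            PressureFlowPoint(row.pressure_mmHg, row.flow_uL_min)
            for row in grp.itertuples()
        ]
        diameter = float(grp["exposed_diameter_mm"].iloc[0]) * 1e-3
        fit = fit_effective_pore_radius(pts, fluid, thickness, diameter,
                                        pore_density)
        out.append(
            {
                "membrane_id": mid,
                "mwco_kda": grp["mwco_kda"].iloc[0],
                "pore_radius_m": fit.pore_radius,
                "sse": fit.sse,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Stepped pressure sweep
# ---------------------------------------------------------------------------
def up_down_steps(
    start: float, stop: float, n_steps: int
) -> list[float]:
    """Ascending then descending staircase of pressures (Pa), mirror-symmetric."""
    up = list(np.linspace(start, stop, n_steps))
    return up + up[-2::-1]


def stepped_pressure_sweep(
    fluid: FluidSpec,
    membrane: MembraneSpec,
    pressure_steps: Sequence[float],
    hold_duration: float,
    sample_rate: float = c.DEFAULT_RECORDING_HZ,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the automated staircase protocol.

    Pressure (Pa) is held at each step for ``hold_duration`` seconds while
    flow is recorded at ``sample_rate`` Hz with Gaussian sensor noise of
    standard deviation ``noise_sigma`` (µL/min). The membrane model has no
    hysteresis, so descending steps re-trace the ascending branch.

    Returns a wide DataFrame with ``time_s``, ``step_index``,
    ``pressure_mmHg`` and ``flow_uL_min`` columns.
    """
    if len(pressure_steps) == 0:
        raise InvalidParameterError("pressure_steps must be non-empty")
    if hold_duration <= 0:
        raise InvalidParameterError("hold_duration must be > 0")
    if noise_sigma < 0:
        raise InvalidParameterError("noise sigma must be >= 0")
    rng = child_rng(seed, "membrane.sweep")

    n_per = max(1, int(round(hold_duration * sample_rate)))
    dt = 1.0 / sample_rate
    rows = []
    t = 0.0
    for idx, p in enumerate(pressure_steps):
        if membrane.burst_pressure is not None and p > membrane.burst_pressure:
            raise MembraneRuptureError(p, membrane.burst_pressure)
        q_true = membrane_flow(fluid, membrane, p) * c.M3S_TO_ULMIN
        noise = rng.normal(0.0, noise_sigma, n_per) if noise_sigma else np.zeros(n_per)
        for k in range(n_per):
            rows.append((t, idx, p * c.PA_TO_MMHG, q_true + noise[k]))
            t += dt
    return pd.DataFrame(
        rows, columns=["time_s", "step_index", "pressure_mmHg", "flow_uL_min"]
    )
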