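"""Lumped compartmental intraocular clearance model and half-life estimation.

The eye-model prototypes are abstracted as well-mixed compartments: a
posterior cavity (vitreous substitute, volume V_p) and an anterior cavity
(aqueous, volume V_a) separated by a dialysis ("hyaloid") membrane. Drug
crosses the membrane by convection — the fraction ``sieving`` of the
posterior-routed inflow carries drug with it — and by diffusion with a
permeability–area product PA_h (expressed in µL/min so it adds directly to
convective clearance). The anterior cavity washes out through the aqueous
outflow. The RCS prototype adds a second membrane at the back of the
posterior cavity (PA_rcs) whose permeate is swept to a reservoir by a
dedicated back flow. With masses M and concentrations C = M/V:

    dM_p/dt = −(s·Q_p + PA_h)·C_p + PA_h·C_a − PA_rcs·C_p
    dM_a/dt = +(s·Q_p + PA_h)·C_p − PA_h·C_a − Q_out·C_a

These dynamics are this package's formalisation of the physical prototypes
(the bench publications describe the geometry, not governing equations).
The system is linear, so terminal half-life equals ln 2 over the slowest
eigenvalue of the rate matrix; :func:`estimate_half_life` recovers it from
a sampled trace by log-linear regression, the standard terminal-phase
estimator in pharmacokinetics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import constants as c
from .errors import (
    ConfigurationError,
    InvalidParameterError,
    ModeError,
    StabilityError,
    UndefinedHalfLifeError,
    WindowError,
)
from .flow_network import FlowProgram

log = logging.getLogger("pkeye.pk")

Prototype = Literal[
    "first_generation", "posterior_inflow", "ciliary_inflow", "rcs",
    "intracameral",
]

#: Prototypes whose aqueous inflow enters the posterior cavity and crosses
#: the hyaloid membrane convectively.
_POSTERIOR_INFLOW = {"first_generation", "posterior_inflow"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EyeModelConfig:
    """Geometry, flows and membrane transfer parameters of one prototype."""

    prototype: Prototype = "first_generation"
    posterior_volume: float = c.DEFAULT_POSTERIOR_VOLUME_ML   # mL
    anterior_volume: float = c.DEFAULT_ANTERIOR_VOLUME_ML     # mL
    aqueous_inflow: float | FlowProgram = c.DEFAULT_AQUEOUS_FLOW_ULMIN  # µL/min
    hyaloid_transfer: float = c.DEFAULT_HYALOID_TRANSFER_ULMIN  # PA, µL/min
    hyaloid_sieving: float = c.DEFAULT_HYALOID_SIEVING          # 0..1
    rcs_transfer: float | None = None                           # PA, µL/min
    back_flow: float | None = None                              # µL/min

    def __post_init__(self):
        if self.posterior_volume <= 0 or self.anterior_volume <= 0:
            raise InvalidParameterError("compartment volumes must be > 0")
        if not 0.0 <= self.hyaloid_sieving <= 1.0:
            raise InvalidParameterError("sieving must be within [0, 1]")
        if self.hyaloid_transfer < 0:
            raise InvalidParameterError("hyaloid_transfer must be >= 0")
        if self.prototype == "rcs":
            if self.rcs_transfer is None:
                object.__setattr__(self, "rcs_transfer",
                                   c.DEFAULT_RCS_TRANSFER_ULMIN)
            if self.back_flow is None:
                object.__setattr__(self, "back_flow", c.DEFAULT_BACK_FLOW_ULMIN)
            if self.rcs_transfer < 0 or self.back_flow < 0:
                raise InvalidParameterError("RCS parameters must be >= 0")
        elif self.rcs_transfer is not None or self.back_flow is not None:
            raise ConfigurationError(
                "rcs_transfer/back_flow are only valid for the rcs prototype"
            )

    @property
    def inflow_site(self) -> str:
        return "posterior" if self.prototype in _POSTERIOR_INFLOW else "anterior"

    def inflow_at(self, t_min: float) -> float:
        """Aqueous inflow (µL/min) at time ``t_min`` minutes."""
        if isinstance(self.aqueous_inflow, FlowProgram):
            return float(self.aqueous_inflow.flow_at(t_min * 60.0))
        return float(self.aqueous_inflow)


@dataclass(frozen=True)
class DrugSpec:
    """An injected bolus and its probe response."""

    name: str
    dose_mass: float                       # µg
    injection_volume: float                # µL
    injection_site: Literal["posterior", "anterior"] = "posterior"
    probe_response: float = c.DEFAULT_PROBE_RESPONSE_FACTOR  # AUC per (µg/mL)

    def __post_init__(self):
        if self.dose_mass < 0:
            raise InvalidParameterError("dose_mass must be >= 0")
        if not self.injection_volume > 0:
            raise InvalidParameterError("injection_volume must be > 0")

    @classmethod
    def from_concentration(cls, name: str, concentration_mg_ml: float,
                           volume_ul: float, **kw) -> "DrugSpec":
        """Build from an injected concentration (mg/mL) and volume (µL)."""
        return cls(name, concentration_mg_ml * volume_ul, volume_ul, **kw)


@dataclass
class ClearanceResult:
    """Simulated clearance traces plus the terminal-phase fit."""

    traces: pd.DataFrame          # time_s, posterior/anterior µg/mL, outlets µg
    dose: float                   # µg
    half_life: float | None      # days
    fit_window: tuple[float, float] | None   # s
    fit_r2: float | None
    prototype: Prototype
    outlet_channel: str = "anterior_outlet_ug"
    diagnostics: dict = field(default_factory=dict)

    def mass_balance_error(self) -> float:
        """Max relative mass-balance violation over all output times."""
        df = self.traces
        remaining = (
            df["posterior_ug_mL"] * self.diagnostics["posterior_volume_mL"]
            + df["anterior_ug_mL"] * self.diagnostics["anterior_volume_mL"]
        )
        cleared = df["anterior_outlet_ug"] + df.get(
            "posterior_outlet_ug", 0.0
        )
        scale = self.dose if self.dose > 0 else 1.0
        return float(np.max(np.abs(remaining + cleared - self.dose)) / scale)

    def outlet_concentration(self) -> pd.DataFrame:
        """Concentration seen at the anterior outflow port (equals C_a)."""
        return self.traces[["time_s", "anterior_ug_mL"]].rename(
            columns={"anterior_ug_mL": "concentration_ug_mL"}
        )


# ---------------------------------------------------------------------------
# Rate matrix and closed forms
# ---------------------------------------------------------------------------
def rate_matrix(model: EyeModelConfig, inflow_ulmin: float | None = None
                ) -> np.ndarray:
    """First-order rate matrix (per minute) acting on masses [M_p, M_a]."""
    q = model.inflow_at(0.0) if inflow_ulmin is None else inflow_ulmin
    q_ml = q * 1e-3                   # µL/min -> mL/min
    pa_h = model.hyaloid_transfer * 1e-3
    pa_rcs = (model.rcs_transfer or 0.0) * 1e-3
    s = model.hyaloid_sieving
    q_p = q_ml if model.inflow_site == "posterior" else 0.0
    vp, va = model.posterior_volume, model.anterior_volume
    k_pa = (s * q_p + pa_h) / vp      # posterior -> anterior
    k_ap = pa_h / va                  # anterior -> posterior (back diffusion)
    k_rcs = pa_rcs / vp               # posterior -> RCS reservoir
    k_out = q_ml / va                 # anterior -> outflow
    return np.array(
        [[-(k_pa + k_rcs), k_ap],
         [k_pa, -(k_ap + k_out)]]
    )


def terminal_half_life(model: EyeModelConfig) -> float:
    """Terminal half-life (days) from the slowest eigenvalue."""
    eig = np.linalg.eigvals(rate_matrix(model))
    slow = -np.max(eig.real)
    if slow <= 0:
        raise UndefinedHalfLifeError("rate matrix is not dissipative")
    return math.log(2.0) / slow / (24 * 60)


def single_compartment_half_life(volume_ml: float, outflow_ulmin: float
                                 ) -> float:
    """Closed-form t½ (minutes) of one well-mixed compartment: ln2·V/Q."""
    return math.log(2.0) * volume_ml * 1e3 / outflow_ulmin


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------
def simulate_clearance(
    model: EyeModelConfig,
    drug: DrugSpec,
    duration: float,
    step: float = 60.0,
    fit_fraction: float = 0.5,
) -> ClearanceResult:
    """Simulate bolus clearance and fit the terminal half-life.

    Parameters
    ----------
    duration, step
        Simulation horizon and output grid spacing, seconds. The output
        step must resolve the fastest compartment time constant
        (``step <= tau_min / 10``); the adaptive integrator's internal
        steps are independent of the output grid.
    fit_fraction
        Fraction of the horizon (from the end) used for the terminal
        log-linear fit.

    The drug appears instantaneously, well mixed, in the injection-site
    compartment; the injected volume displaces an equal buffer volume so
    compartment volumes do not change.
    """
    if drug.injection_site == "posterior":
        cavity_ml = model.posterior_volume
    else:
        cavity_ml = model.anterior_volume
    if drug.injection_volume * 1e-3 >= cavity_ml:
        raise ConfigurationError(
            "injection volume must be smaller than the target cavity"
        )
    if duration <= 0 or step <= 0:
        raise InvalidParameterError("duration and step must be > 0")

    a_ref = rate_matrix(model)
    tau_min_minutes = 1.0 / np.max(-np.diag(a_ref))
    if step / 60.0 > tau_min_minutes / 10.0:
        raise StabilityError(
            f"output step {step:.3g} s exceeds tau_min/10 "
            f"({tau_min_minutes * 6:.3g} s)"
        )

    m0 = np.zeros(4)  # [M_p, M_a, out_anterior, out_rcs], µg
    m0[0 if drug.injection_site == "posterior" else 1] = drug.dose_mass

    time_varying = isinstance(model.aqueous_inflow, FlowProgram)

    def rhs(t_min, y):
        a = rate_matrix(model, model.inflow_at(t_min)) if time_varying else a_ref
        mp, ma = y[0], y[1]
        dmp = a[0, 0] * mp + a[0, 1] * ma
        dma = a[1, 0] * mp + a[1, 1] * ma
        q_ml = (model.inflow_at(t_min) if time_varying
                else model.inflow_at(0.0)) * 1e-3
        d_out_ant = q_ml / model.anterior_volume * ma
        d_out_rcs = (model.rcs_transfer or 0.0) * 1e-3 / model.posterior_volume * mp
        return [dmp, dma, d_out_ant, d_out_rcs]

    t_grid_min = np.arange(0.0, duration + step / 2, step) / 60.0
    sol = solve_ivp(
        rhs, (0.0, t_grid_min[-1]), m0, method="LSODA",
        t_eval=t_grid_min, rtol=1e-9,
        atol=max(1e-9 * drug.dose_mass, 1e-15),
    )
    if not sol.success:
        raise StabilityError(f"integration failed: {sol.message}")

    mp, ma, out_a, out_r = sol.y
    traces = pd.DataFrame(
        {
            "time_s": sol.t * 60.0,
            "posterior_ug_mL": np.maximum(mp, 0.0) / model.posterior_volume,
            "anterior_ug_mL": np.maximum(ma, 0.0) / model.anterior_volume,
            "anterior_outlet_ug": out_a,
            "posterior_outlet_ug": out_r,
        }
    )

    result = ClearanceResult(
        traces=traces,
        dose=drug.dose_mass,
        half_life=None,
        fit_window=None,
        fit_r2=None,
        prototype=model.prototype,
        diagnostics={
            "posterior_volume_mL": model.posterior_volume,
            "anterior_volume_mL": model.anterior_volume,
        },
    )

    window = (duration * (1.0 - fit_fraction), duration)
    try:
        hl, r2 = estimate_half_life(result.outlet_concentration(), window)
        result.half_life, result.fit_window, result.fit_r2 = hl, window, r2
        log.info("clearance %s: t1/2 = %.3g d (R^2 %.4f)",
                 model.prototype, hl, r2)
    except (WindowError, UndefinedHalfLifeError):
        pass
    return result


# ---------------------------------------------------------------------------
# Half-life estimation
# ---------------------------------------------------------------------------
def estimate_half_life(
    trace: pd.DataFrame, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Terminal half-life (days) by log-linear least squares.

    ``trace`` carries ``time_s`` and ``concentration_ug_mL`` columns (any
    second column is accepted as concentration). Returns ``(t_half_days,
    r_squared)``.

    Raises
    ------
    WindowError
        Fewer than 5 strictly positive samples in the window.
    UndefinedHalfLifeError
        The fitted slope is non-negative (no decay).
    """
    df = pd.DataFrame(trace)
    tcol = "time_s"
    ccol = [col for col in df.columns if col != tcol][0]
    t = df[tcol].to_numpy(dtype=float)
    y = df[ccol].to_numpy(dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    pos = y > 0
    if pos.sum() < 5:
        raise WindowError("need >= 5 strictly positive samples in window")
    if (~pos).any():
        raise WindowError("window contains non-positive concentrations")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        raise UndefinedHalfLifeError("trace does not decay over the window")
    resid = np.log(y) - (slope * t + intercept)
    ss_tot = float(np.sum((np.log(y) - np.log(y).mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    t_half_days = math.log(2.0) / (-slope) / c.SECONDS_PER_DAY
    return t_half_days, r2


# ---------------------------------------------------------------------------
# Elimination-route split
# ---------------------------------------------------------------------------
def split_elimination(result: ClearanceResult) -> dict[str, float]:
    """Fractions of the dose cleared via the anterior vs RCS outlet.

    Only meaningful for the rcs prototype (the only one with two outlets).
    Fractions are cumulative at the final output time; together with the
    remaining fraction they sum to one.
    """
    if result.prototype != "rcs":
        raise ModeError("elimination split requires the rcs prototype")
    last = result.traces.iloc[-1]
    anterior = float(last["anterior_outlet_ug"]) / result.dose
    posterior = float(last["posterior_outlet_ug"]) / result.dose
    remaining = 1.0 - anterior - posterior
    return {
        "anterior_fraction": anterior,
        "posterior_fraction": posterior,
        "remaining_fraction": remaining,
    }
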