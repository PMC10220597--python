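import numpy as np
import pytest

from pkeye import compartment_pk as pk
from pkeye import membrane_hydraulics as mh


@pytest.fixture
def water():
    return mh.FluidSpec("water", 1.0e-3)


@pytest.fixture
def membrane():
    """A mid-permeability membrane over the 20 mm pursing clamp."""
    return mh.MembraneSpec(
        mwco="50", pore_radius=4e-9, thickness=30e-6,
        exposed_diameter=20e-3, pore_density=1e12,
    )


@pytest.fixture
def first_gen_model():
    return pk.EyeModelConfig(prototype="first_generation")


@pytest.fixture
def bolus():
    """5.0 mg/mL x 100 µL intravitreal bolus (500 µg)."""
    return pk.DrugSpec.from_concentration("tracer", 5.0, 100.0)


def rk4_two_compartment(model, dose_ug, t_grid_s, substep=100):
    """Fixed-step explicit RK4 oracle for the linear clearance dynamics.

    Independent of the package's adaptive integrator: builds the rate
    terms directly from the model parameters and integrates masses
    [M_p, M_a, out_ant, out_rcs] with `substep` RK4 steps per output
    interval.
    """
    q_ml = model.inflow_at(0.0) * 1e-3
    pa_h = model.hyaloid_transfer * 1e-3
    pa_rcs = (model.rcs_transfer or 0.0) * 1e-3
    s = model.hyaloid_sieving
    q_p = q_ml if model.inflow_site == "posterior" else 0.0
    vp, va = model.posterior_volume, model.anterior_volume

    def deriv(y):
        cp, ca = y[0] / vp, y[1] / va
        j_pa = (s * q_p + pa_h) * cp - pa_h * ca
        j_rcs = pa_rcs * cp
        j_out = q_ml * ca
        return np.array([-j_pa - j_rcs, j_pa - j_out, j_out, j_rcs])

    y = np.array([dose_ug, 0.0, 0.0, 0.0])
    out = [y.copy()]
    t_min = np.asarray(t_grid_s, dtype=float) / 60.0
    for t0, t1 in zip(t_min[:-1], t_min[1:]):
        h = (t1 - t0) / substep
        for _ in range(substep):
            k1 = deriv(y)
            k2 = deriv(y + h / 2 * k1)
            k3 = deriv(y + h / 2 * k2)
            k4 = deriv(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)
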