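import numpy as np
import pytest

from pymus.muscle import default_muscle_parameters
from pymus.passive import CableParameters
from pymus.presets import cat_cable, cat_system_properties


@pytest.fixture(scope="session")
def cat_props():
    return cat_system_properties()


@pytest.fixture(scope="session")
def cable(cat_props):
    return cat_cable()


@pytest.fixture()
def small_cable():
    """Hand-sized passive circuit with round numbers (absolute g ~ mS)."""
    return CableParameters(G_mS=0.5, G_mD=0.3, G_C=0.2, C_mS=1.0, C_mD=2.0,
                           A_S=0.1, A_D=0.9)


@pytest.fixture(scope="session")
def muscle_params():
    return default_muscle_parameters(P0_ratio=1.0)


def passive_ode_steady_state(cable, I_soma_nA=1.0, t_end=None):
    """Independent oracle: integrate the passive two-compartment circuit to
    steady state under a DC somatic current and return (V_S, V_D) in mV."""
    from scipy.integrate import solve_ivp
    gS, gD, gC = cable.g_S, cable.g_D, cable.g_C
    cS, cD = cable.c_S, cable.c_D
    I = I_soma_nA * 1e-3  # µA; g in mS → V in mV

    def rhs(t, v):
        vs, vd = v
        return [(-gS * vs - gC * (vs - vd) + I) / cS,
                (-gD * vd - gC * (vd - vs)) / cD]

    if t_end is None:
        import numpy as np
        lam = np.linalg.eigvals(cable.system_matrix()).real.min()
        t_end = 30.0 / lam
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12)
    return sol.y[0, -1], sol.y[1, -1]
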