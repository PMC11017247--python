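"""Shared fixtures: parameter sets and small equilibrated water boxes.

Equilibrated states are session-scoped because preparing them (L-BFGS
relaxation + staged thermostatted equilibration) is the expensive part
of the suite; every test that consumes them treats them as read-only
and copies before mutating.
"""

import numpy as np
import pytest

import rwail
from rwail.ewald import EwaldParams
from rwail.forces import CutoffScheme, ForceField, minimize_energy


@pytest.fixture(scope="session")
def params_flexible():
    return rwail.load_parameters("flexible")


@pytest.fixture(scope="session")
def params_eg273():
    return rwail.load_parameters("EG273")


@pytest.fixture(scope="session")
def params_eg298():
    return rwail.load_parameters("EG298")


def make_forcefield(params, box_edge, accuracy=1e-7, lrc=True, **toggles):
    r_cut = box_edge / 2 * 0.98
    return ForceField(params, EwaldParams(r_cut=r_cut, accuracy=accuracy),
                      CutoffScheme(r_cut_vdw=r_cut, apply_lrc_energy=lrc,
                                   apply_lrc_pressure=lrc), **toggles)


def equilibrate(params, n=32, T=298.0, seed=3, pre_steps=2000, prod_steps=800):
    """Minimized + staged-equilibrated liquid box at temperature T."""
    st = rwail.build_water_box(n, 997.0, seed=seed, r_e=params.r_e,
                               theta_e_deg=params.theta_e)
    ff = make_forcefield(params, st.box[0])
    st = minimize_energy(st, ff, max_iter=200)
    dt0 = 0.00025 if not params.is_rigid else 0.001
    tr = rwail.run_nvt(st, ff, rwail.ThermostatParams(T, tau_t=0.1),
                       n_steps=pre_steps, dt=dt0, seed=seed, sample_every=500)
    dt1 = 0.0005 if not params.is_rigid else 0.002
    tr = rwail.run_nvt(tr.state, ff, rwail.ThermostatParams(T, tau_t=0.5),
                       n_steps=prod_steps, dt=dt1, seed=seed + 1,
                       sample_every=500)
    return tr.state, ff


@pytest.fixture(scope="session")
def liquid32_flexible(params_flexible):
    """Equilibrated 32-molecule flexible box at 298 K (state, forcefield)."""
    return equilibrate(params_flexible, n=32, T=298.0, seed=3)


@pytest.fixture(scope="session")
def liquid32_eg273(params_eg273):
    """Equilibrated 32-molecule rigid EG273 box at 273 K."""
    return equilibrate(params_eg273, n=32, T=273.0, seed=11)
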