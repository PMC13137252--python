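import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nmsse import DimerSpec, ModelSpec, SpectralDensitySpec, ThermalSpec, VibronicSpec
from nmsse.model import wavenumber_to_ev

#: Canonical parameterization used throughout the suite: bias 0.1487 eV,
#: four structured bands at 836/1000/1240/1600 cm^-1, linewidth 5 meV,
#: room-temperature thermal energy 25 meV.
CANON_EPS = 0.1487
CANON_MODES_CM = (836.0, 1000.0, 1240.0, 1600.0)
CANON_LINEWIDTH = 0.005
CANON_KBT = 0.025


@pytest.fixture(scope="session")
def canon_dimer():
    return DimerSpec(epsilon=CANON_EPS, delta=0.1)


@pytest.fixture(scope="session")
def canon_bath():
    return SpectralDensitySpec(
        mode_freqs=[wavenumber_to_ev(w) for w in CANON_MODES_CM],
        gamma=0.1,
        linewidth=CANON_LINEWIDTH,
    )


@pytest.fixture(scope="session")
def canon_thermal():
    return ThermalSpec(kbt=CANON_KBT)


@pytest.fixture(scope="session")
def vibronic_model(canon_dimer):
    return ModelSpec(
        dimer=canon_dimer,
        vibronic=VibronicSpec(omega=CANON_EPS, coupling=0.2, fock_cutoff=10),
        gamma_nj=0.02,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
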