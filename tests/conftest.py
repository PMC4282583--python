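import numpy as np
import pytest

from puckerdyn.jcoupling import CouplingSet, couplings_for_torsions
from puckerdyn.relaxation import SpectrometerContext
from puckerdyn.ringgeom import ideal_ring_torsions


@pytest.fixture(scope="session")
def ctx():
    """14.1 T spectrometer context (600.13 / 150.90 MHz), backbone CH defaults."""
    return SpectrometerContext()


def two_state_couplings(p_exo, p_endo, chi_m, x_endo):
    """Closed-form population-weighted two-conformer coupling set."""
    j_exo = couplings_for_torsions(ideal_ring_torsions(p_exo, chi_m))
    j_endo = couplings_for_torsions(ideal_ring_torsions(p_endo, chi_m))
    return CouplingSet({
        lab: x_endo * j_endo.values[lab] + (1 - x_endo) * j_exo.values[lab]
        for lab in j_exo.values
    })


@pytest.fixture(scope="session")
def nmr_truth_couplings():
    """Couplings generated from the NMR-derived two-state truth for NAcPro."""
    truth = dict(p_exo=14.0, p_endo=185.0, chi_m=40.3, x_endo=0.611)
    return truth, two_state_couplings(**truth)
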