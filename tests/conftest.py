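import numpy as np
import pytest

import fisskit as fk
from fisskit.synthfix import make_labelled_domain


@pytest.fixture(scope="session")
def lab_frame():
    """Identity filament frame: +z axis, gamma=0 along +x."""
    return fk.AxisFrame(np.zeros(3), [0.0, 0.0, 1.0], [1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def domain5():
    """Toy five-helix labelled domain: (model, reference frame, probes)."""
    return make_labelled_domain(5)


def probe_data(probes, df, sigma=None):
    """Pair ProbeGeometry objects with OrderParameters rows of a dataset."""
    out = []
    for p, (_, row) in zip(probes, df.iterrows()):
        out.append(
            (p, fk.OrderParameters(row.p2, row.p4, sigma_p2=sigma, sigma_p4=sigma))
        )
    return out
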