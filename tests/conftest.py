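import numpy as np
import pytest

from neocolumn.cells import (CellTemplate, CompartmentGeometry,
                             MembraneMechanism, default_synapses)
from neocolumn.network import Network, Population


def leak_only_template(gbar: float = 0.05, v_rest: float = -65.0,
                       length: float = 25.0, diameter: float = 20.0) -> CellTemplate:
    """Single passive compartment; membrane time constant C/g_leak."""
    tpl = CellTemplate(
        cell_class="L5_basket",
        compartments=[CompartmentGeometry("soma", length, diameter, length)],
        mechanisms={"soma": [MembraneMechanism("leak", gbar, v_rest)]},
        synapse_sites={"soma": ["soma"]},
        synapses=default_synapses(),
        v_rest=v_rest,
    )
    tpl.validate()
    return tpl


def passive_point_network(gbar: float = 0.05) -> Network:
    tpl = leak_only_template(gbar=gbar)
    return Network([Population("L5_basket", [(0.0, 0.0, 0.0)])],
                   templates={"L5_basket": tpl})


@pytest.fixture
def single_l5_network():
    """One L5 pyramidal cell, no connectivity."""
    return Network([Population("L5_pyramidal", [(0.0, 0.0, 0.0)])])


@pytest.fixture
def small_column():
    """Reduced column (9 pyramidal + 3 basket cells per layer)."""
    from neocolumn.network import default_network

    return default_network(grid_shape=(3, 3), n_basket=3)


def driven_small_column(seed: int = 0):
    """Reduced column with the standard proximal evoked drive attached."""
    from neocolumn.fixtures import (EVPROX1_DELAYS, EVPROX1_WEIGHTS_AMPA)
    from neocolumn.network import default_network

    net = default_network(grid_shape=(3, 3), n_basket=3)
    net.add_evoked_drive(name="evprox1", mu=20.0, sigma=2.0, numspikes=1,
                         location="proximal",
                         weights_ampa=dict(EVPROX1_WEIGHTS_AMPA),
                         synaptic_delays=dict(EVPROX1_DELAYS), seed=seed)
    return net
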