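import numpy as np
import pytest

from bicnn import microcircuit as mc


@pytest.fixture(scope="session")
def full_hemisphere():
    """Default-configuration hemisphere, built once per session."""
    net, table, positions = mc.build_hemisphere(rng_seed=1)
    return net, table, positions


SMALL_SPECS = [
    mc.PopulationSpec("mf", 20, mc.GRANULAR, 4.0),
    mc.PopulationSpec("gr", 60, mc.GRANULAR, 2.0),
    mc.PopulationSpec("Go", 4, mc.GRANULAR, 8.0),
    mc.PopulationSpec("ba", 8, mc.MOLECULAR, 3.0),
    mc.PopulationSpec("Pk", 3, mc.MOLECULAR, 8.0),
]

SMALL_RATIOS = {
    ("mf", "gr"): (4, 12),
    ("mf", "Go"): (6, 2),
    ("gr", "Go"): (20, 2),
    ("Go", "gr"): (2, 30),
    ("gr", "ba"): (10, 2),
    ("gr", "Pk"): (20, 1),
    ("ba", "Pk"): (4, 2),
    ("Pk", "ba"): (2, 6),
    ("ba", "Go"): (3, 2),
}


@pytest.fixture(scope="session")
def small_hemisphere():
    """95-node hemisphere with scaled-down ratios for fast tests."""
    net, table, positions = mc.build_hemisphere(
        rng_seed=7, specs=SMALL_SPECS, ratios=SMALL_RATIOS
    )
    return net, table, positions


@pytest.fixture()
def fig4_table():
    """Hand-built 4-neuron, 6-synapse toy network.

    Neuron 3 is contacted by neurons 1 (w=0.3) and 2 (w=-0.4); neurons 1, 2
    and 4 get filler presynapses so the stacked layout is 1, 2, 2, 1.
    """
    pre = np.array([2, 3, 4, 1, 2, 3], dtype=np.int64)
    post = np.array([1, 2, 2, 3, 3, 4], dtype=np.int64)
    weight = np.array([0.5, 0.2, 0.1, 0.3, -0.4, 0.6])
    nature = np.sign(weight).astype(np.int8)
    table = mc.SynapseTable(
        pre=pre, post=post, weight=weight, nature=nature,
        cls=np.zeros(6, dtype=np.int16), class_keys=[("x", "x")],
    )
    table.sort_canonical()
    positions = [
        mc.NeuronPosition(i, "gr", float(i), 0.0, 0.0) for i in (1, 2, 3, 4)
    ]
    return table, positions
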