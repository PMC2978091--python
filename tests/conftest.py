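import numpy as np
import pandas as pd
import pytest

from egfrda.egfr_model import build_egfr_network
from egfrda.network import (
    Component,
    Observable,
    Parameter,
    Reaction,
    ReactionNetwork,
    Species,
)
from egfrda.scoring import MUTANT, WT, TimeCourseTable
from egfrda.simulate import StimulusSpec, simulate
from egfrda.synth import small_test_network


@pytest.fixture(scope="session")
def egfr_net():
    return build_egfr_network()


@pytest.fixture(scope="session")
def small_net():
    return small_test_network()


@pytest.fixture(scope="session")
def egfr_strict_run(egfr_net):
    """One default-network run to 60 min at strict tolerances, shared by the
    conservation / non-negativity checks."""
    return simulate(egfr_net, egfr_net.default_parameters(),
                    [0, 1, 5, 20, 40, 60], StimulusSpec(dose=100.0))


def decay_network(k=0.1, a0=1.0):
    """Isolated mass-action A -> B with a closed-form solution."""
    net = ReactionNetwork(name="decay")
    net.add_species(Species("A", "CY", (Component("A"),)))
    net.add_species(Species("B", "CY", (Component("A"),)))
    net.add_species(Species("L_ex", "EX", (Component("L"),)))  # stimulus target
    net.add_parameter(Parameter("k", k, group="other"))
    net.add_parameter(Parameter("a0", a0, role="initial_abundance", group="abundance"))
    net.initial_abundance = {"A": "a0"}
    net.add_reaction(Reaction("r", {"A": 1}, {"B": 1},
                              "mass_action_irreversible", ("k",)))
    net.add_observable(Observable("A_obs", ("A",)))
    return net.validate()


def table_from_dict(values, times):
    """Build a TimeCourseTable from {(protein, condition): series}."""
    index = pd.MultiIndex.from_tuples(list(values))
    data = pd.DataFrame(np.array([np.asarray(v, dtype=float)
                                  for v in values.values()]),
                        index=index, columns=list(map(float, times)))
    return TimeCourseTable(data)
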