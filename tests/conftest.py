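import pathlib

import pandas as pd
import pytest

import lpmgem as L
from lpmgem.fit import FitConfig, FitTargets, ReactionPartition

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def path_net():
    return L.make_path_network()


@pytest.fixture(scope="session")
def loop_net():
    """Path network with an attached reversible 3-cycle (FVA-inflating)."""
    return L.make_loop_network(cycle_len=3, attach_to_path=True)


@pytest.fixture(scope="session")
def loop3_path():
    return DATA / "loop3.tsv"


@pytest.fixture(scope="session")
def loop_scenario():
    return L.make_loop_scenario(seed=1)


@pytest.fixture(scope="session")
def loop_fit_inputs(loop_scenario):
    sc = loop_scenario
    return L.prepare_fit(sc.network, sc.expression, sc.gpr, sc.core, alpha=0.01)


def riding_cycle_case(alpha: float = 0.0):
    """Path+3-cycle fit whose unconstrained optimum rides the cycle.

    All cycle members are fitted with a large common target (600), which an
    internal circulation can satisfy exactly; the loop-law-respecting
    optimum instead is path flux 5 with the cycle silent.
    """
    net = L.make_loop_network(cycle_len=3, attach_to_path=True)
    core = ["R1", "R2", "C1", "C2", "C3"]
    fva = L.run_fva(net, core)
    partition = ReactionPartition.from_sets(net, core, [], fva)
    config = FitConfig(alpha=alpha, weights=L.compute_weights(fva, partition))
    vfit = pd.DataFrame({"c1": [5.0, 5.0, 600.0, 600.0, 600.0]}, index=core)
    targets = FitTargets(vfit=vfit, vmin=fva["min"], vmax=fva["max"])
    return net, targets, partition, config
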