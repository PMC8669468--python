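import numpy as np
import pytest

import gluconeoflux as gf
from gluconeoflux import synth
from gluconeoflux.network import (AtomTransition, NetworkModel, Reaction)


@pytest.fixture(scope="session")
def pputida_model():
    return gf.load_bundled_model("pputida_kt2440_succinate")


@pytest.fixture(scope="session")
def ctest_model():
    return gf.load_bundled_model("ctestosteroni_kf1_succinate")


@pytest.fixture(scope="session")
def demo_model():
    return gf.load_bundled_model("pputida_succinate_demo")


@pytest.fixture(scope="session")
def demo_truth_fluxes():
    return gf.FluxVector(dict(synth.DEMO_TRUE_FLUXES))


@pytest.fixture(scope="session")
def toy_models():
    return {name: gf.load_bundled_model(name)
            for name in ("toy_chain_split", "toy_cycle_scramble",
                         "toy_reversible_mix")}


def linear_chain_model():
    """uptake -> A -> B -> biomass drain; 2 balanced metabolites."""
    return NetworkModel([
        Reaction("UPT", {"A_EXT": 1}, {"A": 1}, kind="uptake",
                 atom_transitions=(AtomTransition((("A_EXT", "ab"),),
                                                  (("A", "ab"),)),)),
        Reaction("V1", {"A": 1}, {"B": 1},
                 atom_transitions=(AtomTransition((("A", "ab"),),
                                                  (("B", "ab"),)),)),
        Reaction("BM", {"B": 1}, {}, kind="biomass_drain"),
    ])


@pytest.fixture
def chain_model():
    return linear_chain_model()


def dilution_toy_model():
    """Two-carbon chain with two unlabeled influx dilution points.

    With uptake fixed, exactly two free fluxes remain (the influxes),
    both identifiable from the M+0 of A and B under a fully labeled
    tracer.  Used for CI coverage simulations.
    """
    t = lambda s, p: (AtomTransition(((s, "ab"),), ((p, "ab"),)),)
    return NetworkModel([
        Reaction("UPT", {"A_EXT": 1}, {"A": 1}, kind="uptake",
                 atom_transitions=t("A_EXT", "A")),
        Reaction("A_IN", {}, {"A": 1}, kind="unlabeled_influx"),
        Reaction("V1", {"A": 1}, {"B": 1}, atom_transitions=t("A", "B")),
        Reaction("B_IN", {}, {"B": 1}, kind="unlabeled_influx"),
        Reaction("OUT", {"B": 1}, {"B_EXT": 1}, kind="secretion",
                 atom_transitions=t("B", "B_EXT")),
    ])


@pytest.fixture
def dilution_model():
    return dilution_toy_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
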