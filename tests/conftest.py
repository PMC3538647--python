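import numpy as np
import pytest

from purineflux import label_sim, network_model as nm, scenarios
from purineflux.network_model import FluxVector


@pytest.fixture(scope="session")
def network():
    return nm.build_network()


@pytest.fixture(scope="session")
def demand():
    return nm.load_demands()


@pytest.fixture(scope="session")
def fragments():
    return label_sim.load_fragments()


@pytest.fixture(scope="session")
def wt_setup():
    return scenarios.build_scenario("wild_type")


@pytest.fixture(scope="session")
def wt_system(wt_setup, fragments):
    return label_sim.decompose_emus(wt_setup.network, fragments)


# -- toy networks for oracle cross-checks ----------------------------------

TOY_SPEC = """
@external GLC_ext P_ext Q_ext
upt: GLC_ext (ab) -> A (ab) | irr
split: A (ab) -> B (a) + C (b) | irr
cond: B (a) + C (b) <-> D (ba) | rev
scramble: D (ab) -> E (ab) ; D (ab) -> E (ba) | irr
out: E (ab) -> P_ext (ab) | irr
leak: A (ab) -> Q_ext (ab) | irr
"""

TOY_FRAGMENTS = [
    label_sim.FragmentDef("frag_E", (("E", (0, 1)),)),
    label_sim.FragmentDef("frag_D1", (("D", (0,)),)),
    label_sim.FragmentDef("frag_AE", (("A", (0, 1)), ("E", (0, 1)))),
]


def toy_tracer(pattern: str = "10", purity: float = 0.99) -> label_sim.TracerMixture:
    return label_sim.TracerMixture(((pattern, 1.0),), purity=purity)


@pytest.fixture(scope="session")
def toy_network():
    return nm.load_network_spec(TOY_SPEC)


def toy_fluxes(leak: float = 20.0, exchange: float = 0.3) -> FluxVector:
    split = 100.0 - leak
    return FluxVector(
        net={
            "upt": 100.0,
            "leak": leak,
            "split": split,
            "cond": split,
            "scramble": split,
            "out": split,
        },
        exchange={"cond": exchange},
    )
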