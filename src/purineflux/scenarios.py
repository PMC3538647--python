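"""Strain scenarios for simulation studies.

Each scenario bundles the growth parameters of one engineered
*C. glutamicum* strain, its gene knockouts and purine supplementation
state, the tracer used for it ([1-13C] glucose normally, [1,2-13C2]
glucose for strains lacking glucose 6-phosphate isomerase, whose labeling
is otherwise uninformative), and the reported flux landmarks its
synthetic ground-truth flux distribution must reproduce (TCA cycle flux
= citrate synthase; PPP entry = glucose 6-phosphate dehydrogenase).
Remaining degrees of freedom sit at realistic secretion priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import label_sim, network_model
from .network_model import AnabolicDemand, FluxVector, MetabolicNetwork

#: exchange parameters (bounded [0,1) scale) used for ground-truth fluxes
DEFAULT_EXCHANGE_TRUTH = {
    "pgi": 0.3,
    "tkt1": 0.3,
    "tal": 0.3,
    "tkt2": 0.3,
    "mdh": 0.5,
    "ppc": 0.4,
}


@dataclass(frozen=True)
class StrainScenario:
    name: str
    mu: float
    q_s: float
    knockouts: tuple[str, ...] = ()
    adenine: bool = False
    guanine: bool = False
    imp_pool: float = 0.0  # mmol IMP per g CDW added to the P5P demand
    tracer_name: str = "1-13C"
    flux_targets: dict[str, float] = field(default_factory=dict)
    priors: dict[str, float] = field(default_factory=dict)

    def tracer(self) -> label_sim.TracerMixture:
        return {
            "1-13C": label_sim.tracer_1_13c,
            "1,2-13C2": label_sim.tracer_12_13c2,
        }[self.tracer_name]()


SCENARIOS: dict[str, StrainScenario] = {
    s.name: s
    for s in [
        StrainScenario(
            name="wild_type",
            mu=0.443,
            q_s=4.67,
            flux_targets={"cs": 47.3},
            priors={"zwf": 55.0, "tre_sec": 2.0, "gly_sec": 1.5},
        ),
        StrainScenario(
            name="pgi_deletion",
            mu=0.376,
            q_s=4.18,
            knockouts=("pgi",),
            tracer_name="1,2-13C2",
            flux_targets={"cs": 45.7},
            priors={"zwf": 92.0, "gly_sec": 2.0},
        ),
        StrainScenario(
            name="purA_guaB2",
            mu=0.317,
            q_s=4.24,
            adenine=True,
            guanine=True,
            imp_pool=0.0219,
            flux_targets={"zwf": 29.3, "cs": 88.0},
            priors={"zwf": 29.3, "tre_sec": 2.0, "gly_sec": 2.0},
        ),
        StrainScenario(
            name="quadruple",
            mu=0.146,
            q_s=1.92,
            knockouts=("pgi",),
            adenine=True,
            guanine=True,
            imp_pool=0.0129,
            tracer_name="1,2-13C2",
            flux_targets={"zwf": 98.0},
            priors={"gly_sec": 0.3},
        ),
    ]
}


@dataclass
class ScenarioSetup:
    scenario: StrainScenario
    network: MetabolicNetwork
    demand: AnabolicDemand
    true_fluxes: FluxVector
    tracer: label_sim.TracerMixture


def build_scenario(
    name: str,
    network: MetabolicNetwork | None = None,
    demand: AnabolicDemand | None = None,
    exchange: dict[str, float] | None = None,
) -> ScenarioSetup:
    """Network, demands and ground-truth flux vector for one strain scenario."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]
    net = network or network_model.build_network()
    for tag in sc.knockouts:
        net = net.apply_deletion(tag)
    if demand is None:
        demand = network_model.load_demands()
    demand = AnabolicDemand(
        dict(demand.coefficients),
        adenine=sc.adenine,
        guanine=sc.guanine,
        imp_pool_correction=sc.imp_pool,
        sparing_3pg=dict(demand.sparing_3pg),
    )
    fixed = network_model.drain_fixed_fluxes(net, demand, sc.mu, sc.q_s)
    param = net.parameterization(fixed)
    theta = param.solve_targets(sc.flux_targets, priors=sc.priors)
    exch = dict(DEFAULT_EXCHANGE_TRUTH if exchange is None else exchange)
    flux = param.flux_vector(theta, exch)
    neg = [
        r.id
        for r in net.reactions
        if not r.reversible and flux.net[r.id] < -1e-6
    ]
    if neg:
        raise ValueError(f"scenario {name}: infeasible flux vector (negative {neg})")
    param.check_balances(flux)
    return ScenarioSetup(sc, net, demand, flux, sc.tracer())
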