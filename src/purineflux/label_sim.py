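"""Steady-state simulation of mass isotopomer distributions (MDVs).

The forward model of the flux analysis: given a flux distribution and a
13C tracer mixture, predict the mass isotopomer distribution of each
measured fragment.  The simulation uses the elementary metabolite unit
(EMU) decomposition — the minimal set of metabolite carbon subsets
reachable backward from the measured fragments — so each labeling state
is obtained from one linear solve per EMU size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import DATA_DIR
from .network_model import EXCHANGE_FLOOR, FluxVector, MetabolicNetwork, Reaction

DEFAULT_FRAGMENT_FILE = "fragments.tsv"


class LabelingError(ValueError):
    pass


# -- tracers ---------------------------------------------------------------


@dataclass(frozen=True)
class TracerMixture:
    """Glucose tracer composition.

    Each component is a 6-character pattern over the glucose carbons
    ('1' = nominally 13C-labeled position) with its molar fraction.
    ``purity`` is the isotopic enrichment of nominally labeled positions;
    unlabeled positions carry natural 13C abundance.
    """

    components: tuple[tuple[str, float], ...]
    purity: float = 0.99
    natural_13c: float = 0.0107

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("tracer component fractions must sum to 1")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")

    def emu_mdv(self, positions: tuple[int, ...]) -> np.ndarray:
        """MDV of a glucose EMU covering the given 0-based carbon positions."""
        out = np.zeros(len(positions) + 1)
        for pattern, frac in self.components:
            mdv = np.array([1.0])
            for pos in positions:
                p = self.purity if pattern[pos] == "1" else self.natural_13c
                mdv = np.convolve(mdv, [1.0 - p, p])
            out += frac * mdv
        return out


def tracer_1_13c(purity: float = 0.99) -> TracerMixture:
    return TracerMixture((("100000", 1.0),), purity=purity)


def tracer_12_13c2(purity: float = 0.99) -> TracerMixture:
    return TracerMixture((("110000", 1.0),), purity=purity)


def tracer_unlabeled() -> TracerMixture:
    return TracerMixture((("000000", 1.0),), purity=1.0, natural_13c=0.0)


def tracer_u_13c6(purity: float = 1.0) -> TracerMixture:
    return TracerMixture((("111111", 1.0),), purity=purity, natural_13c=0.0)


# -- fragments -------------------------------------------------------------


@dataclass(frozen=True)
class FragmentDef:
    """A measured fragment: convolution of one or more precursor EMUs.

    ``parts`` lists (metabolite id, 0-based carbon positions); ``formula``
    is the derivatized-ion composition beyond the tracer carbons, consumed
    by the natural-abundance correction.
    """

    id: str
    parts: tuple[tuple[str, tuple[int, ...]], ...]
    formula: str = ""

    @property
    def n_carbons(self) -> int:
        return sum(len(pos) for _, pos in self.parts)


def _parse_part(token: str) -> tuple[str, tuple[int, ...]]:
    met, _, poslist = token.partition(":")
    positions = tuple(sorted(int(p) - 1 for p in poslist.split(",")))
    return met.strip(), positions


def load_fragments(path=None) -> list[FragmentDef]:
    import pandas as pd

    if path is None:
        path = DATA_DIR / DEFAULT_FRAGMENT_FILE
    with (open(path) if isinstance(path, str) else path.open()) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    frags = []
    for _, row in df.iterrows():
        parts = tuple(_parse_part(tok) for tok in str(row["precursors"]).split("+"))
        frags.append(FragmentDef(str(row["fragment"]), parts, str(row["formula"])))
    return frags


# -- EMU system ------------------------------------------------------------

EMU = tuple[str, tuple[int, ...]]  # (metabolite id, sorted 0-based positions)


@dataclass
class _UniReaction:
    rxn: Reaction
    forward: bool
    weight: float
    # product_source of the direction actually used
    source: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    substrate_slots: tuple = ()
    product_slots: tuple = ()


@dataclass
class EMUSystem:
    """Size-ordered EMU balance structure for a fixed fragment set."""

    network: MetabolicNetwork
    fragments: list[FragmentDef]
    unirxns: list[_UniReaction]
    sizes: list[int]
    emus_by_size: dict[int, list[EMU]]
    # per size: list over EMUs of term lists; each term is
    # (unirxn index, [factor ...]) with factor = ('emu', EMU) or ('input', EMU)
    terms: dict[int, list[list[tuple[int, list[tuple[str, EMU]]]]]]
    consumption: dict[str, list[tuple[int, int]]]  # met -> [(unirxn, nslots)]

    @property
    def n_emus(self) -> int:
        return sum(len(v) for v in self.emus_by_size.values())


def _unidirectional_reactions(network: MetabolicNetwork) -> list[_UniReaction]:
    out = []
    for rxn in network.reactions:
        w = 1.0 / len(rxn.atom_maps)
        for am in rxn.atom_maps:
            out.append(
                _UniReaction(rxn, True, w, am.source_of(), am.substrate_slots, am.product_slots)
            )
            if rxn.reversible:
                rev = am.reversed()
                out.append(
                    _UniReaction(rxn, False, w, rev.source_of(), rev.substrate_slots, rev.product_slots)
                )
    return out


def decompose_emus(
    network: MetabolicNetwork, fragments: list[FragmentDef]
) -> EMUSystem:
    """Minimal EMU set reachable backward from the measured fragments."""
    unirxns = _unidirectional_reactions(network)
    producers: dict[str, list[tuple[int, int]]] = {}
    consumption: dict[str, list[tuple[int, int]]] = {}
    for k, ur in enumerate(unirxns):
        for slot, (met, _) in enumerate(ur.product_slots):
            producers.setdefault(met, []).append((k, slot))
        seen: dict[str, int] = {}
        for met, _ in ur.substrate_slots:
            seen[met] = seen.get(met, 0) + 1
        for met, n in seen.items():
            consumption.setdefault(met, []).append((k, n))

    balanced = set(network.balanced_metabolites)
    for frag in fragments:
        for met, positions in frag.parts:
            if met not in network.metabolites:
                raise LabelingError(f"fragment {frag.id}: metabolite {met} not in network")
            nc = network.metabolites[met].n_carbons
            if any(p < 0 or p >= nc for p in positions):
                raise LabelingError(f"fragment {frag.id}: carbon positions invalid for {met}")
            if met in balanced and met not in producers:
                raise LabelingError(f"fragment {frag.id}: {met} is never produced")

    todo = [
        (met, positions)
        for frag in fragments
        for met, positions in frag.parts
        if met in balanced
    ]
    known: set[EMU] = set()
    terms: dict[EMU, list] = {}
    while todo:
        emu = todo.pop()
        if emu in known:
            continue
        known.add(emu)
        met, atoms = emu
        emu_terms = []
        for k, slot in producers.get(met, []):
            ur = unirxns[k]
            groups: dict[int, list[int]] = {}
            for a in atoms:
                s_slot, s_pos = ur.source[(slot, a)]
                groups.setdefault(s_slot, []).append(s_pos)
            factors = []
            for s_slot, pos in sorted(groups.items()):
                s_met = ur.substrate_slots[s_slot][0]
                sub_emu = (s_met, tuple(sorted(pos)))
                if s_met in balanced:
                    factors.append(("emu", sub_emu))
                    todo.append(sub_emu)
                else:
                    factors.append(("input", sub_emu))
            emu_terms.append((k, factors))
        terms[emu] = emu_terms

    emus_by_size: dict[int, list[EMU]] = {}
    for emu in sorted(known):
        emus_by_size.setdefault(len(emu[1]), []).append(emu)
    sizes = sorted(emus_by_size)
    terms_by_size = {
        size: [terms[emu] for emu in emus_by_size[size]] for size in sizes
    }
    return EMUSystem(
        network, list(fragments), unirxns, sizes, emus_by_size, terms_by_size, consumption
    )


def _unirxn_fluxes(system: EMUSystem, fluxes: FluxVector) -> np.ndarray:
    vals = np.empty(len(system.unirxns))
    for k, ur in enumerate(system.unirxns):
        fwd, bwd = fluxes.unidirectional(ur.rxn)
        vals[k] = (fwd if ur.forward else bwd) * ur.weight
    return vals


def simulate_mdvs(
    system: EMUSystem, fluxes: FluxVector, tracer: TracerMixture
) -> dict[str, np.ndarray]:
    """Steady-state MDV of every fragment in the system.

    Solves the EMU balance blocks in order of increasing size; raises
    :class:`LabelingError` when a pool carries no flux (singular block),
    which usually means an exchange-flux floor is needed.
    """
    v = _unirxn_fluxes(system, fluxes)
    cons = {
        met: sum(v[k] * n for k, n in system.consumption.get(met, []))
        for met in {emu[0] for lst in system.emus_by_size.values() for emu in lst}
    }
    solved: dict[EMU, np.ndarray] = {}

    def factor_mdv(kind: str, emu: EMU) -> np.ndarray:
        if kind == "input":
            met, positions = emu
            if met == "GLC_ext":
                return tracer.emu_mdv(positions)
            raise LabelingError(f"no tracer distribution for input metabolite {met}")
        return solved[emu]

    for size in system.sizes:
        emus = system.emus_by_size[size]
        index = {emu: i for i, emu in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for i, emu in enumerate(emus):
            c = cons[emu[0]]
            if c <= 10 * EXCHANGE_FLOOR:
                raise LabelingError(
                    f"metabolite {emu[0]} carries (almost) no flux; the EMU block is "
                    "singular — raise the exchange-flux floor or prune the reaction"
                )
            A[i, i] = c
            for k, factors in system.terms[size][i]:
                if v[k] == 0.0:
                    continue
                if len(factors) == 1 and factors[0][0] == "emu":
                    A[i, index[factors[0][1]]] -= v[k]
                else:
                    mdv = np.array([1.0])
                    for kind, sub in factors:
                        mdv = np.convolve(mdv, factor_mdv(kind, sub))
                    B[i] += v[k] * mdv
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise LabelingError(
                f"singular EMU block of size {size} (a zero-flux cycle?) — "
                "raise the exchange-flux floor or prune zero-flux reactions"
            ) from exc
        for i, emu in enumerate(emus):
            solved[emu] = X[i]

    out: dict[str, np.ndarray] = {}
    for frag in system.fragments:
        mdv = np.array([1.0])
        for met, positions in frag.parts:
            emu = (met, positions)
            if met in set(system.network.balanced_metabolites):
                mdv = np.convolve(mdv, solved[emu])
            else:
                mdv = np.convolve(mdv, factor_mdv("input", emu))
        out[frag.id] = mdv
    return out


# -- isotopic steady state -------------------------------------------------


@dataclass
class SteadyStateReport:
    max_deviation: float
    per_fragment: dict[str, float]
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_deviation <= self.tolerance


def check_isotopic_steady_state(
    mdvs_t1: dict[str, np.ndarray],
    mdvs_t2: dict[str, np.ndarray],
    tolerance: float = 0.01,
) -> SteadyStateReport:
    """Compare fragment MDVs sampled at two biomass concentrations.

    At isotopic (and metabolic) steady state the labeling patterns are
    time-invariant, so the per-fraction deviations stay within the
    measurement tolerance.
    """
    if set(mdvs_t1) != set(mdvs_t2):
        raise ValueError(
            f"fragment sets differ: {sorted(set(mdvs_t1) ^ set(mdvs_t2))}"
        )
    per = {
        frag: float(np.max(np.abs(np.asarray(mdvs_t1[frag]) - np.asarray(mdvs_t2[frag]))))
        for frag in mdvs_t1
    }
    return SteadyStateReport(max(per.values()), per, tolerance)
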