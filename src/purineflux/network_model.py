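"""Central-metabolism network with carbon atom transitions.

The bundled network covers glycolysis, the oxidative and non-oxidative
pentose phosphate pathway (lumped pentose 5-phosphate pool), pyruvate
dehydrogenase, the full TCA cycle, a single net anaplerotic
PEP + CO2 <-> OAA interconversion, glycine and trehalose secretion, and
growth-rate-dependent anabolic precursor drains.  Net fluxes are
expressed as molar percentages of the specific glucose uptake rate,
which is fixed at 100.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from . import DATA_DIR

log = logging.getLogger(__name__)

DEFAULT_NETWORK_FILE = "network_cg_central.txt"
DEFAULT_DEMAND_FILE = "biomass_demands.tsv"

#: net-flux magnitude (in % of uptake) that an exchange parameter of 0.5 maps to
EXCHANGE_SCALE = 100.0
#: floor applied to exchange fluxes of reversible reactions to keep the
#: labeling systems nonsingular
EXCHANGE_FLOOR = 1e-6


class NetworkValidationError(ValueError):
    """Raised when a network specification violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    balanced: bool = True


@dataclass(frozen=True)
class AtomMap:
    """One atom-transition variant of a reaction.

    ``substrate_slots``/``product_slots`` list (metabolite id, n_carbons)
    per molecule occurrence; ``product_source[(p_slot, p_pos)]`` gives the
    (substrate slot, substrate position) each product carbon comes from
    (positions are 0-based).
    """

    substrate_slots: tuple[tuple[str, int], ...]
    product_slots: tuple[tuple[str, int], ...]
    product_source: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def source_of(self) -> dict[tuple[int, int], tuple[int, int]]:
        return dict(self.product_source)

    def reversed(self) -> "AtomMap":
        inv = tuple((src, dst) for dst, src in self.product_source)
        return AtomMap(self.product_slots, self.substrate_slots, inv)


@dataclass(frozen=True)
class Reaction:
    id: str
    atom_maps: tuple[AtomMap, ...]
    reversible: bool = False
    gene_tag: str | None = None
    drain_precursor: str | None = None

    @property
    def substrates(self) -> list[tuple[str, int]]:
        return _slot_stoich(self.atom_maps[0].substrate_slots)

    @property
    def products(self) -> list[tuple[str, int]]:
        return _slot_stoich(self.atom_maps[0].product_slots)


def _slot_stoich(slots) -> list[tuple[str, int]]:
    out: dict[str, int] = {}
    for met, _ in slots:
        out[met] = out.get(met, 0) + 1
    return sorted(out.items())


@dataclass
class AnabolicDemand:
    """Biomass precursor demands in mmol per g cell dry weight.

    ``adenine``/``guanine`` supplementation spares the de novo purine-ring
    carbon normally drawn from 3-phosphoglycerate (glycine plus formyl
    units); ``imp_pool_correction`` (mmol/g CDW) adds the ribose moiety of
    an accumulating IMP pool to the pentose 5-phosphate demand.
    """

    coefficients: dict[str, float]
    adenine: bool = False
    guanine: bool = False
    imp_pool_correction: float = 0.0
    sparing_3pg: dict[str, float] = field(
        default_factory=lambda: {"adenine": 0.26, "guanine": 0.24}
    )

    def __post_init__(self) -> None:
        for prec, c in self.coefficients.items():
            if c < 0:
                raise ValueError(f"negative demand coefficient for {prec}")

    def effective(self) -> dict[str, float]:
        eff = dict(self.coefficients)
        spared = 0.0
        if self.adenine:
            spared += self.sparing_3pg["adenine"]
        if self.guanine:
            spared += self.sparing_3pg["guanine"]
        if spared:
            new = eff.get("3PG", 0.0) - spared
            if new < 0:
                log.warning("3PG demand spared below zero; clamped to 0")
                new = 0.0
            eff["3PG"] = new
        if self.imp_pool_correction:
            eff["P5P"] = eff.get("P5P", 0.0) + self.imp_pool_correction
        return eff


@dataclass
class FluxVector:
    """Net fluxes (% of glucose uptake) and exchange parameters.

    ``exchange`` maps reversible reaction ids to the bounded parameter
    x in [0, 1); the corresponding exchange flux magnitude is
    ``EXCHANGE_SCALE * x / (1 - x)``.
    """

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def exchange_flux(self, rxn_id: str) -> float:
        x = self.exchange.get(rxn_id, 0.0)
        return max(EXCHANGE_SCALE * x / (1.0 - x), 0.0)

    def scaled(self, factor: float) -> "FluxVector":
        """Scale the whole flux distribution (net and exchange fluxes).

        The exchange parameters are re-derived so the exchange flux
        magnitudes scale together with the net fluxes.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        exchange = {}
        for rxn_id, x in self.exchange.items():
            e = EXCHANGE_SCALE * x / (1.0 - x) * factor
            exchange[rxn_id] = e / (EXCHANGE_SCALE + e)
        return FluxVector({r: factor * v for r, v in self.net.items()}, exchange)

    def unidirectional(self, rxn: Reaction) -> tuple[float, float]:
        """(forward, backward) flux pair for the labeling simulation."""
        v = self.net.get(rxn.id, 0.0)
        if not rxn.reversible:
            return max(v, 0.0), 0.0
        exch = max(self.exchange_flux(rxn.id), EXCHANGE_FLOOR)
        if v >= 0:
            return v + exch, exch
        return exch, -v + exch


_TERM_RE = re.compile(r"\s*([A-Za-z0-9_]+)\s*\(([A-Za-z]*)\)\s*")


def _parse_side(side: str):
    slots, letters = [], []
    for term in side.split("+"):
        m = _TERM_RE.fullmatch(term)
        if m is None:
            raise NetworkValidationError(f"cannot parse species term {term!r}")
        slots.append((m.group(1), len(m.group(2))))
        letters.append(m.group(2))
    return slots, letters


def _parse_equation(rxn_id: str, eqn: str) -> tuple[AtomMap, bool]:
    reversible = "<->" in eqn
    lhs, rhs = re.split(r"<->|->", eqn, maxsplit=1)
    sub_slots, sub_letters = _parse_side(lhs)
    prod_slots, prod_letters = _parse_side(rhs)

    src_by_letter: dict[str, tuple[int, int]] = {}
    for slot, letters in enumerate(sub_letters):
        for pos, ch in enumerate(letters):
            if ch in src_by_letter:
                raise NetworkValidationError(
                    f"reaction {rxn_id}: substrate atom letter {ch!r} repeated"
                )
            src_by_letter[ch] = (slot, pos)

    mapping, used = [], set()
    for slot, letters in enumerate(prod_letters):
        for pos, ch in enumerate(letters):
            if ch not in src_by_letter:
                raise NetworkValidationError(
                    f"reaction {rxn_id}: product atom {ch!r} has no substrate source"
                )
            if ch in used:
                raise NetworkValidationError(
                    f"reaction {rxn_id}: substrate atom {ch!r} used twice in products"
                )
            used.add(ch)
            mapping.append(((slot, pos), src_by_letter[ch]))
    missing = set(src_by_letter) - used
    if missing:
        raise NetworkValidationError(
            f"reaction {rxn_id}: substrate carbons {sorted(missing)} not conserved "
            "in products (map them to CO2 or another sink)"
        )
    return AtomMap(tuple(sub_slots), tuple(prod_slots), tuple(mapping)), reversible


def parse_reaction_line(line: str) -> Reaction:
    """Parse one reaction entry.

    Format: ``id: eqn [; eqn-variant ...] | rev|irr [| gene=tag] [| drain=PREC]``.
    Equal-weight equation variants express symmetric-molecule scrambling.
    """
    head, _, rest = line.partition(":")
    rxn_id = head.strip()
    fields = [f.strip() for f in rest.split("|")]
    eqns = [e.strip() for e in fields[0].split(";")]
    maps, revs = [], []
    for eqn in eqns:
        am, rev = _parse_equation(rxn_id, eqn)
        maps.append(am)
        revs.append(rev)
    reversible = revs[0]
    gene_tag = drain = None
    for f in fields[1:]:
        if f in ("rev", "irr"):
            reversible = f == "rev"
        elif f.startswith("gene="):
            gene_tag = f[5:]
        elif f.startswith("drain="):
            drain = f[6:]
        elif f:
            raise NetworkValidationError(f"reaction {rxn_id}: unknown field {f!r}")
    base = maps[0]
    for am in maps[1:]:
        if _slot_stoich(am.substrate_slots) != _slot_stoich(base.substrate_slots) or \
           _slot_stoich(am.product_slots) != _slot_stoich(base.product_slots):
            raise NetworkValidationError(
                f"reaction {rxn_id}: scrambling variants differ in stoichiometry"
            )
    return Reaction(rxn_id, tuple(maps), reversible, gene_tag, drain)


class MetabolicNetwork:
    """Validated reaction network with atom transitions."""

    def __init__(
        self,
        metabolites: dict[str, Metabolite],
        reactions: list[Reaction],
        uptake_reaction: str,
        knockouts: frozenset[str] = frozenset(),
    ) -> None:
        self.metabolites = metabolites
        self.reactions = list(reactions)
        self.reaction_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.uptake_reaction = uptake_reaction
        self.knockouts = frozenset(knockouts)
        self._validate()

    # -- structure ---------------------------------------------------------

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index[rxn_id]]

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.balanced]

    @property
    def drain_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.drain_precursor]

    @property
    def gene_tags(self) -> set[str]:
        return {r.gene_tag for r in self.reactions if r.gene_tag}

    def is_knocked_out(self, rxn: Reaction) -> bool:
        return rxn.gene_tag is not None and rxn.gene_tag in self.knockouts

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        mets = self.balanced_metabolites
        met_idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.substrates:
                if met in met_idx:
                    S[met_idx[met], j] -= coeff
            for met, coeff in rxn.products:
                if met in met_idx:
                    S[met_idx[met], j] += coeff
        return S, mets, [r.id for r in self.reactions]

    def _validate(self) -> None:
        if len(self.reaction_index) != len(self.reactions):
            raise NetworkValidationError("duplicate reaction ids")
        produced: set[str] = set()
        consumed: set[str] = set()
        for rxn in self.reactions:
            for am in rxn.atom_maps:
                for met, nc in am.substrate_slots + am.product_slots:
                    if met not in self.metabolites:
                        raise NetworkValidationError(
                            f"reaction {rxn.id}: unknown metabolite {met}"
                        )
                    if self.metabolites[met].balanced and self.metabolites[met].n_carbons != nc:
                        raise NetworkValidationError(
                            f"reaction {rxn.id}: {met} carries {nc} carbons here "
                            f"but {self.metabolites[met].n_carbons} elsewhere"
                        )
            for met, _ in rxn.substrates:
                consumed.add(met)
            for met, _ in rxn.products:
                produced.add(met)
        for met in self.balanced_metabolites:
            if self.metabolites[met].n_carbons < 1:
                raise NetworkValidationError(f"balanced metabolite {met} has no carbon")
            if met not in produced or met not in consumed:
                raise NetworkValidationError(
                    f"orphan metabolite {met}: must be both produced and consumed"
                )
        if self.uptake_reaction not in self.reaction_index:
            raise NetworkValidationError(
                f"uptake reaction {self.uptake_reaction} not in network"
            )
        S, _, _ = self.stoichiometric_matrix()
        if S.shape[1] - np.linalg.matrix_rank(S) < 1:
            raise NetworkValidationError("network has no degrees of freedom")

    # -- knockouts ---------------------------------------------------------

    def apply_deletion(self, gene_tag: str) -> "MetabolicNetwork":
        """Return a copy with all reactions tagged ``gene_tag`` forced to zero."""
        if gene_tag not in self.gene_tags:
            raise KeyError(
                f"unknown gene tag {gene_tag!r}; available: {sorted(self.gene_tags)}"
            )
        return MetabolicNetwork(
            self.metabolites,
            self.reactions,
            self.uptake_reaction,
            self.knockouts | {gene_tag},
        )

    # -- flux parameterization --------------------------------------------

    def parameterization(
        self,
        fixed: dict[str, float],
        prefer_free: tuple[str, ...] = ("zwf", "tre_sec", "gly_sec", "ppc", "pgi"),
    ) -> "FluxParameterization":
        """Null-space parameterization of the net-flux balance equations.

        ``fixed`` pins named reactions (the uptake at 100 and the anabolic
        drains); knocked-out reactions are pinned at 0 automatically.  Free
        fluxes are picked from ``prefer_free`` first, then by reaction id,
        so the choice is deterministic.
        """
        fixed = dict(fixed)
        for rxn in self.reactions:
            if self.is_knocked_out(rxn):
                fixed[rxn.id] = 0.0
        return FluxParameterization(self, fixed, prefer_free)


class FluxParameterization:
    """Affine map theta -> net flux vector satisfying all node balances."""

    def __init__(self, network, fixed, prefer_free):
        self.network = network
        self.fixed = dict(fixed)
        S, mets, rxn_ids = network.stoichiometric_matrix()
        self.rxn_ids = rxn_ids
        n = len(rxn_ids)
        idx = {r: i for i, r in enumerate(rxn_ids)}
        for r in fixed:
            if r not in idx:
                raise KeyError(f"fixed flux for unknown reaction {r}")
        free_cols = [i for i, r in enumerate(rxn_ids) if r not in fixed]
        v_fixed = np.zeros(n)
        for r, val in fixed.items():
            v_fixed[idx[r]] = val
        rhs = -S @ v_fixed
        Su = S[:, free_cols]
        sol, *_ = np.linalg.lstsq(Su, rhs, rcond=None)
        if not np.allclose(Su @ sol, rhs, atol=1e-8):
            raise NetworkValidationError("fixed fluxes are inconsistent with balances")
        # null space of the unfixed system
        u, s, vt = np.linalg.svd(Su)
        rank = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
        N = vt[rank:].T  # (n_free_cols, k)
        self.v0 = np.zeros(n)
        self.v0[free_cols] = sol
        self.v0 += v_fixed
        self.basis = np.zeros((n, N.shape[1]))
        self.basis[free_cols] = N
        # choose k reactions whose values serve as the free coordinates
        order = [r for r in prefer_free if r in idx and r not in fixed]
        order += sorted(r for r in rxn_ids if r not in fixed and r not in order)
        chosen: list[int] = []
        for r in order:
            cand = chosen + [idx[r]]
            if np.linalg.matrix_rank(self.basis[cand]) == len(cand):
                chosen.append(idx[r])
            if len(chosen) == N.shape[1]:
                break
        if len(chosen) != N.shape[1]:
            raise NetworkValidationError("could not select independent free fluxes")
        self.free_indices = chosen
        self.free_names = [rxn_ids[i] for i in chosen]
        M = self.basis[chosen]  # (k, k), invertible
        self._Minv = np.linalg.inv(M)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def flux_array(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        c = self._Minv @ (theta - self.v0[self.free_indices])
        return self.v0 + self.basis @ c

    def flux_vector(
        self, theta: np.ndarray, exchange: dict[str, float] | None = None
    ) -> FluxVector:
        v = self.flux_array(theta)
        net = dict(zip(self.rxn_ids, v))
        exch = dict(exchange or {})
        for rxn in self.network.reactions:
            if self.network.is_knocked_out(rxn):
                exch[rxn.id] = 0.0
        return FluxVector(net, exch)

    def solve_targets(
        self, targets: dict[str, float], priors: dict[str, float] | None = None
    ) -> np.ndarray:
        """Free coordinates meeting linear targets, closest to the priors.

        ``targets`` maps reaction ids to required net-flux values; remaining
        degrees of freedom stay at the prior values (default: the values of
        the free reactions in the particular solution).
        """
        theta0 = self.v0[self.free_indices].copy()
        if priors:
            for r, val in priors.items():
                if r in self.free_names:
                    theta0[self.free_names.index(r)] = val
        idx = {r: i for i, r in enumerate(self.rxn_ids)}
        rows, vals = [], []
        for r, val in targets.items():
            rows.append(idx[r])
            vals.append(val)
        # net fluxes are affine in theta: v = a + A theta
        A = self.basis @ self._Minv
        a = self.v0 - A @ self.v0[self.free_indices]
        Asub = A[rows]
        resid = np.array(vals) - (a[rows] + Asub @ theta0)
        theta = theta0 + np.linalg.pinv(Asub) @ resid
        v = self.flux_array(theta)
        for r, val in targets.items():
            if abs(v[idx[r]] - val) > 1e-6:
                raise ValueError(f"target flux for {r} unreachable (got {v[idx[r]]:.3f})")
        return theta

    def check_balances(self, flux: FluxVector, atol: float = 1e-8) -> float:
        S, _, rxn_ids = self.network.stoichiometric_matrix()
        v = np.array([flux.net.get(r, 0.0) for r in rxn_ids])
        dev = float(np.max(np.abs(S @ v)))
        if dev > atol:
            raise ValueError(f"node balances violated (max deviation {dev:.3e})")
        return dev


# -- anabolic drains -------------------------------------------------------


def compute_drain_fluxes(
    demand: AnabolicDemand, mu: float, q_s: float
) -> dict[str, float]:
    """Precursor drain fluxes in % of glucose uptake.

    drain_i = demand_i (mmol/g CDW) * mu (1/h) / q_S (mmol/g/h) * 100.
    """
    if mu <= 0 or q_s <= 0:
        raise ValueError("mu and q_s must be positive")
    return {prec: c * mu / q_s * 100.0 for prec, c in demand.effective().items()}


def drain_fixed_fluxes(
    network: MetabolicNetwork, demand: AnabolicDemand, mu: float, q_s: float
) -> dict[str, float]:
    """Fixed-flux dict (uptake at 100 plus drain reactions) for fitting."""
    drains = compute_drain_fluxes(demand, mu, q_s)
    fixed = {network.uptake_reaction: 100.0}
    for rxn in network.drain_reactions:
        fixed[rxn.id] = drains.get(rxn.drain_precursor, 0.0)
    return fixed


# -- bundled data ----------------------------------------------------------


def load_network_spec(text: str, uptake_reaction: str = "upt") -> MetabolicNetwork:
    external: set[str] = set()
    reactions: list[Reaction] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@external"):
            external.update(line.split()[1:])
            continue
        reactions.append(parse_reaction_line(line))
    mets: dict[str, Metabolite] = {}
    for rxn in reactions:
        for am in rxn.atom_maps:
            for met, nc in am.substrate_slots + am.product_slots:
                mets.setdefault(met, Metabolite(met, nc, met not in external))
    return MetabolicNetwork(mets, reactions, uptake_reaction)


def build_network(spec_path=None) -> MetabolicNetwork:
    """Load a network-spec document (default: the bundled central network)."""
    if spec_path is None:
        text = (DATA_DIR / DEFAULT_NETWORK_FILE).read_text()
    else:
        with open(spec_path) as fh:
            text = fh.read()
    return load_network_spec(text)


def load_demands(path=None, **kwargs) -> AnabolicDemand:
    """Load precursor demand coefficients (mmol per g CDW) from a TSV table."""
    import pandas as pd

    if path is None:
        path = DATA_DIR / DEFAULT_DEMAND_FILE
    with (open(path) if isinstance(path, str) else path.open()) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    coeffs = dict(zip(df["precursor"], df["mmol_per_gCDW"].astype(float)))
    sparing = {
        "adenine": coeffs.pop("sparing_3PG_adenine", 0.26),
        "guanine": coeffs.pop("sparing_3PG_guanine", 0.24),
    }
    return AnabolicDemand(coeffs, sparing_3pg=sparing, **kwargs)
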