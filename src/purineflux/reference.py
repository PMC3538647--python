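"""Exhaustive positional-isotopomer reference simulator.

Independent cross-check for the EMU solver: represents every balanced
metabolite by its full 2^n isotopomer distribution and iterates the
steady-state balances to a fixed point.  Exponential in carbon number, so
only suitable for small networks; the EMU path is the production solver.
"""

from __future__ import annotations

import itertools

import numpy as np

from .label_sim import TracerMixture, FragmentDef, _unidirectional_reactions
from .network_model import FluxVector, MetabolicNetwork


def glucose_isotopomers(tracer: TracerMixture, n_carbons: int = 6) -> np.ndarray:
    """Full isotopomer distribution of the tracer glucose (bit 0 = C1)."""
    dist = np.zeros(2**n_carbons)
    for pattern, frac in tracer.components:
        probs = [
            tracer.purity if pattern[i] == "1" else tracer.natural_13c
            for i in range(n_carbons)
        ]
        for bits in itertools.product((0, 1), repeat=n_carbons):
            p = frac
            idx = 0
            for i, b in enumerate(bits):
                p *= probs[i] if b else 1.0 - probs[i]
                idx |= b << i
            dist[idx] += p
    return dist


def simulate_isotopomers(
    network: MetabolicNetwork,
    fluxes: FluxVector,
    inputs: dict[str, np.ndarray],
    tol: float = 1e-13,
    max_iter: int = 200_000,
) -> dict[str, np.ndarray]:
    """Fixed-point solve of the full isotopomer balances.

    ``inputs`` maps unbalanced source metabolites (the tracer substrate) to
    their full isotopomer distributions.
    """
    unirxns = _unidirectional_reactions(network)
    flux = []
    for ur in unirxns:
        fwd, bwd = fluxes.unidirectional(ur.rxn)
        flux.append((fwd if ur.forward else bwd) * ur.weight)
    balanced = set(network.balanced_metabolites)

    nc = {m.id: m.n_carbons for m in network.metabolites.values()}
    dist: dict[str, np.ndarray] = {}
    for met in balanced:
        d = np.zeros(2 ** nc[met])
        d[0] = 1.0
        dist[met] = d
    dist.update({m: np.asarray(v, dtype=float) for m, v in inputs.items()})

    cons: dict[str, float] = {met: 0.0 for met in balanced}
    for k, ur in enumerate(unirxns):
        for met, _ in ur.substrate_slots:
            if met in balanced:
                cons[met] += flux[k]

    # per (unirxn, product slot): function mapping substrate joint patterns
    # to the product pattern
    producers: dict[str, list[tuple[int, int]]] = {}
    for k, ur in enumerate(unirxns):
        for slot, (met, _) in enumerate(ur.product_slots):
            if met in balanced:
                producers.setdefault(met, []).append((k, slot))

    def production(met: str) -> np.ndarray:
        out = np.zeros(2 ** nc[met])
        for k, slot in producers[met]:
            if flux[k] == 0.0:
                continue
            ur = unirxns[k]
            subs = [s for s, _ in ur.substrate_slots]
            spaces = [range(2 ** nc[s]) for s in subs]
            for patterns in itertools.product(*spaces):
                p = flux[k]
                for s_met, pat in zip(subs, patterns):
                    p *= dist[s_met][pat]
                    if p == 0.0:
                        break
                else:
                    idx = 0
                    for pos in range(nc[met]):
                        s_slot, s_pos = ur.source[(slot, pos)]
                        idx |= ((patterns[s_slot] >> s_pos) & 1) << pos
                    out[idx] += p
        return out

    for _ in range(max_iter):
        delta = 0.0
        for met in sorted(balanced):
            if cons[met] <= 0:
                continue
            new = production(met) / cons[met]
            # project back onto the simplex: the mass-1 manifold is unstable
            # under fixed-point iteration (bimolecular terms add the mass
            # perturbations of both substrates), and the true solution has
            # unit mass, so renormalizing stabilizes without biasing.
            total = new.sum()
            if total > 0:
                new /= total
            delta = max(delta, float(np.max(np.abs(new - dist[met]))))
            dist[met] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed-point iteration did not converge")
    return dist


def mdv_from_isotopomers(dist: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    """Marginal mass distribution over the given 0-based carbon positions."""
    n = len(positions)
    out = np.zeros(n + 1)
    for pattern, p in enumerate(dist):
        if p == 0.0:
            continue
        mass = sum((pattern >> pos) & 1 for pos in positions)
        out[mass] += p
    return out


def fragment_mdvs_reference(
    network: MetabolicNetwork,
    fluxes: FluxVector,
    tracer: TracerMixture,
    fragments: list[FragmentDef],
    tracer_metabolite: str = "GLC_ext",
    **kwargs,
) -> dict[str, np.ndarray]:
    """Fragment MDVs via the exhaustive isotopomer simulation."""
    n = network.metabolites[tracer_metabolite].n_carbons
    inputs = {tracer_metabolite: glucose_isotopomers(tracer, n)}
    dists = simulate_isotopomers(network, fluxes, inputs, **kwargs)
    out = {}
    for frag in fragments:
        mdv = np.array([1.0])
        for met, positions in frag.parts:
            mdv = np.convolve(mdv, mdv_from_isotopomers(dists[met], positions))
        out[frag.id] = mdv
    return out
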