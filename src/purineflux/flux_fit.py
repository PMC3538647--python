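"""Flux estimation from labeling data and extracellular rates.

Fits the free net fluxes and exchange parameters of a
:class:`~purineflux.network_model.MetabolicNetwork` by weighted least
squares against corrected fragment MDVs and measured secretion rates,
with statistically varied start values (multi-start local optimization)
and a Monte Carlo resampling of the measurements for flux standard
deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .label_sim import EMUSystem, TracerMixture, simulate_mdvs
from .network_model import (
    AnabolicDemand,
    FluxVector,
    MetabolicNetwork,
    drain_fixed_fluxes,
)

log = logging.getLogger(__name__)

#: default absolute SD of a mass isotopomer fraction (typical GC-MS precision)
DEFAULT_MDV_SD = 0.004

_NET_BOUNDS = {"zwf": (0.0, 110.0), "tre_sec": (0.0, 40.0), "gly_sec": (0.0, 40.0)}
_NET_BOUNDS_DEFAULT = (0.0, 160.0)
_EXCH_BOUND = 0.9
_PENALTY = 1e3


class FitError(RuntimeError):
    pass


@dataclass
class MeasurementSet:
    """Corrected labeling data plus extracellular rates for one culture."""

    mdvs: dict[str, np.ndarray]
    tracer: TracerMixture
    mu: float
    q_s: float
    mdv_sds: dict[str, np.ndarray] = field(default_factory=dict)
    #: secretion fluxes in % of glucose uptake: reaction id -> (value, sd)
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frag, mdv in self.mdvs.items():
            mdv = np.asarray(mdv, dtype=float)
            if np.any(mdv < -1e-9) or abs(mdv.sum() - 1.0) > 1e-6:
                raise ValueError(f"MDV of {frag} is not on the simplex")
            self.mdvs[frag] = mdv
            if frag not in self.mdv_sds:
                self.mdv_sds[frag] = np.full(len(mdv), DEFAULT_MDV_SD)
            if np.any(np.asarray(self.mdv_sds[frag]) < 0):
                raise ValueError(f"negative MDV SD for {frag}")


@dataclass
class StartResult:
    theta: np.ndarray
    exchange: np.ndarray
    ssr: float
    success: bool


@dataclass
class FluxEstimate:
    """Best-fit flux distribution with fit diagnostics."""

    flux: FluxVector
    ssr: float
    n_starts: int
    converged: bool
    global_minimum: bool
    free_names: list[str]
    exchange_names: list[str]
    starts: list[StartResult]
    sd: dict[str, float] | None = None
    mc_mean: dict[str, float] | None = None
    n_mc_runs: int = 0


def _bounds_for(names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([_NET_BOUNDS.get(n, _NET_BOUNDS_DEFAULT)[0] for n in names])
    hi = np.array([_NET_BOUNDS.get(n, _NET_BOUNDS_DEFAULT)[1] for n in names])
    return lo, hi


def _build_problem(
    network: MetabolicNetwork,
    system: EMUSystem,
    measurements: MeasurementSet,
    demand: AnabolicDemand,
    fit_exchange: list[str] | None,
):
    fixed = drain_fixed_fluxes(network, demand, measurements.mu, measurements.q_s)
    param = network.parameterization(fixed)
    if fit_exchange is None:
        fit_exchange = sorted(
            r.id
            for r in network.reactions
            if r.reversible and not network.is_knocked_out(r)
        )
    frag_order = [f.id for f in system.fragments if f.id in measurements.mdvs]
    meas = np.concatenate([measurements.mdvs[f] for f in frag_order])
    # zero SDs mean "unperturbed" for Monte Carlo; floor them for weighting
    sds = np.maximum(
        np.concatenate([measurements.mdv_sds[f] for f in frag_order]), 1e-6
    )
    rate_items = sorted(measurements.rates.items())
    rxn_ids = param.rxn_ids
    irrev_idx = [
        i
        for i, r in enumerate(rxn_ids)
        if not network.reaction(r).reversible and r not in fixed
    ]

    k = param.n_free

    def unpack(p):
        return p[:k], dict(zip(fit_exchange, p[k:]))

    def residuals(p):
        theta, exch = unpack(p)
        flux = param.flux_vector(theta, exch)
        sim = simulate_mdvs(system, flux, measurements.tracer)
        sim_vec = np.concatenate([sim[f] for f in frag_order])
        res = [(sim_vec - meas) / sds]
        v = np.array([flux.net[r] for r in rxn_ids])
        if rate_items:
            res.append(
                np.array(
                    [
                        (flux.net[r] - val) / max(sd, 1e-6)
                        for r, (val, sd) in rate_items
                    ]
                )
            )
        res.append(_PENALTY * np.minimum(v[irrev_idx], 0.0))
        return np.concatenate(res)

    lo_t, hi_t = _bounds_for(param.free_names)
    lo = np.concatenate([lo_t, np.zeros(len(fit_exchange))])
    hi = np.concatenate([hi_t, np.full(len(fit_exchange), _EXCH_BOUND)])
    return param, fit_exchange, residuals, (lo, hi)


def _data_ssr(res: np.ndarray) -> float:
    return float(np.sum(res**2))


def fit_fluxes(
    network: MetabolicNetwork,
    system: EMUSystem,
    measurements: MeasurementSet,
    demand: AnabolicDemand,
    n_starts: int = 10,
    seed: int = 0,
    fit_exchange: list[str] | None = None,
    ssr_global: float = 1e-8,
) -> FluxEstimate:
    """Multi-start weighted least-squares flux estimation.

    Start values are drawn uniformly over the parameter box from the given
    seed; the best of ``n_starts`` local fits is returned.  Iteration over
    starts stops early once a start reaches ``ssr_global`` (an essentially
    perfect fit cannot be improved).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    param, exch_names, residuals, (lo, hi) = _build_problem(
        network, system, measurements, demand, fit_exchange
    )
    rng = np.random.default_rng(seed)
    starts: list[StartResult] = []
    k = param.n_free
    for _ in range(n_starts):
        # draw a start; redraw when it lands on a singular (zero-flux) region
        for _attempt in range(10):
            p0 = lo + rng.uniform(size=len(lo)) * (hi - lo)
            # keep exchange starts away from the hard bound
            p0[k:] = rng.uniform(0.0, 0.7, size=len(lo) - k)
            try:
                if np.all(np.isfinite(residuals(p0))):
                    break
            except Exception:
                continue
        try:
            sol = least_squares(
                residuals, p0, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-10, gtol=1e-10,
            )
            starts.append(
                StartResult(sol.x[:k].copy(), sol.x[k:].copy(), _data_ssr(sol.fun), sol.success)
            )
        except Exception as exc:  # singular labeling system etc.
            log.warning("fit start failed: %s", exc)
            starts.append(StartResult(p0[:k], p0[k:], np.inf, False))
        if starts[-1].success and starts[-1].ssr < ssr_global:
            break
    ok = [s for s in starts if s.success and np.isfinite(s.ssr)]
    if not ok:
        raise FitError(
            "no start converged; per-start SSRs: "
            + ", ".join(f"{s.ssr:.3g}" for s in starts)
        )
    best = min(ok, key=lambda s: s.ssr)
    ranked = sorted(ok, key=lambda s: s.ssr)
    global_min = len(ranked) == 1 or ranked[1].ssr <= max(
        ranked[0].ssr * 1.001, ranked[0].ssr + 1e-9
    )
    flux = param.flux_vector(best.theta, dict(zip(exch_names, best.exchange)))
    return FluxEstimate(
        flux=flux,
        ssr=best.ssr,
        n_starts=len(starts),
        converged=True,
        global_minimum=global_min,
        free_names=list(param.free_names),
        exchange_names=list(exch_names),
        starts=starts,
    )


def monte_carlo(
    network: MetabolicNetwork,
    system: EMUSystem,
    measurements: MeasurementSet,
    demand: AnabolicDemand,
    base: FluxEstimate | None = None,
    n_runs: int = 100,
    seed: int = 0,
    max_failed_fraction: float = 0.2,
) -> FluxEstimate:
    """Measurement-resampling Monte Carlo for per-flux standard deviations.

    Each run perturbs every measured quantity by Gaussian noise at its SD,
    refits from the base solution, and the per-flux mean and SD over runs
    are attached to the returned estimate.
    """
    if base is None:
        base = fit_fluxes(network, system, measurements, demand, seed=seed)
    param, exch_names, _, (lo, hi) = _build_problem(
        network, system, measurements, demand, base.exchange_names
    )
    k = param.n_free
    p_base = np.concatenate(
        [
            [base.flux.net[n] for n in param.free_names],
            [base.flux.exchange.get(n, 0.0) for n in exch_names],
        ]
    )
    p_base = np.clip(p_base, lo, hi)
    rng = np.random.default_rng(seed)
    samples: list[np.ndarray] = []
    failed = 0
    rxn_ids = param.rxn_ids
    for _ in range(n_runs):
        pert = MeasurementSet(
            mdvs={
                f: _perturb_mdv(m, measurements.mdv_sds[f], rng)
                for f, m in measurements.mdvs.items()
            },
            tracer=measurements.tracer,
            mu=measurements.mu,
            q_s=measurements.q_s,
            mdv_sds={f: np.asarray(s).copy() for f, s in measurements.mdv_sds.items()},
            rates={
                r: (val + rng.normal(0.0, sd) if sd > 0 else val, sd)
                for r, (val, sd) in measurements.rates.items()
            },
        )
        _, _, residuals, _ = _build_problem(network, system, pert, demand, exch_names)
        try:
            sol = least_squares(
                residuals, p_base, bounds=(lo, hi), method="trf",
                ftol=1e-9, xtol=1e-9, gtol=1e-9,
            )
            if not sol.success:
                raise FitError("local fit did not converge")
            flux = param.flux_vector(sol.x[:k], dict(zip(exch_names, sol.x[k:])))
            samples.append(np.array([flux.net[r] for r in rxn_ids]))
        except Exception as exc:
            log.warning("Monte Carlo run failed: %s", exc)
            failed += 1
    if failed > max_failed_fraction * n_runs:
        raise FitError(f"{failed}/{n_runs} Monte Carlo runs failed")
    arr = np.array(samples)
    sd = dict(zip(rxn_ids, arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1])))
    mean = dict(zip(rxn_ids, arr.mean(axis=0)))
    return FluxEstimate(
        flux=base.flux,
        ssr=base.ssr,
        n_starts=base.n_starts,
        converged=True,
        global_minimum=base.global_minimum,
        free_names=base.free_names,
        exchange_names=base.exchange_names,
        starts=base.starts,
        sd=sd,
        mc_mean=mean,
        n_mc_runs=len(samples),
    )


def _perturb_mdv(mdv: np.ndarray, sd: np.ndarray, rng) -> np.ndarray:
    noisy = np.maximum(np.asarray(mdv) + rng.normal(0.0, np.asarray(sd)), 0.0)
    total = noisy.sum()
    if total <= 0:
        noisy = np.asarray(mdv).copy()
        total = noisy.sum()
    return noisy / total


def normalize_to_uptake(
    fluxes: FluxVector, q_s: float
) -> tuple[FluxVector, dict[str, float]]:
    """Percent-of-uptake fluxes plus absolute rates (mmol / g CDW / h)."""
    if q_s <= 0:
        raise ValueError("q_s must be positive")
    absolute = {r: v / 100.0 * q_s for r, v in fluxes.net.items()}
    return fluxes, absolute
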