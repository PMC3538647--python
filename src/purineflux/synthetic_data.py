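"""Synthetic datasets emulating the wet-lab measurements.

Generates every input the pipeline consumes: noisy fragment MDV datasets
from a known flux distribution (Gaussian per-fraction noise, renormalized
to the simplex), exponential growth curves with substrate depletion
(multiplicative noise), and replicate purine metabolome tables (lognormal
noise at a given CV).  Every generator is deterministic per seed and
returns or records the ground truth so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .flux_fit import MeasurementSet
from .growth_kinetics import DEFAULT_OD_TO_CDW, GrowthDataset
from .label_sim import EMUSystem, TracerMixture, simulate_mdvs
from .network_model import FluxVector, MetabolicNetwork

#: smallest SD (in % of uptake) assigned to a secretion-rate measurement
RATE_SD_FLOOR = 0.05


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes of the emulated assays."""

    mdv_sd: float = 0.004  # absolute SD per mass isotopomer fraction
    rate_cv: float = 0.02  # relative SD of extracellular rates
    metabolome_cv: float = 0.12  # relative SD of pool concentrations

    def __post_init__(self) -> None:
        if min(self.mdv_sd, self.rate_cv, self.metabolome_cv) < 0:
            raise ValueError("noise magnitudes must be non-negative")


NOISE_FREE = NoiseModel(0.0, 0.0, 0.0)


def generate_mdv_dataset(
    network: MetabolicNetwork,
    system: EMUSystem,
    true_fluxes: FluxVector,
    tracer: TracerMixture,
    mu: float,
    q_s: float,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 1,
    seed: int = 0,
    secreted: tuple[str, ...] = ("gly_sec", "tre_sec"),
) -> tuple[MeasurementSet, dict[str, Any]]:
    """Noisy labeling + rate dataset from a known flux distribution.

    Replicate MDVs are averaged; the attached per-fraction SD is the
    single-replicate noise level (a deliberate, conservative weighting).
    Returns the measurement set and a ground-truth record.
    """
    S, _, rxn_ids = network.stoichiometric_matrix()
    v = np.array([true_fluxes.net.get(r, 0.0) for r in rxn_ids])
    if np.max(np.abs(S @ v)) > 1e-6:
        raise ValueError("true fluxes violate the node balances")
    rng = np.random.default_rng(seed)
    clean = simulate_mdvs(system, true_fluxes, tracer)
    mdvs: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for frag, mdv in clean.items():
        reps = []
        for _ in range(n_replicates):
            noisy = np.maximum(mdv + rng.normal(0.0, noise.mdv_sd, size=len(mdv)), 0.0)
            reps.append(noisy / noisy.sum())
        mdvs[frag] = np.mean(reps, axis=0)
        sds[frag] = np.full(len(mdv), max(noise.mdv_sd, 1e-4))
    rates: dict[str, tuple[float, float]] = {}
    for rxn_id in secreted:
        val = true_fluxes.net.get(rxn_id, 0.0)
        sd = max(noise.rate_cv * abs(val), RATE_SD_FLOOR)
        observed = val + rng.normal(0.0, noise.rate_cv * abs(val)) if noise.rate_cv else val
        rates[rxn_id] = (observed, sd)
    measurements = MeasurementSet(
        mdvs=mdvs, tracer=tracer, mu=mu, q_s=q_s, mdv_sds=sds, rates=rates
    )
    truth = {"fluxes": true_fluxes, "clean_mdvs": clean, "seed": seed, "noise": noise}
    return measurements, truth


def generate_growth_curve(
    mu: float,
    x0: float,
    s0: float,
    y_xs: float,
    times: np.ndarray,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    od_to_cdw: float = DEFAULT_OD_TO_CDW,
) -> GrowthDataset:
    """Exponential growth with substrate depletion.

    X(t) = x0 exp(mu t) (g CDW/L), S(t) = s0 - (X - x0)/y_xs (mM),
    truncated where substrate runs out; multiplicative noise at the rate CV.
    """
    if min(mu, x0, s0, y_xs) <= 0:
        raise ValueError("all growth parameters must be positive")
    times = np.asarray(times, dtype=float)
    x = x0 * np.exp(mu * times)
    s = s0 - (x - x0) / y_xs
    keep = s >= 0
    if keep.sum() < 2:
        raise ValueError("substrate exhausted before the second sample")
    times, x, s = times[keep], x[keep], s[keep]
    rng = np.random.default_rng(seed)
    if noise.rate_cv > 0:
        x = x * np.exp(rng.normal(0.0, noise.rate_cv, size=len(x)))
        s = s * np.exp(rng.normal(0.0, noise.rate_cv, size=len(s)))
    return GrowthDataset(times, x / od_to_cdw, s, od_to_cdw=od_to_cdw)


def generate_metabolome_table(
    strain_profiles: pd.DataFrame | None = None,
    n_replicates: int = 4,
    cv: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate metabolome table with lognormal noise around strain means.

    ``strain_profiles`` is a tidy table (strain, compound, phase, mean, sd,
    flag) as returned by
    :func:`purineflux.metabolome_analysis.load_purine_pools` (the bundled
    reference profiles by default).  Mean-preserving lognormal noise keeps
    concentrations positive; flagged (below-detection / not-determined)
    cells are propagated unchanged with empty values.
    """
    from .metabolome_analysis import load_purine_pools

    if strain_profiles is None:
        strain_profiles = load_purine_pools()
    if strain_profiles.empty:
        raise ValueError("need at least one strain profile")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for _, rec in strain_profiles.iterrows():
        for rep in range(1, n_replicates + 1):
            row = {
                "strain": rec["strain"],
                "compound": rec["compound"],
                "phase": rec["phase"],
                "replicate": rep,
                "flag": rec["flag"],
                "value": np.nan,
            }
            if rec["flag"] == "ok":
                mean = float(rec["mean"])
                if mean < 0:
                    raise ValueError("negative mean concentration")
                if cv == 0:
                    row["value"] = mean
                else:
                    row["value"] = mean * np.exp(
                        rng.normal(-0.5 * sigma**2, sigma)
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def replicate_matrix(table: pd.DataFrame, phase2_strains=("DpurA", "DguaB2")) -> pd.DataFrame:
    """Replicate-level strain x metabolite matrix (rows strain/replicate)."""
    df = table.copy()
    sel = []
    for (strain, compound), grp in df.groupby(["strain", "compound"]):
        phase = 2 if strain in phase2_strains and (grp["phase"] == 2).any() else 1
        sel.append(grp[grp["phase"] == phase])
    df = pd.concat(sel)
    if (df["flag"] == "nd").any():
        dropped = df.loc[df["flag"] == "nd", "compound"].unique()
        df = df[~df["compound"].isin(dropped)]
    df.loc[df["flag"] == "b", "value"] = 0.0
    mat = df.pivot_table(
        index=["strain", "replicate"], columns="compound", values="value"
    )
    return mat.dropna(axis=1)
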