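"""End-to-end orchestration of the analysis stages.

One call runs, for a chosen strain scenario: labeling simulation from the
ground-truth fluxes, corruption to raw GC-MS patterns (natural-abundance
convolution plus noise), natural-abundance correction, multi-start flux
fitting, Monte Carlo statistics, the XADH cofactor report, growth-curve
parameter recovery and the metabolome PCA.  Every output is stamped with
the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import (
    cofactor_balance,
    flux_fit,
    growth_kinetics,
    io,
    label_sim,
    metabolome_analysis,
    ms_correction,
    scenarios,
    synthetic_data,
)


@dataclass
class RunConfig:
    scenario: str = "wild_type"
    seed: int = 0
    n_starts: int = 10
    mc_runs: int = 100
    noise: synthetic_data.NoiseModel = field(default_factory=synthetic_data.NoiseModel)
    apply_ms_correction: bool = True
    out_dir: str | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    truth: flux_fit.FluxVector
    estimate: flux_fit.FluxEstimate
    xadh: cofactor_balance.XadhReport
    growth: growth_kinetics.GrowthParameters
    pca: metabolome_analysis.PcaResult
    groups: "object"
    log: dict


def corrupt_and_correct(
    clean_mdvs: dict[str, np.ndarray],
    fragments: list[label_sim.FragmentDef],
    mdv_sd: float,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Raw-GC-MS round trip: convolve with the natural-abundance pattern,
    add measurement noise, then recover the tracer-carbon MDV.

    Also returns the per-fraction SDs after correction: deconvolution
    amplifies the raw noise by the row norms of the matrix pseudoinverse
    (noticeably for heavily derivatized ions), and the fit must weight
    each fragment by its actual post-correction uncertainty.
    """
    out, sds = {}, {}
    by_id = {f.id: f for f in fragments}
    for frag_id, mdv in clean_mdvs.items():
        frag = by_id[frag_id]
        formula = ms_correction.FragmentFormula.parse(frag.formula)
        matrix = ms_correction.build_correction_matrix(formula, frag.n_carbons)
        raw = matrix.apply(mdv)
        if mdv_sd > 0:
            raw = np.maximum(raw + rng.normal(0.0, mdv_sd, size=len(raw)), 0.0)
        out[frag_id] = ms_correction.correct_mdv(raw, matrix)
        amp = np.linalg.norm(np.linalg.pinv(matrix.matrix), axis=1)
        sds[frag_id] = np.maximum(amp * mdv_sd, 1e-4)
    return out, sds


def run_pipeline(config: RunConfig) -> PipelineResult:
    setup = scenarios.build_scenario(config.scenario)
    sc = setup.scenario
    fragments = label_sim.load_fragments()
    system = label_sim.decompose_emus(setup.network, fragments)
    rng = np.random.default_rng(config.seed)

    # labeling dataset (optionally through the raw-spectrum round trip)
    measurements, truth = synthetic_data.generate_mdv_dataset(
        setup.network, system, setup.true_fluxes, setup.tracer,
        sc.mu, sc.q_s,
        noise=synthetic_data.NoiseModel(0.0, config.noise.rate_cv, config.noise.metabolome_cv)
        if config.apply_ms_correction
        else config.noise,
        seed=config.seed,
    )
    if config.apply_ms_correction:
        measurements.mdvs, measurements.mdv_sds = corrupt_and_correct(
            truth["clean_mdvs"], fragments, config.noise.mdv_sd, rng
        )

    estimate = flux_fit.fit_fluxes(
        setup.network, system, measurements, setup.demand,
        n_starts=config.n_starts, seed=config.seed,
    )
    if config.mc_runs:
        estimate = flux_fit.monte_carlo(
            setup.network, system, measurements, setup.demand,
            base=estimate, n_runs=config.mc_runs, seed=config.seed + 1,
        )

    y_xs = sc.mu / sc.q_s
    xadh = cofactor_balance.compute_xadh(estimate.flux, sc.mu, y_xs)

    # sample over ~25-fold growth so glucose consumption dominates the noise
    curve = synthetic_data.generate_growth_curve(
        sc.mu, x0=0.2, s0=80.0, y_xs=y_xs,
        times=np.linspace(0.0, np.log(25.0) / sc.mu, 10),
        noise=config.noise, seed=config.seed,
    )
    growth = growth_kinetics.fit_growth_parameters(curve)

    table = synthetic_data.generate_metabolome_table(
        cv=config.noise.metabolome_cv, seed=config.seed
    )
    matrix = synthetic_data.replicate_matrix(table)
    pca = metabolome_analysis.run_pca(metabolome_analysis.pareto_scale(matrix), 2)
    strain_scores = pca.scores.groupby(level="strain").mean()
    groups = metabolome_analysis.cluster_groups(strain_scores)

    log = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "scenario": sc.name,
        "ssr": estimate.ssr,
        "global_minimum": estimate.global_minimum,
        "defaults": {
            "mdv_sd": config.noise.mdv_sd,
            "rate_cv": config.noise.rate_cv,
            "metabolome_cv": config.noise.metabolome_cv,
            "exchange_truth": scenarios.DEFAULT_EXCHANGE_TRUTH,
        },
    }
    result = PipelineResult(config, setup.true_fluxes, estimate, xadh, growth, pca, groups, log)
    if config.out_dir:
        _write_bundle(result, setup, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, setup, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_flux_table(out / "fluxes.tsv", result.estimate, q_s=setup.scenario.q_s)
    with open(out / "xadh.tsv", "w") as fh:
        parts = result.xadh.contributions
        fh.write("\t".join([*parts, "anabolic", "total"]) + "\n")
        fh.write(
            "\t".join(
                f"{x:.2f}" for x in [*parts.values(), result.xadh.anabolic, result.xadh.total]
            )
            + "\n"
        )
    with open(out / "growth.tsv", "w") as fh:
        g = result.growth
        fh.write("mu\ty_xs\tq_s\tr_squared\n")
        fh.write(f"{g.mu:.4f}\t{g.y_xs:.4f}\t{g.q_s:.3f}\t{g.r_squared:.5f}\n")
    result.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    result.pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    result.groups.rename("group").to_csv(out / "pca_groups.tsv", sep="\t")
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)
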