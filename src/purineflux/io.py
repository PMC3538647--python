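"""Delimited-table readers/writers for the pipeline's file formats.

All artifacts are plain TSV with header rows: MDV tables
(fragment / mass_shift / fraction / sd), flux tables
(reaction / net_pct / sd_pct / absolute), rate tables (name / value / sd)
and growth time series (time_h / od660 / glucose_mM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .flux_fit import FluxEstimate
from .growth_kinetics import GrowthDataset


def write_mdv_table(path, mdvs: dict[str, np.ndarray], sds=None) -> None:
    rows = []
    for frag, mdv in mdvs.items():
        sd = None if sds is None else sds.get(frag)
        for shift, frac in enumerate(np.asarray(mdv)):
            rows.append(
                {
                    "fragment": frag,
                    "mass_shift": shift,
                    "fraction": frac,
                    "sd": np.nan if sd is None else sd[shift],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mdv_table(path) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    mdvs: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for frag, grp in df.groupby("fragment", sort=False):
        grp = grp.sort_values("mass_shift")
        mdvs[frag] = grp["fraction"].to_numpy(dtype=float)
        if grp["sd"].notna().all():
            sds[frag] = grp["sd"].to_numpy(dtype=float)
    return mdvs, sds


def write_rate_table(path, rates: dict[str, tuple[float, float]]) -> None:
    pd.DataFrame(
        [{"name": n, "value": v, "sd": s} for n, (v, s) in rates.items()]
    ).to_csv(path, sep="\t", index=False)


def read_rate_table(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {r["name"]: (float(r["value"]), float(r["sd"])) for _, r in df.iterrows()}


def write_flux_table(path, estimate: FluxEstimate, q_s: float | None = None) -> None:
    rows = []
    for rxn, net in estimate.flux.net.items():
        rows.append(
            {
                "reaction": rxn,
                "net_pct": net,
                "sd_pct": np.nan if estimate.sd is None else estimate.sd.get(rxn, np.nan),
                "exchange_param": estimate.flux.exchange.get(rxn, np.nan),
                "absolute_mmol_g_h": np.nan if q_s is None else net / 100.0 * q_s,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_growth_table(path, dataset: GrowthDataset) -> None:
    pd.DataFrame(
        {
            "time_h": dataset.time_h,
            "od660": dataset.od660,
            "glucose_mM": dataset.glucose_mM,
        }
    ).to_csv(path, sep="\t", index=False)


def read_growth_table(path, od_to_cdw: float | None = None) -> GrowthDataset:
    df = pd.read_csv(path, sep="\t", comment="#")
    kwargs = {} if od_to_cdw is None else {"od_to_cdw": od_to_cdw}
    return GrowthDataset(
        df["time_h"].to_numpy(),
        df["od660"].to_numpy(),
        df["glucose_mM"].to_numpy(),
        **kwargs,
    )
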