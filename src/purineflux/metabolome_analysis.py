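"""Purine-pool phenotyping: fold changes, pareto scaling and PCA.

Works on strain x metabolite concentration tables (umol per g CDW) with
below-detection ('b') and not-determined ('nd') flags.  Pareto scaling
mean-centers each metabolite and divides by the square root of its sample
standard deviation — a compromise between unit-variance scaling (which
inflates near-noise metabolites) and no scaling (which lets the largest
pools dominate).  PCA is an eigendecomposition of the covariance of the
scaled matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import DATA_DIR

TABLE1_FILE = "table1_purine_pools.csv"
TABLE2_FILE = "table2_growth.csv"

#: strains whose phase-2 pools are the representative (steady) ones
PHASE2_STRAINS = ("DpurA", "DguaB2")

STRAIN_ORDER = [
    "ATCC13032",
    "Dpgi",
    "purF_K348Q",
    "DpurA",
    "DguaB2",
    "DpurA_DguaB2",
    "DpurA_DguaB2_purF_Dpgi",
]


def load_purine_pools(path=None) -> pd.DataFrame:
    """Tidy purine-pool concentration table (bundled reference by default)."""
    src = DATA_DIR / TABLE1_FILE if path is None else path
    with (open(src) if isinstance(src, str) else src.open()) as fh:
        return pd.read_csv(fh, comment="#")


def load_growth_parameters(path=None) -> pd.DataFrame:
    src = DATA_DIR / TABLE2_FILE if path is None else path
    with (open(src) if isinstance(src, str) else src.open()) as fh:
        return pd.read_csv(fh, comment="#")


def strain_mean_matrix(
    pools: pd.DataFrame | None = None,
    phase2_strains: tuple[str, ...] = PHASE2_STRAINS,
) -> pd.DataFrame:
    """Strain x metabolite concentration matrix for multivariate analysis.

    Below-detection cells become 0; metabolites not determined in some
    strains are dropped column-wise; for the strains with transient pools
    the phase-2 concentrations are used where reported.
    """
    df = load_purine_pools() if pools is None else pools
    rows: dict[str, dict[str, float]] = {}
    dropped: set[str] = set()
    for (strain, compound), grp in df.groupby(["strain", "compound"]):
        phase = 2 if strain in phase2_strains and (grp["phase"] == 2).any() else 1
        rec = grp[grp["phase"] == phase].iloc[0]
        if rec["flag"] == "nd":
            dropped.add(compound)
            continue
        value = 0.0 if rec["flag"] == "b" else float(rec["mean"])
        rows.setdefault(strain, {})[compound] = value
    mat = pd.DataFrame.from_dict(rows, orient="index").drop(
        columns=list(dropped), errors="ignore"
    )
    order = [s for s in STRAIN_ORDER if s in mat.index]
    return mat.loc[order].dropna(axis=1)


# -- fold / percent changes ------------------------------------------------

_ROUNDERS = {
    None: lambda x: x,
    "integer": lambda x: float(round(x)),
    "nearest5": lambda x: 5.0 * round(x / 5.0),
    "nearest10": lambda x: 10.0 * round(x / 10.0),
    "tenth": lambda x: round(x, 1),
}


def fold_change(sample_conc: float, reference_conc: float, rounding=None) -> float:
    """sample / reference, optionally rounded for reporting."""
    if reference_conc <= 0:
        raise ValueError("reference concentration must be positive; report absolute values instead")
    return _ROUNDERS[rounding](sample_conc / reference_conc)


def percent_change(sample_conc: float, reference_conc: float, rounding=None) -> float:
    """(sample - reference) / reference * 100, optionally rounded."""
    if reference_conc <= 0:
        raise ValueError("reference concentration must be positive; report absolute values instead")
    return _ROUNDERS[rounding]((sample_conc - reference_conc) / reference_conc * 100.0)


# -- pareto scaling and PCA ------------------------------------------------


def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-center and divide by sqrt(sample SD), dropping constant columns."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to scale")
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance columns: {list(matrix.columns[~keep])}",
            stacklevel=2,
        )
    m = matrix.loc[:, keep]
    return (m - m.mean(axis=0)) / np.sqrt(sd[keep])


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_variance: np.ndarray  # fractions over returned components

    @property
    def explained_percent(self) -> np.ndarray:
        return 100.0 * self.explained_variance


def run_pca(scaled: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA via SVD of the (already scaled) data matrix.

    Components are ordered by decreasing variance; each loading vector's
    sign is fixed so its largest-magnitude entry is positive.
    """
    X = scaled.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp or n_components < 1:
        raise ValueError(f"n_components must be in 1..{max_comp}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("degenerate matrix: no variance")
    comps = [f"PC{i+1}" for i in range(n_components)]
    loadings = Vt[:n_components].T.copy()
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=pd.DataFrame(scores, index=scaled.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=scaled.columns, columns=comps),
        explained_variance=var[:n_components] / total,
    )


def cluster_groups(
    scores: pd.DataFrame,
    reference: str | None = None,
    components: tuple[str, ...] = ("PC1", "PC2"),
) -> pd.Series:
    """Two-group partition of strains in the score plane.

    Group 'A' collects the strains whose purine phenotype is
    indistinguishable from the reference strain (the first row by
    default, i.e. the unperturbed wild type): distances to the reference
    are sorted and split at their largest gap.  Everything beyond the gap
    is group 'B'.  Identical rows give a single group; the result does
    not depend on row order.
    """
    cols = [c for c in components if c in scores.columns]
    X = scores[cols].to_numpy(dtype=float)
    ref = scores.index[0] if reference is None else reference
    d = np.linalg.norm(X - scores.loc[ref, cols].to_numpy(dtype=float), axis=1)
    scale = max(d.max(), 1.0e-12)
    if d.max() - d.min() <= 1e-9 * scale:
        return pd.Series("A", index=scores.index)
    ds = np.sort(d)
    gaps = np.diff(ds)
    cut = ds[np.argmax(gaps)] + gaps.max() / 2.0
    return pd.Series(np.where(d < cut, "A", "B"), index=scores.index)


def confidence_ellipse(
    points: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, float, float, float]:
    """(center, width, height, angle_deg) of a covariance confidence ellipse."""
    from scipy.stats import chi2

    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    vals, vecs = np.linalg.eigh(cov)
    scale = chi2.ppf(level, df=2)
    width, height = 2.0 * np.sqrt(scale * vals[::-1])
    angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
    return center, float(width), float(height), angle
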