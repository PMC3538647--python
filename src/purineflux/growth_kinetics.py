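"""Growth parameters from culture time series.

Computes the specific growth rate mu (1/h) from ln-linear regression of
biomass over a balanced-growth window, the biomass yield Y_x/s (g CDW per
mmol glucose) from biomass formed versus glucose consumed, and the
specific glucose uptake rate q_S = mu / Y_x/s (mmol / g CDW / h).
Optical density converts to cell dry weight by a gravimetric correlation
factor (default 0.414 g CDW per OD660 unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_OD_TO_CDW = 0.414


@dataclass
class GrowthDataset:
    time_h: np.ndarray
    od660: np.ndarray
    glucose_mM: np.ndarray
    od_to_cdw: float = DEFAULT_OD_TO_CDW

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od660 = np.asarray(self.od660, dtype=float)
        self.glucose_mM = np.asarray(self.glucose_mM, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.od660 <= 0):
            raise ValueError("OD readings must be positive")

    @property
    def cdw(self) -> np.ndarray:
        """Biomass concentration in g CDW per liter."""
        return self.od660 * self.od_to_cdw


@dataclass
class GrowthParameters:
    mu: float
    y_xs: float
    q_s: float
    r_squared: float = float("nan")
    window: tuple[int, int] | None = None


def select_exponential_window(
    dataset: GrowthDataset, min_points: int = 3, r2_threshold: float = 0.995
) -> tuple[int, int]:
    """Longest index span with ln-linear biomass (R^2 >= threshold)."""
    t, lnx = dataset.time_h, np.log(dataset.cdw)
    n = len(t)
    best = (0, min(n, min_points))
    best_len = 0
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            r = stats.linregress(t[i:j], lnx[i:j])
            if r.rvalue**2 >= r2_threshold and (j - i) > best_len:
                best, best_len = (i, j), j - i
    return best


def fit_growth_rate(
    dataset: GrowthDataset, window: tuple[int, int] | None = None
) -> GrowthParameters:
    """mu from the slope of ln(CDW) versus time (least squares)."""
    if window is None:
        window = select_exponential_window(dataset)
    i, j = window
    if j - i < 3:
        raise ValueError("need at least 3 points in the window")
    r = stats.linregress(dataset.time_h[i:j], np.log(dataset.cdw[i:j]))
    mu = float(r.slope)
    return GrowthParameters(
        mu=mu, y_xs=float("nan"), q_s=float("nan"),
        r_squared=float(r.rvalue**2), window=window,
    )


def compute_yield(
    dataset: GrowthDataset, window: tuple[int, int] | None = None
) -> float:
    """Y_x/s (g CDW per mmol glucose): slope of CDW formed vs glucose consumed.

    Fitted as the (negative) slope of CDW against glucose with an
    intercept, which is the same estimand as a through-origin fit of the
    differences but does not anchor on the (noisy) first sample.
    """
    i, j = window if window else (0, len(dataset.time_h))
    x = dataset.cdw[i:j]
    s = dataset.glucose_mM[i:j]
    trend = stats.linregress(dataset.time_h[i:j], s).slope
    if trend >= 0 or s[-1] >= s[0]:
        raise ValueError("glucose must be decreasing over the window")
    if np.ptp(s) == 0:
        raise ValueError("no glucose consumption in the window")
    return float(-stats.linregress(s, x).slope)


def specific_uptake(mu: float, y_xs: float) -> float:
    """q_S = mu / Y_x/s (mmol glucose per g CDW per h)."""
    if y_xs <= 0:
        raise ValueError("y_xs must be positive")
    return mu / y_xs


def fit_growth_parameters(dataset: GrowthDataset) -> GrowthParameters:
    """mu, Y_x/s and q_S from one culture time series."""
    window = select_exponential_window(dataset)
    params = fit_growth_rate(dataset, window)
    y_xs = compute_yield(dataset, window)
    return GrowthParameters(
        mu=params.mu, y_xs=y_xs, q_s=specific_uptake(params.mu, y_xs),
        r_squared=params.r_squared, window=window,
    )
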