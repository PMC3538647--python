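"""Natural-abundance correction of GC-MS mass isotopomer measurements.

Raw fragment spectra contain mass shifts contributed by natural heavy
isotopes of the derivatization reagent and of all fragment atoms outside
the tracer carbon skeleton (H, N, O, Si, S and non-skeleton C).  The
correction builds the isotope-pattern convolution of those atoms, places
it in every column of a shift matrix and recovers the tracer-only MDV by
non-negative least squares.  Natural 13C in the tracer carbons themselves
is deliberately left in place: the forward simulation accounts for it via
the tracer purity and natural-abundance terms, so removing it here would
correct it twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import nnls

from . import DATA_DIR

DEFAULT_ISOTOPE_FILE = "isotopes.tsv"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class FragmentFormula:
    """Atom counts of the measured ion beyond the tracer-carbon skeleton."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    Si: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts().values()):
            raise ValueError("atom counts must be non-negative")

    def counts(self) -> dict[str, int]:
        return {"C": self.C, "H": self.H, "N": self.N, "O": self.O,
                "Si": self.Si, "S": self.S}

    @classmethod
    def parse(cls, formula: str) -> "FragmentFormula":
        """Parse e.g. 'C8H26N1O2Si2' (missing count means 1)."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(**counts)


@lru_cache(maxsize=1)
def isotope_patterns(path=None) -> dict[str, np.ndarray]:
    """Per-element natural isotope mass-shift patterns from the bundled table."""
    import pandas as pd

    src = DATA_DIR / DEFAULT_ISOTOPE_FILE if path is None else path
    with (open(src) if isinstance(src, str) else src.open()) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    patterns: dict[str, np.ndarray] = {}
    for element, grp in df.groupby("element"):
        arr = np.zeros(int(grp["shift"].max()) + 1)
        for _, row in grp.iterrows():
            arr[int(row["shift"])] = float(row["abundance"])
        patterns[element] = arr / arr.sum()
    return patterns


@dataclass
class CorrectionMatrix:
    """Maps a theoretical tracer-carbon MDV to the observed mass pattern.

    Shape (n+1+k, n+1): column j is the natural-abundance pattern of the
    non-tracer atoms shifted down by j mass units; k extra rows retain the
    overflow shifts so little probability mass is truncated.
    """

    matrix: np.ndarray
    n_tracer_carbons: int

    @property
    def n_extra_shifts(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]

    def apply(self, mdv: np.ndarray) -> np.ndarray:
        """Forward-convolve a theoretical MDV into an observed pattern."""
        return self.matrix @ np.asarray(mdv, dtype=float)


def natural_pattern(formula: FragmentFormula) -> np.ndarray:
    """Mass-shift distribution of all non-tracer atoms (convolution)."""
    patterns = isotope_patterns()
    out = np.array([1.0])
    for element, count in formula.counts().items():
        for _ in range(count):
            out = np.convolve(out, patterns[element])
    return out


def build_correction_matrix(
    formula: FragmentFormula, n_tracer_carbons: int, n_extra_shifts: int = 4
) -> CorrectionMatrix:
    if n_tracer_carbons < 1:
        raise ValueError("n_tracer_carbons must be >= 1")
    pattern = natural_pattern(formula)
    n_rows = n_tracer_carbons + 1 + n_extra_shifts
    M = np.zeros((n_rows, n_tracer_carbons + 1))
    for j in range(n_tracer_carbons + 1):
        avail = min(len(pattern), n_rows - j)
        M[j : j + avail, j] = pattern[:avail]
    return CorrectionMatrix(M, n_tracer_carbons)


def correct_mdv(raw: np.ndarray, matrix: CorrectionMatrix) -> np.ndarray:
    """Recover the tracer-carbon MDV from an observed mass pattern.

    Non-negative least squares followed by renormalization to the simplex;
    the raw vector may be shorter than the matrix rows (missing overflow
    shifts are treated as unobserved zero intensity).
    """
    raw = np.asarray(raw, dtype=float)
    M = matrix.matrix
    if raw.ndim != 1 or len(raw) > M.shape[0] or len(raw) < M.shape[1]:
        raise ValueError(
            f"raw MDV length {len(raw)} incompatible with correction matrix {M.shape}"
        )
    if np.all(raw == 0):
        raise ValueError("all-zero raw measurement")
    if len(raw) < M.shape[0]:
        raw = np.concatenate([raw, np.zeros(M.shape[0] - len(raw))])
    x, _ = nnls(M, raw)
    total = x.sum()
    if total <= 0:
        raise ValueError("correction produced an empty MDV")
    return x / total
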