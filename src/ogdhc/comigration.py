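"""Complexome-profiling analysis: migration profiles, calibration, peaks.

In complexome profiling, native complexes are separated on a blue-native gel
that is cut into S slices; per-slice MS quantification gives each protein a
migration profile over the slice axis.  Migration distance on BN-PAGE is
log-linear in complex mass, so a small set of markers (slice, known mass)
calibrates slice index to apparent mass.  Proteins that belong to one
complex co-migrate: their profiles peak at the same slice and correlate
strongly.  The apparent mass of the complex is read off the common peak.

Slice indices are 1-based, matching gel-slice numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MassCalibration",
    "PeakCall",
    "normalize_profiles",
    "calibrate_mass",
    "estimate_apparent_mass",
    "comigration_score",
]


@dataclass
class MassCalibration:
    """Log-linear fit: log10(mass kDa) = slope * slice + intercept."""

    slope: float
    intercept: float
    markers: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def mass_kda(self, slice_index: float) -> float:
        return float(10.0 ** (self.slope * slice_index + self.intercept))

    def slice_for_mass(self, mass_kda: float) -> float:
        if mass_kda <= 0:
            raise ValueError("mass must be positive")
        return float((np.log10(mass_kda) - self.intercept) / self.slope)


@dataclass
class PeakCall:
    """One profile peak: fractional slice position, height, apparent mass."""

    slice: float
    height: float
    apparent_mass_kda: float

    def __post_init__(self) -> None:
        if not 0 < self.height <= 1:
            raise ValueError("peak height must be in (0, 1] on a normalized profile")


def normalize_profiles(matrix: pd.DataFrame, method: str = "max") -> tuple[pd.DataFrame, list[str]]:
    """Scale each protein row to max 1 (or to unit sum with ``method='sum'``).

    Returns the normalized matrix and the list of all-zero rows, which are
    left unchanged and flagged rather than divided by zero.  Negative
    intensities are an error.
    """
    if (matrix.values < 0).any():
        raise ValueError("negative intensities in profile matrix")
    if method not in {"max", "sum"}:
        raise ValueError(f"unknown normalization {method!r}")
    scale = matrix.max(axis=1) if method == "max" else matrix.sum(axis=1)
    flagged = list(matrix.index[scale == 0])
    safe = scale.replace(0, 1.0)
    return matrix.div(safe, axis=0), flagged


def calibrate_mass(markers: Sequence[tuple[float, float]]) -> MassCalibration:
    """Least-squares fit of log10(mass kDa) against slice index.

    Needs at least two markers at distinct slices; masses must be positive.
    """
    markers = list(markers)
    slices = np.asarray([m[0] for m in markers], dtype=float)
    masses = np.asarray([m[1] for m in markers], dtype=float)
    if len(set(slices.tolist())) < 2:
        raise ValueError("need markers at >= 2 distinct slices")
    if (masses <= 0).any():
        raise ValueError("marker masses must be positive")
    slope, intercept = np.polyfit(slices, np.log10(masses), 1)
    return MassCalibration(float(slope), float(intercept), markers)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic interpolation around the discrete maximum at i (0-based)."""
    if i == 0 or i == len(y) - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = y1 - 0.25 * (y0 - y2) * delta
    return i + delta, float(min(height, 1.0))


def estimate_apparent_mass(
    profile: Sequence[float] | np.ndarray | pd.Series,
    calibration: MassCalibration,
    min_height: float = 0.2,
    smooth: bool = False,
) -> list[PeakCall]:
    """Call peaks on a normalized migration profile and convert to mass.

    Local maxima above ``min_height`` are refined to sub-slice positions by
    3-point parabolic interpolation and converted to apparent mass via the
    calibration.  Peaks are returned sorted by height, tallest first.  A
    flat or empty profile yields an empty list.  ``smooth`` applies a
    moving-average window of 3 before detection (off by default).
    """
    y = np.asarray(profile, dtype=float)
    if y.size == 0 or np.all(y == y.flat[0]):
        return []
    if y.max() > 1 + 1e-9:
        raise ValueError("profile must be normalized (max <= 1) before peak calling")
    if smooth:
        kernel = np.ones(3) / 3.0
        y = np.convolve(y, kernel, mode="same")
    peaks: list[PeakCall] = []
    for i in range(y.size):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < y.size - 1 else -np.inf
        # plateau tie-break: the left edge of a flat top is the peak
        if y[i] > left and y[i] >= right and y[i] >= min_height:
            pos0, height = _parabolic_refine(y, i)
            slice_1based = pos0 + 1.0
            peaks.append(
                PeakCall(
                    slice=slice_1based,
                    height=height,
                    apparent_mass_kda=calibration.mass_kda(slice_1based),
                )
            )
    peaks.sort(key=lambda p: -p.height)
    return peaks


def comigration_score(matrix: pd.DataFrame, proteins: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of normalized migration profiles.

    Symmetric with unit diagonal for non-constant profiles; a zero-variance
    profile has undefined correlations, reported as NaN.  Requires at least
    two proteins and three slices.
    """
    if proteins is not None:
        missing = [p for p in proteins if p not in matrix.index]
        if missing:
            raise KeyError(f"proteins not in matrix: {missing}")
        matrix = matrix.loc[list(proteins)]
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 proteins for co-migration scoring")
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 slices for co-migration scoring")
    normalized, _ = normalize_profiles(matrix)
    corr = normalized.T.corr(method="pearson")
    # pandas leaves the diagonal of a constant row at 1.0 in some versions;
    # make undefined correlations explicit
    variances = normalized.var(axis=1)
    for protein, var in variances.items():
        if var == 0:
            corr.loc[protein, :] = np.nan
            corr.loc[:, protein] = np.nan
    return corr


def load_profile_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a protein × slice TSV (first column protein id, columns slices)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = [int(c) for c in df.columns]
    return df


def load_markers(path, sep: str = "\t") -> list[tuple[float, float]]:
    """Read a marker TSV with columns ``slice`` and ``mass_kda``."""
    df = pd.read_csv(path, sep=sep)
    if not {"slice", "mass_kda"}.issubset(df.columns):
        raise ValueError(f"marker file needs columns slice, mass_kda; got {list(df.columns)}")
    return [(float(r["slice"]), float(r["mass_kda"])) for _, r in df.iterrows()]
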