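"""In-memory containers shared by all pipeline stages.

The pipeline moves through three representations:

``FidSet``
    complex time-domain signals (free induction decays), one row per
    sample, on a shared dwell-time grid;
``SpectrumSet``
    frequency-domain spectra on a shared chemical-shift (ppm) axis,
    complex until phase correction and real afterwards;
``FeatureMatrix``
    the samples x bins table produced by binning and normalization.

All containers validate their invariants on construction, so a stage can
assume a well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StageError


def _check_ids(sample_ids: list[str], n_rows: int) -> list[str]:
    ids = [str(s) for s in sample_ids]
    if len(ids) != n_rows:
        raise StageError(
            f"sample_ids has {len(ids)} entries for {n_rows} rows"
        )
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise StageError(f"duplicate sample ids: {dupes}")
    return ids


@dataclass
class FidSet:
    """A cohort of complex free induction decays on a shared time grid.

    Parameters
    ----------
    data
        Complex matrix, shape ``(n_samples, n_points)``.
    dwell_time
        Sampling interval in seconds (reciprocal of the sweep width in Hz).
    sample_ids
        Ordered sample keys, one per row.
    """

    data: np.ndarray
    dwell_time: float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.complex128))
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise StageError("FidSet.data must be a 2-D matrix with >= 1 column")
        if not np.all(np.isfinite(self.data)):
            raise StageError("FidSet.data contains non-finite values")
        if not self.dwell_time > 0:
            raise StageError("dwell_time must be positive")
        self.sample_ids = _check_ids(self.sample_ids, self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        """Time grid ``t_k = k * dwell_time`` in seconds."""
        return np.arange(self.n_points) * self.dwell_time

    def with_data(self, data: np.ndarray) -> "FidSet":
        """A copy of this set with the signal matrix replaced."""
        return FidSet(data=data, dwell_time=self.dwell_time,
                      sample_ids=list(self.sample_ids))


@dataclass
class SpectrumSet:
    """Frequency-domain spectra on one shared ppm axis.

    The axis follows NMR plotting convention: strictly decreasing,
    high ppm first.  Intensities stay complex until phase correction.
    """

    intensities: np.ndarray
    ppm_axis: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities))
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.ppm_axis.ndim != 1:
            raise StageError("ppm_axis must be 1-D")
        if self.intensities.shape[1] != self.ppm_axis.size:
            raise StageError(
                f"axis length {self.ppm_axis.size} != row length "
                f"{self.intensities.shape[1]}"
            )
        if self.ppm_axis.size > 1 and not np.all(np.diff(self.ppm_axis) < 0):
            raise StageError("ppm_axis must be strictly decreasing")
        if not np.all(np.isfinite(self.intensities)):
            raise StageError("intensities contain non-finite values")
        self.sample_ids = _check_ids(self.sample_ids, self.intensities.shape[0])

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def is_real(self) -> bool:
        return not np.iscomplexobj(self.intensities)

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(intensities=intensities,
                           ppm_axis=self.ppm_axis.copy(),
                           sample_ids=list(self.sample_ids))

    def ppm_step(self) -> float:
        """Grid spacing in ppm (positive scalar)."""
        return float(abs(np.median(np.diff(self.ppm_axis))))


@dataclass
class FeatureMatrix:
    """Samples x bins area table with decreasing ppm bin edges."""

    values: np.ndarray
    bin_edges: np.ndarray
    sample_ids: list[str]
    partial_last_bin: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise StageError("bin_edges must hold at least two edges")
        if not np.all(np.diff(self.bin_edges) < 0):
            raise StageError("bin_edges must be strictly decreasing (ppm)")
        if self.values.shape[1] != self.bin_edges.size - 1:
            raise StageError("values column count must equal len(bin_edges) - 1")
        if not np.all(np.isfinite(self.values)):
            raise StageError("feature values contain non-finite entries")
        self.sample_ids = _check_ids(self.sample_ids, self.values.shape[0])

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: rows = samples, columns = bin centers in ppm."""
        cols = [f"{c:.5f}" for c in self.bin_centers]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(values=values, bin_edges=self.bin_edges.copy(),
                             sample_ids=list(self.sample_ids),
                             partial_last_bin=self.partial_last_bin)


@dataclass
class PhaseResult:
    """Zero-order phase angles recovered per sample.

    ``angles`` holds the rotation (radians, in ``(-pi, pi]``) that was
    applied to each spectrum; ``objectives`` the optimized criterion value.
    """

    angles: np.ndarray
    objectives: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.objectives = np.asarray(self.objectives, dtype=float)
        if self.angles.shape != self.objectives.shape:
            raise StageError("angles and objectives must have the same shape")
        if not np.all(np.isfinite(self.objectives)):
            raise StageError("phase objectives must be finite")
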