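"""Feature extraction: equidistant binning and cohort normalization."""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .containers import FeatureMatrix, SpectrumSet
from .errors import StageError

NORMALIZE_METHODS = ("pqn", "total_area", "snv")


def binning(spectra: SpectrumSet, bin_width: float = 0.04) -> FeatureMatrix:
    """Integrate each spectrum over consecutive fixed-width ppm bins.

    Bins of exactly *bin_width* ppm start at the high-ppm end of the
    axis; a trailing partial bin, if any, is kept and flagged.  Each
    feature is the trapezoidal integral of the intensity over the bin's
    ppm span (bin edges falling between grid points are handled by
    linear interpolation of the cumulative integral, which makes the
    bin sum telescope exactly to the whole-spectrum integral).
    """
    if not spectra.is_real:
        raise StageError("binning expects real intensities")
    axis = spectra.ppm_axis
    if axis.size < 2:
        raise StageError("binning needs at least two axis points")
    step = spectra.ppm_step()
    if not bin_width > 0:
        raise StageError("bin_width must be positive")
    if bin_width < step:
        raise StageError(
            f"bin_width {bin_width} ppm is smaller than the grid step "
            f"{step:.2e} ppm"
        )
    span = float(axis[0] - axis[-1])
    if bin_width >= span:
        raise StageError("bin_width must be smaller than the axis span")

    # integrate on x = distance from the high-ppm end (increasing)
    x = axis[0] - axis
    n_full = int(np.floor(span / bin_width + 1e-9))
    edges_x = bin_width * np.arange(n_full + 1)
    partial = span - n_full * bin_width > 1e-9 * bin_width
    if partial:
        edges_x = np.append(edges_x, span)

    cum = cumulative_trapezoid(spectra.intensities, x, axis=1, initial=0.0)
    values = np.empty((spectra.n_samples, edges_x.size - 1))
    for i in range(spectra.n_samples):
        at_edges = np.interp(edges_x, x, cum[i])
        values[i] = np.diff(at_edges)

    return FeatureMatrix(values=values, bin_edges=axis[0] - edges_x,
                         sample_ids=list(spectra.sample_ids),
                         partial_last_bin=bool(partial))


def _total_area(values: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    sums = values.sum(axis=1)
    bad = np.flatnonzero(sums == 0)
    if bad.size:
        raise StageError(
            f"total-area normalization: zero row sum for sample "
            f"{sample_ids[bad[0]]!r}"
        )
    return values / sums[:, None]


def normalize(features: FeatureMatrix, method: str = "pqn") -> FeatureMatrix:
    """Normalize the feature matrix across samples.

    ``total_area`` divides each row by its sum.  ``snv`` centres each
    row by its mean and scales by its (population) standard deviation.
    ``pqn`` — probabilistic quotient normalization — first total-area
    normalizes, takes the element-wise median spectrum as reference,
    and divides each row by the median of its feature-wise quotients
    against that reference (features where the reference is ~0, e.g. a
    removed water band, are excluded); this removes per-sample dilution.
    """
    if method not in NORMALIZE_METHODS:
        raise StageError(f"unknown normalization {method!r}; "
                         f"valid: {', '.join(NORMALIZE_METHODS)}")
    x = features.values.astype(float)
    ids = features.sample_ids
    if method == "total_area":
        return features.with_values(_total_area(x, ids))
    if method == "snv":
        sd = x.std(axis=1, ddof=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise StageError(f"snv: constant row for sample {ids[bad[0]]!r}")
        return features.with_values((x - x.mean(axis=1)[:, None])
                                    / sd[:, None])
    # pqn
    if x.shape[0] < 2:
        raise StageError("pqn needs at least 2 samples for a cohort reference")
    ta = _total_area(x, ids)
    ref = np.median(ta, axis=0)
    eps = 1e-12 * ref.max()
    mask = ref > eps
    if not mask.any():
        raise StageError("pqn: reference spectrum is all ~zero")
    quotients = ta[:, mask] / ref[mask]
    med = np.median(quotients, axis=1)
    return features.with_values(ta / med[:, None])
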