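"""Frequency-domain preprocessing.

Covers the transform itself (FFT plus ppm-axis construction), internal
referencing against the 0-ppm standard, automatic zero-order phase
correction, interfering-region removal, penalized-least-squares
baseline correction (ALS / ARPLS / AIRPLS), negative-value zeroing and
spectral window selection.

Conventions used throughout:

* the ppm axis is strictly decreasing (high field left), shared by all
  samples; ppm intervals are closed and interpreted on chemical-shift
  values, not indices;
* the forward FFT is unnormalized, so Parseval reads
  ``sum |fid|^2 = (1/m) sum |spectrum|^2``; the first FID point is not
  halved;
* region removal zeroes intensities in place so the axis stays uniform
  for alignment and binning — window selection is the only excising
  step.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import FidSet, PhaseResult, SpectrumSet
from .errors import StageError
from .time_domain import whittaker_smooth

BASELINE_METHODS = ("als", "arpls", "airpls")

#: Preset interfering regions (ppm): urine drops urea/maleic acid/water,
#: serum only the water resonance.
REGION_PRESETS = {"urine": [(4.5, 6.1)], "serum": [(4.5, 5.1)]}


def fourier_transform(fids: FidSet, params: pd.DataFrame) -> SpectrumSet:
    """Transform FIDs to spectra on a shared chemical-shift axis.

    Each row is FFT'd and centre-shifted; the frequency grid ``f_j``
    (Hz, centred on the carrier) maps to chemical shift via
    ``delta_j = (f_j + O1) / SFO1``, ordered high-to-low ppm.  Complex
    values are retained for downstream phase correction.  Requires
    identical ``SW_h``/``SFO1``/``O1`` across the cohort.
    """
    for key in ("SW_h", "SFO1"):
        if key not in params.columns:
            raise StageError(f"fourier_transform: acqus table lacks {key}")
    sw = params["SW_h"].astype(float).to_numpy()
    sfo1 = params["SFO1"].astype(float).to_numpy()
    o1 = (params["O1"].astype(float).to_numpy()
          if "O1" in params.columns else np.zeros_like(sw))
    if (np.ptp(sw) > 1e-9 * sw[0] or np.ptp(sfo1) > 1e-9 * sfo1[0]
            or np.ptp(o1) > 1e-6):
        raise StageError("fourier_transform: samples disagree on "
                         "SW_h/SFO1/O1; a shared axis is impossible")

    m = fids.n_points
    spectra = np.fft.fftshift(np.fft.fft(fids.data, axis=1), axes=1)
    freq_hz = np.fft.fftshift(np.fft.fftfreq(m, d=fids.dwell_time))
    ppm = (freq_hz + o1[0]) / sfo1[0]
    # reverse to the decreasing-ppm plotting convention
    return SpectrumSet(intensities=spectra[:, ::-1], ppm_axis=ppm[::-1],
                       sample_ids=list(fids.sample_ids))


def _axis_window_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (axis >= lo) & (axis <= hi)


def internal_referencing(spectra: SpectrumSet, ppm_min: float = -0.2,
                         ppm_max: float = 0.2, *,
                         return_offsets: bool = False):
    """Calibrate each spectrum so the reference peak sits at 0 ppm.

    The maximum-magnitude point inside ``[ppm_min, ppm_max]`` is located
    per sample and the sample's intensities are shifted by whole grid
    points so that maximum lands on the axis point nearest 0 ppm.  The
    shared axis is unchanged; vacated edge points replicate the edge
    value.  With ``return_offsets=True`` the per-sample point shifts are
    returned alongside.
    """
    mask = _axis_window_mask(spectra.ppm_axis, ppm_min, ppm_max)
    if not mask.any():
        raise StageError(
            f"reference window [{ppm_min}, {ppm_max}] ppm does not "
            "overlap the axis"
        )
    window_idx = np.flatnonzero(mask)
    target = int(np.argmin(np.abs(spectra.ppm_axis)))
    out = np.empty_like(spectra.intensities)
    offsets = np.zeros(spectra.n_samples, dtype=int)
    mag = np.abs(spectra.intensities)
    for i in range(spectra.n_samples):
        peak = window_idx[int(np.argmax(mag[i, window_idx]))]
        k = target - peak
        offsets[i] = k
        row = np.roll(spectra.intensities[i], k)
        if k > 0:
            row[:k] = spectra.intensities[i, 0]
        elif k < 0:
            row[k:] = spectra.intensities[i, -1]
        out[i] = row
    result = spectra.with_intensities(out)
    return (result, offsets) if return_offsets else result


def _phase_objective(real_spec: np.ndarray) -> float:
    # RMS of the positive part, penalized 5x by the RMS of the negative
    # part: the penalty breaks the sign ambiguity of a pure positive-RMS
    # criterion.
    pos = np.sqrt(np.mean(np.square(np.maximum(real_spec, 0.0))))
    neg = np.sqrt(np.mean(np.square(np.minimum(real_spec, 0.0))))
    return pos - 5.0 * neg


def phase_objective(spectrum: np.ndarray, phi: float) -> float:
    """Criterion maximized by :func:`phase_correction` at angle *phi*."""
    return _phase_objective((spectrum * np.exp(1j * phi)).real)


def phase_correction(spectra: SpectrumSet, grid_deg: float = 2.0):
    """Zero-order phase correction by positive-RMS maximization.

    Per sample, finds the rotation ``phi`` maximizing the RMS of the
    positive part of ``Re(e^{i phi} s)`` minus five times the RMS of the
    negative part, via a coarse grid (*grid_deg* spacing over the full
    circle) followed by bounded scalar refinement.  Returns the real
    part of the rotated spectra and a :class:`PhaseResult` with the
    applied angles in ``(-pi, pi]``.  For a spectrum carrying a phase
    error ``Phi_error`` the recovered angle is ``-Phi_error``: the
    correction that restores a pure absorption lineshape.
    """
    if spectra.is_real:
        raise StageError("phase_correction expects complex intensities")
    grid = np.deg2rad(np.arange(-180.0, 180.0, grid_deg))
    rot = np.exp(1j * grid)
    half_width = np.deg2rad(grid_deg)

    out = np.empty(spectra.intensities.shape, dtype=float)
    angles = np.zeros(spectra.n_samples)
    objectives = np.zeros(spectra.n_samples)
    for i in range(spectra.n_samples):
        s = spectra.intensities[i]
        if not np.any(s):
            warnings.warn(f"sample {spectra.sample_ids[i]!r}: all-zero "
                          "spectrum, phase angle set to 0")
            out[i] = 0.0
            continue
        coarse = np.array([_phase_objective((r * s).real) for r in rot])
        phi0 = grid[int(np.argmax(coarse))]
        res = minimize_scalar(
            lambda phi: -phase_objective(s, phi),
            bounds=(phi0 - half_width, phi0 + half_width),
            method="bounded", options={"xatol": 1e-10},
        )
        phi = float(res.x)
        # wrap to (-pi, pi]
        phi = -((-phi + np.pi) % (2.0 * np.pi) - np.pi)
        angles[i] = phi
        objectives[i] = phase_objective(s, phi)
        out[i] = (s * np.exp(1j * phi)).real

    result = PhaseResult(angles=angles, objectives=objectives,
                         sample_ids=list(spectra.sample_ids))
    return spectra.with_intensities(out), result


def region_removal(spectra: SpectrumSet,
                   regions: list[tuple[float, float]] | str = "urine"
                   ) -> SpectrumSet:
    """Zero intensities inside interfering ppm regions.

    *regions* is a list of ``(ppm_lo, ppm_hi)`` pairs or a preset name
    (``urine``: 4.5-6.1 ppm covering urea, maleic acid and water;
    ``serum``: 4.5-5.1 ppm, water only).  Points are zeroed, not
    excised, so the axis stays uniform for alignment and binning.
    """
    if spectra.is_real is False:
        raise StageError("region_removal expects real intensities "
                         "(run phase_correction first)")
    if isinstance(regions, str):
        try:
            regions = REGION_PRESETS[regions]
        except KeyError:
            raise StageError(
                f"unknown region preset {regions!r}; "
                f"presets: {sorted(REGION_PRESETS)}"
            ) from None
    out = spectra.intensities.astype(float, copy=True)
    axis = spectra.ppm_axis
    for lo, hi in regions:
        if lo > hi:
            raise StageError(f"inverted region bounds ({lo}, {hi})")
        if hi < axis[-1] or lo > axis[0]:
            warnings.warn(f"region ({lo}, {hi}) ppm lies outside the axis "
                          f"span [{axis[-1]:.3f}, {axis[0]:.3f}]; clipped")
        out[:, _axis_window_mask(axis, lo, hi)] = 0.0
    return spectra.with_intensities(out)


def _als_baseline(y, lam, p, max_iter):
    # Eilers' asymmetric least squares: fixed asymmetric weights
    # p above / 1-p below the current baseline.
    w = np.ones(y.size)
    z = y
    for _ in range(max_iter):
        z = whittaker_smooth(y, lam, w)
        w = np.where(y > z, p, 1.0 - p)
    return z


def _arpls_baseline(y, lam, max_iter, tol):
    # Baek's adaptive reweighting: logistic weights from the statistics
    # of the negative residuals.
    w = np.ones(y.size)
    z = whittaker_smooth(y, lam, w)
    for _ in range(max_iter):
        d = y - z
        neg = d[d < 0]
        if neg.size < 2:
            break
        m, s = float(np.mean(neg)), float(np.std(neg))
        if s == 0:
            break
        arg = np.clip(2.0 * (d - (-m + 2.0 * s)) / s, -500.0, 500.0)
        w_new = 1.0 / (1.0 + np.exp(arg))
        if np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-30) < tol:
            w = w_new
            break
        w = w_new
        z = whittaker_smooth(y, lam, w)
    else:
        warnings.warn("arpls did not converge; returning last iterate")
    return z

def _airpls_baseline(y, lam, max_iter, tol):
    # Zhang's adaptive iteratively reweighted scheme: weights vanish
    # above the baseline and grow exponentially with iteration below it.
    w = np.ones(y.size)
    abs_y = np.sum(np.abs(y))
    z = y
    for it in range(1, max_iter + 1):
        z = whittaker_smooth(y, lam, w)
        d = y - z
        neg = d < 0
        s_neg = np.sum(np.abs(d[neg]))
        if s_neg < tol * abs_y:
            return z
        w = np.zeros(y.size)
        w[neg] = np.exp(it * np.abs(d[neg]) / s_neg)
    warnings.warn("airpls did not converge; returning last iterate")
    return z


def baseline_correction(spectra: SpectrumSet, method: str = "als",
                        lam: float = 1e7, p: float = 0.01,
                        max_iter: int | None = None,
                        tol: float | None = None) -> SpectrumSet:
    """Estimate and subtract a smooth baseline per spectrum.

    Three penalized-least-squares estimators sharing the Whittaker
    smoother core, differing in how residuals are asymmetrically
    reweighted: ``als`` (fixed asymmetry *p*, default 0.01, 10
    iterations), ``arpls`` (logistic reweighting of negative residuals,
    tol 1e-6, up to 50 iterations) and ``airpls`` (exponentially
    growing weights on negative residuals, stopping when their mass
    falls below ``tol * sum|y|``, tol 1e-3, up to 50 iterations).
    """
    if method not in BASELINE_METHODS:
        raise StageError(f"unknown baseline method {method!r}; "
                         f"valid: {', '.join(BASELINE_METHODS)}")
    if not spectra.is_real:
        raise StageError("baseline_correction expects real intensities")
    y_all = spectra.intensities
    out = np.empty_like(y_all, dtype=float)
    for i in range(spectra.n_samples):
        y = y_all[i].astype(float)
        if not np.any(y):
            out[i] = 0.0
            continue
        if method == "als":
            z = _als_baseline(y, lam, p, max_iter or 10)
        elif method == "arpls":
            z = _arpls_baseline(y, lam, max_iter or 50, tol or 1e-6)
        else:
            z = _airpls_baseline(y, lam, max_iter or 50, tol or 1e-3)
        out[i] = y - z
    return spectra.with_intensities(out)


def negative_values_zeroing(spectra: SpectrumSet) -> SpectrumSet:
    """Clip residual negative intensities to zero (element-wise max)."""
    if not spectra.is_real:
        raise StageError("negative_values_zeroing expects real intensities")
    return spectra.with_intensities(np.maximum(spectra.intensities, 0.0))


def window_selection(spectra: SpectrumSet, ppm_lo: float = 0.2,
                     ppm_hi: float = 10.0) -> SpectrumSet:
    """Excise axis points outside the closed interval [ppm_lo, ppm_hi]."""
    if ppm_lo >= ppm_hi:
        raise StageError("window_selection requires ppm_lo < ppm_hi")
    mask = _axis_window_mask(spectra.ppm_axis, ppm_lo, ppm_hi)
    if not mask.any():
        raise StageError(
            f"window [{ppm_lo}, {ppm_hi}] ppm does not intersect the axis"
        )
    return SpectrumSet(intensities=spectra.intensities[:, mask],
                       ppm_axis=spectra.ppm_axis[mask],
                       sample_ids=list(spectra.sample_ids))
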