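"""Time-domain preprocessing: group delay removal, solvent suppression,
apodization and zero filling.

Solvent suppression follows the penalized-least-squares approach: a
Whittaker smoother with a second-difference roughness penalty estimates
the slowly varying solvent component of each FID (the water resonance
sits at or near the carrier, so it appears as a low-frequency envelope
in the rotating frame), and the estimate is subtracted.  The smoother
solves the pentadiagonal system ``(W + lam * D2' D2) z = W y`` with a
banded Cholesky factorization, which is O(n).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded

from .containers import FidSet
from .errors import StageError

logger = logging.getLogger(__name__)

APODIZATION_KINDS = ("exponential", "gaussian")


def group_delay_removal(fids: FidSet, params: pd.DataFrame) -> FidSet:
    """Drop the digital-filter transient at the start of each FID.

    The first ``round(GRPDLY)`` complex points of each row are removed;
    no phase-based reconstruction is attempted.  A missing ``GRPDLY``
    is treated as 0 (logged).  Rows are re-padded with trailing zeros to
    a common length.
    """
    n = fids.n_points
    kept: list[np.ndarray] = []
    for i, sid in enumerate(fids.sample_ids):
        grpdly = 0.0
        if "GRPDLY" in params.columns:
            raw = params.loc[sid, "GRPDLY"]
            grpdly = float(raw) if np.isfinite(pd.to_numeric(raw, errors="coerce")) else 0.0
        else:
            logger.info("sample %s: no GRPDLY in acqus, assuming 0", sid)
        drop = int(round(grpdly))
        if drop >= n:
            raise StageError(
                f"sample {sid!r}: GRPDLY {grpdly} >= signal length {n}"
            )
        kept.append(fids.data[i, drop:])

    n_max = max(row.size for row in kept)
    out = np.zeros((fids.n_samples, n_max), dtype=np.complex128)
    for i, row in enumerate(kept):
        out[i, : row.size] = row
    return fids.with_data(out)


def whittaker_smooth(y: np.ndarray, lam: float,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Whittaker smoother: discrete penalized least squares with a
    second-order difference penalty.

    Returns the ``z`` minimizing ``sum_i w_i (y_i - z_i)^2 +
    lam * sum_i (delta^2 z_i)^2`` via the banded symmetric
    positive-definite system ``(W + lam D2' D2) z = W y``.
    ``lam = 0`` returns the input unchanged; straight lines lie in the
    penalty's null space and survive arbitrarily strong smoothing.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise StageError("whittaker_smooth needs a 1-D signal of length >= 3")
    if not np.all(np.isfinite(y)):
        raise StageError("whittaker_smooth: input contains non-finite values")
    if lam < 0:
        raise StageError("lam must be >= 0")
    n = y.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise StageError("weights must be a finite non-negative vector "
                             "matching the signal")
    if lam == 0:
        return y.copy()

    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    if lam > 1e8 and np.all(w > 0):
        # Strong penalties make the primal system (W + lam D2'D2)
        # ill-conditioned; the equivalent Woodbury form
        #   z = y - W^{-1} D2' (lam^{-1} I + D2 W^{-1} D2')^{-1} D2 y
        # stays well-conditioned as lam -> inf and passes straight
        # lines (null space of D2) through bit-exactly.
        m = (sparse.diags(np.ones(n - 2) / lam, 0)
             + d2 @ sparse.diags(1.0 / w, 0) @ d2.T).tocsc()
        ab = np.zeros((3, n - 2))
        ab[0] = m.diagonal(0)
        ab[1, :-1] = m.diagonal(-1)
        ab[2, :-2] = m.diagonal(-2)
        rhs = np.diff(y, 2)
        u = solveh_banded(ab, rhs, lower=True)
        scale = np.max(np.abs(rhs))
        for _ in range(2):  # iterative refinement for the smoothing limit
            r = rhs - m @ u
            if scale == 0 or np.max(np.abs(r)) <= 1e-15 * scale:
                break
            u = u + solveh_banded(ab, r, lower=True)
        return y - (d2.T @ u) / w

    a = (sparse.diags(w, 0) + lam * (d2.T @ d2)).tocsc()
    # lower banded storage for solveh_banded: bandwidth 2
    ab = np.zeros((3, n))
    ab[0] = a.diagonal(0)
    ab[1, :-1] = a.diagonal(-1)
    ab[2, :-2] = a.diagonal(-2)
    return solveh_banded(ab, w * y, lower=True)


def solvent_residuals_removal(fids: FidSet, lam: float = 1e6) -> FidSet:
    """Subtract the Whittaker-smoothed solvent envelope from each FID.

    The smoother runs on the real and imaginary parts independently
    (with uniform weights this is algebraically identical to smoothing
    the complex signal jointly, since the operator is a real linear
    map).  The default penalty ``lam = 1e6`` passes resonances more than
    a few tens of Hz from the carrier essentially untouched at typical
    sweep widths while capturing the near-carrier water envelope.
    """
    if not lam > 0:
        raise StageError("solvent lam must be > 0")
    out = np.empty_like(fids.data)
    for i in range(fids.n_samples):
        est = (whittaker_smooth(fids.data[i].real, lam)
               + 1j * whittaker_smooth(fids.data[i].imag, lam))
        out[i] = fids.data[i] - est
    return fids.with_data(out)


def apodization(fids: FidSet, kind: str = "exponential",
                lb: float = 0.3) -> FidSet:
    """Multiply each FID by a decaying window.

    ``exponential``: ``exp(-pi * lb * t)`` (Lorentzian broadening of
    *lb* Hz).  ``gaussian``: ``exp(-(pi * lb * t)^2 / (4 ln 2))``,
    normalized so *lb* is the full width at half maximum in Hz.
    """
    if kind not in APODIZATION_KINDS:
        raise StageError(
            f"unknown apodization kind {kind!r}; valid kinds: "
            f"{', '.join(APODIZATION_KINDS)}"
        )
    if lb < 0:
        raise StageError("line broadening lb must be >= 0")
    t = fids.times()
    if kind == "exponential":
        window = np.exp(-np.pi * lb * t)
    else:
        window = np.exp(-((np.pi * lb * t) ** 2) / (4.0 * np.log(2.0)))
    return fids.with_data(fids.data * window)


def next_pow2_double(n: int) -> int:
    """Smallest power of two >= 2 n (the default zero-fill target)."""
    return 1 << int(np.ceil(np.log2(2 * n)))


def zero_filling(fids: FidSet, target: int | str = "next_pow2_double") -> FidSet:
    """Extend each FID with trailing complex zeros.

    *target* is an explicit point count (must be >= the current length)
    or the policy ``"next_pow2_double"``: the smallest power of two at
    least twice the current length.  Zero filling interpolates the
    frequency grid without adding information.
    """
    n = fids.n_points
    if target == "next_pow2_double":
        m = next_pow2_double(n)
    else:
        m = int(target)
        if m < n:
            raise StageError(f"zero-fill target {m} < current length {n}")
    out = np.zeros((fids.n_samples, m), dtype=np.complex128)
    out[:, :n] = fids.data
    return fids.with_data(out)
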