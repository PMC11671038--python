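"""Readers for Bruker acquisition directories.

A Bruker 1D acquisition lives in one directory per sample containing a
text parameter file ``acqus`` (JCAMP-DX-like ``##$KEY= value`` records)
and a headerless binary ``fid`` holding interleaved real/imaginary
values.  ``extract_params`` collects every ``acqus`` under a root into a
:class:`pandas.DataFrame` indexed by sample directory name;
``extract_fids`` then decodes the sibling ``fid`` files into a
:class:`~nmrprep.containers.FidSet`.

Decoding honours the on-disk flags:

``BYTORDA``
    byte order, 0 = little-endian, 1 = big-endian;
``DTYPA``
    0 = 32-bit signed integers (converted to float; multiplied by
    ``2**NC`` when an ``NC`` scaling exponent is present),
    2 = 64-bit IEEE floats;
``TD``
    total number of real+imaginary values; the complex signal holds
    ``TD/2`` points.

Samples are ordered lexicographically by directory name so results are
reproducible across filesystems.  Only 1D data (``fid``) is supported;
``ser`` files and processed-data imports are out of scope.
"""

from __future__ import annotations

import logging
import os
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FidSet
from .errors import BrukerFormatError, EmptyCohortError

logger = logging.getLogger(__name__)

_KEY_RE = re.compile(r"^##(\$?)([^=]+)=\s*(.*)$")
_ARRAY_RE = re.compile(r"^\((\d+)\.\.(\d+)\)\s*(.*)$")


def _coerce(token: str):
    """Parse a JCAMP token as int, then float, else keep the raw string."""
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


def parse_acqus(path: Path) -> dict:
    """Parse one ``acqus`` file into a flat ``{key: value}`` mapping.

    Array values — ``##$KEY= (0..N)`` followed by whitespace-separated
    numbers on continuation lines — are returned as Python lists.
    Malformed records are skipped with a warning rather than aborting
    the whole cohort.
    """
    lines = Path(path).read_text(errors="replace").splitlines()
    params: dict = {}
    i = 0
    while i < len(lines):
        line = lines[i].rstrip()
        i += 1
        if not line.startswith("##"):
            continue
        if line.startswith("##END"):
            break
        m = _KEY_RE.match(line)
        if m is None:
            warnings.warn(f"{path}: malformed record skipped: {line!r}")
            continue
        key = m.group(2).strip()
        raw = m.group(3).strip()
        arr = _ARRAY_RE.match(raw)
        if arr is not None:
            tokens = arr.group(3).split()
            # continuation lines until the next ## record
            while i < len(lines) and not lines[i].startswith("##"):
                tokens.extend(lines[i].split())
                i += 1
            params[key] = [_coerce(t) for t in tokens]
        else:
            params[key] = _coerce(raw)
    return params


def extract_params(root_dir: str | os.PathLike) -> pd.DataFrame:
    """Collect acquisition parameters from every ``acqus`` under *root_dir*.

    Returns a DataFrame with one row per sample, indexed by the name of
    the directory containing the ``acqus`` file, in lexicographic order.

    Raises
    ------
    EmptyCohortError
        If no ``acqus`` file is found anywhere below *root_dir*.
    BrukerFormatError
        If two sample directories share the same name.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise EmptyCohortError(f"empty cohort: {root} is not a directory")
    acqus_paths = sorted(root.rglob("acqus"), key=lambda p: p.parent.name)
    if not acqus_paths:
        raise EmptyCohortError(f"empty cohort: no 'acqus' files under {root}")

    rows: dict[str, dict] = {}
    for path in acqus_paths:
        sample_id = path.parent.name
        if sample_id in rows:
            raise BrukerFormatError(
                f"duplicate sample id {sample_id!r} under {root}"
            )
        params = parse_acqus(path)
        params["_acqus_path"] = str(path)
        rows[sample_id] = params

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table.sort_index()


def _fid_dtype(bytorda: int, dtypa: int, sample_id: str) -> np.dtype:
    endian = {0: "<", 1: ">"}.get(int(bytorda))
    if endian is None:
        raise BrukerFormatError(
            f"sample {sample_id!r}: BYTORDA must be 0 or 1, got {bytorda}"
        )
    base = {0: "i4", 2: "f8"}.get(int(dtypa))
    if base is None:
        raise BrukerFormatError(
            f"sample {sample_id!r}: unknown DTYPA {dtypa} (expected 0 or 2)"
        )
    return np.dtype(endian + base)


def extract_fids(root_dir: str | os.PathLike, params: pd.DataFrame) -> FidSet:
    """Decode the binary ``fid`` next to each sample's ``acqus``.

    Consecutive (real, imaginary) values are interleaved into complex
    points, giving ``TD/2`` points per sample.  Cohorts whose
    acquisitions differ in length are zero-padded to the maximum length
    (the pad count is logged).  The shared dwell time is ``1/SW_h``.
    """
    root = Path(root_dir)
    signals: list[np.ndarray] = []
    sw_h = None
    for sample_id, row in params.iterrows():
        acqus_path = Path(row.get("_acqus_path", root / sample_id / "acqus"))
        fid_path = acqus_path.parent / "fid"
        if not fid_path.is_file():
            raise BrukerFormatError(f"sample {sample_id!r}: missing fid file")
        td = int(row["TD"])
        dtype = _fid_dtype(row["BYTORDA"], row["DTYPA"], str(sample_id))
        raw = np.fromfile(fid_path, dtype=dtype)
        if raw.size < td:
            raise BrukerFormatError(
                f"sample {sample_id!r}: fid holds {raw.size} values, "
                f"TD = {td}"
            )
        values = raw[:td].astype(np.float64)
        nc = row.get("NC")
        if nc is not None and np.isfinite(pd.to_numeric(nc, errors="coerce")):
            values = values * 2.0 ** float(nc)
        signals.append(values[0::2] + 1j * values[1::2])
        if sw_h is None:
            sw_h = float(row["SW_h"])

    n_max = max(s.size for s in signals)
    data = np.zeros((len(signals), n_max), dtype=np.complex128)
    for i, s in enumerate(signals):
        if s.size < n_max:
            logger.info(
                "sample %s padded with %d trailing zeros",
                params.index[i], n_max - s.size,
            )
        data[i, : s.size] = s

    return FidSet(data=data, dwell_time=1.0 / sw_h,
                  sample_ids=list(params.index.astype(str)))
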