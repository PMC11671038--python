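"""Ground-truth cohort simulator.

A 1D NMR free induction decay is modelled as a sum of exponentially
decaying complex sinusoids,

    S(t) = sum_p  S0_p * exp(i 2 pi nu_p t) * exp(-t / T_p)
                 * exp(i (phi_p + Phi_error)),

where ``S0`` is the amplitude, ``nu`` the resonance offset from the
carrier in Hz, ``T`` the decay (relaxation) constant in seconds and
``Phi_error`` a per-sample zero-order phase error.  Peak positions are
given in ppm and converted to Hz offsets via
``nu = (position_ppm - carrier_ppm) * SFO1`` with ``carrier_ppm =
O1 / SFO1``.

A simulated cohort layers the experimental artifacts the preprocessing
stages are built to remove: a group-delay filter transient prepended to
each FID, a dominant broad water resonance near 4.7 ppm, per-sample
phase errors, per-sample chemical-shift drift, per-sample dilution of
the metabolite peaks, and additive complex white Gaussian noise.  Every
draw is recorded in a :class:`GroundTruthLedger` so downstream tests can
compare recovered corrections against the injected truth.

Cohorts can be written to disk as parseable Bruker ``acqus``/``fid``
directory trees (:func:`write_bruker_fixture`), which makes the reader
testable without any external download.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FidSet
from .errors import StageError

__all__ = [
    "PeakSpec", "CohortSpec", "GroundTruthLedger", "DEFAULT_PEAKS",
    "simulate_fid", "simulate_cohort", "write_bruker_fixture",
    "cohort_spec_from_yaml",
]


@dataclass(frozen=True)
class PeakSpec:
    """One resonance: position (ppm), amplitude S0, decay T (s), phase (rad)."""

    position: float
    amplitude: float
    t2: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.t2 > 0:
            raise StageError("PeakSpec.t2 must be positive")
        if self.amplitude < 0:
            raise StageError("PeakSpec.amplitude must be non-negative")


#: Urine-flavoured singlet template: (position ppm, amplitude, T2 s).
#: Approximate positions of common urinary metabolites (lactate, alanine,
#: acetate, citrate, creatinine, glycine, hippurate, formate).
DEFAULT_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(1.33, 6.0, 0.50),   # lactate CH3
    PeakSpec(1.48, 3.0, 0.60),   # alanine CH3
    PeakSpec(1.92, 2.0, 0.70),   # acetate
    PeakSpec(2.54, 5.0, 0.30),   # citrate AB
    PeakSpec(2.66, 5.0, 0.30),   # citrate AB
    PeakSpec(3.05, 8.0, 0.50),   # creatinine CH3
    PeakSpec(3.56, 4.0, 0.50),   # glycine
    PeakSpec(3.97, 3.0, 0.35),   # hippurate CH2
    PeakSpec(4.06, 6.0, 0.40),   # creatinine CH2
    PeakSpec(7.64, 2.5, 0.30),   # hippurate ring
    PeakSpec(7.83, 2.5, 0.30),   # hippurate ring
    PeakSpec(8.46, 1.0, 0.80),   # formate
)


def _default_reference() -> PeakSpec:
    return PeakSpec(position=0.0, amplitude=4.0, t2=1.0)


def _default_water() -> PeakSpec:
    # Broad dominant solvent resonance: 50x the largest metabolite peak.
    return PeakSpec(position=4.70, amplitude=50.0 * 8.0, t2=0.02)


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    Defaults mirror a urine study on a 600 MHz instrument: 70 samples,
    12 ppm sweep width centred on the water resonance at 4.7 ppm,
    16k acquired values, a 76-point group delay, phase errors up to
    +-150 degrees, +-0.02 ppm shift drift and 0.5x-2x dilution spread.
    """

    n_samples: int = 70
    peaks: tuple[PeakSpec, ...] = DEFAULT_PEAKS
    reference_peak: PeakSpec = field(default_factory=_default_reference)
    water_peak: PeakSpec = field(default_factory=_default_water)
    td: int = 16384
    sw_h: float = 12.0 * 600.13
    sfo1: float = 600.13
    o1: float = 4.70 * 600.13
    group_delay: float = 76.0
    phase_error_range: float = math.radians(150.0)
    shift_range: float = 0.02
    dilution_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.05
    baseline: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise StageError("n_samples must be >= 1")
        if self.td <= 0 or self.td % 2:
            raise StageError("td must be positive and even")
        if self.sw_h <= 0 or self.sfo1 <= 0:
            raise StageError("sw_h and sfo1 must be positive")
        if self.group_delay < 0:
            raise StageError("group_delay must be >= 0")
        lo, hi = self.dilution_range
        if not (0 < lo <= hi):
            raise StageError("dilution_range must be well-ordered and positive")
        if self.phase_error_range < 0 or self.shift_range < 0:
            raise StageError("ranges must be non-negative")
        if self.noise_sd < 0:
            raise StageError("noise_sd must be >= 0")

    @property
    def carrier_ppm(self) -> float:
        return self.o1 / self.sfo1


@dataclass
class GroundTruthLedger:
    """Per-sample injected truths plus the global simulation settings.

    ``samples`` maps sample id to a record holding ``phase_error_rad``,
    ``dilution_factor``, ``shift_ppm`` (one drift value applied to every
    peak of that sample), ``first_point_abs`` (magnitude of the first
    true signal point, after the group-delay transient) and, when an
    integer fixture was written, ``int32_scale``.
    """

    samples: dict[str, dict]
    seed: int
    noise_sd: float
    peaks: list[dict]

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruthLedger":
        return cls(**json.loads(Path(path).read_text()))


def simulate_fid(peaks, td, sw_h, sfo1, phase_error=0.0, noise_sd=0.0,
                 seed=0, o1=0.0):
    """Simulate one FID of ``td/2`` complex points.

    Each peak contributes ``S0 exp(i 2 pi nu t) exp(-t/T)
    exp(i (phase + phase_error))`` on the grid ``t_k = k / sw_h``;
    complex white Gaussian noise of standard deviation *noise_sd* per
    component is added on top.  An empty peak list yields a pure-noise
    (or all-zero) signal.  Deterministic given *seed*.
    """
    if td <= 0 or td % 2:
        raise StageError("td must be positive and even")
    if sw_h <= 0:
        raise StageError("sw_h must be positive")
    n = td // 2
    t = np.arange(n) / sw_h
    carrier_ppm = o1 / sfo1
    signal = np.zeros(n, dtype=np.complex128)
    for p in peaks:
        nu = (p.position - carrier_ppm) * sfo1
        signal += (
            p.amplitude
            * np.exp(1j * (2.0 * np.pi * nu * t + p.phase + phase_error))
            * np.exp(-t / p.t2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=(2, n))
        signal = signal + eps[0] + 1j * eps[1]
    return signal


def _group_delay_transient(first_point: complex, n_points: int) -> np.ndarray:
    """Crude digital-filter transient: linear ramp from 0 toward the
    first true point over *n_points* samples."""
    if n_points == 0:
        return np.zeros(0, dtype=np.complex128)
    ramp = (np.arange(n_points) + 1) / (n_points + 1)
    return ramp * first_point


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort; returns ``(FidSet, AcqusTable, GroundTruthLedger)``.

    Per sample the generator draws a phase error, a dilution factor and
    a chemical-shift drift from the spec's uniform ranges, scales the
    metabolite amplitudes by the dilution (the reference standard and
    the solvent peak are not diluted), shifts every peak by the drift,
    and prepends ``ceil(group_delay)`` transient points so the group
    delay removal stage has something to remove.  The acqus table rows
    describe the on-disk layout (``TD`` counts transient + signal).
    """
    gd = int(math.ceil(spec.group_delay))
    n_signal = spec.td // 2 - gd
    if n_signal < 1:
        raise StageError("group_delay leaves no signal points")
    rng = np.random.default_rng(spec.seed)

    sample_ids = [f"sample{(i + 1):03d}" for i in range(spec.n_samples)]
    data = np.zeros((spec.n_samples, spec.td // 2), dtype=np.complex128)
    records: dict[str, dict] = {}
    acqus_rows: dict[str, dict] = {}

    for i, sid in enumerate(sample_ids):
        phase_error = rng.uniform(-spec.phase_error_range,
                                  spec.phase_error_range)
        dilution = rng.uniform(*spec.dilution_range)
        shift = rng.uniform(-spec.shift_range, spec.shift_range)
        noise_seed = int(rng.integers(2 ** 31))

        peaks = [replace(p, position=p.position + shift,
                         amplitude=p.amplitude * dilution)
                 for p in spec.peaks]
        peaks.append(replace(spec.reference_peak,
                             position=spec.reference_peak.position + shift))
        peaks.append(replace(spec.water_peak,
                             position=spec.water_peak.position + shift))

        fid = simulate_fid(peaks, 2 * n_signal, spec.sw_h, spec.sfo1,
                           phase_error=phase_error, noise_sd=spec.noise_sd,
                           seed=noise_seed, o1=spec.o1)
        data[i, :gd] = _group_delay_transient(fid[0], gd)
        data[i, gd:] = fid

        records[sid] = {
            "phase_error_rad": float(phase_error),
            "dilution_factor": float(dilution),
            "shift_ppm": float(shift),
            "first_point_abs": float(abs(fid[0])),
            "noise_seed": noise_seed,
        }
        acqus_rows[sid] = {
            "TD": spec.td,
            "SW": spec.sw_h / spec.sfo1,
            "SW_h": spec.sw_h,
            "SFO1": spec.sfo1,
            "O1": spec.o1,
            "BF1": spec.sfo1 - spec.o1 / 1e6,
            "GRPDLY": spec.group_delay,
            "BYTORDA": 0,
            "DTYPA": 2,
            "PULPROG": "<zg30>",
            "P": [10.5, 21.0, 15000.0, 9.0],
        }

    fids = FidSet(data=data, dwell_time=1.0 / spec.sw_h,
                  sample_ids=sample_ids)
    params = pd.DataFrame.from_dict(acqus_rows, orient="index")
    params.index.name = "sample_id"
    ledger = GroundTruthLedger(
        samples=records, seed=spec.seed, noise_sd=spec.noise_sd,
        peaks=[asdict(p) for p in spec.peaks],
    )
    return fids, params, ledger


def _format_value(value) -> str:
    if isinstance(value, (list, tuple, np.ndarray)):
        vals = " ".join(repr(float(v)) if isinstance(v, (float, np.floating))
                        else str(v) for v in value)
        return f"(0..{len(value) - 1})\n{vals}"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def write_bruker_fixture(fids: FidSet, params: pd.DataFrame,
                         out_dir: str | os.PathLike, dtype_flag: int = 2,
                         overwrite: bool = False,
                         ledger: GroundTruthLedger | None = None) -> Path:
    """Serialize a cohort as a Bruker directory tree.

    One subdirectory per sample holds a parseable ``acqus`` and a binary
    ``fid``.  ``dtype_flag`` selects the on-disk payload: 2 writes the
    float64 values verbatim (bit-exact round trip); 0 scales each sample
    by a power of two so the largest magnitude sits near ``2**30``,
    rounds to int32 and records the exponent as ``NC`` so readers that
    honour the conventional ``2**NC`` scaling recover the amplitudes.
    The scale is also recorded in the ledger when one is supplied.
    """
    if dtype_flag not in (0, 2):
        raise StageError(f"dtype_flag must be 0 (int32) or 2 (float64), "
                         f"got {dtype_flag}")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise StageError(f"refusing to write into non-empty {out} "
                         "(pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    for i, sid in enumerate(fids.sample_ids):
        sample_dir = out / sid
        sample_dir.mkdir(exist_ok=True)
        row = params.loc[sid].to_dict()
        row.pop("_acqus_path", None)
        row["BYTORDA"] = 0
        row["DTYPA"] = dtype_flag

        values = np.empty(2 * fids.n_points)
        values[0::2] = fids.data[i].real
        values[1::2] = fids.data[i].imag
        row["TD"] = 2 * fids.n_points

        if dtype_flag == 0:
            peak = np.max(np.abs(values))
            exp = 0 if peak == 0 else int(math.floor(math.log2(2 ** 30 / peak)))
            row["NC"] = -exp
            payload = np.round(values * 2.0 ** exp).astype("<i4")
            if ledger is not None:
                ledger.samples[sid]["int32_scale"] = 2.0 ** exp
        else:
            payload = values.astype("<f8")

        lines = ["##TITLE= Parameter file, nmrprep synthetic fixture",
                 "##JCAMPDX= 5.0"]
        for key, value in row.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            lines.append(f"##${key}= {_format_value(value)}")
        lines.append("##END=")
        (sample_dir / "acqus").write_text("\n".join(lines) + "\n")
        payload.tofile(sample_dir / "fid")

    return out


def cohort_spec_from_yaml(path: str | os.PathLike) -> CohortSpec:
    """Load a :class:`CohortSpec` from a YAML mapping.

    Peak lists may be given as ``{position, amplitude, t2, phase}``
    mappings; omitted keys fall back to the dataclass defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("peaks",):
        if key in raw:
            raw[key] = tuple(PeakSpec(**p) for p in raw[key])
    for key in ("reference_peak", "water_peak"):
        if key in raw:
            raw[key] = PeakSpec(**raw[key])
    if "dilution_range" in raw:
        raw["dilution_range"] = tuple(raw["dilution_range"])
    if "baseline" in raw and raw["baseline"] is not None:
        raw["baseline"] = tuple(raw["baseline"])
    return CohortSpec(**raw)
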