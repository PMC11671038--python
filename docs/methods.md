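# Methods

## Signal model

A 1D ¹H-NMR free induction decay is modelled as a sum of exponentially
decaying complex sinusoids sampled at the dwell time `1/SW_h`:

    S(t_k) = Σ_p S0_p · exp(i 2π ν_p t_k) · exp(−t_k / T_p)
             · exp(i (φ_p + Φ_error)),   t_k = k / SW_h.

Peak positions are specified in ppm and converted to Hz offsets from
the carrier, `ν = (δ − O1/SFO1) · SFO1`. The discrete Fourier transform
of one such component is a Lorentzian of half-width `1/(πT)` Hz centred
at `ν`, which is why the simulator's linewidths grow as `T` shrinks.
`Φ_error` is a per-sample zero-order (frequency-independent) phase; the
correction that restores a pure absorption lineshape is the rotation by
`−Φ_error`.

## The synthetic cohort generator

The generator exists so that every preprocessing stage can be tested
against a recorded ground truth. Its defaults describe a urine-like
study on a 600 MHz instrument:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 70 | cohort size |
| `td` | 16384 | acquired values (8192 complex points) |
| `sw_h` | 7201.56 Hz | 12 ppm sweep width at 600.13 MHz |
| `o1` | 2820.6 Hz | carrier on the water resonance (4.70 ppm) |
| `group_delay` | 76 | transient points prepended per FID |
| `phase_error_range` | ±150° | uniform per-sample phase error |
| `shift_range` | ±0.02 ppm | uniform per-sample chemical-shift drift |
| `dilution_range` | 0.5–2.0 | uniform per-sample metabolite scaling |
| `noise_sd` | 0.05 | complex white Gaussian noise per component |

The peak template holds twelve singlets at the approximate positions of
common urinary metabolites (lactate, alanine, acetate, citrate,
creatinine, glycine, hippurate, formate), a reference standard at
0 ppm (T = 1 s, not diluted — it is added at fixed concentration), and
a broad water resonance at 4.70 ppm with `T = 0.02 s` and fifty times
the largest metabolite amplitude. The group delay is emulated as a
linear ramp from zero to the first true point — a crude stand-in for
Bruker's decimation-filter transient, adequate because the removal
stage simply drops those points. The shift drift is a single value per
sample applied to every peak: this models field/referencing drift,
makes internal referencing and alignment recovery well-defined against
the ledger, and is the documented meaning of the ledger's `shift_ppm`.

What the generator does **not** emulate: J-coupling multiplets,
pH-dependent shifts of individual metabolites (all peaks move
together), chemical noise, receiver-gain steps, and Bruker's exact
digital-filter phase ramp. Tests passing on these cohorts therefore
demonstrate the correctness of each transformation under the stated
model, not robustness to every artifact of real biofluid spectra. The
noise model (complex white Gaussian) is an explicit assumption.

Fixtures are written as genuine Bruker directory trees. The float64
path (`DTYPA = 2`) round-trips bit-exactly. The int32 path scales each
sample by a power of two so its largest magnitude sits near 2³⁰ and
records the exponent as the conventional `NC` parameter, giving a
round-trip relative error below 1e−9 at default amplitudes.

## Whittaker smoother

Solvent suppression and all three baseline methods share the
penalized-least-squares smoother
`(W + λ D₂ᵀD₂) z = W y` with second-order differences. Two solver
paths are used:

* **λ ≤ 1e8** (all routine smoothing): banded Cholesky
  (`scipy.linalg.solve_banded` family), O(n), pentadiagonal.
* **λ > 1e8 with strictly positive weights**: the primal system's
  conditioning grows like λ and, worse, the residual computation
  multiplies second-difference cancellation noise by λ, which destroys
  the property that straight lines (the penalty's null space) pass
  through unchanged. The equivalent Woodbury form
  `z = y − W⁻¹D₂ᵀ (λ⁻¹I + D₂W⁻¹D₂ᵀ)⁻¹ D₂ y` stays well conditioned as
  λ → ∞ and returns line inputs bit-exactly; two steps of iterative
  refinement push the self-consistency of the smoothing limit to
  ~1e−11.

Note the exact smoother is only idempotent in the λ → ∞ limit: at
finite λ, re-smoothing changes the output by ~`1/(λ μ_min)` with
`μ_min ≈ (π/n)⁴` the smallest nonzero eigenvalue of `D₂ᵀD₂`.

The default solvent penalty `λ = 1e6` acts as a low-pass filter with a
half-power point near `ω ≈ λ^(−1/4)` rad/sample, i.e. ≈ 36 Hz at the
default sweep width — wide enough to capture the on-carrier water
envelope (a 16 Hz-wide Lorentzian in the rotating frame) and narrow
enough to leave a metabolite 500 Hz away essentially untouched
(measured: ≥ 190× water reduction, < 4% metabolite distortion). Because
the cutoff scales with `n` and `SW_h`, λ is exposed in the config. The
smoother is applied to the real and imaginary parts separately; with
uniform weights this is algebraically identical to smoothing the
complex signal, since the operator is a real linear map.

## Baseline estimators

All three iterate the weighted smoother with different asymmetric
reweighting of the residual `d = y − z` (defaults: `λ = 1e7`):

* **ALS** — fixed asymmetry: `w = p` above the baseline, `1 − p`
  below (`p = 0.01`, 10 iterations).
* **ARPLS** — logistic weights from the statistics of the negative
  residuals, `w = 1/(1 + exp(2(d − (−m̄ + 2σ))/σ))` with `m̄, σ` the
  mean and SD of `d < 0`; stops when the weight change drops below
  1e−6 or after 50 iterations.
* **AIRPLS** — `w = 0` where `d ≥ 0`, `exp(iter·|d|/Σ|d⁻|)` below;
  stops when `Σ|d⁻| < 1e−3 · Σ|y|` or after 50 iterations.

Exponential arguments are clipped at ±500 to avoid overflow.
Non-convergence returns the last iterate with a warning. Measured on
constant, linear and sinusoidal baselines under Lorentzian peaks, all
three keep the off-peak residual median below 1% of the baseline
amplitude.

## Phase correction

Zero-order only: the correction is a single rotation per spectrum.
First-order (frequency-dependent) phase is out of scope — the group
delay, its usual source, is removed by point deletion in the time
domain. The objective is the RMS of the positive part of
`Re(e^{iφ} s)` minus five times the RMS of the negative part; a pure
positive-RMS criterion has a sign ambiguity (a spectrum flipped by
180° also has large positive RMS) that the penalty removes. The
optimizer evaluates a 2° grid over the full circle and refines the
best point with bounded scalar minimization (`xatol = 1e−10` rad).
Angles are reported in (−π, π].

Accuracy depends on the spectra being apodized: without a decaying
window, truncation ringing of slowly decaying components biases the
objective by about a degree. Under the pipeline's default exponential
window the worst recovery error over ±150° injected errors is ~0.1°.

## Internal referencing, region removal, windowing

Referencing finds the maximum-magnitude point in the −0.2 to +0.2 ppm
window and shifts the sample by whole grid points so it lands on the
axis point nearest 0 ppm — data move against one fixed shared axis
(never per-sample axes), because alignment and binning need a common
grid. No sub-grid (centroid/parabolic) refinement is attempted.
Vacated edge points replicate the edge value. Region removal zeroes
intensities in place rather than excising points, again to keep the
axis uniform; presets are urine (4.5–6.1 ppm: urea, maleic acid,
water) and serum (4.5–5.1 ppm: water). Window selection (default
0.2–10 ppm, closed interval on chemical-shift values) is the only
stage that drops axis points. The FT is unnormalized
(`Σ|fid|² = (1/m)·Σ|spectrum|²`) and the first FID point is not halved
— a documented deviation from some spectrometer conventions.

## Alignment

Interval-correlation shifting: the axis is split into intervals
(default 50 equal widths), a target spectrum is built (mean by
default; median, point-wise max envelope, a named sample, or an
explicit vector), and each sample's interval is shifted by the integer
lag maximizing its FFT circular cross-correlation with the target's
interval. Shifting is segment-local with edge replication (or zeros);
circular wrap is deliberately disallowed so peaks cannot teleport
across interval borders. Ties break toward the smaller |lag|, then
negative. `max_shift="auto"` resolves to half the interval length,
capped so a full correlation window fits. Ledger-recovery measurements
use a single whole-window interval and a zero-shift template target,
because the injected drift is global per sample; ≥ 95% of lags match
the ledger exactly (misses are shifts near half a grid point).

## Binning and normalization

Bins of exactly 0.04 ppm (a conventional bucket width; configurable)
start at the high-ppm end; a trailing partial bin is kept and flagged.
Each feature is the trapezoidal integral over the bin's ppm span, with
bin edges between grid points handled by linear interpolation of the
cumulative integral — this makes the bin sum telescope to the
whole-spectrum integral exactly (measured conservation error < 1e−14
relative). PQN total-area-normalizes first, uses the element-wise
median spectrum as reference, excludes features where the reference is
below `1e−12 · max(ref)` (the zeroed water band), and divides each row
by the median quotient. SNV uses the population (n) standard
deviation. Degenerate inputs (zero row sums, constant rows,
single-sample PQN) raise errors naming the offending sample.

## Pipeline and determinism

Stages may be disabled but never permuted; `extract`, `fft` and `bin`
are mandatory. If phasing is disabled the pipeline bins the magnitude
spectrum (with a warning) so the minimal extract → fft → bin path
still yields a valid nonnegative matrix. All randomness flows from the
cohort seed through `numpy.random.default_rng`; two runs with the same
config and seed produce byte-identical feature CSVs.

## Problem sizes

Defaults were chosen once as realistic study conditions: 70 samples,
8192 complex points per FID (12 ppm at 600 MHz, ~1.1 s acquisition),
zero-filled to 16384. At these sizes a full 70-sample end-to-end run
takes on the order of ten seconds on one CPU, dominated by the
per-sample phase grid search and the baseline smoother iterations.

## Known limitations

* Zero-order phase only; spectra with genuine first-order errors from
  other sources will show rolling baselines that the baseline stage
  must absorb.
* The icoshift variant implements equal-width or user intervals only —
  no variable-size interval merging or warping (COW/PAFFT).
* `acqus` parsing covers the `##$KEY= value` dialect including
  `(0..N)` arrays; Varian/JEOL imports and 2D (`ser`) data are out of
  scope.
* PQN assumes the majority of features are dilution-driven; cohorts
  where most features change biologically violate its premise.
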