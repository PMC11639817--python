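# Methods

## Signal model

`amaresfit` quantifies magnetic resonance spectroscopy (MRS) data in the
time domain.  The free induction decay (FID) is modelled as a sum of `K`
exponentially damped complex sinusoids

    y_n = sum_k  a_k · exp(j φ_k) · exp(−d_k [(1−g_k) + g_k t_n] t_n) · exp(j 2π f_k t_n)

evaluated at the true post-excitation times `t_n = dead_time + n·dwell_time`.
Including the receiver dead time in the time axis is deliberate: it is what
produces the frequency-dependent first-order phase observed in real spectra,
and it is the quantity users most often get wrong when importing
vendor-converted data, so it is an explicit field of every `FIDSignal`.

Per line the model carries an amplitude `a_k` (arbitrary units,
proportional to the integrated spectral area), a frequency offset `f_k`
from the carrier (Hz; exposed to users as a chemical shift in ppm via
`ppm = ref_ppm + Hz / carrier_MHz`), a damping factor `d_k` (1/s), a phase
`φ_k` (degrees at every user surface, radians internally), and a lineshape
parameter `g_k ∈ [0, 1]` whose envelope exponent `−d[(1−g) + g·t]t`
interpolates linearly between a Lorentzian (`g = 0`, exponent ∝ t) and a
Gaussian (`g = 1`, exponent ∝ t²) sharing the single coefficient `d`.

**Linewidth convention.** User-facing tables store a "linewidth" in Hz.  We
map it to the damping through the Lorentzian-equivalent bijection
`d = π·LW` for *every* `g`.  For `g = 0` this makes LW the exact FWHM of
the absorption profile; for `g > 0` the true FWHM is a derived quantity and
is measured numerically from a densely zero-filled spectrum when needed.
A single documented bijection keeps the fit well-posed; making the column
mean "true FWHM" would require inverting a lineshape-dependent relation
inside every objective evaluation for no statistical benefit.

**DFT convention.** `fid_to_spectrum` uses the unnormalized forward FFT,
rotated so index 0 maps to −SW/2 and the centre bin to 0 Hz (carrier).
Parseval then reads `Σ|y_n|² = (1/M)·Σ|Y_m|²`.  First-order phase is
parameterized as a time delay `τ` and applied as `exp(j 2π f τ)`, matching
dead-time physics.  Plots render ppm high-to-low (NMR convention).

## Prior knowledge

Prior knowledge is a small spreadsheet (CSV or XLSX, first sheet): peaks in
columns, the five fields (`amplitude`, `chemicalshift`, `linewidth`,
`phase`, `g`) in rows, an "Initial Values" block above a "Bounds" block.
Multiplets are named by suffixing the primary peak with digits (`BATP`,
`BATP2`, …); digits are reserved for that purpose.  Rows or cells starting
with `#` are comments.  Unicode minus signs and stray whitespace from
spreadsheet exports are normalized before parsing.

Bounds grammar: `(lo, hi)` is a range, `(lo,` and `, hi)` (or `hi)`) are
one-sided, a bare number fixes the parameter.  Tie grammar (initial-value
cells): `NAME` (identity), `NAME/c` or `NAME*c` (ratio), `NAME±cHz`
(chemical-shift offset in Hz, converted to ppm through the carrier at
compile time), `NAME±c` (bare ppm offset).  One binary operation per cell;
additive offsets are only accepted in the `chemicalshift` row, and
expressions inside the Bounds block are rejected with a clear message —
both choices close grammar corners the dialect never uses rather than
guessing semantics for them.  Because the table is parsed left to right, a
tie may only reference a peak to its left, which structurally rules out
cycles.

Classification of each (peak, field):

* initial value is an expression → **tied**: the constraint holds exactly
  for the whole fit (not merely at initialization).  This is what makes
  multiplet ratios and J-splittings hard prior knowledge, and it is also
  what the CRLB propagation relies on.
* bare number + range bound → **free**;
* bare number + bare-number bound, or no bounds entry → **fixed** at the
  initial value.

`compile_parameters` lowers the table onto an `lmfit.Parameters` object;
ties become lmfit constraint expressions evaluated at every objective call,
so tied parameters satisfy their defining relation to machine precision at
any point the optimizer visits.

Note that in the packaged ³¹P example table the lineshape row has range
bounds `(0, 1)`, which under the rules above makes `g` a free parameter
(12 free in total).  Fixing the bounds row to `0` — the common ³¹P usage,
pure Lorentzian — yields the 7-free-parameter configuration used in most of
the test benchmarks.

## Initializers

**HSVD.**  The FID is arranged into an `L × (N−L+1)` Hankel matrix
(`L = N//2` by default), whose rank-`K` truncated SVD spans the signal
subspace.  Signal poles `z_k = exp((−d_k + j2πf_k)·dwell)` are estimated
from the row-shift structure of the left singular vectors (least-squares
solve of `U_top Z ≈ U_bottom`, poles = eigenvalues of `Z`), and complex
amplitudes by linear least squares of the data on the pole basis.
Amplitudes and phases are referred back to `t = 0` (the dead-time evolution
`exp((−d + j2πf)·t0)` is divided out).  When `K` is not given it is chosen
by the largest relative gap between consecutive singular values, capped at
25 — a documented default, adequate for the noiseless/high-SNR regimes
where prior-free fitting is sensible.  Components with negative estimated
damping (growing exponentials, typically noise) are dropped by default and
reported separately.  `hsvd_to_prior` turns retained components into a
prior (one peak per component, free with wide bounds, `g` fixed at 0) so
spectra can be fitted with no prior knowledge at all.

**LM pre-fit.**  `lm_initialize` runs an *unconstrained*
Levenberg–Marquardt pass on the free parameters (ties still enforced),
then clips the result into the declared bounds.  Removing the box bounds is
the point: a starting chemical shift off by 100 Hz usually lies outside the
bounds window, and a bounded solver started there stalls on the boundary,
whereas unconstrained LM walks to the true line and is then clipped (a
no-op when the refined value is feasible).  The refined values are kept
only if they do not worsen the residual; otherwise the input values are
returned with a warning.

## Fitting

The default objective is the concatenated real/imaginary time-domain
residual (length 2N), optionally weighted per sample.  Three solver
configurations: `LM` (unconstrained MINPACK Levenberg–Marquardt, bounds
enforced by post-hoc clipping), `TRR` (SciPy trust region reflective with
box bounds), and `TRR+Init` (unconstrained LM pass first, then TRR) — the
default, and the most robust when starting values are far off.  Jacobians
are numerical forward differences throughout; with free parameters held in
user units (a.u., ppm, Hz, deg) the default steps are well scaled.
Tolerances default to 1e-8 on objective and parameters with a 3000-
evaluation budget, all overridable.  The fitter contains no randomness:
identical inputs give identical outputs, which is what makes batch results
worker-count invariant.  If the solver endpoint is worse than the starting
point (beyond float dust), the starting point is returned and the result
flagged unconverged; active box bounds at the solution are recorded in the
convergence message.

**Frequency-selective fitting** comes in two flavours:

* *Masked objective*: model and data are Fourier transformed at the data
  length (no extra zero-fill, so bin membership is unambiguous) and the
  complex difference is restricted to bins whose ppm falls in the window.
* *FIR extraction* (`mpfir_extract`): a Hamming-window low-pass prototype
  of order 50 (default) is modulated to the window centre, giving a complex
  band-pass FIR.  It is applied zero-phase in the frequency domain —
  circular convolution with the delay-compensated filter.  A causal
  convolution would corrupt the first `order/2` samples of a decaying FID
  (exactly the most signal-rich ones); circular application has no startup
  transient, and its wrap-around contribution is negligible because the FID
  has decayed by the end of the record.  The Hamming design gives ≈0.2%
  passband ripple and ≈53 dB stopband attenuation, comfortably beyond the
  40 dB the equivalence experiments require.

## Uncertainty

Noise is summarized as the per-channel (real/imag) standard deviation σ of
the time-domain samples, estimated by default from the trailing 1/8 of the
raw FID (each channel mean-centred, then pooled); `residual` mode uses the
fit residual instead.  Tail estimation is robust to fit bias, residual mode
to short records.

The Fisher information of the free parameters is `F = (1/σ²)·JᵀJ`, where
`J` is the central-difference Jacobian of the 2N-long real model vector
with respect to the *free* parameters only — ties enter through the chain
rule via the compiled constraint expressions, which is how the prior
knowledge tightens the bound.  Because the residual convention is the
2N-real concatenation with per-channel σ, no factor of 2 appears, and the
single-free-amplitude case reduces exactly to `CRLB_a = σ/‖m‖₂`.
`CRLB% = 100·CRLB/|estimate|`.  Per-peak amplitude CRLBs (including tied
subpeaks) and summed multiplet amplitudes use the linear combination
`wᵀ F⁻¹ w` with `w` the gradient of the (summed) amplitude with respect to
the free parameters; a scale-tied subpeak therefore inherits its source's
relative uncertainty exactly.  A singular `F` is pseudo-inverted, flagged
with its condition number, and unidentifiable directions report infinite
CRLBs.  SNR is the fitted amplitude per one σ; amplitude rows with
`CRLB% < 20` (default threshold) are flagged reliable and rendered green in
the HTML report, red otherwise.

## Post-processing for macromolecule spectra

Three small operations support isolating the mobile-macromolecule (MM)
baseline of short-echo ¹H spectra: quarter-sine weighting of the first `M`
FID points (`w_i = sin(i·π/(2(M−1)))`, anchored `w_0 = 0`, `w_{M−1} = 1`,
default `M = 20`; the anchoring is pinned so tests can be bit-exact),
frequency alignment by multiplying the FID with `exp(−j2πΔf·t_n)` (e.g. to
put water at 4.7 ppm), and subtraction of selected fitted components from
the original FID.  In the removal pipeline the quarter-sine ramp is used as
*objective weights* for the metabolite fit: it de-emphasizes the early
samples where the fast-decaying MM signal lives, so the narrow-line fit is
nearly unbiased, and the fitted metabolites are then subtracted from the
*unweighted* FID.

## Batch fitting

`fit_batch` maps one prior over many FIDs with a process pool (the fits
are CPU-bound, so thread-level parallelism would be serialized by the
interpreter lock).  Payloads are picklable, output order always equals
input order, per-index failures are logged without aborting the batch, and
— because each fit is deterministic — the numeric outputs are bit-identical
for any worker count.

## Synthetic validation designs

The Monte-Carlo harness (`mc_validation`) is first-class, tested code and
the repository's only fixture source.  Designs are frozen so results mean
the same thing everywhere:

* **Singlet robustness benchmark**: one Lorentzian line, amplitude 1,
  0 ppm on a 120.645 MHz carrier (³¹P at 7 T), 30 Hz linewidth, zero phase,
  SW 5 kHz, N = 512.  The *truth* chemical shift is perturbed uniformly
  within ±100 Hz replicate-by-replicate while the prior stays nominal, so
  the initializer must correct large frequency errors.  SNR is defined as
  the largest true amplitude per one per-channel time-domain σ; the grid
  {5, 10, 20} spans low to high SNR.  Perturbations are uniform on the
  stated half-width (the distribution is otherwise unconstrained; uniform
  makes the worst case as likely as the typical one).  Benchmarks use 200
  replicates — enough for ~0.5% precision on a mean bias — with base seed
  20241127 and per-replicate seed `base + index`, making every replicate
  individually reproducible.
* **Two-peak frequency-selective study**: in-band line at the carrier,
  larger nuisance line 1000 Hz away, window ±300 Hz; used to show MPFIR
  extraction, the masked objective and the full two-peak fit agree.
* **MM-removal study**: two broad components (250–300 Hz linewidth,
  T2* ≈ 1.3 ms) plus two narrow lines (4–5 Hz) sampled at 2 kHz, so the
  20-point weighting window (10 ms) spans several MM time constants — the
  regime the weighting is designed for.
* **Dynamic series**: 366 spectra (N = 256) with a phosphocreatine-like
  amplitude ramp (rest → linear depletion → mono-exponential recovery,
  τ = 40 s at 2 s per spectrum) and a mirrored inorganic-phosphate line,
  at SNR 40; exercises batch fitting and time-course recovery.

What these designs do *not* emulate: static-field drift, eddy-current and
lineshape distortions, non-Gaussian or correlated noise, baseline signals
other than the modelled MM components, and J-coupling evolution beyond
fixed splittings.  Passing the synthetic benchmarks therefore demonstrates
the estimator and its uncertainty calculus, not robustness to acquisition
artifacts — those are expected to be handled upstream by preprocessing
tools.

## Degenerate inputs and numerical edges

Zero FIDs yield zero-amplitude HSVD components (poles are clipped away from
the origin so the amplitude solve stays finite).  All-fixed priors return
an evaluation-only result with a warning.  Masked objectives reject empty
masks; FIR extraction rejects passbands narrower than two bins and orders
below 8.  Relative CRLBs are flagged undefined for zero estimates.  Noise
estimation requires at least 16 usable samples (128 for tail mode).

## Known limitations

* Only linear ties (identity, ratio, offset) are supported — deliberately
  matching the spreadsheet dialect; no general expression language.
* Analytic Jacobians are not implemented; numerical differentiation costs
  roughly one residual evaluation per free parameter per iteration.
* The CRLB is computed for the time-domain objective even when a masked
  objective was used for fitting; for narrow masks this can understate the
  uncertainty of out-of-band-contaminated parameters.
* Vendor raw-data reading, coil combination, apodization/zero-filling
  pipelines and eddy-current correction are out of scope; FIDs enter as
  plain CSV/NPY plus a JSON metadata sidecar.
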