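# amaresfit

Time-domain AMARES fitting of magnetic resonance spectroscopy (MRS) data in
Python: model-based quantification of free induction decays (FIDs) as sums
of exponentially damped sinusoids under spreadsheet-encoded prior knowledge,
with HSVD and Levenberg–Marquardt initializers, Cramér–Rao lower bounds
propagated through parameter ties, frequency-selective fitting, parallel
batch processing, and a Monte-Carlo validation harness.

## Who this is for

MRS researchers quantifying metabolites — especially X-nuclei (³¹P, ¹³C,
²H, ¹²⁹Xe) spectra, dynamic series and MRSI voxel data — who want the
AMARES approach (time-domain fitting with hard prior knowledge, no basis
sets, no phasing step) as a plain Python library and CLI.

## The model

The FID is fitted as

    y_n = Σ_k  a_k · e^{jφ_k} · e^{−d_k[(1−g_k)+g_k t_n]t_n} · e^{j2πf_k t_n},
    t_n = dead_time + n·dwell_time,

with per-line amplitude `a_k`, frequency `f_k` (exposed as chemical shift in
ppm), damping `d_k` (exposed as linewidth, `d = π·LW`), phase `φ_k`
(degrees), and lineshape `g_k ∈ [0,1]` mixing Lorentzian (`g=0`) and
Gaussian (`g=1`) decay.  Prior knowledge — initial values, box bounds, and
algebraic ties such as the amplitude ratio `BATP/2` or the J-coupling
splitting `BATP-15Hz` — is read from a small CSV/XLSX table, compiled into
constrained parameters, and enforced exactly throughout the fit.  Free
parameters are solved by bounded trust-region least squares, by default
preceded by an unconstrained Levenberg–Marquardt pass that corrects starting
frequencies off by as much as ±100 Hz.  Each parameter's Cramér–Rao lower
bound is reported as a percentage of its estimate (rows under 20% flagged
reliable), and each peak's SNR as the fitted amplitude per one standard
deviation of the time-domain noise.  See `docs/methods.md` for conventions,
defaults and limitations.

## Worked example

Fit a synthetic ³¹P ATP-region spectrum against the packaged prior table
(β-ATP triplet + α-ATP doublet, tied by J-coupling and amplitude ratios):

```python
import numpy as np
import amaresfit as af
from amaresfit.prior_knowledge import compile_parameters, params_to_peaks
from amaresfit.uncertainty import compute_crlb, estimate_noise_sd
from amaresfit.results_report import assemble_results

pk = af.parse_prior_knowledge(af.example_prior_path(), carrier_mhz=120.645)

# synthesize "measured" data at the prior's initial values + noise
compiled = compile_parameters(pk)
truth = params_to_peaks(compiled.params, compiled.peak_names, 120.645, 0.0)
clean = af.synthesize_fid(truth.values(), n_points=1024,
                          dwell_time=1 / 5000, carrier_mhz=120.645)
rng = np.random.default_rng(0)
fid = clean.with_samples(clean.samples
                         + 0.02 * (rng.standard_normal(1024)
                                   + 1j * rng.standard_normal(1024)))

result = af.fit_amares(fid, pk, method="TRR+Init")
noise = estimate_noise_sd(fid)
report = compute_crlb(result, noise)
tables = assemble_results(result, report)
print(tables.result_sum[["name", "amplitude", "crlb_pct", "snr",
                         "reliable"]].round(3).to_string(index=False))
print(f"sigma = {noise.sigma:.4f}, converged = {result.success}")
```

Output:

```
name  amplitude  crlb_pct     snr  reliable
BATP      2.817     0.356 141.473      True
AATP      3.092     0.234 155.280      True
sigma = 0.0199, converged = True
```

`result_sum` has one row per multiplet: the β-ATP amplitude 2.817 is the
sum of the triplet's subpeaks (the table was generated with 1.41 + 0.705 +
0.705 = 2.82), its amplitude CRLB is 0.36% of the estimate (well under the
20% reliability threshold, hence `reliable = True`), and the SNR of ~141 is
the summed amplitude divided by the estimated noise SD 0.0199.  The
per-subpeak breakdown is in `tables.result_multiplet`.

The same pipeline is available from the shell:

```sh
amaresfit fit --fid fid.csv --meta meta.json --prior prior.csv --out results/
amaresfit batch --fids voxels/ --meta meta.json --prior prior.csv --workers 4 --out results/
amaresfit hsvd --fid fid.csv --meta meta.json --out results/   # prior-free starting values
```

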