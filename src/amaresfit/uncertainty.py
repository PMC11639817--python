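"""Cramér-Rao lower bounds, noise estimation, and per-peak SNR.

For Gaussian noise of standard deviation ``sigma`` per real/imaginary
channel, the Fisher information of the free parameters is

    F = (1 / sigma^2) * J^T J,

where ``J`` is the Jacobian of the concatenated real/imaginary model vector
with respect to the *free* parameters only: linear ties between parameters
(multiplet amplitude ratios, shared linewidths, J-coupling splittings) are
exact constraints and enter through the chain rule, which is what makes the
bound account for the prior knowledge.  The CRLB of each free parameter is
``sqrt((F^-1)_ii)``; summed multiplet amplitudes use the corresponding
linear combination of the amplitude covariance block.  SNR is the fitted
amplitude per one standard deviation of the time-domain noise.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .signal_model import FIDSignal
from .fit_engine import FitResult, _model_samples
from .prior_knowledge import param_name

__all__ = [
    "NoiseEstimate",
    "UncertaintyReport",
    "estimate_noise_sd",
    "compute_crlb",
    "compute_snr",
]

MIN_NOISE_SAMPLES = 16


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-channel (real/imag) noise standard deviation and its provenance."""

    sigma: float
    source: str
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_samples_used < MIN_NOISE_SAMPLES:
            raise ValueError(
                f"noise estimate needs >= {MIN_NOISE_SAMPLES} samples, "
                f"got {self.n_samples_used}"
            )


def estimate_noise_sd(series, fraction: float = 0.125, source: str = "fid_tail") -> NoiseEstimate:
    """Estimate the per-channel noise SD of an FID or residual series.

    ``fid_tail`` mode pools the real and imaginary parts of the trailing
    ``fraction`` of the samples (where the signal has decayed); ``residual``
    mode pools the whole series.  Each channel is mean-centred before
    pooling.
    """
    samples = series.samples if isinstance(series, FIDSignal) else np.asarray(series)
    samples = np.asarray(samples, dtype=complex).ravel()
    if source == "fid_tail":
        if samples.size < 128:
            raise ValueError("tail-mode noise estimation needs >= 128 samples")
        n_used = max(int(round(samples.size * fraction)), MIN_NOISE_SAMPLES)
        tail = samples[-n_used:]
    elif source == "residual":
        tail = samples
        n_used = samples.size
    else:
        raise ValueError(f"unknown noise source {source!r}")
    if n_used < MIN_NOISE_SAMPLES:
        raise ValueError(f"fewer than {MIN_NOISE_SAMPLES} usable samples")
    re = tail.real - tail.real.mean()
    im = tail.imag - tail.imag.mean()
    # pooled per-channel SD; ddof=1 per channel
    sigma = float(np.sqrt((np.sum(re**2) + np.sum(im**2)) / (2 * (n_used - 1))))
    return NoiseEstimate(sigma=sigma, source=source, n_samples_used=n_used)


def compute_snr(amplitude: float, sigma) -> float:
    """SNR = fitted amplitude per one standard deviation of the noise."""
    s = sigma.sigma if isinstance(sigma, NoiseEstimate) else float(sigma)
    if s == 0:
        return float("inf") if amplitude != 0 else 0.0
    return float(amplitude) / s


@dataclass
class UncertaintyReport:
    """CRLBs per free parameter, per peak amplitude, and per multiplet group.

    ``free`` maps parameter names to ``{"crlb_abs", "crlb_pct"}``;
    ``peak_amplitude`` maps peak names to ``{"amplitude", "crlb_abs",
    "crlb_pct", "snr"}`` (tied amplitudes propagated through their linear
    constraint); ``group_amplitude`` maps multiplet roots to the summed
    amplitude and its propagated CRLB.
    """

    sigma: float
    free: dict
    peak_amplitude: dict
    group_amplitude: dict
    covariance: np.ndarray
    free_names: list
    condition_number: float
    singular: bool = False
    flags: list = dataclass_field(default_factory=list)


def _free_jacobian(fitresult: FitResult, rel_step: float = 1e-6) -> tuple:
    """Central-difference Jacobian of the 2N real model vector wrt free params."""
    compiled = fitresult.compiled
    fid = fitresult.fid
    base = copy.deepcopy(fitresult.params)
    free_names = [n for n, p in base.items() if p.vary]
    columns = []
    for name in free_names:
        theta = base[name].value
        h = rel_step * max(abs(theta), 1.0)
        plus, minus = copy.deepcopy(base), copy.deepcopy(base)
        plus[name].value = theta + h
        minus[name].value = theta - h
        plus.update_constraints()
        minus.update_constraints()
        m_plus = _model_samples(plus, fid, compiled)
        m_minus = _model_samples(minus, fid, compiled)
        diff = (m_plus - m_minus) / (2.0 * h)
        columns.append(np.concatenate([diff.real, diff.imag]))
    return free_names, np.column_stack(columns)


def _amplitude_gradients(fitresult: FitResult, free_names, rel_step: float = 1e-6) -> dict:
    """d(amplitude of each peak) / d(free params); exact for linear ties."""
    base = copy.deepcopy(fitresult.params)
    grads = {name: np.zeros(len(free_names)) for name in fitresult.peak_names}
    amp_names = {p: param_name(p, "amplitude") for p in fitresult.peak_names}
    for i, name in enumerate(free_names):
        theta = base[name].value
        h = rel_step * max(abs(theta), 1.0)
        plus, minus = copy.deepcopy(base), copy.deepcopy(base)
        plus[name].value = theta + h
        minus[name].value = theta - h
        plus.update_constraints()
        minus.update_constraints()
        for peak, amp_name in amp_names.items():
            grads[peak][i] = (plus[amp_name].value - minus[amp_name].value) / (2.0 * h)
    return grads


def compute_crlb(
    fitresult: FitResult,
    sigma: NoiseEstimate | float,
    groups: dict | None = None,
) -> UncertaintyReport:
    """Cramér-Rao lower bounds at the fitted solution.

    The Jacobian is numerical and taken with respect to the free parameters
    only; tied parameters enter via the chain rule through the lmfit
    constraint expressions.  A singular Fisher matrix is pseudo-inverted and
    the report flagged, with infinite CRLBs for unidentifiable directions.
    """
    s = sigma.sigma if isinstance(sigma, NoiseEstimate) else float(sigma)
    if not s > 0:
        raise ValueError("sigma must be > 0 for CRLB computation")
    groups = groups if groups is not None else fitresult.compiled.multiplet_groups

    free_names, jac = _free_jacobian(fitresult)
    fisher = jac.T @ jac / s**2
    cond = float(np.linalg.cond(fisher)) if fisher.size else float("inf")
    flags: list = []
    singular = False
    try:
        cov = np.linalg.inv(fisher)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError("non-finite inverse")
    except np.linalg.LinAlgError:
        singular = True
        cov = np.linalg.pinv(fisher)
        flags.append(f"singular Fisher matrix (cond={cond:.3g}); pseudo-inverse used")
        warnings.warn(flags[-1])

    crlb_abs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if singular:
        # directions outside the range of F are unidentifiable
        rank = np.linalg.matrix_rank(fisher)
        if rank < len(free_names):
            null_mask = np.isclose(np.diag(fisher), 0.0)
            crlb_abs = np.where(null_mask, np.inf, crlb_abs)

    free: dict = {}
    for name, bound in zip(free_names, crlb_abs):
        estimate = fitresult.params[name].value
        if estimate == 0:
            pct = float("nan")
            flags.append(f"CRLB% undefined for {name}: estimate is 0")
        else:
            pct = 100.0 * bound / abs(estimate)
        free[name] = {"crlb_abs": float(bound), "crlb_pct": float(pct)}

    amp_grads = _amplitude_gradients(fitresult, free_names)
    peak_amplitude: dict = {}
    for peak in fitresult.peak_names:
        amp = fitresult.params[param_name(peak, "amplitude")].value
        w = amp_grads[peak]
        var = float(w @ cov @ w)
        bound = float(np.sqrt(max(var, 0.0)))
        pct = 100.0 * bound / abs(amp) if amp != 0 else float("nan")
        peak_amplitude[peak] = {
            "amplitude": float(amp),
            "crlb_abs": bound,
            "crlb_pct": float(pct),
            "snr": compute_snr(amp, s),
        }

    group_amplitude: dict = {}
    for root, members in groups.items():
        missing = [m for m in members if m not in peak_amplitude]
        if missing:
            raise ValueError(f"multiplet group {root!r} references unknown peaks {missing}")
        w = np.sum([amp_grads[m] for m in members], axis=0)
        total = float(np.sum([peak_amplitude[m]["amplitude"] for m in members]))
        var = float(w @ cov @ w)
        bound = float(np.sqrt(max(var, 0.0)))
        pct = 100.0 * bound / abs(total) if total != 0 else float("nan")
        group_amplitude[root] = {
            "amplitude": total,
            "crlb_abs": bound,
            "crlb_pct": float(pct),
            "snr": compute_snr(total, s),
        }

    return UncertaintyReport(
        sigma=s,
        free=free,
        peak_amplitude=peak_amplitude,
        group_amplitude=group_amplitude,
        covariance=cov,
        free_names=free_names,
        condition_number=cond,
        singular=singular,
        flags=flags,
    )
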