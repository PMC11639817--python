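"""Starting-value generators: Hankel-SVD decomposition and an LM pre-fit.

HSVD models the FID as a sum of exponentially damped sinusoids without any
prior knowledge: the FID is arranged into a Hankel matrix whose rank-``K``
truncated SVD spans the signal subspace; the signal poles
``z_k = exp((-d_k + j 2 pi f_k) * dwell)`` follow from the row-shift
structure of the left singular vectors (state-space estimation), and the
complex amplitudes from a linear least-squares fit of the data onto the pole
basis.  The Levenberg-Marquardt (LM) pre-fit refines compiled starting values
by an *unconstrained* least-squares pass (so it can correct large frequency
errors), then clips the result back into the declared bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.linalg

from .signal_model import FIDSignal, hz_to_ppm
from .prior_knowledge import (
    Bound,
    CompiledParams,
    PeakSpec,
    PriorKnowledge,
    param_name,
)

__all__ = [
    "HSVDComponents",
    "hsvd_decompose",
    "reconstruct_components",
    "hsvd_to_prior",
    "lm_initialize",
    "hsvd_initialize",
]

#: cap on the automatically selected model order
MAX_AUTO_ORDER = 25


@dataclass
class HSVDComponents:
    """Damped-sinusoid components recovered by Hankel-SVD.

    Arrays are sorted by frequency.  Components whose estimated damping is
    negative (growing signals, typically noise artifacts) are dropped by
    default and kept in ``dropped`` for inspection.  Amplitudes and phases
    are referenced to ``t = 0`` (dead time removed).
    """

    frequency_hz: np.ndarray
    damping: np.ndarray
    amplitude: np.ndarray
    phase_deg: np.ndarray
    singular_values: np.ndarray
    model_order: int
    dropped: list = dataclass_field(default_factory=list)
    ill_conditioned: bool = False

    @property
    def n_components(self) -> int:
        return self.frequency_hz.size


def _auto_order(s: np.ndarray) -> int:
    # largest relative gap between consecutive singular values, capped
    limit = min(MAX_AUTO_ORDER, s.size - 1)
    if limit < 1:
        return 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = s[:limit] / s[1 : limit + 1]
    ratios = np.where(np.isfinite(ratios), ratios, np.inf)
    return int(np.argmax(ratios)) + 1


def hsvd_decompose(
    fid: FIDSignal,
    k: int | None = None,
    hankel_rows: int | None = None,
    drop_negative_damping: bool = True,
) -> HSVDComponents:
    """Black-box decomposition of an FID into damped sinusoids.

    Parameters
    ----------
    fid
        Input signal.
    k
        Model order (number of components).  When omitted it is chosen by
        the largest relative singular-value gap, capped at 25.
    hankel_rows
        Number of Hankel rows ``L`` (default ``N // 2``); the matrix is
        ``L x (N - L + 1)``.
    drop_negative_damping
        Drop components with negative estimated damping (default).
    """
    y = fid.samples
    n = y.size
    rows = n // 2 if hankel_rows is None else int(hankel_rows)
    if not 2 <= rows <= n - 1:
        raise ValueError(f"hankel_rows must be in [2, {n - 1}], got {rows}")
    hankel = scipy.linalg.hankel(y[:rows], y[rows - 1 :])
    u, s, _ = np.linalg.svd(hankel, full_matrices=False)
    k_max = min(rows - 1, n - rows)
    if k is None:
        k = min(_auto_order(s), k_max)
    if not 1 <= k <= k_max:
        raise ValueError(f"model order K must be in [1, {k_max}], got {k}")

    uk = u[:, :k]
    # row-shifted least squares: U_bottom ~= U_top @ Z; poles = eig(Z)
    z_mat, _, rank, _ = np.linalg.lstsq(uk[:-1], uk[1:], rcond=None)
    ill = rank < k
    if ill:
        warnings.warn("ill-conditioned HSVD pole solve; components flagged")
    poles = np.linalg.eigvals(z_mat)

    abs_poles = np.maximum(np.abs(poles), 1e-300)
    damping = -np.log(abs_poles) / fid.dwell_time
    frequency = np.angle(poles) / (2.0 * np.pi * fid.dwell_time)

    # complex amplitudes of y_n = sum_k c_k z_k^n by linear least squares;
    # degenerate poles (|z| ~ 0 on null input) are clipped so the basis stays finite
    safe_poles = np.where(np.abs(poles) < 1e-300, 1e-300, poles)
    exponents = np.arange(n)[:, None] * np.log(safe_poles)[None, :]
    exponents = np.clip(exponents.real, -700.0, 700.0) + 1j * exponents.imag
    basis = np.exp(exponents)
    coeffs, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)

    # refer amplitude/phase to t=0: c_k includes the dead-time evolution
    t0 = fid.dead_time
    amplitude = np.abs(coeffs) * np.exp(damping * t0)
    phase = np.rad2deg(np.angle(coeffs) - 2.0 * np.pi * frequency * t0)
    phase = (phase + 180.0) % 360.0 - 180.0

    order = np.argsort(frequency)
    frequency, damping = frequency[order], damping[order]
    amplitude, phase = amplitude[order], phase[order]

    dropped: list = []
    if drop_negative_damping:
        keep = damping >= 0
        for i in np.where(~keep)[0]:
            dropped.append(
                {
                    "frequency_hz": float(frequency[i]),
                    "damping": float(damping[i]),
                    "amplitude": float(amplitude[i]),
                    "phase_deg": float(phase[i]),
                }
            )
        frequency, damping = frequency[keep], damping[keep]
        amplitude, phase = amplitude[keep], phase[keep]

    return HSVDComponents(
        frequency_hz=frequency,
        damping=damping,
        amplitude=amplitude,
        phase_deg=phase,
        singular_values=s,
        model_order=int(k),
        dropped=dropped,
        ill_conditioned=bool(ill),
    )


def reconstruct_components(components: HSVDComponents, fid: FIDSignal) -> np.ndarray:
    """Re-synthesize the component sum on the acquisition grid of ``fid``."""
    t = fid.time_axis
    y = np.zeros(fid.n_points, dtype=complex)
    for a, f, d, ph in zip(
        components.amplitude,
        components.frequency_hz,
        components.damping,
        components.phase_deg,
    ):
        y += a * np.exp(1j * np.deg2rad(ph)) * np.exp((-d + 2j * np.pi * f) * t)
    return y


def hsvd_to_prior(
    components: HSVDComponents,
    carrier_mhz: float,
    sw_hz: float,
    ref_ppm: float = 0.0,
) -> PriorKnowledge:
    """Build prior knowledge from HSVD components when none was supplied.

    One peak ``Peak1..PeakK`` per retained component, sorted by frequency:
    amplitude, chemical shift, linewidth and phase free with wide default
    bounds (shift bounded by the spectral window), lineshape g fixed at 0.
    """
    if components.n_components < 1:
        raise ValueError("no retained HSVD components to build a prior from")
    half_window_ppm = (sw_hz / 2.0) / carrier_mhz
    peaks = []
    for i in range(components.n_components):
        a = float(components.amplitude[i])
        cs = float(hz_to_ppm(components.frequency_hz[i], carrier_mhz, ref_ppm))
        lw = float(components.damping[i] / np.pi)
        ph = float(components.phase_deg[i])
        initial = {
            "amplitude": a,
            "chemicalshift": cs,
            "linewidth": lw,
            "phase": ph,
            "g": 0.0,
        }
        bounds = {
            "amplitude": Bound(lower=0.0),
            "chemicalshift": Bound(
                lower=ref_ppm - half_window_ppm, upper=ref_ppm + half_window_ppm
            ),
            "linewidth": Bound(lower=0.0),
            "phase": Bound(lower=-180.0, upper=180.0),
            "g": Bound(fixed=0.0),
        }
        peaks.append(PeakSpec(name=f"Peak{i + 1}", initial=initial, bounds=bounds))
    return PriorKnowledge(peaks=tuple(peaks), carrier_mhz=carrier_mhz, ref_ppm=ref_ppm)


def _residual_norm(params, fid, compiled, objective) -> float:
    from .fit_engine import build_residual

    r = build_residual(params, fid, compiled, objective)
    return float(np.dot(r, r))


def lm_initialize(fid: FIDSignal, compiled: CompiledParams, params=None, objective=None):
    """Refine starting values with an unconstrained Levenberg-Marquardt pass.

    Box bounds are removed for the pass (LM is unconstrained, which lets it
    correct initial frequencies that are off by far more than the bound
    width), the result is clipped back into the declared bounds, and the
    refined values are returned only if they do not worsen the residual.
    ``params`` defaults to the compiled starting values.
    """
    import copy

    import lmfit

    from .fit_engine import build_residual, default_objective

    objective = objective or default_objective()
    params = compiled.fresh() if params is None else copy.deepcopy(params)
    baseline = _residual_norm(params, fid, compiled, objective)

    unbounded = copy.deepcopy(params)
    bounds = {}
    for name, par in unbounded.items():
        if par.vary:
            bounds[name] = (par.min, par.max)
            par.min, par.max = -np.inf, np.inf
    try:
        result = lmfit.minimize(
            build_residual,
            unbounded,
            args=(fid, compiled, objective),
            method="leastsq",
            xtol=1e-8,
            ftol=1e-8,
            max_nfev=3000,
            calc_covar=False,
        )
        refined = result.params
    except Exception as err:  # pragma: no cover - lmfit internal failures
        warnings.warn(f"LM initializer did not converge ({err}); keeping input values")
        return params

    for name, (lo, hi) in bounds.items():
        par = refined[name]
        par.min, par.max = lo, hi
        par.value = float(min(max(par.value, lo), hi))
    refined.update_constraints()

    refined_norm = _residual_norm(refined, fid, compiled, objective)
    if refined_norm > baseline + 1e-12 * (1.0 + baseline):
        warnings.warn("LM initializer worsened the residual; keeping input values")
        return params
    return refined


def hsvd_initialize(fid: FIDSignal, compiled: CompiledParams):
    """Refine free starting values from an HSVD decomposition of the data.

    Each peak is matched to the nearest HSVD component in frequency; its free
    amplitude/shift/linewidth/phase starting values are replaced by the
    component estimates, clipped into the declared bounds.
    """
    params = compiled.fresh()
    comps = hsvd_decompose(fid, k=max(len(compiled.peak_names), 1))
    if comps.n_components == 0:
        warnings.warn("HSVD returned no usable components; keeping input values")
        return params
    comp_ppm = hz_to_ppm(comps.frequency_hz, compiled.carrier_mhz, compiled.ref_ppm)
    for peak in compiled.peak_names:
        cs_name = param_name(peak, "chemicalshift")
        i = int(np.argmin(np.abs(comp_ppm - params[cs_name].value)))
        updates = {
            "amplitude": float(comps.amplitude[i]),
            "chemicalshift": float(comp_ppm[i]),
            "linewidth": float(comps.damping[i] / np.pi),
            "phase": float(comps.phase_deg[i]),
        }
        for fieldname, value in updates.items():
            par = params[param_name(peak, fieldname)]
            if par.vary:
                par.value = float(min(max(value, par.min), par.max))
    params.update_constraints()
    return params
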