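"""Result tables, reliability flagging, MM-removal helpers, and plot data.

Fitting results are reported in two tables: ``result_multiplet`` has one row
per modelled peak (including every subpeak of a J-coupled multiplet) and
``result_sum`` one row per multiplet group, with the subpeak amplitudes
summed and the CRLB of the sum propagated through the amplitude covariance.
Rows whose amplitude CRLB% falls below a threshold (default 20%) are flagged
reliable, and the HTML rendering colours them green (red otherwise).

This module also carries the post-processing steps used when isolating the
mobile-macromolecule (MM) baseline from short-echo spectra: quarter-sine
weighting of the first FID points, frequency alignment by FID phase ramping,
and subtraction of fitted metabolite components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_model import FIDSignal, fid_to_spectrum, synthesize_like
from .fit_engine import FitResult
from .uncertainty import UncertaintyReport

__all__ = [
    "ResultTables",
    "assemble_results",
    "quarter_sine_weights",
    "quarter_sine_weight",
    "shift_fid_to_reference",
    "subtract_fitted",
    "render_report",
    "fit_arrays",
    "plot_fit",
]

DEFAULT_CRLB_THRESHOLD = 20.0

MULTIPLET_COLUMNS = [
    "name",
    "amplitude",
    "chemicalshift_ppm",
    "linewidth_hz",
    "phase_deg",
    "g",
    "crlb_pct",
    "snr",
    "reliable",
]


@dataclass
class ResultTables:
    """The two result tables plus the reliability threshold used."""

    result_multiplet: pd.DataFrame
    result_sum: pd.DataFrame
    threshold: float


def assemble_results(
    fitresult: FitResult,
    report: UncertaintyReport,
    groups: dict | None = None,
    threshold: float = DEFAULT_CRLB_THRESHOLD,
) -> ResultTables:
    """Build ``result_multiplet`` and ``result_sum`` from a fit and its CRLBs.

    The group amplitude in ``result_sum`` is exactly the sum of its members'
    amplitudes (the time-domain amplitude is proportional to the integrated
    spectral area under this model, so no lineshape re-integration is done).
    """
    groups = groups if groups is not None else fitresult.compiled.multiplet_groups
    from .prior_knowledge import param_name

    rows = []
    for peak in fitresult.peak_names:
        amp_stats = report.peak_amplitude[peak]
        rows.append(
            {
                "name": peak,
                "amplitude": fitresult.params[param_name(peak, "amplitude")].value,
                "chemicalshift_ppm": fitresult.params[param_name(peak, "chemicalshift")].value,
                "linewidth_hz": fitresult.params[param_name(peak, "linewidth")].value,
                "phase_deg": fitresult.params[param_name(peak, "phase")].value,
                "g": fitresult.params[param_name(peak, "g")].value,
                "crlb_pct": amp_stats["crlb_pct"],
                "snr": amp_stats["snr"],
            }
        )
    multiplet = pd.DataFrame(rows, columns=[c for c in MULTIPLET_COLUMNS if c != "reliable"])
    multiplet["reliable"] = multiplet["crlb_pct"] < threshold

    sum_rows = []
    for root, members in groups.items():
        missing = [m for m in members if m not in set(multiplet["name"])]
        if missing:
            raise ValueError(f"group {root!r} references missing peaks {missing}")
        member_rows = multiplet[multiplet["name"].isin(members)]
        gstats = report.group_amplitude[root]
        sum_rows.append(
            {
                "name": root,
                "amplitude": float(np.sum(member_rows["amplitude"].to_numpy())),
                "chemicalshift_ppm": float(member_rows["chemicalshift_ppm"].iloc[0]),
                "linewidth_hz": float(member_rows["linewidth_hz"].iloc[0]),
                "n_subpeaks": len(members),
                "crlb_pct": gstats["crlb_pct"],
                "snr": gstats["snr"],
            }
        )
    result_sum = pd.DataFrame(sum_rows)
    result_sum["reliable"] = result_sum["crlb_pct"] < threshold
    return ResultTables(result_multiplet=multiplet, result_sum=result_sum, threshold=threshold)


def quarter_sine_weights(n_weighted: int, n_points: int) -> np.ndarray:
    """Quarter-sine ramp: ``w_i = sin(i * pi / (2 (M-1)))`` for ``i < M``, else 1.

    Anchored at ``w_0 = 0`` and ``w_{M-1} = 1`` so the first sample is zeroed
    and the ramp reaches unity exactly at the last weighted point.
    """
    if n_weighted <= 1:
        raise ValueError("n_weighted must be > 1")
    if n_weighted >= n_points:
        raise ValueError("n_weighted must be smaller than the number of points")
    w = np.ones(n_points)
    i = np.arange(n_weighted)
    w[:n_weighted] = np.sin(i * np.pi / (2.0 * (n_weighted - 1)))
    return w


def quarter_sine_weight(fid: FIDSignal, n_weighted: int = 20) -> FIDSignal:
    """Apply the quarter-sine ramp to the first ``n_weighted`` FID samples."""
    w = quarter_sine_weights(n_weighted, fid.n_points)
    samples = fid.samples.copy()
    samples[:n_weighted] = samples[:n_weighted] * w[:n_weighted]
    return fid.with_samples(samples)


def shift_fid_to_reference(
    fid: FIDSignal, observed_peak_ppm: float, target_ppm: float
) -> FIDSignal:
    """Shift the spectrum so a peak observed at one ppm lands on another.

    Multiplies the FID by ``exp(-j 2 pi df t_n)`` with
    ``df = (observed - target) * carrier_mhz``; the magnitude spectrum is
    circularly shifted, its shape preserved.
    """
    delta_hz = (observed_peak_ppm - target_ppm) * fid.carrier_mhz
    if abs(delta_hz) >= fid.sw_hz / 2:
        raise ValueError(
            f"shift of {delta_hz:g} Hz exceeds half the spectral window"
        )
    if delta_hz == 0.0:
        return fid.with_samples(fid.samples)
    ramp = np.exp(-2j * np.pi * delta_hz * fid.time_axis)
    return fid.with_samples(fid.samples * ramp)


def subtract_fitted(fid: FIDSignal, fitted_peaks: dict, subset=None) -> FIDSignal:
    """Subtract selected fitted components from the FID (metabolite removal).

    ``fitted_peaks`` maps names to model-unit peak parameters (as stored on
    :class:`FitResult`); ``subset`` selects which to subtract (default all;
    an empty subset returns the input unchanged).
    """
    names = list(fitted_peaks) if subset is None else list(subset)
    unknown = [n for n in names if n not in fitted_peaks]
    if unknown:
        raise ValueError(f"unknown peak names {unknown}")
    if not names:
        return fid.with_samples(fid.samples)
    model = synthesize_like([fitted_peaks[n] for n in names], fid)
    return fid.with_samples(fid.samples - model.samples)


_HTML_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>AMARES fit results</title>
<style>
table {{ border-collapse: collapse; font-family: sans-serif; }}
td, th {{ border: 1px solid #999; padding: 4px 8px; text-align: right; }}
tr.reliable {{ background-color: #c8e6c9; }}
tr.unreliable {{ background-color: #ffcdd2; }}
</style></head>
<body>
<p>Amplitude CRLB threshold: {threshold:g}% (green: reliable, red: unreliable)</p>
<table>
<tr>{header}</tr>
{rows}
</table>
</body></html>
"""


def _html_table(df: pd.DataFrame, threshold: float) -> str:
    header = "".join(f"<th>{c}</th>" for c in df.columns)
    rows = []
    for _, row in df.iterrows():
        cls = "reliable" if bool(row["reliable"]) else "unreliable"
        cells = "".join(
            f"<td>{v:.6g}</td>" if isinstance(v, float) else f"<td>{v}</td>"
            for v in row
        )
        rows.append(f'<tr class="{cls}">{cells}</tr>')
    return _HTML_PAGE.format(threshold=threshold, header=header, rows="\n".join(rows))


def render_report(tables: ResultTables, out_dir, formats=("csv", "html")) -> dict:
    """Write ``result_multiplet.csv``, ``result_sum.csv`` and the HTML table.

    Returns a mapping of artifact names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if "csv" in formats:
        for key, df in (
            ("result_multiplet", tables.result_multiplet),
            ("result_sum", tables.result_sum),
        ):
            path = out_dir / f"{key}.csv"
            df.to_csv(path, index=False)
            written[key] = path
    if "html" in formats:
        path = out_dir / "result_sum.html"
        path.write_text(_html_table(tables.result_sum, tables.threshold))
        written["result_sum_html"] = path
    return written


def fit_arrays(fitresult: FitResult, zero_fill: int | None = None) -> dict:
    """Spectra of the original, fitted, residual, and per-component signals.

    The plotted residual equals original minus fitted bin-wise, and the sum
    of the component spectra equals the fitted spectrum to machine precision
    (Fourier linearity); these arrays are the tested plotting surface.
    """
    fid = fitresult.fid
    original = fid_to_spectrum(fid, zero_fill=zero_fill)
    fitted = fid_to_spectrum(fitresult.model_fid(), zero_fill=zero_fill)
    components = {}
    for name, peak in fitresult.peaks.items():
        comp_fid = synthesize_like([peak], fid)
        components[name] = fid_to_spectrum(comp_fid, zero_fill=zero_fill).intensities
    return {
        "freq_hz": original.freq_hz,
        "ppm": original.ppm,
        "original": original.intensities,
        "fitted": fitted.intensities,
        "residual": original.intensities - fitted.intensities,
        "components": components,
    }


def plot_fit(fitresult: FitResult, path=None, zero_fill: int | None = None, ifphase: bool = False):
    """Render the standard fit figure (original/fitted/residual + components).

    ppm increases right-to-left following NMR convention.  Returns the
    matplotlib figure; writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arrays = fit_arrays(fitresult, zero_fill=zero_fill)
    ppm = arrays["ppm"]
    if ifphase:
        # display-only zero-order phasing that maximizes the real integral
        phase = -np.angle(np.sum(arrays["fitted"]))
        rot = np.exp(1j * phase)
    else:
        rot = 1.0
    fig, (top, bottom) = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    top.plot(ppm, (arrays["original"] * rot).real, color="0.4", label="original")
    top.plot(ppm, (arrays["fitted"] * rot).real, color="crimson", label="fitted")
    top.plot(ppm, (arrays["residual"] * rot).real, "--", color="green", label="residual")
    top.legend(loc="best")
    for name, comp in arrays["components"].items():
        bottom.plot(ppm, (comp * rot).real, label=name)
    bottom.legend(loc="best", fontsize="small")
    bottom.set_xlabel("chemical shift (ppm)")
    top.invert_xaxis()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def total_amplitude(df: pd.DataFrame) -> float:
    """Deterministic row-order sum of a table's amplitude column."""
    return math.fsum(df["amplitude"].tolist())
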