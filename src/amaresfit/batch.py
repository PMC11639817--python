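"""Parallel batch fitting of many FIDs against one prior-knowledge set.

Dynamic series and MRSI voxel data are fitted spectrum-by-spectrum with the
same prior knowledge and settings.  Parallelism is process-based (so the
CPU-bound fits are not serialized by the interpreter lock) with a picklable
task payload; every fit is deterministic, so the numeric outputs are
identical regardless of worker count or execution order, and failures are
isolated per input index rather than aborting the batch.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field as dataclass_field

import pandas as pd

from .fit_engine import ObjectiveSpec, fit_amares
from .prior_knowledge import PriorKnowledge, param_name
from .uncertainty import compute_crlb, estimate_noise_sd

__all__ = ["FitSettings", "BatchResult", "fit_batch"]


@dataclass(frozen=True)
class FitSettings:
    """Settings shared by every fit in a batch."""

    method: str = "TRR+Init"
    objective: ObjectiveSpec | None = None
    initializer: str | None = None
    noise_from: str = "auto"  # fid_tail when long enough, else residual
    crlb: bool = True


@dataclass
class BatchResult:
    """Per-index results (input order), a long-format table, and failures."""

    results: list
    failures: dict
    table: pd.DataFrame
    reports: list = dataclass_field(default_factory=list)


def _noise_source(settings: FitSettings, n_points: int) -> str:
    if settings.noise_from != "auto":
        return settings.noise_from
    return "fid_tail" if n_points >= 128 else "residual"


def _fit_one(payload):
    index, fid, pk, settings = payload
    try:
        result = fit_amares(
            fid,
            pk,
            method=settings.method,
            objective=settings.objective,
            initializer=settings.initializer,
        )
        report = None
        if settings.crlb:
            source = _noise_source(settings, fid.n_points)
            series = fid if source == "fid_tail" else result.residual
            noise = estimate_noise_sd(series, source=source)
            if noise.sigma > 0:
                report = compute_crlb(result, noise)
        return index, result, report, None
    except Exception as err:  # noqa: BLE001 - failures are isolated per index
        return index, None, None, f"{type(err).__name__}: {err}"


def _long_rows(index, result, report):
    rows = []
    for peak in result.peak_names:
        stats = report.peak_amplitude[peak] if report is not None else {}
        rows.append(
            {
                "index": index,
                "peak": peak,
                "amplitude": result.params[param_name(peak, "amplitude")].value,
                "chemicalshift_ppm": result.params[param_name(peak, "chemicalshift")].value,
                "linewidth_hz": result.params[param_name(peak, "linewidth")].value,
                "phase_deg": result.params[param_name(peak, "phase")].value,
                "g": result.params[param_name(peak, "g")].value,
                "crlb_pct": stats.get("crlb_pct", float("nan")),
                "snr": stats.get("snr", float("nan")),
                "success": result.success,
            }
        )
    return rows


def fit_batch(
    fids,
    pk: PriorKnowledge,
    settings: FitSettings | None = None,
    n_workers: int = 1,
    progress: bool = False,
) -> BatchResult:
    """Fit a list of FIDs and aggregate a long-format results table.

    Output order always matches input order.  ``n_workers > 1`` distributes
    the fits over processes; results are bit-identical to a sequential run.
    """
    settings = settings or FitSettings()
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    payloads = [(i, fid, pk, settings) for i, fid in enumerate(fids)]

    if n_workers == 1:
        iterator = map(_fit_one, payloads)
    else:
        executor = ProcessPoolExecutor(max_workers=n_workers)
        iterator = executor.map(_fit_one, payloads, chunksize=max(len(payloads) // (4 * n_workers), 1))

    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, total=len(payloads), desc="batch fit")

    outcomes = sorted(iterator, key=lambda item: item[0])
    if n_workers > 1:
        executor.shutdown()

    results, reports, failures, rows = [], [], {}, []
    for index, result, report, error in outcomes:
        results.append(result)
        reports.append(report)
        if error is not None:
            failures[index] = error
        else:
            rows.extend(_long_rows(index, result, report))
    table = pd.DataFrame(rows)
    return BatchResult(results=results, failures=failures, table=table, reports=reports)
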