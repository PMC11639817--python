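"""File readers/writers, run configuration, and the end-to-end pipeline.

FIDs travel as two-column ``real,imag`` CSV files (one complex sample per
row) or packed ``.npy`` arrays, with acquisition metadata in a JSON sidecar
(``carrier_mhz``, ``sw_hz``, ``dead_time_s``, ``ref_ppm``).  Vendor raw
formats are out of scope; dedicated conversion tools already exist and their
output can be exported to these simple containers.

``run_pipeline`` ties the stages together: load, optional initializer,
optional frequency-selective extraction, fit, noise/CRLB, result tables and
plot arrays, plus a machine-readable manifest (package and library versions,
seed, merged configuration and its hash) sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .signal_model import FIDSignal
from .prior_knowledge import parse_prior_knowledge
from .fit_engine import ObjectiveSpec, fit_amares, mpfir_extract
from .uncertainty import compute_crlb, estimate_noise_sd
from .results_report import assemble_results, fit_arrays, render_report

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_fid",
    "write_fid",
    "read_meta",
    "run_pipeline",
]

logger = logging.getLogger("amaresfit")

META_KEYS = ("carrier_mhz", "sw_hz", "dead_time_s", "ref_ppm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def read_meta(meta) -> dict:
    """Load and validate acquisition metadata (dict or JSON path)."""
    if isinstance(meta, (str, Path)):
        with open(meta) as handle:
            meta = json.load(handle)
    missing = [k for k in META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"metadata missing keys: {missing}")
    if not meta["carrier_mhz"] > 0 or not meta["sw_hz"] > 0 or meta["dead_time_s"] < 0:
        raise ValueError("metadata physical quantities out of range")
    return {k: float(meta[k]) for k in META_KEYS}


def read_fid(path, meta) -> FIDSignal:
    """Read an FID from ``real,imag`` CSV or a packed ``.npy`` complex array."""
    path = Path(path)
    meta = read_meta(meta)
    if path.suffix.lower() == ".npy":
        samples = np.load(path, allow_pickle=False).astype(complex)
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
        for column in ("real", "imag"):
            if column not in frame.columns:
                raise ValueError(f"FID CSV {path} lacks a {column!r} column")
        numeric = frame[["real", "imag"]].apply(pd.to_numeric, errors="coerce")
        bad = numeric.index[numeric.isna().any(axis=1)]
        if len(bad):
            raise ValueError(f"FID CSV {path} has non-numeric samples at rows {list(bad[:5])}")
        samples = numeric["real"].to_numpy(float) + 1j * numeric["imag"].to_numpy(float)
    if not np.all(np.isfinite(samples)):
        rows = np.where(~np.isfinite(samples))[0]
        raise ValueError(f"FID {path} has non-finite samples at rows {rows[:5].tolist()}")
    logger.info("read FID %s: %d points", path, samples.size)
    return FIDSignal(
        samples=samples,
        dwell_time=1.0 / meta["sw_hz"],
        carrier_mhz=meta["carrier_mhz"],
        dead_time=meta["dead_time_s"],
        ref_ppm=meta["ref_ppm"],
    )


def write_fid(fid: FIDSignal, path) -> None:
    """Write an FID as ``real,imag`` CSV (lossless round trip with read_fid)."""
    path = Path(path)
    # pandas' default float repr is shortest-round-trip, so the CSV is lossless
    frame = pd.DataFrame({"real": fid.samples.real, "imag": fid.samples.imag})
    frame.to_csv(path, index=False)


def meta_of(fid: FIDSignal) -> dict:
    return {
        "carrier_mhz": fid.carrier_mhz,
        "sw_hz": fid.sw_hz,
        "dead_time_s": fid.dead_time,
        "ref_ppm": fid.ref_ppm,
    }


@dataclass
class RunConfig:
    """Everything one fitting run needs; round-trips losslessly via JSON."""

    fid: str
    meta: str | dict
    prior: str
    out_dir: str
    method: str = "TRR+Init"
    objective: str = "time"  # "time" | "mask" | "mpfir"
    ppm_range: tuple | None = None
    initializer: str | None = None
    crlb_threshold: float = 20.0
    noise_from: str = "fid_tail"
    zero_fill: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        if payload["ppm_range"] is not None:
            payload["ppm_range"] = list(payload["ppm_range"])
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        if payload.get("ppm_range") is not None:
            payload["ppm_range"] = tuple(payload["ppm_range"])
        return cls(**payload)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _stage(stage: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute load -> (initializer) -> (extraction) -> fit -> CRLB -> report.

    Writes result tables, the fit-array bundle and a run manifest into
    ``config.out_dir``; re-running the same configuration reproduces the
    outputs bit-for-bit.  Raises :class:`PipelineError` naming the failing
    stage otherwise.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fid = _stage("load_fid")(read_fid, config.fid, config.meta)
    if not Path(config.prior).exists():
        raise PipelineError("load_prior", f"prior file not found: {config.prior}")
    pk = _stage("load_prior")(
        parse_prior_knowledge, config.prior, fid.carrier_mhz, fid.ref_ppm
    )

    objective = ObjectiveSpec()
    fit_fid = fid
    if config.objective == "mask":
        objective = _stage("objective")(
            ObjectiveSpec, mode="frequency_masked", ppm_range=config.ppm_range
        )
    elif config.objective == "mpfir":
        if config.ppm_range is None:
            raise PipelineError("objective", "mpfir extraction needs --ppm-range")
        fit_fid = _stage("mpfir")(mpfir_extract, fid, config.ppm_range)
    elif config.objective != "time":
        raise PipelineError("objective", f"unknown objective {config.objective!r}")

    result = _stage("fit")(
        fit_amares,
        fit_fid,
        pk,
        method=config.method,
        objective=objective,
        initializer=config.initializer,
    )
    logger.info(
        "fit: N=%d SW=%.1f Hz dead=%.4g s free=%d method=%s converged=%s",
        fid.n_points,
        fid.sw_hz,
        fid.dead_time,
        sum(p.vary for p in result.params.values()),
        config.method,
        result.success,
    )

    source = config.noise_from if fid.n_points >= 128 else "residual"
    series = fit_fid if source == "fid_tail" else result.residual
    noise = _stage("noise")(estimate_noise_sd, series, source=source)
    logger.info("noise sigma=%.6g (%s)", noise.sigma, noise.source)
    artifacts: dict = {}
    if noise.sigma > 0:
        report = _stage("crlb")(compute_crlb, result, noise)
        tables = _stage("report")(
            assemble_results, result, report, threshold=config.crlb_threshold
        )
        artifacts.update(_stage("report")(render_report, tables, out_dir))

    arrays = _stage("arrays")(fit_arrays, result, config.zero_fill)
    bundle = out_dir / "fit_arrays.npz"
    np.savez(
        bundle,
        freq_hz=arrays["freq_hz"],
        ppm=arrays["ppm"],
        original=arrays["original"],
        fitted=arrays["fitted"],
        residual=arrays["residual"],
        **{f"component_{k}": v for k, v in arrays["components"].items()},
    )
    artifacts["fit_arrays"] = bundle

    manifest = {
        "amaresfit_version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "converged": result.success,
        "message": result.message,
        "sigma": noise.sigma,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    artifacts["manifest"] = manifest_path
    return artifacts
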