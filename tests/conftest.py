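"""Shared fixtures: all test inputs are synthesized programmatically."""

import numpy as np
import pytest

import amaresfit as af
from amaresfit.prior_knowledge import (
    compile_parameters,
    load_prior_table,
    params_to_peaks,
    parse_prior_knowledge,
)

CARRIER_31P_7T = 120.645  # MHz
SW_HZ = 5000.0


@pytest.fixture(scope="session")
def table1_rows():
    return load_prior_table(af.example_prior_path())


@pytest.fixture(scope="session")
def table1_pk():
    """The packaged ATP multiplet prior, parsed as printed (g free)."""
    return parse_prior_knowledge(af.example_prior_path(), carrier_mhz=CARRIER_31P_7T)


@pytest.fixture(scope="session")
def table1_fixed_g_pk(table1_rows):
    """Variant with the lineshape fixed Lorentzian (g bounds row = 0)."""
    rows = [list(r) for r in table1_rows]
    seen_bounds = False
    for row in rows:
        if row and row[0].strip().lower() == "bounds":
            seen_bounds = True
        if seen_bounds and row and row[0].strip() == "g":
            row[1:] = ["0"] * (len(row) - 1)
    return parse_prior_knowledge(rows, carrier_mhz=CARRIER_31P_7T)


@pytest.fixture(scope="session")
def atp_truth_peaks(table1_fixed_g_pk):
    """Model-unit truth taken from the prior's initial values."""
    compiled = compile_parameters(table1_fixed_g_pk)
    return params_to_peaks(
        compiled.params, compiled.peak_names, compiled.carrier_mhz, compiled.ref_ppm
    )


@pytest.fixture(scope="session")
def atp_fid(atp_truth_peaks):
    """Noiseless 5-peak ATP-region FID at the prior's initial values."""
    return af.synthesize_fid(
        atp_truth_peaks.values(),
        n_points=1024,
        dwell_time=1.0 / SW_HZ,
        carrier_mhz=CARRIER_31P_7T,
    )


def make_singlet(
    amplitude=1.0,
    frequency_hz=250.0,
    damping=30.0,
    phase_deg=30.0,
    g=0.0,
    n_points=512,
    sw_hz=SW_HZ,
    carrier_mhz=CARRIER_31P_7T,
    dead_time=0.0,
):
    return af.synthesize_fid(
        [af.PeakParameters(amplitude, frequency_hz, damping, phase_deg, g)],
        n_points=n_points,
        dwell_time=1.0 / sw_hz,
        carrier_mhz=carrier_mhz,
        dead_time=dead_time,
    )


@pytest.fixture()
def singlet_fid():
    return make_singlet()


def add_noise(fid, sigma, seed=0):
    rng = np.random.default_rng(seed)
    noise = sigma * (
        rng.standard_normal(fid.n_points) + 1j * rng.standard_normal(fid.n_points)
    )
    return fid.with_samples(fid.samples + noise)
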