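"""Objectives, MPFIR extraction, and the bounded nonlinear fit."""

import numpy as np
import pytest

import amaresfit as af
from amaresfit.fit_engine import ObjectiveSpec, build_residual, mpfir_extract
from amaresfit.prior_knowledge import (
    Bound,
    PeakSpec,
    PriorKnowledge,
    compile_parameters,
)
from amaresfit.mc_validation import (
    SINGLET_CARRIER_MHZ,
    singlet_prior,
    two_peak_selective_study,
)

from conftest import add_noise, make_singlet

C = SINGLET_CARRIER_MHZ
SW = 5000.0


def _singlet_compiled_at_truth():
    compiled = compile_parameters(singlet_prior())
    params = compiled.fresh()
    params["Peak_amp"].value = 1.0
    params["Peak_lw"].value = 30.0
    params.update_constraints()
    return compiled, params


class TestBuildResidual:
    def test_zero_at_a_perfect_fit_with_length_2n(self):
        compiled, params = _singlet_compiled_at_truth()
        fid = make_singlet(amplitude=1.0, frequency_hz=0.0, damping=np.pi * 30.0,
                           phase_deg=0.0)
        r = build_residual(params, fid, compiled, ObjectiveSpec())
        assert r.shape == (2 * fid.n_points,)
        assert np.max(np.abs(r)) < 1e-12

    def test_norm_squared_matches_complex_misfit(self):
        compiled, params = _singlet_compiled_at_truth()
        fid = add_noise(make_singlet(amplitude=1.0, frequency_hz=0.0,
                                     damping=np.pi * 30.0, phase_deg=0.0), 0.1)
        r = build_residual(params, fid, compiled, ObjectiveSpec())
        from amaresfit.fit_engine import _model_samples

        misfit = _model_samples(params, fid, compiled) - fid.samples
        assert np.dot(r, r) == pytest.approx(np.sum(np.abs(misfit) ** 2), rel=1e-12)

    def test_empty_mask_rejected(self):
        compiled, params = _singlet_compiled_at_truth()
        fid = make_singlet()
        spec = ObjectiveSpec(mode="frequency_masked", ppm_range=(300.0, 301.0))
        with pytest.raises(ValueError, match="no spectral bins"):
            build_residual(params, fid, compiled, spec)

    def test_user_hook_output_validated(self):
        compiled, params = _singlet_compiled_at_truth()
        fid = make_singlet()
        bad = ObjectiveSpec(mode="user_hook", user_hook=lambda p, f, c: np.empty(0))
        with pytest.raises(ValueError, match="non-empty"):
            build_residual(params, fid, compiled, bad)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ObjectiveSpec(weights=np.array([1.0, -1.0]))

    def test_mask_requires_a_range(self):
        with pytest.raises(ValueError, match="ppm_range"):
            ObjectiveSpec(mode="frequency_masked")


class TestMPFIR:
    def test_out_of_band_attenuated_in_band_preserved(self):
        study = two_peak_selective_study()
        fid = study["fid"]
        filtered = mpfir_extract(fid, study["ppm_range"])
        spec0 = af.fid_to_spectrum(fid)
        spec1 = af.fid_to_spectrum(filtered)
        i_in = int(np.argmin(np.abs(spec0.freq_hz - 0.0)))
        i_out = int(np.argmin(np.abs(spec0.freq_hz - 1000.0)))
        in_ratio = abs(spec1.intensities[i_in]) / abs(spec0.intensities[i_in])
        out_db = 20 * np.log10(
            abs(spec1.intensities[i_out]) / abs(spec0.intensities[i_out])
        )
        assert in_ratio == pytest.approx(1.0, abs=0.02)
        assert out_db <= -40.0

    def test_full_window_passband_is_transparent(self):
        fid = make_singlet(frequency_hz=200.0)
        half = (0.49 * SW) / C
        filtered = mpfir_extract(fid, (-half, half))
        mag0 = af.fid_to_spectrum(fid).magnitude
        mag1 = af.fid_to_spectrum(filtered).magnitude
        keep = mag0 > 0.05 * mag0.max()
        np.testing.assert_allclose(mag1[keep], mag0[keep], rtol=0.02)

    def test_narrow_passband_and_low_order_rejected(self):
        fid = make_singlet()
        bin_ppm = (SW / fid.n_points) / C
        with pytest.raises(ValueError, match="2 spectral bins"):
            mpfir_extract(fid, (0.0, bin_ppm))
        with pytest.raises(ValueError, match="filter_order"):
            mpfir_extract(fid, (-1.0, 1.0), filter_order=4)

    def test_out_of_window_band_rejected(self):
        fid = make_singlet()
        with pytest.raises(ValueError, match="outside"):
            mpfir_extract(fid, (0.0, SW / C))


class TestFitAmares:
    def test_noiseless_multiplet_fit_at_truth(self, atp_fid, table1_fixed_g_pk):
        result = af.fit_amares(atp_fid, table1_fixed_g_pk, method="TRR")
        rel = np.linalg.norm(result.residual) / np.linalg.norm(atp_fid.samples)
        assert rel < 1e-8
        assert result.params["BATP_amp"].value == pytest.approx(1.41, rel=1e-6)
        assert result.params["AATP_amp"].value == pytest.approx(1.545, rel=1e-6)
        assert result.params["BATP_cs"].value == pytest.approx(-16.15, rel=1e-6)

    def test_masked_full_window_matches_time_domain(self):
        fid = make_singlet(amplitude=1.2, frequency_hz=80.0, damping=np.pi * 30.0,
                           phase_deg=20.0)
        window = (-(SW / 2 - 1) / C, (SW / 2 - 1) / C)
        t_res = af.fit_amares(fid, singlet_prior(), method="TRR")
        m_res = af.fit_amares(
            fid,
            singlet_prior(),
            method="TRR",
            objective=ObjectiveSpec(mode="frequency_masked", ppm_range=window),
        )
        for name in ("Peak_amp", "Peak_cs", "Peak_lw", "Peak_phase"):
            scale = max(abs(t_res.params[name].value), 1.0)
            assert abs(m_res.params[name].value - t_res.params[name].value) / scale < 1e-6

    def test_truth_outside_bound_lands_on_the_bound(self):
        # true amplitude above a deliberately wrong upper bound
        fid = make_singlet(amplitude=2.0, frequency_hz=0.0, damping=np.pi * 30.0,
                           phase_deg=0.0)
        peak = PeakSpec(
            name="Peak",
            initial={"amplitude": 1.0, "chemicalshift": 0.0, "linewidth": 30.0,
                     "phase": 0.0, "g": 0.0},
            bounds={
                "amplitude": Bound(lower=0.0, upper=1.5),
                "chemicalshift": Bound(lower=-1.0, upper=1.0),
                "linewidth": Bound(lower=5.0, upper=100.0),
                "phase": Bound(fixed=0.0),
                "g": Bound(fixed=0.0),
            },
        )
        pk = PriorKnowledge(peaks=(peak,), carrier_mhz=C)
        result = af.fit_amares(fid, pk, method="TRR")
        assert result.params["Peak_amp"].value == pytest.approx(1.5, abs=1e-6)
        assert any("Peak_amp" in b for b in result.active_bounds)
        assert "active bounds" in result.message

    def test_all_fixed_returns_evaluation_only(self):
        fid = make_singlet(amplitude=1.0, frequency_hz=0.0, damping=np.pi * 30.0,
                           phase_deg=0.0)
        peak = PeakSpec(
            name="Peak",
            initial={"amplitude": 1.0, "chemicalshift": 0.0, "linewidth": 30.0,
                     "phase": 0.0, "g": 0.0},
            bounds={f: Bound(fixed=v) for f, v in
                    [("amplitude", 1.0), ("chemicalshift", 0.0), ("linewidth", 30.0),
                     ("phase", 0.0), ("g", 0.0)]},
        )
        pk = PriorKnowledge(peaks=(peak,), carrier_mhz=C)
        with pytest.warns(UserWarning, match="evaluation-only"):
            result = af.fit_amares(fid, pk, method="TRR")
        assert result.evaluation_only
        assert np.max(np.abs(result.residual)) < 1e-12

    def test_objective_never_worse_than_start(self):
        fid = add_noise(make_singlet(amplitude=1.0, frequency_hz=60.0,
                                     damping=np.pi * 30.0, phase_deg=0.0), 0.2, seed=3)
        compiled = compile_parameters(singlet_prior())
        start = compiled.fresh()
        from amaresfit.fit_engine import _objective_value

        start_value = _objective_value(start, fid, compiled, ObjectiveSpec())
        for method in ("LM", "TRR", "TRR+Init"):
            result = af.fit_amares(fid, compiled, method=method)
            assert result.objective_value <= start_value + 1e-9

    def test_nonfinite_fid_rejected(self):
        fid = make_singlet().with_samples(np.full(512, np.nan, dtype=complex))
        with pytest.raises(ValueError, match="non-finite"):
            af.fit_amares(fid, singlet_prior())

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            af.fit_amares(make_singlet(), singlet_prior(), method="nelder")

    def test_deterministic_given_identical_inputs(self):
        fid = add_noise(make_singlet(), 0.1, seed=11)
        a = af.fit_amares(fid, singlet_prior(), method="TRR+Init")
        b = af.fit_amares(fid, singlet_prior(), method="TRR+Init")
        for name in a.params:
            assert a.params[name].value == b.params[name].value

    def test_trr_init_not_worse_than_trr_on_perturbed_singlets(self):
        # TRR+Init should match or better plain TRR when the starting
        # frequency is far off (30 draws of the perturbed-singlet benchmark)
        from amaresfit.mc_validation import simulate_dataset, singlet_design

        design = singlet_design(snr=5.0, n_replicates=30)
        data = simulate_dataset(design)
        compiled = compile_parameters(singlet_prior())
        gains = []
        for fid, _truth in data:
            plain = af.fit_amares(fid, compiled, method="TRR")
            seeded = af.fit_amares(fid, compiled, method="TRR+Init")
            gains.append(plain.objective_value - seeded.objective_value)
        assert np.mean(gains) >= -1e-9
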