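"""Generator-level checks: determinism, closed forms, conservation laws."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsdquant import qc
from nsdquant import synthetic_data as synth
from nsdquant.quantification import fit_standard_addition


class TestGroundTruth:
    def test_deterministic_per_seed_and_varying_across_seeds(self):
        draws = [synth.make_ground_truth(seed=s) for s in range(10)]
        again = synth.make_ground_truth(seed=0)
        assert draws[0] == again
        pools = {tuple(g.pool_cp for g in d) for d in draws}
        assert len(pools) == 10

    def test_ratios_within_configured_interval(self):
        for seed in range(10):
            for gt in synth.make_ground_truth(seed=seed):
                assert 2.0 <= gt.ga_cp_ratio <= 20.0

    def test_degenerate_interval_gives_equal_pools(self):
        truth = synth.make_ground_truth(seed=3, ratio_interval=(1.0, 1.0))
        for gt in truth:
            assert gt.pool_ga == gt.pool_cp

    def test_negative_pool_rejected_with_analyte_name(self):
        with pytest.raises(ValueError, match="badNSD"):
            synth.make_ground_truth([("badNSD", -5.0)], seed=0)

    def test_default_panel_spans_observed_range(self):
        totals = {g.analyte: g.total for g in synth.make_ground_truth(seed=0)}
        assert totals["GDP-Man"] == pytest.approx(10.93)
        assert totals["UDP-Glc/Gal"] == pytest.approx(2923.58)


class TestTitration:
    def test_noise_free_matches_generator_formula(self, metabolite_params):
        truth = [synth.GroundTruth("X", pool_cp=40.0, pool_ga=160.0)]
        cfg = synth.SimulationConfig(noise_cv=0.0, replicates=1,
                                     digitonin_grid=(0.0, 50.0, 400.0))
        df = synth.simulate_titration(truth, metabolite_params, cfg)
        p = metabolite_params
        for x in (0.0, 50.0, 400.0):
            expected_cp = 40.0 * synth.release_fraction(p, x) + 160.0 * synth.contamination_fraction(p, x)
            got = df[(df.digitonin_ug_per_ml == x) & (df.fraction == "CP")][
                "amount_amol_per_cell"
            ].item()
            assert got == pytest.approx(expected_cp, rel=1e-12)

    def test_saturating_digitonin_limit(self, metabolite_params):
        # far beyond both midpoints the supernatant holds (floor+span)*CP
        # plus the whole leaked GA pool
        truth = [synth.GroundTruth("X", pool_cp=40.0, pool_ga=160.0)]
        p = metabolite_params
        cp = 40.0 * synth.release_fraction(p, 4000.0) + 160.0 * synth.contamination_fraction(p, 4000.0)
        assert cp == pytest.approx(40.0 * (p.floor + p.span) + 160.0, rel=1e-6)

    def test_conservation_before_noise(self, metabolite_params):
        truth = synth.make_ground_truth(seed=1)
        cfg = synth.SimulationConfig(noise_cv=0.0, replicates=2)
        df = synth.simulate_titration(truth, metabolite_params, cfg)
        totals = df.groupby(["analyte", "digitonin_ug_per_ml", "replicate"])[
            "amount_amol_per_cell"
        ].sum()
        for gt in truth:
            assert np.allclose(totals[gt.analyte], gt.total, rtol=1e-12)

    def test_metabolites_release_before_proteins(self):
        met, prot = synth.METABOLITE_RELEASE, synth.PROTEIN_RELEASE
        assert met.midpoint < prot.midpoint
        # half-release point of the noise-free curves, not just the parameter
        x = np.linspace(0, 400, 4001)
        for p in (met, prot):
            y = synth.release_fraction(p, x)
            half = x[np.searchsorted(y, (y[0] + y[-1]) / 2)]
            if p is met:
                met_half = half
            else:
                assert met_half < half

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            synth.SimulationConfig(digitonin_grid=(0.0, 500.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_cv"):
            synth.SimulationConfig(noise_cv=-0.1)

    @given(
        pool_cp=st.floats(0.1, 1e4),
        ratio=st.floats(0.1, 50.0),
        x=st.floats(0.0, 400.0),
    )
    def test_conservation_property(self, pool_cp, ratio, x):
        p = synth.METABOLITE_RELEASE
        cp = pool_cp * synth.release_fraction(p, x) + pool_cp * ratio * synth.contamination_fraction(p, x)
        total = pool_cp * (1.0 + ratio)
        org = total - cp
        assert cp + org == pytest.approx(total, rel=1e-12)
        assert 0.0 <= cp <= total * (1.0 + 1e-9)


class TestStandardAddition:
    def test_noise_free_line(self):
        sa = synth.simulate_standard_addition(0.5, (0.0, 1.0, 2.0), 100.0)
        assert [a for _, a in sa.points] == pytest.approx([50.0, 150.0, 250.0])

    def test_zero_native_zero_area_at_zero_spike(self):
        sa = synth.simulate_standard_addition(0.0, (0.0, 1.0), 100.0)
        assert dict(sa.points)[0.0] == 0.0

    def test_identical_spikes_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            synth.simulate_standard_addition(0.5, (1.0, 1.0, 1.0), 100.0)

    def test_monte_carlo_mean_recovery_within_two_percent(self):
        estimates = [
            fit_standard_addition(
                synth.simulate_standard_addition(
                    0.5, (0.0, 0.5, 1.0, 2.0), 100.0, noise_cv=0.05, seed=s
                )
            ).native_conc_nm
            for s in range(500)
        ]
        assert np.mean(estimates) == pytest.approx(0.5, rel=0.02)


class TestDegradation:
    def test_zero_duration_is_identity(self):
        panel = synth.DEFAULT_FRESH_PANELS[0]
        out = synth.simulate_degradation(panel, "lyophilization", duration_h=0.0)
        assert out == panel

    @pytest.mark.parametrize("method", ["lyophilization", "evaporation"])
    @pytest.mark.parametrize("duration", [1.0, 24.0, 72.0])
    def test_per_base_totals_conserved(self, method, duration):
        for panel in synth.DEFAULT_FRESH_PANELS:
            out = synth.simulate_degradation(panel, method, duration_h=duration)
            assert abs(out.total - panel.total) <= 1e-12 * panel.total

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown concentration method"):
            synth.simulate_degradation(synth.DEFAULT_FRESH_PANELS[0], "air-drying")

    def test_default_calibration_reproduces_ec_ratio(self):
        ecs = {}
        for method in ("lyophilization", "evaporation"):
            ecs[method] = np.mean(
                [
                    qc.energy_charge(synth.simulate_degradation(p, method))
                    for p in synth.DEFAULT_FRESH_PANELS
                ]
            )
        assert ecs["evaporation"] / ecs["lyophilization"] == pytest.approx(0.63, abs=0.005)

    def test_lyophilization_preserves_triphosphates(self):
        for panel in synth.DEFAULT_FRESH_PANELS:
            out = synth.simulate_degradation(panel, "lyophilization")
            assert qc.triphosphate_fraction(out) > 0.54

    def test_warmer_processing_degrades_faster(self):
        panel = synth.DEFAULT_FRESH_PANELS[0]
        cold = synth.simulate_degradation(panel, "lyophilization", temperature_k=277.15)
        warm = synth.simulate_degradation(panel, "lyophilization", temperature_k=310.15)
        assert warm.ntp < cold.ntp


class TestPulseTimecourse:
    def test_default_condition_c_peak(self):
        kernels = [k for k in synth.default_pulse_kernels()
                   if k.condition == "C" and k.compartment == "GA"]
        t = np.linspace(0, 200, 20001)
        trace = kernels[0].evaluate(t)
        assert trace.max() == pytest.approx(2150.0, rel=1e-4)
        assert t[np.argmax(trace)] == pytest.approx(120.0, abs=0.05)

    def test_condition_b_peak(self):
        kern = next(k for k in synth.default_pulse_kernels()
                    if k.condition == "B" and k.compartment == "GA")
        t = np.linspace(0, 300, 30001)
        trace = kern.evaluate(t)
        assert trace.max() == pytest.approx(1400.0, rel=1e-4)
        assert t[np.argmax(trace)] == pytest.approx(150.5, abs=0.05)

    def test_zero_amplitude_is_flat(self):
        kern = synth.PulseKernel.from_peak("A", "GA", "X", baseline=500.0,
                                           peak_amplitude=0.0, peak_time_h=120.0,
                                           decay_rate=0.02)
        assert np.allclose(kern.evaluate([0, 80.5, 120, 200]), 500.0)

    def test_causal_baseline_before_pulse(self):
        kern = synth.default_pulse_kernels()[0]
        t = np.array([0.0, 50.0, kern.pulse_time_h - 1e-9, kern.pulse_time_h])
        assert np.allclose(kern.evaluate(t), kern.baseline)

    def test_returns_toward_baseline(self):
        kern = synth.default_pulse_kernels()[0]
        assert kern.evaluate(5000.0) == pytest.approx(kern.baseline, rel=1e-6)

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError, match="decay_rate"):
            synth.PulseKernel("A", "GA", "X", baseline=1.0, peak_amplitude=1.0,
                              peak_time_h=120.0, rise_rate=0.1, decay_rate=0.0)

    def test_dataframe_layout_and_determinism(self):
        kernels = synth.default_pulse_kernels()
        a = synth.simulate_pulse_timecourse(kernels, noise_cv=0.1, seed=7)
        b = synth.simulate_pulse_timecourse(kernels, noise_cv=0.1, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) == {
            "condition", "compartment", "analyte", "time_h", "replicate",
            "amount_amol_per_cell",
        }

    def test_unsorted_sample_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            synth.simulate_pulse_timecourse(
                synth.default_pulse_kernels(), sample_times_h=(0.0, 10.0, 5.0)
            )


class TestGlycanCoupling:
    def test_zero_exposure_pure_fa2(self):
        profile = synth.simulate_glycan_profiles(0.0)
        assert profile["FA2"] == 1.0
        assert profile["FA2G2"] == 0.0

    def test_saturation_limit(self):
        mapping = synth.GalCouplingMap(p_max=1.0, half_saturation=10.0, hill=2.0)
        profile = synth.simulate_glycan_profiles(1e9, mapping=mapping)
        assert profile["FA2G2"] == pytest.approx(1.0, abs=1e-6)

    def test_simplex_invariant(self):
        for exposure in (0.0, 5.0, 50.0, 500.0):
            profile = synth.simulate_glycan_profiles(exposure, seed=1, noise_cv=0.1)
            vals = list(profile.abundances.values())
            assert sum(vals) == pytest.approx(1.0, abs=1e-12)
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_fa2g2_monotone_in_exposure(self):
        exposures = np.linspace(0, 400, 50)
        g2 = [synth.simulate_glycan_profiles(e)["FA2G2"] for e in exposures]
        assert np.all(np.diff(g2) >= 0)

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValueError, match="exposure"):
            synth.simulate_glycan_profiles(-1.0)
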