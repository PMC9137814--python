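"""Capacitance extraction: interpolation, shift estimator, round trips,
event detection on footprints with known ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capchip import (
    ExtractionSettings,
    InvalidParameterError,
    ReadoutConfig,
    Run,
    SaturatedSweepError,
    Scenario,
    extract_delta,
    extract_offset,
    output_at,
    rightward_shift,
    simulate_experiment,
    sweep_reference,
    time_resolved,
)


def analytic_curve(c_total: float, cfg: ReadoutConfig):
    """Noiseless fractional-pulse bank curve for a given sensing capacitance."""
    x = cfg.bank
    diff = np.clip(c_total - x, -cfg.idr, cfg.idr)
    return x, cfg.balance_count + diff / cfg.resolution


def noisy_curve(c_sense: float, cfg: ReadoutConfig, rng, gate_on=True):
    """Averaged noisy sweep as (c_ref, pulses) arrays."""
    reps = [
        sweep_reference(c_sense, cfg, gate_on=gate_on, rng=rng)["pulses"].to_numpy(float)
        for _ in range(cfg.n_average)
    ]
    return cfg.bank, np.mean(reps, axis=0)


class TestOutputAt:
    def test_grid_point_exact(self, quiet_readout):
        x, y = analytic_curve(500.0, quiet_readout)
        assert output_at(x, y, x[17]) == y[17]

    def test_midpoint_is_mean(self, quiet_readout):
        x, y = analytic_curve(500.0, quiet_readout)
        mid = 0.5 * (x[10] + x[11])
        assert output_at(x, y, mid) == pytest.approx(0.5 * (y[10] + y[11]))

    def test_matches_dense_regrid_oracle(self, quiet_readout):
        x, y = analytic_curve(473.0, quiet_readout)
        at = 617.3
        dense = np.linspace(x[0], x[-1], 200001)
        oracle = np.interp(at, dense, np.interp(dense, x, y))
        assert output_at(x, y, at) == pytest.approx(oracle, abs=1e-6)

    def test_out_of_domain_rejected(self, quiet_readout):
        x, y = analytic_curve(500.0, quiet_readout)
        with pytest.raises(InvalidParameterError):
            output_at(x, y, 1900.0)


class TestRightwardShift:
    def test_identical_curves_zero_shift(self, quiet_readout):
        c = analytic_curve(500.0, quiet_readout)
        level = output_at(*c, 500.0)
        assert rightward_shift(c, c, level) == pytest.approx(0.0, abs=1e-12)

    def test_translated_curve_recovers_shift(self, quiet_readout):
        ref = analytic_curve(500.0, quiet_readout)
        meas = analytic_curve(530.0, quiet_readout)
        level = output_at(*ref, 500.0)
        assert rightward_shift(ref, meas, level) == pytest.approx(30.0, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(250.0, 700.0), st.floats(0.0, 300.0), st.floats(-400.0, 400.0))
    def test_translation_equivariance_on_noiseless_curves(self, c0, shift, level_off):
        # the shift estimator is exactly linear-translation-equivariant for
        # fractional (unquantised) curves within the linear region
        cfg = ReadoutConfig(noise_sd=0.0)
        ref = analytic_curve(c0, cfg)
        meas = analytic_curve(c0 + shift, cfg)
        level = cfg.balance_count + np.clip(level_off, -300.0, 300.0)
        try:
            got = rightward_shift(ref, meas, level)
        except SaturatedSweepError:
            return  # level outside the attained range for this curve pair
        assert got == pytest.approx(shift, abs=1e-6)

    def test_rail_flat_curve_signals_saturation(self, quiet_readout):
        ref = analytic_curve(500.0, quiet_readout)
        x = quiet_readout.bank
        flat = (x, np.full(x.size, float(quiet_readout.saturation_rail)))
        level = output_at(*ref, 500.0)
        with pytest.raises(SaturatedSweepError):
            rightward_shift(ref, flat, level)


class TestOffsetAndDelta:
    def test_zero_ide_capacitance(self, quiet_readout):
        off = analytic_curve(quiet_readout.c_internal, quiet_readout)
        on = analytic_curve(quiet_readout.c_internal + 0.0, quiet_readout)
        assert extract_offset(off, on, quiet_readout) == pytest.approx(0.0, abs=1e-9)

    def test_experimental_baseline_round_trip(self):
        # quantised (integer-pulse) noiseless sweeps through the simulator
        cfg = ReadoutConfig(noise_sd=0.0)
        off = (cfg.bank, sweep_reference(0.0, cfg, gate_on=False)["pulses"].to_numpy(float))
        on = (cfg.bank, sweep_reference(109.0, cfg, gate_on=True)["pulses"].to_numpy(float))
        assert extract_offset(off, on, cfg) == pytest.approx(109.0, abs=0.5)

    def test_delta_round_trip_printed_magnitude(self):
        cfg = ReadoutConfig(noise_sd=0.0)
        c_ide = 109.0
        base = (cfg.bank, sweep_reference(c_ide, cfg)["pulses"].to_numpy(float))
        samp = (cfg.bank, sweep_reference(c_ide + 26.1, cfg)["pulses"].to_numpy(float))
        delta, sat = extract_delta(base, samp, c_ide, cfg)
        assert not sat
        assert delta == pytest.approx(26.1, abs=0.5)

    def test_identical_sample_gives_zero_delta(self, quiet_readout):
        base = analytic_curve(509.0, quiet_readout)
        delta, sat = extract_delta(base, base, 109.0, quiet_readout)
        assert delta == 0.0 and not sat

    def test_saturated_sample_zero_encoded(self, quiet_readout):
        cfg = quiet_readout
        base = analytic_curve(509.0, cfg)
        flat = (cfg.bank, np.full(cfg.bank.size, float(cfg.saturation_rail)))
        delta, sat = extract_delta(base, flat, 109.0, cfg)
        assert delta == 0.0 and sat

    def test_noisy_recovery_within_noise_bound(self):
        # sd = 1 pulse with 10-sample averaging: 3σ shift bound in fF
        cfg = ReadoutConfig(noise_sd=1.0, n_average=10)
        rng = np.random.default_rng(42)
        sd_eff = np.sqrt(cfg.noise_sd**2 + 1.0 / 12.0)  # + rounding quantisation
        bound = max(0.5, 3.0 * sd_eff * cfg.resolution * np.sqrt(2.0 / cfg.n_average))
        for c_ide in (10.0, 55.0, 100.0):
            off = noisy_curve(0.0, cfg, rng, gate_on=False)
            on = noisy_curve(c_ide, cfg, rng)
            got = extract_offset(off, on, cfg)
            assert got == pytest.approx(c_ide, abs=bound)


class TestTimeResolved:
    def test_constant_dry_footprint_flat_and_eventless(self):
        scen = Scenario(duration=100.0, sweep_interval=10.0, runs=())
        cfg = ReadoutConfig(noise_sd=0.0)
        fp = simulate_experiment(scen, cfg, seed=0)
        res = time_resolved(fp, cfg)
        assert res.c_ide["left"] == pytest.approx(109.0, abs=0.5)
        d = res.delta_c
        assert not d["saturated"].any()
        assert (d["delta_c_fF"].abs() < 0.5).all()
        for ch in ("left", "right"):
            assert res.events[ch]["sample_introduced_at"] is None
            assert res.events[ch]["evaporation_onset_at"] is None

    def test_missing_gate_off_sweep_rejected(self):
        scen = Scenario(duration=50.0, sweep_interval=10.0, runs=())
        cfg = ReadoutConfig(noise_sd=0.0)
        fp = simulate_experiment(scen, cfg, seed=0)
        from capchip import Footprint3D
        trimmed = Footprint3D(frame=fp.frame[fp.frame["gate"] == "on"].copy())
        with pytest.raises(InvalidParameterError, match="gate-off"):
            time_resolved(trimmed, cfg)

    def test_event_order_on_canonical_run(self):
        scen = Scenario(duration=600.0, sweep_interval=5.0,
                        runs=(Run(t_deposit=60.0, epithelial_count=13,
                                  neutrophil_count=1),))
        cfg = ReadoutConfig(noise_sd=0.5)
        fp = simulate_experiment(scen, cfg, seed=5)
        res = time_resolved(fp, cfg)
        for ch in ("left", "right"):
            ev = res.events[ch]
            assert ev["sample_introduced_at"] is not None
            assert ev["evaporation_onset_at"] is not None
            assert ev["steady_state_from"] is not None
            assert (ev["sample_introduced_at"] < ev["evaporation_onset_at"]
                    < ev["steady_state_from"])

    def test_event_times_match_generator_ground_truth(self):
        from capchip import ground_truth_events
        cfg = ReadoutConfig(noise_sd=0.5)
        for seed in range(6):
            scen = Scenario(duration=500.0, sweep_interval=5.0,
                            runs=(Run(t_deposit=50.0, evap_duration=200.0,
                                      epithelial_count=8, neutrophil_count=1),))
            truth = ground_truth_events(scen)[0]
            fp = simulate_experiment(scen, cfg, seed=seed)
            res = time_resolved(fp, cfg)
            ev = res.events["left"]
            dt = scen.sweep_interval
            assert abs(ev["sample_introduced_at"] - truth["sample_introduced_at"]) <= dt
            assert abs(ev["evaporation_onset_at"] - truth["evaporation_onset_at"]) <= dt

    def test_zero_coding_iff_saturated(self):
        scen = Scenario(duration=400.0, sweep_interval=10.0,
                        runs=(Run(t_deposit=50.0, evap_duration=150.0,
                                  epithelial_count=10),))
        cfg = ReadoutConfig(noise_sd=0.0)
        fp = simulate_experiment(scen, cfg, seed=2)
        res = time_resolved(fp, cfg)
        d = res.delta_c
        sat = d[d["saturated"]]
        assert (sat["delta_c_fF"] == 0.0).all()
        # saturated sweeps exist exactly while the droplet is on the chip
        assert set(sat["time_s"].unique()) == {
            t for t in fp.times("left") if 50.0 <= t < 200.0
        }
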