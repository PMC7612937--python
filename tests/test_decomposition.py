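"""Five-component decomposition: fit recovery, algebraic identities,
phantom ground truth, area bookkeeping and pulse-pressure binning."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wavesep as ws
from wavesep.decomposition import (
    aortic_rereflections,
    bin_by_pulse_pressure,
    decompose,
    fit_diastolic_decay,
    history_pressure,
    pp_bin_label,
    split_within_cycle,
    systolic_area_contributions,
    within_cycle_pressure,
)
from wavesep.errors import EmptySetError, FitError
from wavesep.waveform import make_beat
from wavesep.wsa import water_hammer_pressure

from conftest import exact_decay_beat

RHO = 1060.0


class TestDiastolicFit:
    def test_noiseless_recovery_to_machine_precision(self, decay_beat):
        fit = fit_diastolic_decay(decay_beat)
        assert fit.p_mu == pytest.approx(40.0, rel=1e-6)
        assert fit.b == pytest.approx(1.5, rel=1e-6)
        assert fit.rms_residual < 1e-9

    def test_noisy_monte_carlo_recovery(self):
        """Median asymptote error stays within 1 mmHg under 0.5 mmHg noise."""
        p_mu_err, b_err = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            beat = exact_decay_beat(noise_sd=0.5, rng=rng)
            fit = fit_diastolic_decay(beat)
            p_mu_err.append(abs(fit.p_mu - 40.0))
            b_err.append(abs(fit.b - 1.5) / 1.5)
        assert np.median(p_mu_err) <= 1.0
        assert np.median(b_err) <= 0.05

    def test_flat_diastole_raises(self):
        t = np.arange(0, 0.85, 1e-3)
        u = np.where(t < 0.3, np.sin(np.pi * t / 0.3), 0.0)
        p = np.where(t < 0.3, 80 + 20 * np.sin(np.pi * t / 0.3), 80.0)
        p[0] = 80.0
        beat = make_beat(t, p, u, RHO, 4.5e-4)
        with pytest.raises(FitError):
            fit_diastolic_decay(beat)

    def test_window_skips_first_10ms(self, decay_beat):
        fit = fit_diastolic_decay(decay_beat)
        i_vc = decay_beat.fiducials.i_vc
        assert fit.window[0] == i_vc + 10
        assert fit.window[1] == decay_beat.fiducials.i_end

    def test_phantom_leak_dominated_fit(self, oracle_config, oracle_output):
        """On the leak-dominated phantom the fit lands near the configured
        asymptote and the predicted discharge rate."""
        fit = fit_diastolic_decay(oracle_output.to_beat())
        assert abs(fit.p_mu - oracle_config.p_mu_target_mmhg) <= 2.5
        assert fit.b == pytest.approx(
            oracle_config.predicted_decay_rate(), rel=0.35
        )


class TestHistoryPressure:
    def test_foot_boundary_condition(self, decay_beat):
        fit = fit_diastolic_decay(decay_beat)
        p_his = history_pressure(fit, decay_beat)
        assert p_his[0] == pytest.approx(decay_beat.dbp - fit.p_mu, abs=1e-12)
        # so that pre-ejection pressure is microcirculation + history
        assert fit.p_mu + p_his[0] == pytest.approx(decay_beat.dbp, abs=1e-12)

    def test_fast_decay_vanishes_by_mid_systole(self, decay_beat):
        fit = dataclasses.replace(fit_diastolic_decay(decay_beat), b=50.0)
        p_his = history_pressure(fit, decay_beat)
        i_mid = decay_beat.fiducials.i_qpeak
        assert abs(p_his[i_mid]) < 1e-2 * (decay_beat.dbp - fit.p_mu)

    def test_matches_phantom_beat_of_origin_tags(
        self, oracle_config, oracle_output
    ):
        """Fitted P_μ + P_his tracks the simulator's prior-beat pressure
        content through systole within 2% of pulse pressure."""
        beat = oracle_output.to_beat()
        fit = fit_diastolic_decay(beat)
        est = fit.p_mu + history_pressure(fit, beat)
        truth = oracle_config.p_mu_target_mmhg + oracle_output.p_history
        sl = beat.fiducials.systole
        assert np.max(np.abs(est - truth)[sl]) <= 0.02 * beat.pp


class TestWithinCycle:
    def test_no_ejection_gives_zero(self, decay_beat):
        fit = fit_diastolic_decay(decay_beat)
        p_his = history_pressure(fit, decay_beat)
        p = fit.p_mu + p_his
        p_cc = within_cycle_pressure(p, p_his, fit.p_mu)
        assert np.allclose(p_cc, 0.0, atol=1e-12)

    def test_starts_at_zero(self, default_analysis):
        assert default_analysis.decomposition.p_cc[0] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_matches_phantom_current_beat_tags(
        self, oracle_config, oracle_output
    ):
        beat = oracle_output.to_beat()
        d = decompose(beat)
        sl = beat.fiducials.systole
        err = np.abs(d.p_cc - oracle_output.p_current)[sl]
        assert err.max() <= 0.02 * beat.pp


class TestSplitWithinCycle:
    def test_reflection_free_has_no_downstream_component(
        self, reflection_free_output
    ):
        out = reflection_free_output
        p_cc = out.p - out.dbp  # no history in the absorbent phantom
        p_down, p_cc_f = split_within_cycle(p_cc, out.u, RHO,
                                            out.config.inlet_c)
        assert np.max(np.abs(p_down)) <= 1e-9 * max(np.ptp(out.p), 1)
        assert np.allclose(p_cc_f, p_cc, atol=1e-9)

    def test_zero_flow_splits_symmetrically(self):
        p_cc = np.concatenate(([0.0], np.cumsum(np.sin(np.arange(63)))))
        p_down, p_cc_f = split_within_cycle(p_cc, np.zeros_like(p_cc), RHO, 5.0)
        assert np.allclose(p_down, p_cc / 2, atol=1e-12)
        assert np.allclose(p_cc_f, p_cc / 2, atol=1e-12)

    def test_partition_is_exact(self, default_analysis):
        d = default_analysis.decomposition
        assert np.allclose(d.p_down + d.p_cc_f, d.p_cc, atol=1e-9)

    def test_matches_phantom_backward_tags(self, oracle_output):
        beat = oracle_output.to_beat()
        d = decompose(beat)
        sl = beat.fiducials.systole
        err = np.abs(d.p_down - oracle_output.p_down_true)[sl]
        assert err.max() <= 0.02 * beat.pp

    def test_exact_inputs_give_exact_backward_content(self, oracle_output):
        """With the true within-cycle pressure and wave speed, the
        running-sum split reproduces the tagged backward content to
        machine precision."""
        out = oracle_output
        p_down, _ = split_within_cycle(
            out.p_current, out.u, RHO, out.config.inlet_c
        )
        assert np.max(np.abs(p_down - out.p_down_true)) < 1e-9


class TestAorticRereflections:
    def test_reflection_free_is_zero(self, reflection_free_output):
        out = reflection_free_output
        p_cc = out.p - out.dbp
        _, p_cc_f = split_within_cycle(p_cc, out.u, RHO, out.config.inlet_c)
        p_wh = water_hammer_pressure(out.u, RHO, out.config.inlet_c)
        assert np.max(np.abs(aortic_rereflections(p_cc_f, p_wh))) <= 1e-9

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_downstream_reflections_pointwise(self, seed):
        """P_Ao ≡ P_down: the re-reflected forward wave mirrors the
        downstream backward wave whenever the foot velocity is zero."""
        rng = np.random.default_rng(seed)
        n = 128
        p_cc = np.concatenate(([0.0], np.cumsum(rng.normal(0, 1, n - 1))))
        u = np.concatenate(([0.0], np.abs(np.cumsum(rng.normal(0, 0.01, n - 1)))))
        c = rng.uniform(3, 10)
        p_down, p_cc_f = split_within_cycle(p_cc, u, RHO, c)
        p_wh = water_hammer_pressure(u, RHO, c)
        p_ao = aortic_rereflections(p_cc_f, p_wh)
        rng_p = max(np.ptp(p_cc), 1.0)
        assert np.max(np.abs(p_ao - p_down)) <= 1e-9 * rng_p

    def test_identity_on_phantom(self, default_analysis):
        d = default_analysis.decomposition
        rng_p = np.ptp(default_analysis.beat.p)
        assert np.max(np.abs(d.p_ao - d.p_down)) <= 1e-9 * rng_p


class TestDecompose:
    def test_reconstruction_identity(self, default_analysis):
        d = default_analysis.decomposition
        beat = default_analysis.beat
        resid = np.abs(d.reconstruction() - beat.p)
        assert resid.max() <= 1e-6 * np.ptp(beat.p)

    def test_near_zero_flow_beat_is_baseline_plus_history(self, decay_beat):
        fit = fit_diastolic_decay(decay_beat)
        t = decay_beat.t
        p_his = (decay_beat.dbp - fit.p_mu) * np.exp(-fit.b * t)
        p = fit.p_mu + p_his
        u = np.where(t < 0.3, 1e-7 * np.sin(np.pi * t / 0.3), 0.0)
        beat = make_beat(t, p, u, RHO, 4.5e-4, noise_floor=1e-9)
        d = decompose(beat, fit=fit, c=5.0)
        scale = np.ptp(p)
        assert np.max(np.abs(d.p_wh)) <= 1e-4 * scale
        assert np.max(np.abs(d.p_down)) <= 1e-4 * scale
        assert np.max(np.abs(d.p_ao)) <= 1e-4 * scale

    def test_scaling_about_asymptote_scales_pulsatile_components(
        self, oracle_output
    ):
        beat = oracle_output.to_beat()
        fit = fit_diastolic_decay(beat)
        c = oracle_output.config.inlet_c
        d1 = decompose(beat, fit=fit, c=c)
        a = 1.2
        p2 = fit.p_mu + a * (beat.p - fit.p_mu)
        beat2 = make_beat(beat.t, p2, a * beat.u, beat.rho, beat.area)
        fit2 = dataclasses.replace(
            fit, p_es=float(p2[beat.fiducials.i_vc]), amplitude=a * fit.amplitude
        )
        d2 = decompose(beat2, fit=fit2, c=c)
        for name in ("p_his", "p_wh", "p_down", "p_ao"):
            assert np.allclose(
                getattr(d2, name), a * getattr(d1, name), atol=1e-8
            ), name


class TestAreas:
    def _manual(self, pct_target=None):
        # piecewise-constant components with hand-computed trapezoid areas
        beat = exact_decay_beat()
        d = decompose(beat)
        return beat, d

    def test_percentages_sum_to_100(self, default_analysis, oracle_output):
        for d in (default_analysis.decomposition,
                  decompose(oracle_output.to_beat())):
            s = systolic_area_contributions(d)
            assert sum(s.pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_hand_computed_constant_traces(self, default_analysis):
        """Constant synthetic components reproduce hand trapezoid areas."""
        d0 = default_analysis.decomposition
        beat = default_analysis.beat
        n = beat.p.size
        i_vc = beat.fiducials.i_vc
        t_sys = beat.t[i_vc]
        # constant traces: p_mu=50, his=10, wh=20, down=-5, ao=-5 -> P=70
        d = dataclasses.replace(
            d0, p_mu=50.0, p_his=np.full(n, 10.0), p_wh=np.full(n, 20.0),
            p_down=np.full(n, -5.0), p_ao=np.full(n, -5.0),
            p_cc=np.full(n, 10.0), p_cc_f=np.full(n, 15.0),
            beat=make_beat(beat.t, np.full(n, 70.0) + 1e-9 * (beat.p - beat.p[0]),
                           beat.u, beat.rho, beat.area),
        )
        s = systolic_area_contributions(d)
        assert s.pct["p_mu"] == pytest.approx(100 * 50 / 70, rel=1e-6)
        assert s.pct["p_his"] == pytest.approx(100 * 10 / 70, rel=1e-6)
        assert s.pct["p_wh"] == pytest.approx(100 * 20 / 70, rel=1e-6)
        assert s.pct["p_down"] == pytest.approx(-100 * 5 / 70, rel=1e-6)
        assert t_sys > 0

    def test_doubling_component_area_doubles_percentage(self, default_analysis):
        d0 = default_analysis.decomposition
        s0 = systolic_area_contributions(d0)
        # double p_wh while compensating in p_his so the total is unchanged
        d1 = dataclasses.replace(
            d0, p_wh=2 * d0.p_wh, p_his=d0.p_his - d0.p_wh
        )
        s1 = systolic_area_contributions(d1)
        assert s1.pct["p_wh"] == pytest.approx(2 * s0.pct["p_wh"], rel=1e-9)


class TestPulsePressureBinning:
    @pytest.mark.parametrize("pp,label", [
        (25.0, "<30"), (35.0, "30-40"), (49.999, "40-50"),
        (70.0, ">70"), (88.0, ">70"), (30.0, "30-40"),
    ])
    def test_bin_labels(self, pp, label):
        assert pp_bin_label(pp) == label

    def test_empty_raises(self):
        with pytest.raises(EmptySetError):
            bin_by_pulse_pressure([])

    def test_phantom_sweep_occupancy_is_monotone(self):
        """Increasing stroke volume fills bins of increasing PP."""
        cfg = ws.default_config()
        beats = []
        for sv in (40.0, 55.0, 70.0, 85.0, 100.0):
            out = ws.simulate(
                dataclasses.replace(cfg, stroke_volume_ml=sv),
                provenance=False,
            )
            beats.append(out.to_beat())
        pps = [b.pp for b in beats]
        assert all(a < b for a, b in zip(pps, pps[1:]))
        groups = bin_by_pulse_pressure(beats)
        labels = list(groups.keys())
        order = ["<30", "30-40", "40-50", "50-60", "60-70", ">70"]
        assert labels == [l for l in order if l in labels]
        for g in groups.values():
            assert sum(g["summary"].pct.values()) == pytest.approx(100, abs=0.1)
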