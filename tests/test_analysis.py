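"""Gait-analysis operations on constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from archwalk.analysis import (GaitCycle, contact_intervals, filter_grf,
                               global_measures, last_left_cycle,
                               power_amplification, resample_cycle,
                               segment_gait_cycles, work_breakdown,
                               xcorr_to_reference)
from archwalk.model import CHANNELS
from archwalk.params import ReflexGains, SimConfig
from archwalk.simulate import Trajectory


class TestFilter:
    def test_dc_unchanged(self):
        x = np.full(4000, 700.0)
        assert np.allclose(filter_grf(x, 1000.0), x)

    def test_passband_sinusoid_preserved_zero_phase(self):
        fs = 2000.0
        t = np.arange(0, 2.0, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        y = filter_grf(x, fs)
        core = slice(200, -200)
        amp = y[core].max()
        assert amp == pytest.approx(1.0, rel=0.01)
        # zero phase: peak positions coincide
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (
            len(x[core]) - 1)
        assert lag == 0

    def test_stopband_sinusoid_attenuated(self):
        fs = 2000.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.sin(2 * np.pi * 500.0 * t)
        y = filter_grf(x, fs)
        # 2nd order, forward-backward: ~80 dB/decade; 500 Hz is a decade up
        assert np.abs(y[200:-200]).max() < 0.01

    def test_infeasible_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_grf(np.zeros(100), 80.0)


def square_gait(n_strides=4, fs=1000.0, stance=0.65, stride=1.1, amp=700.0,
                noise=0.0, rng=None):
    """Synthetic vertical GRF: half-sine stance bumps at known transitions."""
    n = int(round(n_strides * stride * fs)) + 1
    t = np.arange(n) / fs
    f = np.zeros(n)
    for k in range(n_strides):
        a = int(round(k * stride * fs))
        b = int(round((k * stride + stance * stride) * fs))
        f[a:b] = amp * np.sin(np.pi * np.arange(b - a) / (b - a))
    if noise:
        f += rng.uniform(-noise, noise, n)
    return t, f


class TestSegmentation:
    def test_square_wave_transitions_recovered(self):
        t, f = square_gait()
        cycles = segment_gait_cycles(t, f)
        assert len(cycles) == 3
        for k, c in enumerate(cycles):
            assert t[c.i0] == pytest.approx(k * 1.1, abs=0.01)
            assert t[c.i1] == pytest.approx((k + 1) * 1.1, abs=0.01)
            assert t[c.i_toe_off] == pytest.approx(k * 1.1 + 0.715, abs=0.01)

    def test_all_swing_errors(self):
        t = np.arange(1000) / 1000.0
        with pytest.raises(ValueError, match="cycle"):
            segment_gait_cycles(t, np.zeros_like(t))

    def test_hysteresis_rejects_threshold_chatter(self, rng):
        # +-0.5 N noise on the baseline must not create spurious steps
        t, f = square_gait(noise=0.45, rng=rng)
        cycles = segment_gait_cycles(t, f)
        assert len(cycles) == 3

    def test_events_from_heel_and_opposite_leg(self):
        t, f = square_gait()
        _, fh = square_gait(stance=0.4)  # heel element releases earlier
        fo = np.roll(f, int(0.55 * 1000))  # opposite leg, half stride later
        c = segment_gait_cycles(t, f, grf_heel=fh, grf_opp=fo)[1]
        assert t[c.i_heel_off] == pytest.approx(1.1 + 0.44, abs=0.02)
        assert t[c.i_opp_td] == pytest.approx(1.1 + 0.55, abs=0.02)


class TestPowerAmplification:
    def test_scaled_sine(self):
        t = np.linspace(0, 2 * np.pi, 500)
        p = np.sin(t)
        p = np.where(p > 0, 2 * p, p)  # max 2, min -1
        assert power_amplification(p) == pytest.approx(2.0)

    def test_pure_positive_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            power_amplification(np.abs(np.sin(np.linspace(0, 6, 100))) + 0.1)


class TestXcorr:
    def test_identical(self, rng):
        x = rng.normal(size=256)
        assert xcorr_to_reference(x, x) == pytest.approx(1.0)

    def test_negation(self, rng):
        x = np.sin(np.linspace(0, 4 * np.pi, 256))
        r = xcorr_to_reference(x, -x)
        # anti-phase sinusoid re-aligns at half a period
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_phase_shifted_sine_realigns(self):
        t = np.linspace(0, 1, 400, endpoint=False)
        x = np.sin(2 * np.pi * 3 * t)
        y = np.sin(2 * np.pi * 3 * t + 1.1)
        assert xcorr_to_reference(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            xcorr_to_reference(np.ones(64), np.arange(64.0))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            xcorr_to_reference(np.ones(64), np.ones(65))


def synthetic_trajectory(n_strides=4, fs=1000.0, stance=0.6, stride=1.0,
                         v=1.3, mass=80.0):
    """A hand-built steady 'gait' trajectory with known global measures."""
    t, fL = square_gait(n_strides, fs, stance, stride)
    n = len(t)
    ch = pd.DataFrame(0.0, index=range(n), columns=list(CHANNELS))
    ch["L_grf_v"] = fL
    ch["L_Fv_H"] = fL * 0.5
    ch["R_grf_v"] = np.roll(fL, int(0.5 * stride * fs))
    ch["hat_x"] = v * t
    ch["hat_y"] = 1.4
    ch["met_rate"] = 300.0
    # ankle power: negative early stance, positive push-off burst
    P = np.zeros(n)
    for k in range(n_strides):
        a = int(k * stride * fs)
        P[a:a + 300] = -50.0
        P[a + 400:a + 550] = 150.0
    ch["L_tau_ank"] = P
    ch["L_phid_ank"] = 1.0
    # contact element powers: constant drag during stance
    ch["L_pow_H"] = np.where(fL > 0, -2.0, 0.0)
    ch["L_pow_B"] = np.where(fL > 0, -2.0, 0.0)
    ch["L_pf_pow"] = np.where(fL > 0, -1.0, 0.0)
    return Trajectory(
        t=t, channels=ch, q=np.zeros((n, 9)), qd=np.zeros((n, 9)),
        stim=np.zeros((n, 14)), kind="1s-hA", config=SimConfig(duration=t[-1]),
        gains=ReflexGains.table("1s-hA"), total_mass=mass, t_sim_max=t[-1])


class TestGlobalMeasures:
    def test_known_arithmetic(self):
        tr = synthetic_trajectory()
        cyc = last_left_cycle(tr)
        m = global_measures(tr, cyc)
        assert m.t_s == pytest.approx(1.0, abs=0.01)
        assert m.l_s == pytest.approx(1.3, rel=0.02)
        assert m.v_HAT == pytest.approx(1.3, rel=0.02)
        assert m.DF == pytest.approx(0.6, abs=0.02)
        # CoT = E / (m l_s) = 300 W * 1 s / (80 kg * 1.3 m)
        assert m.CoT == pytest.approx(300.0 / (80.0 * 1.3), rel=0.02)
        assert m.P_amp == pytest.approx(3.0, rel=0.01)

    def test_cot_formula_directly(self):
        # E = 300 J, m = 80 kg, l_s = 1.25 m -> 3.0 J/(kg m)
        assert 300.0 / (80.0 * 1.25) == pytest.approx(3.0)

    def test_work_breakdown_bookkeeping(self):
        tr = synthetic_trajectory()
        cyc = last_left_cycle(tr)
        w = work_breakdown(tr, cyc)
        # heel drags -2 W for 0.6 s over 80 kg
        assert w["heel"] == pytest.approx(-2.0 * 0.6 / 80.0, rel=0.05)
        assert w["total"] == pytest.approx(
            w["heel"] + w["ball"] + w["toe"] + w["PF"] + w["PL"], rel=1e-9)

    def test_time_reversed_stride_flips_work_sign(self):
        tr = synthetic_trajectory()
        cyc = last_left_cycle(tr)
        w = work_breakdown(tr, cyc)
        tr2 = synthetic_trajectory()
        tr2.channels["L_pow_H"] = -tr2.channels["L_pow_H"]
        tr2.channels["L_pow_B"] = -tr2.channels["L_pow_B"]
        tr2.channels["L_pf_pow"] = -tr2.channels["L_pf_pow"]
        w2 = work_breakdown(tr2, cyc)
        assert w2["total"] == pytest.approx(-w["total"], rel=1e-9)


def test_resample_cycle_endpoints():
    t = np.linspace(0, 2, 201)
    x = t**2
    y = resample_cycle(t, x, 50, 150, npts=11)
    assert y[0] == pytest.approx(x[50])
    assert y[-1] == pytest.approx(x[150])
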