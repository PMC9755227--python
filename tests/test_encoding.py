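"""Preprocessing filter contracts and Izhikevich integrator correctness.

The integrator is validated against an independent reference: a plain
Python forward-Euler loop at a 10x finer step, written here without
reusing any production integration code.
"""

import numpy as np
import pytest
from scipy import signal

from neurotact.encoding import (
    IzhikevichParams,
    PIEZO_BAND_HZ,
    PIEZO_BAND_ORDER,
    SpikeTrain,
    encode_population,
    izhikevich_encode,
    preprocess_piezo,
    preprocess_proprio,
)
from neurotact.synth_rig import ScanConfig, TextureSpec, simulate_scan


def reference_spike_times(current, params, sample_rate=1000.0, refine=40):
    """Independent fine-step Euler oracle (refine substeps per sample)."""
    a, b, c, d = params.a, params.b, params.c, params.d
    v, u = -70.0, -14.0
    dt = 1000.0 / (sample_rate * refine)  # ms
    spikes = []
    for j, I in enumerate(current):
        drive = params.G * I / params.Cm
        for s in range(refine):
            v = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            u = u + dt * (a * (b * v - u))
            if v >= params.v_peak:
                spikes.append((j * refine + s + 1) * dt / 1000.0)
                v = c
                u = u + d
    return np.array(spikes)


class TestPiezoPreprocessing:
    def test_dc_rejected(self):
        out = preprocess_piezo(np.full(2000, 3.3), 1000.0)
        assert np.max(np.abs(out)) < 1e-3

    def test_passband_sinusoid_preserved(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 100.0 * t)
        out = preprocess_piezo(x, 1000.0)
        # after min-max normalisation input is already in [-1, 1]
        amp = np.max(np.abs(out[500:-500]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_low_frequency_attenuated(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 2.0 * t)
        out = preprocess_piezo(x, 1000.0)
        amp = np.max(np.abs(out[2000:-2000]))
        assert 20 * np.log10(amp / 1.0) < -40.0

    def test_fixed_scale_mode_preserves_amplitude_ratio(self):
        t = np.arange(4000) / 1000.0
        small = 0.5 * np.sin(2 * np.pi * 50 * t)
        large = 2.0 * np.sin(2 * np.pi * 50 * t)
        out_s = preprocess_piezo(small, 1000.0, scale=1.0)
        out_l = preprocess_piezo(large, 1000.0, scale=1.0)
        ratio = np.max(np.abs(out_l)) / np.max(np.abs(out_s))
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_short_trace_error(self):
        with pytest.raises(ValueError, match="warm-up"):
            preprocess_piezo(np.ones(10), 1000.0)

    def test_band_corner_magnitudes(self):
        """-3 dB within +-0.5 dB at both Butterworth corners; DC <= -60 dB."""
        sos = signal.butter(PIEZO_BAND_ORDER, PIEZO_BAND_HZ, "bandpass",
                            fs=1000.0, output="sos")
        w, h = signal.sosfreqz(sos, worN=2 ** 16, fs=1000.0)
        for corner in PIEZO_BAND_HZ:
            mag_db = 20 * np.log10(
                np.abs(h[np.argmin(np.abs(w - corner))]))
            assert abs(mag_db - (-3.0)) < 0.5
        dc_db = 20 * np.log10(max(np.abs(h[1]), 1e-300))
        assert dc_db <= -60.0


class TestProprioPreprocessing:
    def test_affine_ramp_mapping(self):
        ramp = np.linspace(0.0, 5.0, 1000)
        out = preprocess_proprio(ramp, 1000.0, filter_mode="none")
        assert np.allclose(out, np.linspace(0.95, 1.08, 1000), atol=1e-12)

    def test_exact_endpoints_any_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000).cumsum()
        out = preprocess_proprio(x, 1000.0)
        assert out.min() == pytest.approx(0.95, abs=1e-12)
        assert out.max() == pytest.approx(1.08, abs=1e-12)

    def test_noisy_ramp_monotone_after_mapping(self):
        t = np.arange(2000) / 1000.0
        x = 2.0 * t + 0.05 * np.sin(2 * np.pi * 50 * t)
        out = preprocess_proprio(x, 1000.0, filter_mode="smooth_only")
        core = out[100:-100]
        # residual against the best isotonic (here: linear) trend is tiny
        assert np.all(np.diff(core) > -1e-4)

    def test_degenerate_trace_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            preprocess_proprio(np.full(100, 2.0), 1000.0)

    def test_highpass_mode_runs(self):
        ramp = np.linspace(0.0, 5.0, 2000)
        out = preprocess_proprio(ramp, 1000.0, filter_mode="highpass")
        assert out.min() == pytest.approx(0.95, abs=1e-12)
        assert out.max() == pytest.approx(1.08, abs=1e-12)


class TestIzhikevichNeuron:
    def test_zero_current_silent_at_rest(self):
        params = IzhikevichParams(G=1.0)
        train = izhikevich_encode(np.zeros(1000), params)
        assert train.n_spikes == 0
        v, u = params.resting_state
        assert v == pytest.approx(-70.0)
        assert u == pytest.approx(-14.0)

    def test_regular_spiking_adaptation(self):
        train = izhikevich_encode(np.full(1000, 15.0),
                                  IzhikevichParams(G=1.0))
        isis = np.diff(train.spike_times)
        assert train.n_spikes >= 5
        assert isis[0] < isis[-1]  # first ISI shorter than adapted ISI

    def test_rate_monotone_in_current(self):
        params = IzhikevichParams(G=1.0)
        rates = [izhikevich_encode(np.full(1000, I), params).rate()
                 for I in (6.0, 10.0, 20.0, 40.0)]
        assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:]))

    @pytest.mark.parametrize("label,current", [
        ("step", np.concatenate([np.zeros(300), np.full(700, 12.0)])),
        ("ramp", np.linspace(0.0, 25.0, 1000)),
        ("sinusoid", 10.0 + 10.0 * np.sin(2 * np.pi * 50.0
                                          * np.arange(1000) / 1000.0)),
    ])
    def test_matches_fine_step_reference(self, label, current):
        """Production step (0.25 ms) vs 10x finer independent oracle."""
        params = IzhikevichParams(G=1.0)
        train = izhikevich_encode(current, params, dt=0.25e-3)
        ref = reference_spike_times(current, params, refine=40)
        assert abs(train.n_spikes - ref.size) <= 1
        for t_prod, t_ref in zip(train.spike_times, ref):
            assert abs(t_prod - t_ref) <= 2e-3, label

    def test_spike_times_strictly_increasing(self):
        train = izhikevich_encode(np.full(2000, 30.0),
                                  IzhikevichParams(G=1.0))
        assert np.all(np.diff(train.spike_times) > 0)
        assert train.spike_times[0] >= 0
        assert train.spike_times[-1] <= train.duration

    def test_dt_too_large_rejected(self):
        with pytest.raises(ValueError):
            izhikevich_encode(np.zeros(100), IzhikevichParams(), dt=2e-3)

    def test_nonfinite_current_rejected(self):
        bad = np.zeros(100)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            izhikevich_encode(bad, IzhikevichParams())

    def test_spike_train_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.5, 1.5]), 1.0)


class TestEncodePopulation:
    def test_null_texture_zero_indentation_silent(self, imap0):
        spec = TextureSpec(1, (1.0,), (0.0,), 0.0)
        rec = simulate_scan(spec, ScanConfig(speed=50.0, duration=0.5,
                                             indentation=0.0, seed=0))
        trains = encode_population(rec, imap0)
        assert all(tr.n_spikes == 0 for tr in trains)

    def test_static_indentation_drives_only_sa(self, imap0):
        spec = TextureSpec(1, (1.0,), (0.0,), 0.0)
        rec = simulate_scan(spec, ScanConfig(speed=50.0, duration=1.0,
                                             indentation=0.9, seed=0))
        trains = encode_population(rec, imap0)
        sa = [tr for tr in trains if tr.afferent_type == "SA-I"]
        ra = [tr for tr in trains if tr.afferent_type in ("RA-I", "RA-II")]
        assert sum(tr.n_spikes for tr in sa) > 0
        # dynamic pathways stay silent after the onset transient
        late = [t for tr in ra for t in tr.spike_times if t > 0.2]
        assert len(late) == 0

    def test_population_layout(self, imap0):
        spec = TextureSpec(1, (1.0,), (1.0,), 0.0)
        rec = simulate_scan(spec, ScanConfig(speed=50.0, duration=0.3,
                                             seed=1))
        trains = encode_population(rec, imap0)
        types = [tr.afferent_type for tr in trains]
        assert types.count("SA-I") == 12
        assert types.count("RA-I") == 24
        assert types.count("RA-II") == 1
        assert types[-1] == "RA-II"

    def test_determinism(self, imap0):
        spec = TextureSpec(2, (0.8,), (1.0,), 0.02)
        rec = simulate_scan(spec, ScanConfig(speed=70.0, duration=0.4,
                                             seed=5))
        a = encode_population(rec, imap0)
        b = encode_population(rec, imap0)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.spike_times, tb.spike_times)
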