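"""Synthetic recording generator: ground-truth fidelity and signal content."""

import numpy as np
import pytest
from scipy import signal as sps

import casbdr as cb

RATE = 12500.0


class TestGenerateFlow:
    def test_cycle_count_gives_matching_phase_counts(self):
        flow, phases = cb.generate_flow(20, 3.0, (0.4, 1.5), seed=0, rate_hz=RATE)
        sides = [p[2] for p in phases]
        assert sides.count("inspiration") == 20
        assert sides.count("expiration") == 20

    def test_single_cycle_constant_range(self):
        flow, phases = cb.generate_flow(1, 2.0, (0.5, 0.5), seed=0, rate_hz=RATE)
        assert len(phases) == 2
        s0, e0, side0, peak0 = phases[0]
        assert side0 == "inspiration"
        assert flow[s0:e0].min() >= 0
        assert np.isclose(flow.max(), 0.5, atol=1e-6)
        assert np.isclose(-flow.min(), 0.5, atol=1e-6)

    def test_progressive_peaks_ramp_up_then_down(self):
        _, phases = cb.generate_flow(9, 2.0, (0.4, 1.2), seed=0, rate_hz=RATE)
        peaks = [p[3] for p in phases if p[2] == "inspiration"]
        mid = len(peaks) // 2
        assert peaks[mid] == max(peaks) == pytest.approx(1.2)
        assert peaks[0] == pytest.approx(0.4)
        assert all(np.diff(peaks[: mid + 1]) >= 0)
        assert all(np.diff(peaks[mid:]) <= 0)

    def test_phases_disjoint_ordered_half_open(self):
        flow, phases = cb.generate_flow(5, 2.0, (0.5, 1.0), seed=1, rate_hz=RATE)
        prev_end = 0
        for s, e, _, _ in phases:
            assert s == prev_end and e > s
            prev_end = e
        assert prev_end == len(flow)

    def test_determinism(self):
        a = cb.generate_flow(4, 2.0, (0.5, 1.0), seed=7, rate_hz=RATE)
        b = cb.generate_flow(4, 2.0, (0.5, 1.0), seed=7, rate_hz=RATE)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    @pytest.mark.parametrize("kwargs", [
        {"cycle_count": 0}, {"rate_hz": -1.0},
        {"peak_flow_range": (0.0, 1.0)}, {"peak_flow_range": (1.0, 0.5)},
    ])
    def test_invalid_arguments(self, kwargs):
        args = {"cycle_count": 2, "base_period_s": 2.0,
                "peak_flow_range": (0.5, 1.0), "seed": 0, "rate_hz": RATE}
        args.update(kwargs)
        with pytest.raises(ValueError):
            cb.generate_flow(**args)


class TestGenerateNormalSound:
    def test_flow_gating_zero_flow_silent(self):
        out = cb.generate_normal_sound(np.zeros(10000), seed=0, rate_hz=RATE)
        assert np.all(out == 0)

    def test_band_limited_power(self):
        rate = 3125.0
        flow = np.ones(int(8 * rate))
        out = cb.generate_normal_sound(flow, band_hz=(70, 250), seed=1,
                                       rate_hz=rate)
        f, p = sps.welch(out, fs=rate, nperseg=2048)
        assert p[f < 300].sum() / p.sum() >= 0.95

    def test_reproducible(self):
        flow = np.abs(np.sin(np.linspace(0, 3, 5000)))
        a = cb.generate_normal_sound(flow, seed=9, rate_hz=RATE)
        b = cb.generate_normal_sound(flow, seed=9, rate_hz=RATE)
        assert np.array_equal(a, b)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cb.generate_normal_sound(np.ones(1000), band_hz=(70, 7000),
                                     rate_hz=RATE)


class TestInjectCas:
    def _base(self, rate=3125.0, dur=2.0):
        n = int(dur * rate)
        flow = np.ones(n)
        normal = cb.generate_normal_sound(flow, seed=4, rate_hz=rate)
        return normal, rate

    def test_fft_peak_at_pitch(self):
        normal, rate = self._base()
        spec = cb.SynthCASSpec(onset_s=0.5, duration_s=0.5, pitch_hz=400.0,
                               snr_db=10.0)
        out = cb.inject_cas(normal, spec, normal**2, rate_hz=rate)
        win = out[int(0.5 * rate):int(1.0 * rate)]
        freqs = np.fft.rfftfreq(len(win), 1 / rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(win)))]
        assert abs(peak - 400.0) <= 5.0

    def test_polyphonic_two_peaks(self):
        normal, rate = self._base()
        s1 = cb.SynthCASSpec(onset_s=0.5, duration_s=0.5, pitch_hz=350.0,
                             snr_db=12.0, polyphonic_group=1)
        s2 = cb.SynthCASSpec(onset_s=0.5, duration_s=0.5, pitch_hz=600.0,
                             snr_db=12.0, polyphonic_group=1)
        out = cb.inject_cas(normal, s1, normal**2, rate_hz=rate)
        out = cb.inject_cas(out, s2, normal**2, rate_hz=rate)
        win = out[int(0.55 * rate):int(0.95 * rate)]
        freqs = np.fft.rfftfreq(len(win), 1 / rate)
        mag = np.abs(np.fft.rfft(win))
        for pitch in (350.0, 600.0):
            band = mag[(freqs > pitch - 15) & (freqs < pitch + 15)]
            outside = np.median(mag[(freqs > 280) & (freqs < 700)])
            assert band.max() > 5 * outside

    def test_snr_negative_infinity_identity(self):
        normal, rate = self._base()
        spec = cb.SynthCASSpec(onset_s=0.2, duration_s=0.3, pitch_hz=500.0,
                               snr_db=-np.inf)
        out = cb.inject_cas(normal, spec, normal**2, rate_hz=rate)
        assert np.array_equal(out, normal)

    def test_achieved_snr_close_to_requested(self):
        normal, rate = self._base()
        spec = cb.SynthCASSpec(onset_s=0.5, duration_s=0.8, pitch_hz=450.0,
                               snr_db=10.0)
        out = cb.inject_cas(normal, spec, normal**2, rate_hz=rate,
                            harmonic_db=-np.inf)
        i0, i1 = int(0.55 * rate), int(1.25 * rate)  # inside the plateau
        tone = out[i0:i1] - normal[i0:i1]
        snr = 10 * np.log10(np.mean(tone**2) / np.mean(normal[i0:i1] ** 2))
        assert abs(snr - 10.0) < 1.5

    def test_pitch_above_nyquist_rejected(self):
        normal, _ = self._base()
        with pytest.raises(ValueError):
            spec = cb.SynthCASSpec(onset_s=0.1, duration_s=0.2, pitch_hz=999.0)
            cb.inject_cas(normal, spec, normal**2, rate_hz=1500.0)

    def test_interval_outside_signal_rejected(self):
        normal, rate = self._base()
        spec = cb.SynthCASSpec(onset_s=1.9, duration_s=0.5, pitch_hz=400.0)
        with pytest.raises(ValueError):
            cb.inject_cas(normal, spec, normal**2, rate_hz=rate)


class TestInjectNoiseEvents:
    def test_empty_spec_list_identity(self):
        sound = np.random.default_rng(0).standard_normal(5000)
        out = cb.inject_noise_events(sound, [], seed=0, rate_hz=RATE)
        assert np.array_equal(out, sound)

    def test_burst_raises_local_rms(self):
        rate = 3125.0
        rng = np.random.default_rng(1)
        sound = 0.1 * rng.standard_normal(int(3 * rate))
        spec = cb.SynthNoiseSpec(onset_s=1.0, duration_s=0.15, center_hz=500.0,
                                 bandwidth_hz=200.0, level_db=6.0)
        out = cb.inject_noise_events(sound, [spec], seed=2, rate_hz=rate)
        i0, i1 = int(1.0 * rate), int(1.15 * rate)
        burst_rms = np.sqrt(np.mean(out[i0:i1] ** 2))
        bg_rms = np.sqrt(np.mean(out[:i0] ** 2))
        assert burst_rms > 2 * bg_rms

    def test_reproducible(self):
        sound = np.zeros(10000)
        spec = cb.SynthNoiseSpec(onset_s=0.1, duration_s=0.1)
        a = cb.inject_noise_events(sound, [spec], seed=5, rate_hz=RATE)
        b = cb.inject_noise_events(sound, [spec], seed=5, rate_hz=RATE)
        assert np.array_equal(a, b)


class TestGenerateRecording:
    @staticmethod
    def _config(**kw):
        base = dict(n_channels=2, cycles_per_maneuver=3, base_period_s=1.5,
                    maneuvers_per_session=1, noise_events_per_maneuver=0,
                    cas_prob_per_inspiration=1.0, cas_per_phase_max=1)
        base.update(kw)
        return cb.RecordingConfig(**base)

    def test_default_config_six_maneuvers(self):
        cfg = cb.RecordingConfig(cycles_per_maneuver=2, n_channels=1,
                                 base_period_s=1.0,
                                 cas_prob_per_inspiration=0.0,
                                 noise_events_per_maneuver=0)
        records = cb.generate_recording(cfg, seed=0)
        assert len(records) == 6  # 3 pre + 3 post
        assert [r.meta.session for r, _ in records].count("pre_bd") == 3

    def test_removal_fraction_one_clears_post_bd(self):
        records = cb.generate_recording(self._config(removal_fraction=1.0), seed=1)
        post = [t for r, t in records if r.meta.session == "post_bd"]
        assert all(len(t.cas) == 0 for t in post)
        pre = [t for r, t in records if r.meta.session == "pre_bd"]
        assert sum(len(t.cas) for t in pre) > 0

    def test_removal_fraction_half_halves_count(self):
        cfg = self._config(removal_fraction=0.5, cycles_per_maneuver=6)
        records = cb.generate_recording(cfg, seed=2)
        n_pre = sum(len(t.cas) for r, t in records if r.meta.session == "pre_bd")
        n_post = sum(len(t.cas) for r, t in records if r.meta.session == "post_bd")
        assert n_post == n_pre - round(0.5 * n_pre)

    def test_determinism(self):
        cfg = self._config(noise_events_per_maneuver=2)
        a = cb.generate_recording(cfg, seed=3)
        b = cb.generate_recording(cfg, seed=3)
        for (ra, ta), (rb, tb) in zip(a, b):
            assert all(np.array_equal(x, y)
                       for x, y in zip(ra.channels, rb.channels))
            assert np.array_equal(ra.flow, rb.flow)
            assert ta.cas == tb.cas and ta.phases == tb.phases

    def test_cas_inside_one_phase_of_stated_side(self):
        records = cb.generate_recording(self._config(cas_per_phase_max=2), seed=4)
        for record, truth in records:
            for spec in truth.cas:
                i0 = spec.onset_s * truth.rate_hz
                i1 = (spec.onset_s + spec.duration_s) * truth.rate_hz
                containing = [p for p in truth.phases
                              if p[0] <= i0 and i1 <= p[1]]
                assert len(containing) == 1
                assert containing[0][2] == spec.phase_side

    def test_energy_locality_without_events(self):
        cfg = self._config(cas_prob_per_inspiration=0.0)
        records = cb.generate_recording(cfg, seed=5)
        record, _ = records[0]
        f, p = sps.welch(record.channels[0], fs=record.rate_hz, nperseg=4096)
        assert p[f > 300].sum() / p.sum() < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cb.RecordingConfig(n_channels=0)
        with pytest.raises(ValueError):
            cb.RecordingConfig(cycles_per_maneuver=0)
        with pytest.raises(ValueError):
            cb.RecordingConfig(removal_fraction=1.5)


class TestSpecValidation:
    def test_cas_spec_invariants(self):
        with pytest.raises(ValueError):
            cb.SynthCASSpec(onset_s=0.0, duration_s=0.0, pitch_hz=400.0)
        with pytest.raises(ValueError):
            cb.SynthCASSpec(onset_s=0.0, duration_s=0.2, pitch_hz=50.0)
        with pytest.raises(ValueError):
            cb.SynthCASSpec(onset_s=-1.0, duration_s=0.2, pitch_hz=400.0)

    def test_ground_truth_roundtrip(self, tmp_path):
        truth = cb.GroundTruth(
            phases=[(0, 100, "inspiration", 0.5)],
            cas=[cb.SynthCASSpec(onset_s=0.0, duration_s=0.2, pitch_hz=400.0)],
            noises=[cb.SynthNoiseSpec(onset_s=0.0, duration_s=0.1)])
        path = tmp_path / "truth.json"
        from casbdr.signal_io import write_ground_truth
        write_ground_truth(truth, path)
        loaded = cb.GroundTruth.from_json(path)
        assert loaded.cas == truth.cas
        assert loaded.phases == truth.phases
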