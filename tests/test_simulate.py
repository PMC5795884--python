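"""Synthetic-EEG generator: spectra, projections, injectors, ground truth."""

import numpy as np
import pytest
import scipy.signal

from earseiz.montage import apply_montage, define_ear_montage, define_scalp_montage
from earseiz.simulate import (
    BackgroundConfig,
    BlinkConfig,
    EmgConfig,
    FaultConfig,
    IctalConfig,
    SimConfig,
    generate_background,
    generate_patient_dataset,
    inject_blinks,
    inject_electrode_fault,
    inject_emg,
    inject_seizure,
    simulate_recording,
)


def quiet_cfg(seed=0, duration=60.0, **bg):
    """Background-only config, blinks off."""
    return SimConfig(
        seed=seed, duration_s=duration, blink=None,
        background=BackgroundConfig(**bg),
    )


class TestBackground:
    def test_deterministic_under_seed(self):
        a = generate_background(quiet_cfg(seed=7))
        b = generate_background(quiet_cfg(seed=7))
        assert np.array_equal(a.data, b.data)
        c = generate_background(quiet_cfg(seed=8))
        assert not np.array_equal(a.data, c.data)

    def test_flat_spectrum_when_exponent_zero(self):
        rec = generate_background(
            quiet_cfg(duration=120.0, one_over_f_exponent=0.0, alpha_gain_uv=0.0)
        )
        f, p = scipy.signal.welch(rec.electrode("Cz"), fs=rec.fs_hz, nperseg=1024)
        keep = (f > 1) & (f < 100)
        slope = np.polyfit(np.log(f[keep]), np.log(p[keep]), 1)[0]
        assert abs(slope) < 0.15

    def test_occipital_alpha_peak(self):
        rec = generate_background(quiet_cfg(duration=120.0, alpha_gain_uv=10.0))
        f, p = scipy.signal.welch(rec.electrode("O1"), fs=rec.fs_hz, nperseg=512)
        alpha = p[(f >= 8) & (f <= 12)].mean()
        neighbors = p[((f >= 4) & (f < 8)) | ((f > 12) & (f <= 16))].mean()
        assert alpha > neighbors

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_background(quiet_cfg(duration=0.0))


class TestBlinks:
    def test_symmetric_blinks_cancel_on_cross_head_channels(self):
        # noiseless projection: the cancellation is exact
        cfg = SimConfig(
            seed=3, duration_s=120.0,
            background=BackgroundConfig(rms_uv=0.0, alpha_gain_uv=0.0),
            blink=BlinkConfig(left_right_asymmetry=0.0),
        )
        rec = generate_background(cfg)
        rec, times = inject_blinks(rec, cfg)
        assert len(times) > 10
        ear = apply_montage(rec, define_ear_montage())
        assert np.allclose(ear.channel("LC-RC"), 0.0)
        assert np.allclose(ear.channel("LT-RT"), 0.0)
        assert np.abs(ear.channel("LT-LC")).max() > 0

    def test_frontal_amplitude_tracks_configured_peak(self):
        cfg = SimConfig(
            seed=5, duration_s=400.0,
            background=BackgroundConfig(rms_uv=0.0, alpha_gain_uv=0.0),
            blink=BlinkConfig(peak_amplitude_uv=60.0, amplitude_jitter=0.0),
        )
        rec = generate_background(cfg)
        rec, times = inject_blinks(rec, cfg)
        assert len(times) >= 50
        fp = apply_montage(rec, define_scalp_montage()).channel("Fp2-F8")
        peaks = [fp[int(round(t * rec.fs_hz))] for t in times]
        assert np.mean(peaks) == pytest.approx(60.0, rel=0.2)

    def test_zero_rate_leaves_recording_unchanged(self):
        cfg = quiet_cfg(seed=1)
        rec = generate_background(cfg)
        out, times = inject_blinks(rec, cfg)
        assert times == [] and np.array_equal(out.data, rec.data)


class TestSeizure:
    def _cfg(self, side="right"):
        return SimConfig(
            seed=2, duration_s=200.0, blink=None,
            ictal=[IctalConfig(onset_s=60.0, duration_s=60.0, base_freq_hz=4.0,
                               focus_side=side)],
        )

    def test_psd_peaks_at_base_frequency(self):
        cfg = self._cfg()
        rec, ann = inject_seizure(generate_background(cfg), cfg)
        seg = rec.electrode("T4")[int(70 * 250) : int(110 * 250)]
        f, p = scipy.signal.welch(seg, fs=250.0, nperseg=1024)
        peak = f[np.argmax(p * ((f > 1) & (f < 30)))]
        assert abs(peak - 4.0) <= f[1] - f[0]
        assert (ann.onset_s, ann.end_s) == (60.0, 120.0)

    def test_ipsilateral_band_power_exceeds_contralateral(self):
        cfg = self._cfg(side="right")
        rec, _ = inject_seizure(generate_background(cfg), cfg)
        sl = slice(int(70 * 250), int(110 * 250))

        def band_power(el):
            f, p = scipy.signal.welch(rec.electrode(el)[sl], fs=250.0, nperseg=512)
            return p[(f >= 3) & (f <= 5)].mean()

        assert band_power("T4") > band_power("T3")
        assert band_power("RT") > band_power("LT")

    def test_zero_amplitude_is_identity(self):
        cfg = self._cfg()
        cfg.ictal[0].amplitude_uv = 0.0
        rec = generate_background(cfg)
        out, _ = inject_seizure(rec, cfg)
        assert np.array_equal(out.data, rec.data)

    def test_interval_outside_recording_rejected(self):
        cfg = self._cfg()
        cfg.ictal[0].onset_s = 190.0
        with pytest.raises(ValueError):
            inject_seizure(generate_background(cfg), cfg)


class TestEmg:
    def test_burst_raises_high_band_power(self):
        cfg = quiet_cfg(seed=9, duration=120.0)
        cfg.emg = EmgConfig(burst_rate_per_min=3.0, burst_duration_s=2.0)
        rec = generate_background(cfg)
        out, intervals = inject_emg(rec, cfg)
        assert intervals

        def high_power(x):
            f, p = scipy.signal.welch(x, fs=250.0, nperseg=256)
            return p[(f >= 20) & (f <= 35)].mean()

        t0, t1 = intervals[0]
        i0, i1 = int(t0 * 250), int(t1 * 250)
        n = i1 - i0
        burst = high_power(out.electrode("T4")[i0:i1])
        before = high_power(rec.electrode("T4")[i0:i1])
        assert burst / max(before, 1e-12) > 5

    def test_unaffected_electrodes_unchanged(self):
        cfg = quiet_cfg(seed=9, duration=60.0)
        cfg.emg = EmgConfig(electrodes=("T4",), burst_rate_per_min=3.0)
        rec = generate_background(cfg)
        out, _ = inject_emg(rec, cfg)
        cz = rec.electrode_labels.index("Cz")
        assert np.array_equal(out.data[cz], rec.data[cz])

    def test_deterministic(self):
        cfg = quiet_cfg(seed=4, duration=60.0)
        cfg.emg = EmgConfig()
        rec = generate_background(cfg)
        a, ia = inject_emg(rec, cfg)
        b, ib = inject_emg(rec, cfg)
        assert ia == ib and np.array_equal(a.data, b.data)


class TestElectrodeFault:
    def test_phase_reversal_across_shared_electrode(self):
        cfg = quiet_cfg(seed=6, duration=60.0)
        cfg.fault = FaultConfig(electrode="RT", start_s=10.0, duration_s=10.0)
        rec = generate_background(cfg)
        out, intervals = inject_electrode_fault(rec, cfg)
        ear = apply_montage(out, define_ear_montage())
        base = apply_montage(rec, define_ear_montage())
        art = ear.data - base.data  # pure artifact in montage space
        sl = slice(int(10 * 250), int(20 * 250))
        lt_rt = art[ear.channel_names.index("LT-RT"), sl]
        rt_rc = art[ear.channel_names.index("RT-RC"), sl]
        assert np.cov(lt_rt, rt_rc)[0, 1] < 0

    def test_confined_to_interval_and_zero_amp_identity(self):
        cfg = quiet_cfg(seed=6, duration=60.0)
        cfg.fault = FaultConfig(electrode="RT", start_s=10.0, duration_s=5.0)
        rec = generate_background(cfg)
        out, _ = inject_electrode_fault(rec, cfg)
        rt = rec.electrode_labels.index("RT")
        assert np.array_equal(out.data[rt, : int(10 * 250)], rec.data[rt, : int(10 * 250)])
        assert np.array_equal(out.data[rt, int(15 * 250) :], rec.data[rt, int(15 * 250) :])
        cfg.fault.amplitude_uv = 0.0
        out2, intervals = inject_electrode_fault(rec, cfg)
        assert intervals == [] and np.array_equal(out2.data, rec.data)


class TestDatasetAndCommutativity:
    def test_cohort_seizure_counts_sum_to_47(self):
        counts = [1, 9, 8, 1, 2, 2, 5, 6, 2, 1, 3, 7]
        cfgs = []
        for pid, k in enumerate(counts, start=1):
            ictal = [
                IctalConfig(onset_s=30.0 + 60.0 * i, duration_s=20.0)
                for i in range(k)
            ]
            cfgs.append(
                SimConfig(seed=pid, duration_s=60.0 * k + 60.0, blink=None,
                          background=BackgroundConfig(rms_uv=2.0, alpha_gain_uv=0.0),
                          ictal=ictal)
            )
        data = generate_patient_dataset(cfgs)
        total = sum(len(t.seizure_annotations) for _, t in data)
        assert total == 47
        for rec, truth in data:
            for a in truth.seizure_annotations:
                assert 0 <= a.onset_s < a.end_s <= rec.duration_s

    def test_injectors_commute(self):
        cfg = quiet_cfg(seed=11, duration=60.0)
        cfg.blink = BlinkConfig()
        cfg.emg = EmgConfig()
        rec = generate_background(cfg)
        a, _ = inject_blinks(rec, cfg)
        a, _ = inject_emg(a, cfg)
        b, _ = inject_emg(rec, cfg)
        b, _ = inject_blinks(b, cfg)
        assert np.allclose(a.data, b.data)

    def test_simulate_recording_deterministic(self):
        cfg = SimConfig(seed=21, duration_s=60.0,
                        ictal=[IctalConfig(onset_s=20.0, duration_s=20.0)])
        a, ta = simulate_recording(cfg)
        b, tb = simulate_recording(cfg)
        assert np.array_equal(a.data, b.data)
        assert ta.blink_times_s == tb.blink_times_s
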