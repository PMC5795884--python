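"""Seeded synthetic referential EEG with the structure the pipeline assumes.

The cohort this package targets (long-term hospital EEG of focal-epilepsy
patients) is not publicly available, so every downstream stage is exercised
on simulated recordings that reproduce the *relevant statistical structure*:

* spatially-correlated 1/f background with an occipital alpha rhythm,
* frontally-dominant, left-right symmetric blink EOG deflections
  (30-80 µV at the frontopolar electrodes),
* lateralized rhythmic 3-5 Hz ictal discharges whose spatial gain falls
  off with distance from the seizure focus (a volume-conduction surrogate),
* high-frequency EMG bursts on temporal/peri-auricular electrodes,
* single-electrode contact faults, which show phase reversal between the
  two derived channels sharing the faulty electrode.

All injectors are additive, draw their randomness from sub-seeds derived
from the master seed, and therefore commute; ground truth (event times)
is returned alongside the signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .montage import ALL_ELECTRODES, Recording, SeizureAnnotation

__all__ = [
    "ELECTRODE_POS",
    "BLINK_GAIN",
    "BackgroundConfig",
    "BlinkConfig",
    "IctalConfig",
    "EmgConfig",
    "FaultConfig",
    "SimConfig",
    "GroundTruth",
    "generate_background",
    "inject_blinks",
    "inject_seizure",
    "inject_emg",
    "inject_electrode_fault",
    "simulate_recording",
    "generate_patient_dataset",
]

#: Schematic 2-D head layout (x: left-negative/right-positive, y: anterior
#: positive), unit head radius.  Mirror-symmetric about the midline so that
#: midline sources project identically to homologous left/right electrodes.
ELECTRODE_POS: dict[str, tuple[float, float]] = {
    "Fpz": (0.0, 1.0), "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.55), "Fz": (0.0, 0.5),
    "F4": (0.42, 0.55), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "Sph1": (-1.02, 0.22), "Sph2": (1.02, 0.22),
    "T5": (-0.81, -0.59), "P3": (-0.42, -0.55), "Pz": (0.0, -0.5),
    "P4": (0.42, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "LT": (-1.1, -0.15), "LC": (-1.15, -0.35),
    "RT": (1.1, -0.15), "RC": (1.15, -0.35),
}

#: Fixed blink-EOG topography: relative gain of the blink source at each
#: electrode (1.0 at the frontopolar sites above the eyes).  Symmetric for
#: homologous pairs; decreases toward posterior sites, with a small residual
#: at the upper ear electrodes so the unilateral ear channels retain the
#: faint averaged blink seen clinically while cross-head channels cancel.
BLINK_GAIN: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "Fpz": 1.05,
    "F7": 0.12, "F8": 0.12, "F3": 0.25, "F4": 0.25, "Fz": 0.30,
    "T3": 0.05, "T4": 0.05, "C3": 0.08, "C4": 0.08, "Cz": 0.10,
    "Sph1": 0.04, "Sph2": 0.04,
    "T5": 0.03, "T6": 0.03, "P3": 0.04, "P4": 0.04, "Pz": 0.05,
    "O1": 0.02, "O2": 0.02,
    "LT": 0.10, "RT": 0.10, "LC": 0.02, "RC": 0.02,
}

_LEFT = ("Fp1", "F7", "F3", "T3", "C3", "Sph1", "T5", "P3", "O1", "LT", "LC")

# fixed sub-seed tags so that each injector's randomness is independent of
# the order in which injectors run
_TAG = {"background": 11, "blink": 23, "ictal": 37, "emg": 53, "fault": 71}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _TAG[stage], extra]))


def _dist(a: str, b_xy: tuple[float, float]) -> float:
    ax, ay = ELECTRODE_POS[a]
    return float(np.hypot(ax - b_xy[0], ay - b_xy[1]))


def _pink_noise(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-RMS noise with power spectrum proportional to 1/f**beta."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz (FFT brick-wall)."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec * mask, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BackgroundConfig:
    one_over_f_exponent: float = 1.2  # PSD slope of the ongoing activity
    rms_uv: float = 12.0              # per-electrode RMS of the correlated part
    alpha_band_hz: tuple[float, float] = (8.0, 12.0)
    alpha_gain_uv: float = 8.0        # alpha RMS at the occipital electrodes
    sensor_noise_frac: float = 0.15   # independent per-electrode noise fraction
    n_latent_sources: int = 10
    source_decay: float = 0.45        # spatial fall-off of the latent patches


@dataclass
class BlinkConfig:
    rate_per_min: float = 12.0
    template_duration_s: float = 0.3
    peak_amplitude_uv: float = 60.0   # at the frontopolar electrodes; 30-80 detectable
    left_right_asymmetry: float = 0.0  # 0 = perfectly symmetric projection
    amplitude_jitter: float = 0.05
    min_separation_s: float = 0.5


@dataclass
class IctalConfig:
    onset_s: float = 60.0
    duration_s: float = 60.0
    base_freq_hz: float = 4.0         # rhythmic discharge frequency, 3-5 Hz
    amplitude_uv: float = 70.0        # at the focus electrode
    focus_side: str = "right"         # left | right
    focus_lobe: str = "temporal"      # temporal | parietal | occipital
    gain_decay: float = 0.5           # spatial fall-off length (head radii)
    harmonic_frac: float = 0.3


@dataclass
class EmgConfig:
    burst_rate_per_min: float = 2.0
    burst_duration_s: float = 2.0
    band_hz: tuple[float, float] = (20.0, 45.0)
    amplitude_uv: float = 25.0
    electrodes: tuple[str, ...] = ("T3", "T4", "Sph1", "Sph2", "LT", "LC", "RT", "RC")


@dataclass
class FaultConfig:
    electrode: str = "RT"
    start_s: float = 0.0
    duration_s: float = 10.0
    amplitude_uv: float = 300.0
    kind: str = "rhythmic"            # rhythmic | step
    freq_hz: float = 2.5


@dataclass
class SimConfig:
    seed: int = 0
    duration_s: float = 600.0
    fs_hz: float = 250.0
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    blink: BlinkConfig | None = field(default_factory=BlinkConfig)
    ictal: list[IctalConfig] = field(default_factory=list)
    emg: EmgConfig | None = None
    fault: FaultConfig | None = None


@dataclass
class GroundTruth:
    blink_times_s: list[float] = field(default_factory=list)
    seizure_annotations: list[SeizureAnnotation] = field(default_factory=list)
    emg_intervals: list[tuple[float, float]] = field(default_factory=list)
    fault_intervals: list[tuple[float, float]] = field(default_factory=list)


_FOCUS_ELECTRODE = {
    ("temporal", "left"): "T3", ("temporal", "right"): "T4",
    ("parietal", "left"): "P3", ("parietal", "right"): "P4",
    ("occipital", "left"): "O1", ("occipital", "right"): "O2",
}


# ---------------------------------------------------------------------------
# generators / injectors


def generate_background(cfg: SimConfig) -> Recording:
    """Spatially-correlated 1/f background plus occipital alpha.

    A small set of latent 1/f sources at fixed scalp locations is projected
    through smooth Gaussian distance gains (a cheap volume-conduction
    surrogate), an alpha-band source is added near the occiput, and a
    fraction of independent per-electrode sensor noise is mixed in.
    Deterministic for a given ``cfg.seed``.
    """
    if cfg.duration_s <= 0:
        raise ValueError(f"duration must be positive, got {cfg.duration_s}")
    bg = cfg.background
    fs = cfg.fs_hz
    n = int(round(cfg.duration_s * fs))
    rng = _rng(cfg.seed, "background")
    labels = list(ALL_ELECTRODES)

    # latent cortical patches spread over the head; fairly local so that
    # bipolar derivations retain correlated broadband activity between
    # neighbouring channels (as scalp EEG does)
    patch_xy = [(-0.5, 0.7), (0.5, 0.7), (0.0, 0.2), (-0.7, 0.3), (0.7, 0.3),
                (-0.95, -0.2), (0.95, -0.2), (-0.5, -0.6), (0.5, -0.6),
                (0.0, -0.8)][: bg.n_latent_sources]
    gains = np.array(
        [
            [np.exp(-_dist(e, p) ** 2 / (2 * bg.source_decay**2)) for p in patch_xy]
            for e in labels
        ]
    )
    norms = np.linalg.norm(gains, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    gains = gains / norms

    data = np.zeros((len(labels), n))
    if bg.rms_uv > 0:
        sources = np.stack(
            [_pink_noise(rng, n, fs, bg.one_over_f_exponent) for _ in patch_xy]
        )
        data += bg.rms_uv * gains @ sources
        if bg.sensor_noise_frac > 0:
            for i in range(len(labels)):
                data[i] += (
                    bg.rms_uv
                    * bg.sensor_noise_frac
                    * _pink_noise(rng, n, fs, bg.one_over_f_exponent)
                )

    if bg.alpha_gain_uv > 0:
        alpha = _narrowband_noise(rng, n, fs, *bg.alpha_band_hz)
        alpha_gain = np.array(
            [np.exp(-_dist(e, (0.0, -1.0)) ** 2 / (2 * 0.5**2)) for e in labels]
        )
        data += bg.alpha_gain_uv * alpha_gain[:, None] * alpha

    return Recording(fs_hz=fs, electrode_labels=labels, data=data)


def _blink_template(fs: float, duration_s: float) -> np.ndarray:
    """Raised-cosine bump, unit peak, ~300 ms — the stylized blink."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return 0.5 * (1 - np.cos(2 * np.pi * t / duration_s))


def inject_blinks(rec: Recording, cfg: SimConfig) -> tuple[Recording, list[float]]:
    """Add blink EOG deflections; returns the new recording and true peak times.

    The blink source projects through :data:`BLINK_GAIN`; with
    ``left_right_asymmetry == 0`` homologous left/right electrodes receive
    exactly equal gain, so cross-head ear derivations cancel identically.
    """
    blink = cfg.blink
    out = rec.copy()
    if blink is None or blink.rate_per_min <= 0:
        return out, []
    if blink.template_duration_s >= rec.duration_s:
        raise ValueError("blink template longer than the recording")
    rng = _rng(cfg.seed, "blink")
    fs = rec.fs_hz
    template = _blink_template(fs, blink.template_duration_s)
    half = blink.template_duration_s / 2

    expected = blink.rate_per_min * rec.duration_s / 60.0
    n_events = rng.poisson(expected)
    candidates = np.sort(
        rng.uniform(half, rec.duration_s - half, size=n_events)
    )
    times: list[float] = []
    for t in candidates:
        if not times or t - times[-1] >= blink.min_separation_s:
            times.append(float(t))

    gain = np.array([BLINK_GAIN[e] for e in rec.electrode_labels])
    if blink.left_right_asymmetry:
        left = np.array([e in _LEFT for e in rec.electrode_labels])
        gain = np.where(left, gain * (1 - blink.left_right_asymmetry), gain)

    for t in times:
        amp = blink.peak_amplitude_uv * (
            1 + blink.amplitude_jitter * rng.standard_normal()
        )
        i0 = int(round((t - half) * fs))
        seg = template[: out.n_samples - i0]
        out.data[:, i0 : i0 + len(seg)] += amp * gain[:, None] * seg[None, :]
    return out, times


def _ictal_gains(labels: Sequence[str], ic: IctalConfig) -> np.ndarray:
    focus = _FOCUS_ELECTRODE[(ic.focus_lobe, ic.focus_side)]
    fxy = ELECTRODE_POS[focus]
    return np.array(
        [np.exp(-_dist(e, fxy) ** 2 / (2 * ic.gain_decay**2)) for e in labels]
    )


def inject_seizure(
    rec: Recording, cfg: SimConfig, ictal: IctalConfig | None = None, index: int = 0
) -> tuple[Recording, SeizureAnnotation]:
    """Add one amplitude-modulated rhythmic ictal discharge.

    The rhythm (base frequency plus a weak second harmonic) ramps up over
    the first tenth of the event and waxes/wanes slowly; spatial gains decay
    with distance from the focus, so ipsilateral channels always exceed
    their contralateral counterparts.
    """
    ic = ictal if ictal is not None else (cfg.ictal[index] if cfg.ictal else IctalConfig())
    if not (0 <= ic.onset_s and ic.onset_s + ic.duration_s <= rec.duration_s):
        raise ValueError("ictal interval falls outside the recording")
    out = rec.copy()
    ann = SeizureAnnotation(ic.onset_s, ic.onset_s + ic.duration_s)
    if ic.amplitude_uv == 0:
        return out, ann

    rng = _rng(cfg.seed, "ictal", index)
    fs = rec.fs_hz
    i0 = int(round(ic.onset_s * fs))
    n = int(round(ic.duration_s * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * ic.base_freq_hz * t + phase)
    wave += ic.harmonic_frac * np.sin(2 * np.pi * 2 * ic.base_freq_hz * t + 2 * phase)
    ramp = np.minimum(t / max(ic.duration_s * 0.1, 1e-9), 1.0)
    waxwane = 1 + 0.25 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    wave *= ic.amplitude_uv * ramp * waxwane

    gains = _ictal_gains(rec.electrode_labels, ic)
    out.data[:, i0 : i0 + n] += gains[:, None] * wave[None, :]
    return out, ann


def inject_emg(rec: Recording, cfg: SimConfig) -> tuple[Recording, list[tuple[float, float]]]:
    """Add band-limited (>= 20 Hz) muscle-noise bursts to chosen electrodes."""
    emg = cfg.emg
    out = rec.copy()
    if emg is None or emg.burst_rate_per_min <= 0 or emg.amplitude_uv == 0:
        return out, []
    rng = _rng(cfg.seed, "emg")
    fs = rec.fs_hz
    n_bursts = rng.poisson(emg.burst_rate_per_min * rec.duration_s / 60.0)
    starts = np.sort(
        rng.uniform(0, max(rec.duration_s - emg.burst_duration_s, 0), size=n_bursts)
    )
    idx = [rec.electrode_labels.index(e) for e in emg.electrodes
           if e in rec.electrode_labels]
    intervals: list[tuple[float, float]] = []
    nseg = int(round(emg.burst_duration_s * fs))
    taper = np.hanning(nseg) if nseg > 2 else np.ones(nseg)
    for s in starts:
        i0 = int(round(s * fs))
        seg_len = min(nseg, out.n_samples - i0)
        for i in idx:
            burst = _narrowband_noise(rng, seg_len, fs, *emg.band_hz)
            out.data[i, i0 : i0 + seg_len] += (
                emg.amplitude_uv * burst * taper[:seg_len]
            )
        intervals.append((float(s), float(s + seg_len / fs)))
    return out, intervals


def inject_electrode_fault(
    rec: Recording, cfg: SimConfig
) -> tuple[Recording, list[tuple[float, float]]]:
    """Add a high-amplitude contact artifact to exactly ONE electrode.

    Because the artifact lives on a single electrode, any two derived
    channels that share it on opposite poles (e.g. LT-RT and RT-RC for a
    faulty RT) carry it with opposite sign — the clinical phase-reversal
    signature of a poor contact.
    """
    fault = cfg.fault
    out = rec.copy()
    if fault is None or fault.amplitude_uv == 0:
        return out, []
    if fault.electrode not in rec.electrode_labels:
        raise KeyError(f"fault electrode {fault.electrode!r} not in recording")
    rng = _rng(cfg.seed, "fault")
    fs = rec.fs_hz
    i0 = int(round(fault.start_s * fs))
    n = min(int(round(fault.duration_s * fs)), out.n_samples - i0)
    if n <= 0:
        return out, []
    t = np.arange(n) / fs
    if fault.kind == "rhythmic":
        art = fault.amplitude_uv * np.sin(
            2 * np.pi * fault.freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
        # soft edges so the artifact stays confined to its interval
        edge = max(int(0.05 * fs), 1)
        w = np.ones(n)
        w[:edge] = np.linspace(0, 1, edge)
        w[-edge:] = np.linspace(1, 0, edge)
        art *= w
    elif fault.kind == "step":
        art = np.full(n, fault.amplitude_uv)
    else:
        raise ValueError(f"unknown fault kind {fault.kind!r}")
    row = rec.electrode_labels.index(fault.electrode)
    out.data[row, i0 : i0 + n] += art
    return out, [(fault.start_s, fault.start_s + n / fs)]


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Full simulation: background plus every configured event type."""
    rec = generate_background(cfg)
    truth = GroundTruth()
    rec, truth.blink_times_s = inject_blinks(rec, cfg)
    for k in range(len(cfg.ictal)):
        rec, ann = inject_seizure(rec, cfg, index=k)
        truth.seizure_annotations.append(ann)
    rec, truth.emg_intervals = inject_emg(rec, cfg)
    rec, truth.fault_intervals = inject_electrode_fault(rec, cfg)
    return rec, truth


def generate_patient_dataset(
    cfg_list: Sequence[SimConfig],
) -> list[tuple[Recording, GroundTruth]]:
    """One annotated recording per pseudo-patient; each must seed >= 1 seizure."""
    out = []
    for cfg in cfg_list:
        if not cfg.ictal:
            raise ValueError("every pseudo-patient needs at least one seizure")
        out.append(simulate_recording(cfg))
    return out
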