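"""Desk-scale synthetic-cohort reproductions of the full analysis.

These functions wire the whole pipeline together on a simulated
12-pseudo-patient cohort: simulation -> montage -> BSS-CCA -> band-pass ->
epoching -> blink-EOG quantification / coherence matchup / leave-one-
seizure-out detection.  Problem sizes are deliberately compact (10-minute
seizure epochs, 5-minute non-seizure epochs, seizure counts capped at
three per patient) so a complete run finishes on one CPU in minutes; the
quantities measured are the same as at clinical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detection import (
    PatientRecords,
    PerformanceReport,
    SvmConfig,
    channel_subset_comparison,
    compare_reports_wilcoxon,
    loo_evaluate,
)
from .eog import analyze_blinks
from .features import FeatureConfig
from .montage import (
    PatientMetadata,
    Recording,
    apply_montage,
    define_ear_montage,
    define_scalp_montage,
)
from .preprocess import (
    BsccaConfig,
    bandpass,
    bsscca_denoise,
    extract_seizure_epochs,
    sample_nonseizure_epochs,
)
from .simulate import (
    BlinkConfig,
    EmgConfig,
    GroundTruth,
    IctalConfig,
    SimConfig,
    simulate_recording,
)
from .spectral import best_matchup

__all__ = [
    "CohortScale",
    "cohort_configs",
    "build_patient_records",
    "run_detection_benchmark",
    "run_eog_benchmark",
    "run_matchup_benchmark",
]

# per-pseudo-patient seizure focus, mirroring the cohort's mix of mostly
# temporal with one parietal and one occipital focus
_FOCI = [
    ("right", "occipital"), ("left", "temporal"), ("right", "temporal"),
    ("left", "temporal"), ("right", "temporal"), ("right", "parietal"),
    ("left", "temporal"), ("left", "temporal"), ("left", "temporal"),
    ("right", "temporal"), ("right", "temporal"), ("left", "temporal"),
]

#: Cohort seizure counts capped at three per patient (desk scale).
_SEIZURE_COUNTS = [1, 3, 3, 1, 2, 2, 3, 3, 2, 1, 3, 3]


@dataclass(frozen=True)
class CohortScale:
    """Problem sizes of the synthetic benchmark cohort."""

    epoch_len_s: float = 600.0        # seizure epoch length (10 min)
    nonseizure_len_s: float = 300.0   # non-seizure epoch length
    n_nonseizure: int = 2
    ictal_duration_s: float = 50.0
    ictal_amplitude_uv: float = 70.0
    guard_s: float = 60.0


def cohort_configs(
    seed: int, scale: CohortScale | None = None
) -> list[tuple[SimConfig, PatientMetadata]]:
    """Simulation config + metadata for each of the 12 pseudo-patients."""
    scale = scale or CohortScale()
    out = []
    for i in range(12):
        pid = i + 1
        side, lobe = _FOCI[i]
        n_seiz = _SEIZURE_COUNTS[i]
        duration = (
            n_seiz * scale.epoch_len_s
            + scale.n_nonseizure * scale.nonseizure_len_s
            + 2 * scale.guard_s
        )
        ictal = [
            IctalConfig(
                onset_s=k * scale.epoch_len_s + scale.epoch_len_s / 2,
                duration_s=scale.ictal_duration_s,
                base_freq_hz=3.0 + 0.25 * (pid % 5),
                amplitude_uv=scale.ictal_amplitude_uv,
                focus_side=side,
                focus_lobe=lobe,
            )
            for k in range(n_seiz)
        ]
        cfg = SimConfig(
            seed=seed * 1000 + pid,
            duration_s=duration,
            ictal=ictal,
            blink=BlinkConfig(),
            emg=EmgConfig(burst_rate_per_min=1.0),
        )
        meta = PatientMetadata(
            pid=pid, n_seizures=n_seiz, sex="F" if i % 2 else "M",
            age=30.0, focus_side=side, focus_lobe=lobe,
            recording_h=duration / 3600.0,
        )
        out.append((cfg, meta))
    return out


def preprocess_recording(
    rec: Recording,
    denoise: bool = True,
    bscca_cfg: BsccaConfig | None = None,
):
    """Scalp + ear montage jointly, BSS-CCA over all 26 channels, band-pass."""
    scalp = define_scalp_montage()
    ear = define_ear_montage()
    joint = apply_montage(rec, _concat_montage(scalp, ear))
    if denoise:
        joint = bsscca_denoise(joint, bscca_cfg or BsccaConfig())
    return bandpass(joint)


def _concat_montage(a, b):
    from .montage import BipolarMontage

    return BipolarMontage(list(a.channels) + list(b.channels))


def build_patient_records(
    cfg: SimConfig,
    meta: PatientMetadata,
    scale: CohortScale | None = None,
    denoise: bool = True,
) -> tuple[PatientRecords, Recording, GroundTruth]:
    """Simulate one pseudo-patient and cut its seizure/non-seizure epochs."""
    scale = scale or CohortScale()
    rec, truth = simulate_recording(cfg)
    sig = preprocess_recording(rec, denoise=denoise)
    seiz = extract_seizure_epochs(
        sig, truth.seizure_annotations, scale.epoch_len_s, patient_id=meta.pid
    )
    nonseiz = sample_nonseizure_epochs(
        sig, truth.seizure_annotations, n=scale.n_nonseizure,
        epoch_len_s=scale.nonseizure_len_s, guard_s=scale.guard_s,
        seed=cfg.seed + 1, patient_id=meta.pid,
    )
    return PatientRecords(meta.pid, seiz, nonseiz, meta), rec, truth


def run_detection_benchmark(
    seed: int = 0,
    scale: CohortScale | None = None,
    svm_cfg: SvmConfig | None = None,
    include_channel_subset: bool = True,
    n_patients: int | None = None,
) -> dict:
    """Leave-one-seizure-out detection over the synthetic cohort.

    Returns scalp and ear :class:`PerformanceReport` objects, their paired
    signed-rank comparison, and (optionally) the per-ear-channel
    ipsi/contra comparison.
    """
    scale = scale or CohortScale()
    svm_cfg = svm_cfg or SvmConfig(seed=seed)
    feat_cfg = FeatureConfig()
    patients = []
    for cfg, meta in cohort_configs(seed, scale)[:n_patients]:
        records, _, _ = build_patient_records(cfg, meta, scale)
        patients.append(records)

    scalp_names = define_scalp_montage().channel_names
    ear_names = define_ear_montage().channel_names
    scalp_report = PerformanceReport(
        "scalp", [loo_evaluate(p, scalp_names, svm_cfg, feat_cfg) for p in patients]
    )
    ear_report = PerformanceReport(
        "ear", [loo_evaluate(p, ear_names, svm_cfg, feat_cfg) for p in patients]
    )
    out = {
        "scalp": scalp_report,
        "ear": ear_report,
        "scalp_vs_ear_p": compare_reports_wilcoxon(scalp_report, ear_report),
    }
    if include_channel_subset:
        out["subset"] = channel_subset_comparison(patients, svm_cfg, feat_cfg)
    return out


def run_eog_benchmark(
    seed: int = 0,
    n_patients: int = 12,
    segment_s: float = 300.0,
    blink_amplitude_uv: float = 60.0,
) -> dict:
    """Blink-EOG amplitude contrast on symmetric synthetic blinks.

    Each pseudo-patient contributes one blink-rich segment; the blink
    source is recovered by ICA on the scalp montage and amplitudes are
    measured on Fp2-F8 and the four ear channels.  Returns per-patient
    amplitude arrays plus the signed-rank comparison of each ear channel
    against Fp2-F8.
    """
    channels = ["Fp2-F8", "LC-RC", "LT-RT", "LT-LC", "RT-RC"]
    amplitudes: dict[str, list[float]] = {ch: [] for ch in channels}
    for i in range(n_patients):
        cfg = SimConfig(
            seed=seed * 1000 + 500 + i,
            duration_s=segment_s,
            blink=BlinkConfig(
                peak_amplitude_uv=blink_amplitude_uv, left_right_asymmetry=0.0
            ),
        )
        rec, _ = simulate_recording(cfg)
        sig = preprocess_recording(rec, denoise=False)
        scalp = define_scalp_montage().channel_names
        scalp_sig = _subset_signal(sig, scalp)
        report = analyze_blinks(
            scalp_sig,
            {ch: sig.channel(ch) for ch in channels},
            seed=seed + i,
            n_components=10,
            strict_ica=False,
        )
        for ch in channels:
            amplitudes[ch].append(report.per_patient_amplitudes[ch])
    from .eog import compare_amplitudes_wilcoxon

    tests = (
        {
            ch: compare_amplitudes_wilcoxon(amplitudes["Fp2-F8"], amplitudes[ch])
            for ch in channels[1:]
        }
        if n_patients >= 5
        else {}
    )
    return {"amplitudes": {k: np.array(v) for k, v in amplitudes.items()},
            "wilcoxon_vs_frontal": tests,
            "blink_amplitude_uv": blink_amplitude_uv}


def _subset_signal(sig, names):
    from .montage import MultichannelSignal

    idx = [sig.channel_names.index(n) for n in names]
    return MultichannelSignal(sig.fs_hz, list(names), sig.data[idx], sig.start_time)


def run_matchup_benchmark(
    seed: int = 0, n_patients: int = 12, scale: CohortScale | None = None
) -> list[dict]:
    """Best-matchup scalp channel per ear channel on the synthetic cohort."""
    import pandas as pd

    scale = scale or CohortScale()
    rows = []
    for cfg, meta in cohort_configs(seed, scale)[:n_patients]:
        rec, truth = simulate_recording(cfg)
        sig = preprocess_recording(rec, denoise=False)
        windows = [(a.onset_s, a.end_s) for a in truth.seizure_annotations]
        scalp_names = define_scalp_montage().channel_names
        scalp = {n: sig.channel(n) for n in scalp_names}
        for ear_name in define_ear_montage().channel_names:
            best, coh = best_matchup(
                sig.channel(ear_name), scalp, windows, sig.fs_hz
            )
            rows.append(
                {"pid": meta.pid, "ear_channel": ear_name,
                 "scalp_channel": best, "coherence": coh}
            )
    return rows
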