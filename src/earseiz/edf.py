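"""EDF (European Data Format) recording I/O.

Writing uses a small self-contained EDF encoder (16-bit samples, 1-second
data records, per-channel physical calibration in µV).  Reading goes
through :func:`mne.io.read_raw_edf`, so every file written here is parsed
back by an independent, widely-used EDF implementation — the round-trip is
exact up to the 16-bit quantization step declared in the header.
"""

from __future__ import annotations

import math
import struct

import numpy as np

from .montage import Recording

__all__ = ["write_recording", "read_recording", "quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def quantization_step(physical_min: float, physical_max: float) -> float:
    """Physical value of one digital unit for a 16-bit EDF signal."""
    return (physical_max - physical_min) / (_DIG_MAX - _DIG_MIN)


def write_recording(rec: Recording, path) -> None:
    """Write a referential recording to EDF.

    The sampling rate must be a positive integer (samples are stored in
    1-second data records).  A final partial second is zero-padded to a
    whole record, as EDF has no partial records.
    """
    fs = rec.fs_hz
    if fs != int(fs) or fs <= 0:
        raise ValueError(f"EDF writer requires integer sampling rate, got {fs}")
    fs = int(fs)
    n_sig = len(rec.electrode_labels)
    n_records = max(1, math.ceil(rec.n_samples / fs))

    data = rec.data
    if rec.n_samples < n_records * fs:
        pad = np.zeros((n_sig, n_records * fs - rec.n_samples))
        data = np.hstack([data, pad])

    # per-channel symmetric physical range covering the data
    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0) * (1 + 1e-6)
    phys_min = -phys_max

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"pid ref_{rec.reference_label}", 80))
        fh.write(_pad("earseiz recording", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))  # record duration, seconds
        fh.write(_pad(str(n_sig), 4))

        for lab in rec.electrode_labels:
            fh.write(_pad(lab, 16))
        fh.write(_pad("", 80) * n_sig)  # transducer
        fh.write(_pad("uV", 8) * n_sig)
        for k in range(n_sig):
            fh.write(_pad(f"{phys_min[k]:.6g}", 8))
        for k in range(n_sig):
            fh.write(_pad(f"{phys_max[k]:.6g}", 8))
        fh.write(_pad(str(_DIG_MIN), 8) * n_sig)
        fh.write(_pad(str(_DIG_MAX), 8) * n_sig)
        fh.write(_pad("", 80) * n_sig)  # prefiltering
        fh.write(_pad(str(fs), 8) * n_sig)
        fh.write(_pad("", 32) * n_sig)

        # physical -> digital, using the ranges as printed in the header
        pmin = np.array([float(f"{v:.6g}") for v in phys_min])
        pmax = np.array([float(f"{v:.6g}") for v in phys_max])
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        digital = np.round((data - pmin[:, None]) * gain[:, None]) + _DIG_MIN
        digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

        for r in range(n_records):
            chunk = digital[:, r * fs : (r + 1) * fs]
            fh.write(chunk.tobytes())


def read_recording(path, reference_label: str = "Fpz") -> Recording:
    """Read an EDF file into a µV :class:`Recording` via MNE."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface a format error
        raise ValueError(f"could not parse {path!r} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE returns volts for EEG-dimension data
    return Recording(
        fs_hz=float(raw.info["sfreq"]),
        electrode_labels=list(raw.ch_names),
        data=data_uv,
        reference_label=reference_label,
    )
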