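"""Minimal EDF reading and writing for 19-channel scalp EEG.

Reading delegates to :func:`mne.io.read_raw_edf`.  Writing implements the
plain (continuous, 16-bit) EDF header and data-record layout directly, with
one-second data records and symmetric per-channel physical ranges; the MNE
reader doubles as an independent round-trip check in the test suite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .montage import normalize_channel_name
from .preprocess import RawRecording


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: RawRecording, patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write a recording as 16-bit EDF with 1 s data records.

    The sampling rate must be an integer; a trailing partial second is
    truncated.  Amplitudes are stored in uV with symmetric physical ranges.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.signal.shape[0]
    n_records = rec.signal.shape[1] // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.signal[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.01, 1.0)
    dig_max = 32767
    scaled = np.round(data / phys_max[:, None] * dig_max).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(patient_id, 80),
        _pad(recording_id, 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    labels = [f"EEG {name}" for name in rec.channel_names]
    per_signal = b"".join([
        b"".join(_pad(lb, 16) for lb in labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(_pad("uV", 8) for _ in labels),
        b"".join(_pad(f"{-pm:.6g}"[:8], 8) for pm in phys_max),
        b"".join(_pad(f"{pm:.6g}"[:8], 8) for pm in phys_max),
        b"".join(_pad(str(-dig_max - 1), 8) for _ in labels),
        b"".join(_pad(str(dig_max), 8) for _ in labels),
        b"".join(_pad("", 80) for _ in labels),
        b"".join(_pad(str(fs), 8) for _ in labels),
        b"".join(_pad("", 32) for _ in labels),
    ])
    records = scaled.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())


def read_edf(path) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (uV, normalized labels)."""
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # V -> uV
    names = [normalize_channel_name(ch) for ch in raw.ch_names]
    return RawRecording(signal=signal, fs=float(raw.info["sfreq"]),
                        channel_names=names)
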