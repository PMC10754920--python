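"""EDF (European Data Format) reading and writing for the EEG recordings.

Writing uses a small self-contained EDF writer (16-bit samples, 1-s data
records, configurable physical range, default ±1000 µV), sufficient for the
four-channel 256-Hz recordings this pipeline produces.  Reading goes through
MNE's EDF reader, which also serves as an independent check on the writer in
the test suite.  Round-tripping preserves samples to within the 16-bit
quantisation step of the declared physical range (±1000 µV -> ~0.03 µV).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .features import EEGRecording

DIG_MIN, DIG_MAX = -32768, 32767


class EDFFormatError(ValueError):
    """Malformed EDF input or an unwritable recording."""


def _field(value: str, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise EDFFormatError(f"EDF header field too long: {text!r} (> {width})")
    return text.ljust(width).encode("ascii")


def write_edf(
    rec: EEGRecording, path: str | Path, physical_range_uV: float = 1000.0
) -> None:
    """Write the recording as EDF with µV channels and 1-s data records.

    The last partial second, if any, is zero-padded; sample values outside
    ``±physical_range_uV`` are clipped.
    """
    fs = rec.sample_rate_hz
    spr = round(fs)
    if abs(fs - spr) > 1e-9:
        raise EDFFormatError("EDF writer requires an integer sampling rate")
    n_sig = len(rec.channel_labels)
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    pmin, pmax = -physical_range_uV, physical_range_uV
    scale = (pmax - pmin) / (DIG_MAX - DIG_MIN)
    digital = np.clip(np.rint((padded - pmin) / scale) + DIG_MIN, DIG_MIN, DIG_MAX)
    digital = digital.astype("<i2")

    header = b"".join(
        [
            _field("0", 8),  # version
            _field("X X X X", 80),  # patient id (anonymous)
            _field("Startdate X X X X", 80),  # recording id
            _field("01.01.00", 8),  # fixed date: simulated data, keeps files reproducible
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_sig)), 8),
            _field("EDF+C", 44),
            _field(str(n_rec), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_sig), 4),
        ]
    )
    sig_fields = [
        (16, [label for label in rec.channel_labels]),
        (80, ["simulated scalp electrode"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{pmin:g}"] * n_sig),
        (8, [f"{pmax:g}"] * n_sig),
        (8, [str(DIG_MIN)] * n_sig),
        (8, [str(DIG_MAX)] * n_sig),
        (80, ["BP 0.5-70 Hz"] * n_sig),
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),
    ]
    header += b"".join(
        b"".join(_field(v, width) for v in values) for width, values in sig_fields
    )

    with open(path, "wb") as fh:
        fh.write(header)
        # records are channel-major within each 1-s block
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an ``EEGRecording`` (µV)."""
    import mne  # deferred: heavy import, only needed for file input

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # pragma: no cover - malformed input path
        raise EDFFormatError(f"cannot parse EDF file {path}: {err}") from err
    data = raw.get_data(units="uV")
    return EEGRecording(
        data, tuple(raw.ch_names), float(raw.info["sfreq"]), start_time_s=0.0
    )
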