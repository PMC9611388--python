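"""Minimal EDF (European Data Format) writer/reader plus a TSV event sidecar.

Implements the classic EDF container directly: a 256-byte ASCII header, one
256-byte header extension per signal, and 16-bit little-endian data records.
Only what the pipeline needs is supported — identical sampling rate across
channels, physical units µV, 1 s data records — which covers round-tripping
the synthetic recordings.  The true sample count is stashed in the reserved
header field so zero-padding of the final record can be trimmed on read.

Events travel in a sidecar TSV with columns ``onset_sample``, ``condition``,
``session``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContinuousRecording, Event

__all__ = ["write_edf", "read_edf", "write_events_tsv", "read_events_tsv",
           "write_recording", "read_recording"]

_DIGITAL_MAX = 32767
_DIGITAL_MIN = -32767  # symmetric range: zero maps to zero exactly


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: ContinuousRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic EEG") -> None:
    """Write a recording as 16-bit EDF (physical units µV)."""
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))                      # samples per 1 s record, per signal
    n_sig = rec.n_channels
    n_records = int(np.ceil(rec.n_times / spr))

    # one symmetric physical range for all channels keeps quantization uniform
    phys = float(np.max(np.abs(rec.samples)))
    phys = max(np.ceil(phys * 1.05), 1.0)
    gain = _DIGITAL_MAX / phys
    digital = np.clip(np.round(rec.samples * gain), _DIGITAL_MIN, _DIGITAL_MAX)
    padded = np.zeros((n_sig, n_records * spr), dtype=np.int16)
    padded[:, : rec.n_times] = digital.astype(np.int16)

    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_sig + 1)), 8),
        _field(f"NSAMP={rec.n_times}", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_sig), 4),
    ])
    sig_fields = [
        (16, rec.channel_names),
        (80, ["synthetic"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{-phys:g}"] * n_sig),
        (8, [f"{phys:g}"] * n_sig),
        (8, [str(_DIGITAL_MIN)] * n_sig),
        (8, [str(_DIGITAL_MAX)] * n_sig),
        (80, [""] * n_sig),
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),
    ]
    header += b"".join(
        b"".join(_field(str(v), width) for v in values) for width, values in sig_fields
    )

    # data records interleave signals: record r = [sig0 spr samples, sig1 ...]
    records = padded.reshape(n_sig, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.astype("<i2").tobytes())


def read_edf(path: str | Path) -> ContinuousRecording:
    """Read an EDF file written by :func:`write_edf` (or any single-rate EDF)."""
    path = Path(path)
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        n_records = int(fixed[236:244].decode().strip())
        duration = float(fixed[244:252].decode().strip())
        n_sig = int(fixed[252:256].decode().strip())
        reserved = fixed[192:236].decode().strip()
        sig = fh.read(256 * n_sig)
        raw = np.frombuffer(fh.read(), dtype="<i2")

    def col(offset: int, width: int) -> list[str]:
        base = offset
        return [sig[base + i * width: base + (i + 1) * width].decode().strip()
                for i in range(n_sig)]

    ofs = 0
    labels = col(ofs, 16); ofs += 16 * n_sig
    ofs += 80 * n_sig      # transducer
    ofs += 8 * n_sig       # dimension
    phys_min = [float(v) for v in col(ofs, 8)]; ofs += 8 * n_sig
    phys_max = [float(v) for v in col(ofs, 8)]; ofs += 8 * n_sig
    dig_min = [int(v) for v in col(ofs, 8)]; ofs += 8 * n_sig
    dig_max = [int(v) for v in col(ofs, 8)]; ofs += 8 * n_sig
    ofs += 80 * n_sig      # prefiltering
    spr = [int(v) for v in col(ofs, 8)]
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr0 = spr[0]
    fs = spr0 / duration

    data = (raw.reshape(n_records, n_sig, spr0).transpose(1, 0, 2)
            .reshape(n_sig, -1).astype(np.float64))  # avoid int16 overflow below
    out = np.empty(data.shape, dtype=float)
    for i in range(n_sig):
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        out[i] = (data[i] - dig_min[i]) * scale + phys_min[i]
    if reserved.startswith("NSAMP="):
        out = out[:, : int(reserved[6:])]
    return ContinuousRecording(out, fs, labels)


def write_events_tsv(events: list[Event], path: str | Path) -> None:
    pd.DataFrame(
        [{"onset_sample": e.sample, "condition": e.condition, "session": e.session}
         for e in events]
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    return [Event(int(r.onset_sample), str(r.condition), str(r.session))
            for r in df.itertuples()]


def write_recording(rec: ContinuousRecording, edf_path: str | Path,
                    events_path: str | Path | None = None) -> None:
    """Write EDF plus the event sidecar (default: same stem, ``_events.tsv``)."""
    edf_path = Path(edf_path)
    if events_path is None:
        events_path = edf_path.with_name(edf_path.stem + "_events.tsv")
    write_edf(rec, edf_path)
    write_events_tsv(rec.events, events_path)


def read_recording(edf_path: str | Path,
                   events_path: str | Path | None = None) -> ContinuousRecording:
    edf_path = Path(edf_path)
    if events_path is None:
        events_path = edf_path.with_name(edf_path.stem + "_events.tsv")
    rec = read_edf(edf_path)
    if Path(events_path).exists():
        rec.events = read_events_tsv(events_path)
    return rec
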