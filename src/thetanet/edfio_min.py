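"""Minimal EDF+C file writing, and reading via mne.

Only what the pipeline needs: 16-bit continuous EDF+ with one annotation
channel carrying the scenario event markers.  Data records are 1 s long;
the last record is zero-padded if the recording is not a whole number of
seconds.  Reading goes through mne's EDF reader, which also serves as an
independent check on the files this module writes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import Event, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    for fmt in (f"%.{width - 2}g", "%.3f", "%.1f", "%d"):
        s = fmt % value
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot encode {value} in {width} chars")


def _tal(onset: float, duration: float | None, label: str) -> bytes:
    out = ("+%g" % onset).encode("ascii")
    if duration is not None:
        out += ("\x15%g" % duration).encode("ascii")
    out += b"\x14" + label.encode("ascii") + b"\x14\x00"
    return out


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a Recording as EDF+C with events as annotations."""
    fs = rec.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    data = rec.data
    if n_records * fs > rec.n_samples:
        pad = n_records * fs - rec.n_samples
        data = np.pad(data, ((0, 0), (0, pad)))

    # physical scaling per channel (flat channels get a +/-1 range)
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round(
        (data - pmin[:, None]) * scale[:, None] + _DIG_MIN
    ).astype("<i2")

    # annotation payload per record: a timestamp TAL plus any events
    # whose onset falls inside the record
    rec_tals: list[bytes] = []
    for r in range(n_records):
        payload = _tal(float(r), None, "")
        for ev in rec.events:
            onset_s = ev.onset / fs
            if r <= onset_s < r + 1:
                payload += _tal(onset_s, (ev.offset - ev.onset) / fs, ev.label)
        rec_tals.append(payload)
    ann_bytes = max(len(t) for t in rec_tals)
    ann_bytes += ann_bytes % 2  # int16 alignment
    ann_samples = ann_bytes // 2

    ns = n_ch + 1
    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field("Startdate X X X X", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(256 * (ns + 1), 8)
    header += _field("EDF+C", 44)
    header += _field(n_records, 8)
    header += _field(1, 8)
    header += _field(ns, 4)

    labels = list(rec.channel_labels) + ["EDF Annotations"]
    header += b"".join(_field(lb, 16) for lb in labels)
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field("uV", 8) for _ in range(n_ch)) + _field("", 8)
    header += b"".join(_num(v) for v in pmin) + _num(-1)
    header += b"".join(_num(v) for v in pmax) + _num(1)
    header += b"".join(_num(_DIG_MIN) for _ in range(ns))
    header += b"".join(_num(_DIG_MAX) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_num(fs) for _ in range(n_ch)) + _num(ann_samples)
    header += b"".join(_field("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            fh.write(rec_tals[r].ljust(ann_bytes, b"\x00"))


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (annotations become events)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    data = raw.get_data(units="uV")
    events = []
    for ann in raw.annotations:
        label = ann["description"]
        if not label:
            continue
        onset = int(round(ann["onset"] * fs))
        offset = onset + int(round(ann["duration"] * fs))
        events.append(Event(label, onset, offset))
    return Recording(
        data=data,
        sample_rate=fs,
        channel_labels=list(raw.ch_names),
        events=events,
    )
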