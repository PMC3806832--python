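"""Reading and writing EEG recordings.

EDF and BrainVision recordings are read through MNE-Python.  EDF export is a
small self-contained writer for the classic 16-bit EDF layout (one-second
data records, physical units microvolts), sufficient for fixture recordings;
a lossless float sidecar (.npz + JSON annotation) accompanies it for
bit-exact round trips, since EDF itself quantizes to 16 bits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forward import ElectrodeMontage, read_montage, write_montage
from .simulate import IctalAnnotation
from .spectral import EEGSegment

__all__ = [
    "write_edf",
    "read_edf",
    "read_brainvision",
    "save_recording",
    "load_recording",
]


def _pad(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(segment: EEGSegment, path) -> None:
    """Write an EEGSegment as 16-bit EDF with 1 s data records.

    Data are expected in microvolts; the sampling rate must be a positive
    integer.  The last record is zero-padded if the segment does not end on
    a record boundary.
    """
    fs = segment.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(fs)                       # samples per 1 s record
    n_ch = segment.n_channels
    n_rec = int(np.ceil(segment.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, :segment.n_samples] = segment.data
    labels = (list(segment.montage.labels) if segment.montage is not None
              else [f"EEG{i:03d}" for i in range(n_ch)])

    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    pmin = -pmax
    dmax, dmin = 32767, -32768
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin[:, None]) * gain[:, None] + dmin),
                      dmin, dmax).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(lab, 16) for lab in labels],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{pmin[i]:.6g}"[:8], 8) for i in range(n_ch)],
        [_pad(f"{pmax[i]:.6g}"[:8], 8) for i in range(n_ch)],
        [_pad(str(dmin), 8)] * n_ch,
        [_pad(str(dmax), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def _segment_from_raw(raw, montage: ElectrodeMontage | None) -> EEGSegment:
    data = raw.get_data() * 1e6        # volts -> microvolts
    return EEGSegment(data=data, fs=float(raw.info["sfreq"]),
                      montage=montage, t0=0.0)


def read_edf(path, montage: ElectrodeMontage | None = None) -> EEGSegment:
    """Load an EDF recording as an EEGSegment (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _segment_from_raw(raw, montage)


def read_brainvision(vhdr_path, montage: ElectrodeMontage | None = None) -> EEGSegment:
    """Load a BrainVision (.vhdr/.eeg/.vmrk) recording as an EEGSegment."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True,
                                      verbose="error")
    return _segment_from_raw(raw, montage)


def save_recording(prefix, segment: EEGSegment,
                   annotation: IctalAnnotation | None = None) -> dict:
    """Persist a recording losslessly: .npz data, .json annotation, montage.

    Returns the mapping of written file paths.  An EDF rendition is written
    alongside when the sampling rate is integral.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    np.savez_compressed(prefix.with_suffix(".npz"), data=segment.data,
                        fs=segment.fs, t0=segment.t0)
    paths["data"] = str(prefix.with_suffix(".npz"))
    if segment.montage is not None:
        write_montage(segment.montage, prefix.parent / (prefix.name + "_montage.txt"))
        paths["montage"] = str(prefix.parent / (prefix.name + "_montage.txt"))
    if annotation is not None:
        annotation.save(prefix.with_suffix(".json"))
        paths["annotation"] = str(prefix.with_suffix(".json"))
    if segment.fs == int(segment.fs):
        write_edf(segment, prefix.with_suffix(".edf"))
        paths["edf"] = str(prefix.with_suffix(".edf"))
    return paths


def load_recording(prefix):
    """Load a recording written by :func:`save_recording`.

    Returns ``(EEGSegment, IctalAnnotation | None)``; the float sidecar is
    the authoritative copy, so the round trip is bit-exact.
    """
    prefix = Path(prefix)
    blob = np.load(prefix.with_suffix(".npz"))
    montage = None
    mfile = prefix.parent / (prefix.name + "_montage.txt")
    if mfile.exists():
        montage = read_montage(mfile)
    ann = None
    if prefix.with_suffix(".json").exists():
        ann = IctalAnnotation.load(prefix.with_suffix(".json"))
    seg = EEGSegment(data=blob["data"], fs=float(blob["fs"]),
                     montage=montage, t0=float(blob["t0"]))
    return seg, ann
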