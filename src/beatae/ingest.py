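"""Read (and write) ECG recordings in a minimal WFDB-compatible subset.

Supports the pieces of the PhysioNet WFDB format the pipeline needs:
text headers (``.hea``), 16-bit little-endian signal files (format 16),
and the MIT annotation format for QRS times and rhythm-change labels.
Rhythm aux strings map onto the closed label vocabulary: ``(AFIB`` ->
AFib, ``(N`` -> NSR, everything else (atrial flutter ``(AFL``,
AV-junctional ``(J``, ...) -> other, which is excluded from the binary
task downstream.

CinC2017-style data are accepted as single-channel WFDB records plus a
``REFERENCE.csv`` manifest (``record,label`` with class letters N/A/O/~).

The reader/writer pair is deliberately small: it exists so synthetic
fixtures can round-trip through on-disk WFDB files and so real AFDB /
CinC2017 downloads can be ingested, not to cover every WFDB variant.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np

from .records import AFIB, NSR, OTHER, ECGRecord

__all__ = [
    "read_afdb_record",
    "read_cinc_record",
    "write_wfdb_record",
    "read_label_manifest",
    "export_csv",
]

log = logging.getLogger(__name__)

# MIT annotation type codes used here
_CODE_NORMAL = 1      # QRS annotation
_CODE_RHYTHM = 28     # rhythm change, label in aux string
_CODE_SKIP = 59
_CODE_NUM = 60
_CODE_SUB = 61
_CODE_CHN = 62
_CODE_AUX = 63

#: rhythm aux string -> internal label; everything unlisted maps to OTHER
RHYTHM_LABELS = {"(AFIB": AFIB, "(N": NSR, "(NSR": NSR}

#: CinC2017 class letter -> internal label (O = other rhythm, ~ = noisy)
CINC_LABELS = {"N": NSR, "A": AFIB, "O": OTHER, "~": OTHER}

_DEFAULT_GAIN = 200.0   # ADC units per millivolt
_DEFAULT_ADC_ZERO = 0


# ------------------------------------------------------------ annotations

def _write_annotations(path: Path, annotations: list) -> None:
    """``annotations``: list of (sample, code, aux-or-None), sorted."""
    out = bytearray()
    prev = 0
    for sample, code, aux in annotations:
        dt = sample - prev
        prev = sample
        if dt > 1023 or dt < 0:
            # SKIP word, then the 32-bit interval (high word first)
            out += struct.pack("<H", _CODE_SKIP << 10)
            out += struct.pack("<H", (dt >> 16) & 0xFFFF)
            out += struct.pack("<H", dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (code << 10) | (dt & 0x3FF))
        if aux:
            raw = aux.encode("ascii")
            out += struct.pack("<H", (_CODE_AUX << 10) | len(raw))
            out += raw
            if len(raw) % 2:
                out += b"\x00"
    out += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(out))


def _read_annotations(path: Path) -> list:
    """Return list of (sample, code, aux-or-None)."""
    data = path.read_bytes()
    anns = []
    time = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        field = word & 0x3FF
        if word == 0:
            break
        if code == _CODE_SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
        elif code == _CODE_AUX:
            aux = data[i : i + field].decode("ascii", errors="replace")
            i += field + (field % 2)
            if anns:
                sample, c, _ = anns[-1]
                anns[-1] = (sample, c, aux)
        elif code in (_CODE_NUM, _CODE_SUB, _CODE_CHN):
            continue
        else:
            time += field + pending_skip
            pending_skip = 0
            anns.append((time, code, None))
    return anns


# ------------------------------------------------------------ header/signal

def write_wfdb_record(
    record: ECGRecord,
    directory,
    gain: float = _DEFAULT_GAIN,
    annotator: str = "atr",
    n_channels: int = 1,
) -> Path:
    """Export a record as ``.hea`` + format-16 ``.dat`` + ``.atr``.

    Signals are scaled from millivolts to integer ADC units at export
    (gain counts/mV), the one place quantization happens.  Rhythm
    intervals become rhythm-change annotations; ground-truth R-peak
    times, if present, become NORMAL QRS annotations.  With
    ``n_channels=2`` the second channel is a half-amplitude copy, which
    lets tests confirm that readers pick channel 0.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    adc = np.round(record.signal * gain).astype("<i2")
    if n_channels == 2:
        adc2 = np.round(record.signal * 0.5 * gain).astype("<i2")
        interleaved = np.empty(2 * adc.size, dtype="<i2")
        interleaved[0::2] = adc
        interleaved[1::2] = adc2
        (directory / f"{name}.dat").write_bytes(interleaved.tobytes())
    else:
        (directory / f"{name}.dat").write_bytes(adc.tobytes())

    lines = [f"{name} {n_channels} {record.fs:g} {record.signal.size}"]
    for ch in range(n_channels):
        lines.append(
            f"{name}.dat 16 {gain:g}({_DEFAULT_ADC_ZERO})/mV 16 0 "
            f"{int(adc[0])} 0 0 ECG{ch + 1}"
        )
    lines.append(f"# patient {record.patient_id}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")

    anns: list = []
    inv_labels = {AFIB: "(AFIB", NSR: "(N"}
    for start, _end, label in record.intervals:
        anns.append((start, _CODE_RHYTHM, inv_labels.get(label, "(OTHER")))
    if record.rpeak_times is not None:
        for rt in record.rpeak_times:
            anns.append((int(round(rt * record.fs)), _CODE_NORMAL, None))
    anns.sort(key=lambda a: (a[0], a[1] != _CODE_RHYTHM))
    _write_annotations(directory / f"{name}.{annotator}", anns)
    return directory / f"{name}.hea"


def _read_header(hea_path: Path) -> dict:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip()
    ]
    first = lines[0].split()
    name, n_sig, fs, n_samples = first[0], int(first[1]), float(first[2]), int(first[3])
    gains = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        gain_field = parts[2]
        g = gain_field.split("(")[0].split("/")[0]
        gains.append(float(g) if float(g) != 0 else _DEFAULT_GAIN)
    patient = None
    for ln in lines:
        if ln.startswith("# patient"):
            patient = ln.split()[-1]
    return {
        "name": name,
        "n_sig": n_sig,
        "fs": fs,
        "n_samples": n_samples,
        "gains": gains,
        "patient": patient,
    }


def _read_signal(dat_path: Path, n_sig: int, n_samples: int, gain: float) -> np.ndarray:
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if n_sig > 1:
        raw = raw.reshape(-1, n_sig)[:, 0]  # channel 0 ("ECG1") only
    return raw[:n_samples].astype(float) / gain


# ------------------------------------------------------------ public API

def read_afdb_record(path) -> ECGRecord:
    """Read an AFDB-style record: channel 0 of the signal, rhythm
    intervals from consecutive rhythm-change annotations, provided QRS
    times retained as candidate R-peaks (to be refined downstream).

    ``path`` is the header path or the record path without extension.
    A missing annotation file yields a record with empty intervals and a
    logged warning; an unreadable signal is a hard error.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".hea" else path
    hdr = _read_header(base.with_suffix(".hea"))
    signal = _read_signal(
        base.with_suffix(".dat"), hdr["n_sig"], hdr["n_samples"], hdr["gains"][0]
    )

    intervals: list = []
    rpeak_times = None
    ann_path = None
    for ext in (".atr", ".qrs"):
        if base.with_suffix(ext).exists():
            ann_path = base.with_suffix(ext)
            break
    if ann_path is None:
        log.warning("no annotation file for %s; record has empty intervals", base.name)
    else:
        anns = _read_annotations(ann_path)
        changes = [
            (s, RHYTHM_LABELS.get(aux, OTHER))
            for s, code, aux in anns
            if code == _CODE_RHYTHM
        ]
        for k, (start, label) in enumerate(changes):
            end = changes[k + 1][0] if k + 1 < len(changes) else signal.size
            if end > start:
                intervals.append((start, min(end, signal.size), label))
        qrs = [s for s, code, _ in anns if code == _CODE_NORMAL]
        if qrs:
            rpeak_times = np.array(qrs, dtype=float) / hdr["fs"]

    return ECGRecord(
        record_id=hdr["name"],
        patient_id=hdr["patient"] or hdr["name"],
        signal=signal,
        fs=hdr["fs"],
        intervals=intervals,
        provenance="afdb-like",
        rpeak_times=rpeak_times,
    )


def read_label_manifest(path) -> dict:
    """Parse a CinC2017 ``REFERENCE.csv``-dialect manifest into
    ``{record_id: class_letter}``."""
    manifest = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.lower().startswith("record,"):
            continue
        rec, label = [p.strip() for p in ln.split(",")[:2]]
        manifest[rec] = label
    return manifest


def read_cinc_record(path, label_manifest: dict) -> ECGRecord:
    """Read a CinC2017-style single-channel record with one whole-record
    interval carrying the manifest label.  Class letters other than N/A
    map to ``other`` and are excluded by the beat-extraction filter
    downstream.  A record id missing from the manifest is an error.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".hea" else path
    hdr = _read_header(base.with_suffix(".hea"))
    if hdr["name"] not in label_manifest:
        raise KeyError(f"record {hdr['name']!r} missing from label manifest")
    letter = label_manifest[hdr["name"]]
    label = CINC_LABELS.get(letter, OTHER)
    signal = _read_signal(
        base.with_suffix(".dat"), hdr["n_sig"], hdr["n_samples"], hdr["gains"][0]
    )
    return ECGRecord(
        record_id=hdr["name"],
        patient_id=hdr["patient"] or hdr["name"],
        signal=signal,
        fs=hdr["fs"],
        intervals=[(0, signal.size, label)],
        provenance="cinc-like",
    )


def export_csv(record: ECGRecord, directory) -> tuple[Path, Path]:
    """Plain-text export: a signal CSV (sample,mV) and an R-time/label CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sig_path = directory / f"{record.record_id}_signal.csv"
    with open(sig_path, "w") as fh:
        fh.write("sample,mV\n")
        for i, v in enumerate(record.signal):
            fh.write(f"{i},{v:.6f}\n")
    ann_path = directory / f"{record.record_id}_rpeaks.csv"
    with open(ann_path, "w") as fh:
        fh.write("r_time_s,label\n")
        if record.rpeak_times is not None:
            labels = record.beat_labels or [""] * len(record.rpeak_times)
            for rt, lab in zip(record.rpeak_times, labels):
                fh.write(f"{rt:.6f},{lab}\n")
    return sig_path, ann_path
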