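"""Minimal reader/writer for the WFDB waveform-database standard.

Implements the subset this tool needs, from the published format
descriptions: single-segment records, format-16 signals (16-bit
little-endian two's-complement ADC units, frame-interleaved), `.hea`
headers with gain/baseline, and MIT-format `.atr` beat annotations
(10-bit time deltas with SKIP escapes for long intervals; NUM/SUB/CHN/
AUX fields are parsed and ignored).  Amplitudes quantize to 1/gain mV
on write, so round trips are exact at ADC resolution.
"""

from __future__ import annotations

import re
import struct
from pathlib import Path

import numpy as np

from .records import Annotation, RawRecord

__all__ = ["read_wfdb", "write_wfdb", "MissingLeadError"]

# standard annotation codes <-> symbols (beat subset)
_CODE_TO_SYM = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_SYM_TO_CODE = {s: c for c, s in _CODE_TO_SYM.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class MissingLeadError(ValueError):
    """Requested lead not present; message lists the available leads."""


def write_wfdb(record: RawRecord, directory, name: str | None = None,
               gain: float = 200.0, lead: str = "MLII") -> Path:
    """Write header, format-16 signal and annotation files; returns the
    header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or (record.record_id or "record")
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")

    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    fs = record.fs
    fs_txt = f"{fs:g}"
    header = [
        f"{name} 1 {fs_txt} {len(adc)}",
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if len(adc) else 0} 0 0 {lead}",
    ]
    (directory / f"{name}.hea").write_text("\n".join(header) + "\n")

    words = bytearray()
    t_prev = 0
    for ann in record.annotations:
        delta = ann.sample - t_prev
        t_prev = ann.sample
        code = _SYM_TO_CODE.get(ann.symbol, 13)  # unknown -> Q
        if delta > 1023:
            # SKIP escape: interval as 32 bits, high word first (PDP-11 order)
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<H", (delta >> 16) & 0xFFFF)
            words += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        words += struct.pack("<H", (code << 10) | (delta & 0x3FF))
    words += struct.pack("<H", 0)
    (directory / f"{name}.atr").write_bytes(bytes(words))
    return directory / f"{name}.hea"


def _read_annotations(path: Path) -> list[Annotation]:
    raw = path.read_bytes()
    anns: list[Annotation] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", raw, i)
            (lo,) = struct.unpack_from("<H", raw, i + 2)
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        t += delta
        sym = _CODE_TO_SYM.get(code)
        if sym is not None:
            anns.append(Annotation(t, sym))
    return anns


def read_wfdb(path, lead: str | None = None) -> RawRecord:
    """Read a single-segment format-16 record; `path` is the header file
    or its stem.  `lead` selects the channel by its description, with a
    fallback to channel 0 (warning) when not given."""
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [
        l.strip() for l in path.read_text().splitlines()
        if l.strip() and not l.startswith("#")
    ]
    head = lines[0].split()
    name, n_sig, fs = head[0], int(head[1]), float(head[2])

    sig_lines = lines[1 : 1 + n_sig]
    leads, gains, baselines, fmts, files = [], [], [], [], []
    for sl in sig_lines:
        parts = sl.split()
        files.append(parts[0])
        fmts.append(parts[1])
        gain, baseline = 200.0, 0.0
        if len(parts) > 2:
            mo = re.match(r"([0-9.eE+-]+)(?:\(([-0-9]+)\))?(?:/\w+)?$", parts[2])
            if mo:
                gain = float(mo.group(1)) or 200.0
                baseline = float(mo.group(2) or 0)
        gains.append(gain)
        baselines.append(baseline)
        leads.append(parts[8] if len(parts) > 8 else f"ch{len(leads)}")
    if any(f.split("x")[0] != "16" for f in fmts):
        raise ValueError(f"only format 16 supported, header has {fmts}")

    if lead is not None:
        if lead not in leads:
            raise MissingLeadError(
                f"lead {lead!r} not in record {name}; available: {leads}"
            )
        ch = leads.index(lead)
    else:
        ch = 0

    dat = path.parent / files[ch]
    adc = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if n_sig > 1:
        adc = adc.reshape(-1, n_sig)[:, ch]
    samples = (adc.astype(np.float64) - baselines[ch]) / gains[ch]

    atr = path.with_suffix(".atr")
    anns = _read_annotations(atr) if atr.exists() else []
    anns = [a for a in anns if 0 <= a.sample < len(samples)]
    return RawRecord(samples, fs, anns, record_id=name)
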