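"""Minimal native WFDB codec (single-signal, format 16).

Supports the subset of the PhysioNet WFDB format family needed to exchange
single-lead records with MIT-BIH-style tooling: a ``.hea`` text header, a
``.dat`` file in format 16 (16-bit little-endian two's complement), and a
``.atr`` beat-annotation file in the standard MIT annotation encoding
(6-bit type / 10-bit interval words, with SKIP escapes for long gaps).
Multi-signal records and the other signal formats are out of scope.
"""

from __future__ import annotations

import os

import numpy as np

# MIT annotation type codes for the beat labels this package understands.
_LABEL_TO_CODE = {"N": 1, "V": 5, "F": 6, "A": 8, "S": 9}
_CODE_TO_LABEL = {v: k for k, v in _LABEL_TO_CODE.items()}

_SKIP = 59  # followed by a 4-byte interval, high word first
_EOF = 0


def read_header(hea_path: str) -> dict:
    """Parse a single-signal WFDB header file."""
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty WFDB header: {hea_path}")
    rec = lines[0].split()
    name = rec[0]
    n_sig = int(rec[1])
    if n_sig != 1:
        raise ValueError(f"only single-signal WFDB records are supported (got {n_sig} signals)")
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    sig = lines[1].split()
    dat_file = sig[0]
    fmt = sig[1].split("x")[0].split(":")[0].split("+")[0]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    gain = 200.0
    baseline = 0
    if len(sig) > 2:
        gain_field = sig[2]
        if "/" in gain_field:
            gain_field = gain_field.split("/")[0]
        if "(" in gain_field:
            gain_part, base_part = gain_field.split("(")
            gain = float(gain_part)
            baseline = int(base_part.rstrip(")"))
        else:
            gain = float(gain_field)
    if gain == 0:
        gain = 200.0
    return {
        "record_name": name,
        "fs": fs,
        "n_samples": n_samples,
        "dat_file": dat_file,
        "gain": gain,
        "baseline": baseline,
    }


def read_signal(record_base: str) -> tuple[np.ndarray, float]:
    """Read ``record_base``.hea/.dat; returns (signal in physical units, fs)."""
    header = read_header(record_base + ".hea")
    dat_path = os.path.join(os.path.dirname(record_base), header["dat_file"])
    raw = np.fromfile(dat_path, dtype="<i2")
    if header["n_samples"]:
        raw = raw[: header["n_samples"]]
    signal = (raw.astype(np.float64) - header["baseline"]) / header["gain"]
    return signal, header["fs"]


def write_signal(record_base: str, signal: np.ndarray, fs: float, gain: float = 200.0) -> None:
    """Write ``record_base``.hea/.dat in format 16 with the given ADC gain."""
    signal = np.asarray(signal, dtype=np.float64)
    name = os.path.basename(record_base)
    raw = np.round(signal * gain).astype(np.int64)
    if raw.min() < -32768 or raw.max() > 32767:
        raise ValueError("signal exceeds 16-bit ADC range at this gain")
    raw.astype("<i2").tofile(record_base + ".dat")
    with open(record_base + ".hea", "w") as fh:
        fh.write(f"{name} 1 {fs:g} {len(signal)}\n")
        fh.write(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(raw[0]) if len(raw) else 0} 0 0 ECG\n")


def read_annotations(atr_path: str) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file into (sample_index, label) pairs."""
    words = np.fromfile(atr_path, dtype="<u2")
    out: list[tuple[int, str]] = []
    time = 0
    i = 0
    while i < len(words):
        word = int(words[i])
        code = word >> 10
        interval = word & 0x3FF
        if code == _EOF and interval == 0:
            break
        if code == _SKIP:
            high, low = int(words[i + 1]), int(words[i + 2])
            skip = (high << 16) | low
            if skip >= 1 << 31:
                skip -= 1 << 32
            time += skip
            i += 3
            continue
        time += interval
        if code in _CODE_TO_LABEL:
            out.append((time, _CODE_TO_LABEL[code]))
        i += 1
    return out


def write_annotations(atr_path: str, annotations: list[tuple[int, str]]) -> None:
    """Encode (sample_index, label) pairs in MIT annotation format."""
    words: list[int] = []
    prev = 0
    for sample_index, label in annotations:
        if label not in _LABEL_TO_CODE:
            raise ValueError(f"unknown label {label!r}")
        gap = sample_index - prev
        if gap < 0:
            raise ValueError("annotations out of order")
        if gap > 1023:
            words.append(_SKIP << 10)
            words.append((gap >> 16) & 0xFFFF)
            words.append(gap & 0xFFFF)
            gap = 0
        words.append((_LABEL_TO_CODE[label] << 10) | gap)
        prev = sample_index
    words.append(0)  # EOF
    np.asarray(words, dtype="<u2").tofile(atr_path)
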