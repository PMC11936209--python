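"""Beat-set and record I/O.

Beat sets travel as plain CSV (one beat per row, samples at 9 significant
digits, optional trailing label column) or as a compressed ``.npz``
container.  For optional real-data use, a minimal reader/writer for the
WFDB formats the MIT-BIH Arrhythmia Database is distributed in is
included: header (``.hea``), signal formats 212 and 16 (``.dat``), and
MIT annotation files (``.atr``).  Only one chosen channel is extracted.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import BeatSet, RawRecord

__all__ = [
    "save_beats_csv",
    "load_beats_csv",
    "save_beats_npz",
    "load_beats_npz",
    "read_wfdb",
    "write_wfdb",
]


# ---------------------------------------------------------------------------
# CSV / npz beat containers
# ---------------------------------------------------------------------------

def save_beats_csv(beats: BeatSet, path: "str | Path") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(beats.count):
            row = ",".join(format(v, ".9g") for v in beats.data[i])
            if beats.labels is not None:
                row += f",{beats.labels[i]}"
            fh.write(row + "\n")


def load_beats_csv(path: "str | Path") -> BeatSet:
    rows: list[list[float]] = []
    labels: list[str] = []
    has_labels = None
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split(",")
            if not parts or parts == [""]:
                continue
            if has_labels is None:
                try:
                    float(parts[-1])
                    has_labels = False
                except ValueError:
                    has_labels = True
            if has_labels:
                rows.append([float(v) for v in parts[:-1]])
                labels.append(parts[-1])
            else:
                rows.append([float(v) for v in parts])
    if not rows:
        raise ValueError(f"no beats found in {path}")
    return BeatSet(np.asarray(rows, dtype=float), labels if has_labels else None)


def save_beats_npz(beats: BeatSet, path: "str | Path") -> None:
    kw = {"data": beats.data}
    if beats.labels is not None:
        kw["labels"] = np.asarray(beats.labels)
    np.savez_compressed(path, **kw)


def load_beats_npz(path: "str | Path") -> BeatSet:
    with np.load(path, allow_pickle=False) as z:
        labels = [str(s) for s in z["labels"]] if "labels" in z else None
        return BeatSet(np.asarray(z["data"], dtype=float), labels)


# ---------------------------------------------------------------------------
# Minimal WFDB (MIT format) support
# ---------------------------------------------------------------------------

# MIT annotation type codes for common beat labels
_CODE_TO_SYMBOL = {1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S", 10: "E",
                   11: "j", 12: "/", 13: "Q", 38: "f"}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}


def _read_header(hea_path: Path):
    lines = [l.strip() for l in hea_path.read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    rec_name, n_sig, fs, n_samp = (lines[0].split() + ["0"])[:4]
    signals = []
    for line in lines[1 : 1 + int(n_sig)]:
        f = line.split()
        gain_field = f[2].split("/")[0]
        if "(" in gain_field:
            gain, baseline = gain_field.rstrip(")").split("(")
        else:
            gain, baseline = gain_field, "0"
        signals.append(
            {
                "file": f[0],
                "fmt": int(f[1]),
                "gain": float(gain) if float(gain) != 0 else 200.0,
                "baseline": int(baseline),
            }
        )
    return rec_name, int(n_sig), float(fs), int(n_samp), signals


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_groups = len(b) // 3
    b = b[: n_groups * 3].reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    s1[s1 > 2047] -= 4096
    s2[s2 > 2047] -= 4096
    out = np.empty(n_groups * 2, dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    return out[:n_values]


def _pack_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if np.any(v > 2047) or np.any(v < -2048):
        raise ValueError("format 212 holds 12-bit samples; value out of range")
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).reshape(-1, 2)
    out = np.empty((v.shape[0], 3), dtype=np.uint8)
    out[:, 0] = v[:, 0] & 0xFF
    out[:, 1] = ((v[:, 1] >> 8) << 4) | (v[:, 0] >> 8)
    out[:, 2] = v[:, 1] & 0xFF
    return out.tobytes()


def read_wfdb(record_path: "str | Path", channel: int = 0) -> RawRecord:
    """Read one channel of a WFDB record (formats 212 and 16).

    ``record_path`` is the path without extension; annotations are loaded
    from a sibling ``.atr`` file when present.
    """
    base = Path(record_path)
    rec_name, n_sig, fs, n_samp, signals = _read_header(base.with_suffix(".hea"))
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range for {n_sig}-signal record")
    sig = signals[channel]
    dat = base.parent / sig["file"]
    raw = dat.read_bytes()
    fmt = sig["fmt"]
    if fmt == 212:
        flat = _unpack_212(raw, n_samp * n_sig if n_samp else (len(raw) // 3) * 2)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if n_samp:
            flat = flat[: n_samp * n_sig]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    adc = flat.reshape(-1, n_sig)[:, channel]
    physical = (adc - sig["baseline"]) / sig["gain"]
    annotations = []
    atr = base.with_suffix(".atr")
    if atr.exists():
        annotations = read_annotations(atr)
    return RawRecord(signal=physical, sampling_rate=fs, annotations=annotations)


def write_wfdb(
    record: RawRecord,
    record_path: "str | Path",
    gain: float = 200.0,
    fmt: int = 212,
    units: str = "mV",
) -> None:
    """Write a single-channel WFDB record (plus ``.atr`` if annotated)."""
    base = Path(record_path)
    adc = np.round(record.signal * gain).astype(np.int32)
    if fmt == 212:
        adc = np.clip(adc, -2048, 2047)
        payload = _pack_212(adc)
    elif fmt == 16:
        adc = np.clip(adc, -32768, 32767)
        payload = adc.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    (base.parent / f"{base.name}.dat").write_bytes(payload)
    fs = record.sampling_rate
    fs_txt = format(fs, "g")
    header = (
        f"{base.name} 1 {fs_txt} {record.signal.size}\n"
        f"{base.name}.dat {fmt} {gain:g}(0)/{units} 12 0 {int(adc[0])} 0 0 lead_I\n"
    )
    (base.parent / f"{base.name}.hea").write_text(header)
    if record.annotations:
        write_annotations(record.annotations, base.with_suffix(".atr"))


def read_annotations(path: "str | Path") -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into (sample_index, symbol) pairs."""
    raw = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code = word >> 10
        inc = word & 0x3FF
        if code == 0 and inc == 0:  # EOF
            break
        if code == 59:  # SKIP: next 4 bytes hold a long time increment
            hi = struct.unpack_from("<H", raw, i)[0]
            lo = struct.unpack_from("<H", raw, i + 2)[0]
            t += (hi << 16) | lo
            i += 4
            continue
        if code == 63:  # AUX: skip the auxiliary string (padded to even)
            i += inc + (inc & 1)
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        t += inc
        out.append((t, _CODE_TO_SYMBOL.get(code, "?")))
    return out


def write_annotations(annotations: list[tuple[int, str]], path: "str | Path") -> None:
    buf = bytearray()
    prev = 0
    for idx, sym in sorted(annotations):
        code = _SYMBOL_TO_CODE.get(sym, 13)  # unknown symbols become Q
        delta = idx - prev
        if delta >= 1024:
            buf += struct.pack("<H", 59 << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = idx
    buf += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(buf))
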