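"""Reading and writing ECG records and segment bundles.

CSV is the primary interchange format: one or two comma-separated columns,
optional header, UTF-8.  Two columns are interpreted as ``time_s, mv`` (the
sampling rate is inferred from the timestamps and checked for uniformity);
one column is amplitude only and requires an explicit sampling rate.

A small reader for PhysioBank-style WFDB records (``.hea`` header plus
``.dat`` signal, formats 16 and 212) is included so public arrhythmia
databases can be fed in directly; only single-segment records are supported
and the first channel is returned.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .records import Segment, EcgRecord

__all__ = ["read_record", "read_csv", "read_wfdb", "write_csv", "save_segments", "load_segments"]

#: Allowed relative deviation of CSV timestamp gaps from the nominal period.
CSV_GAP_TOLERANCE = 0.01


def read_record(path: str | os.PathLike, format: str = "csv", fs: float | None = None) -> EcgRecord:
    """Read an ECG record from ``path``.

    Parameters
    ----------
    path : path-like
        CSV file, or for WFDB the record path with or without ``.hea``.
    format : {"csv", "wfdb"}
    fs : float, optional
        Required for single-column CSV files; ignored otherwise.
    """
    if format == "csv":
        return read_csv(path, fs=fs)
    if format == "wfdb":
        return read_wfdb(path)
    raise FormatError(f"unknown record format {format!r}")


def read_csv(path: str | os.PathLike, fs: float | None = None) -> EcgRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sniff header: first cell must parse as a number otherwise skip row 1
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().split(",")[0].strip()
    try:
        float(first)
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, header=header, comment="#")
    if df.shape[1] == 1:
        if fs is None:
            raise FormatError("single-column CSV requires an explicit sampling rate")
        mv = df.iloc[:, 0].to_numpy(float)
        return EcgRecord(samples=mv, fs=fs, record_id=path.stem)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(float)
        mv = df.iloc[:, 1].to_numpy(float)
        gaps = np.diff(t)
        if gaps.size == 0 or np.any(gaps <= 0):
            raise FormatError("CSV timestamps must be strictly increasing")
        period = np.median(gaps)
        if np.max(np.abs(gaps - period)) > CSV_GAP_TOLERANCE * period:
            raise FormatError("non-uniform CSV timestamps (gap deviation > 1% of period)")
        return EcgRecord(samples=mv, fs=1.0 / period, record_id=path.stem)
    raise FormatError("empty CSV")


def write_csv(record: EcgRecord, path: str | os.PathLike) -> None:
    t = np.arange(len(record)) / record.fs
    pd.DataFrame({"time_s": t, "mv": record.samples}).to_csv(path, index=False)


def _parse_hea(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_s, base_s = gain_part.split("(")
            baseline = int(base_s.rstrip(")"))
        else:
            gain_s, baseline = gain_part, 0
        gain = float(gain_s) if float(gain_s) != 0 else 200.0
        sigs.append({"file": f[0], "fmt": int(fmt), "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samp, sigs


def read_wfdb(path: str | os.PathLike) -> EcgRecord:
    """Read channel 0 of a WFDB record (formats 16 and 212), in physical units."""
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    name, n_sig, fs, n_samp, sigs = _parse_hea(hea)
    dat = hea.parent / sigs[0]["file"]
    if not dat.exists():
        raise FileNotFoundError(dat)
    fmt = sigs[0]["fmt"]
    raw = np.fromfile(dat, dtype=np.uint8)
    if fmt == 16:
        flat = raw[: (raw.size // 2) * 2].view("<i2").astype(int)
        mat = flat[: (flat.size // n_sig) * n_sig].reshape(-1, n_sig)
        adc = mat[:, 0]
    elif fmt == 212:
        # 212 packs two 12-bit samples into 3 bytes, channels interleaved
        usable = (raw.size // 3) * 3
        b = raw[:usable].reshape(-1, 3).astype(int)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0[s0 > 2047] -= 4096
        s1[s1 > 2047] -= 4096
        flat = np.empty(2 * b.shape[0], dtype=int)
        flat[0::2], flat[1::2] = s0, s1
        mat = flat[: (flat.size // n_sig) * n_sig].reshape(-1, n_sig)
        adc = mat[:, 0]
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt}")
    if n_samp:
        adc = adc[:n_samp]
    mv = (adc - sigs[0]["baseline"]) / sigs[0]["gain"]
    return EcgRecord(samples=mv, fs=fs, record_id=name)


def save_segments(segments: list[Segment], path: str | os.PathLike) -> None:
    """Save segments to an .npz bundle (lossless round-trip)."""
    np.savez(
        path,
        samples=np.stack([s.samples for s in segments]),
        start_s=np.array([s.start_s for s in segments]),
        fs=np.array([segments[0].fs]) if segments else np.array([300.0]),
    )


def load_segments(path: str | os.PathLike) -> list[Segment]:
    with np.load(path) as z:
        fs = float(z["fs"][0])
        return [
            Segment(samples=row, fs=fs, start_s=float(t0))
            for row, t0 in zip(z["samples"], z["start_s"])
        ]
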