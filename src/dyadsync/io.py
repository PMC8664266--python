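"""Readers and writers for the on-disk formats.

Two signal formats are supported:

* a columnar TSV (``time_s`` column plus one column per channel, one row
  per sample) with a JSON sidecar carrying ``dyad_id``, ``role``,
  ``condition``, ``sampling_rate`` and ``reference``;
* 16-bit EDF (European Data Format) with 1-s data records, written and
  parsed directly — no external EDF dependency.

Plus behavioral event-log CSVs (``code,onset_s,offset_s``), a long-format
connectivity TSV, and JSON stats reports.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import ConnectivityMap, EventLog, MassUnivariateResult, Recording

__all__ = [
    "write_recording_tsv",
    "read_recording_tsv",
    "write_recording_edf",
    "read_recording_edf",
    "write_event_log",
    "write_connectivity_tsv",
    "write_stats_json",
]


# ---------------------------------------------------------------- TSV

def write_recording_tsv(recording: Recording, path: str | Path) -> Path:
    """Write ``<path>.tsv`` plus ``<path>.json`` sidecar; returns the TSV path."""
    path = Path(path)
    if path.suffix == ".tsv":
        path = path.with_suffix("")
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(recording.channels):
        frame[ch] = recording.signal[i]
    tsv_path = path.with_suffix(".tsv")
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "dyad_id": recording.dyad_id,
        "role": recording.role,
        "condition": recording.condition,
        "sampling_rate": recording.sampling_rate,
        "reference": recording.reference_label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return tsv_path


def read_recording_tsv(path: str | Path) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(path, sep="\t")
    if "time_s" not in frame.columns:
        raise ValueError("TSV must have a time_s column")
    channels = [c for c in frame.columns if c != "time_s"]
    return Recording(
        dyad_id=meta["dyad_id"],
        role=meta["role"],
        condition=meta["condition"],
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
        signal=frame[channels].to_numpy().T,
        reference_label=meta.get("reference", "FCz"),
    )


# ---------------------------------------------------------------- EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_recording_edf(recording: Recording, path: str | Path) -> Path:
    """Write a standard 16-bit EDF file with 1-s data records.

    The sampling rate must be an integer; trailing samples that do not
    fill a whole record are dropped.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = recording.n_channels
    sig = recording.signal[:, : n_records * fs]

    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    # avoid degenerate scaling for flat channels
    flat = phys_max - phys_min < 1e-9
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    # scale with the values as the 8-char header will represent them, so
    # reader reconstruction is limited by 16-bit quantization alone
    phys_min = np.array([float(f"{v:.2f}"[:8]) for v in phys_min - 0.005])
    phys_max = np.array([float(f"{v:.2f}"[:8]) for v in phys_max + 0.005])
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((sig - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")

    path = Path(path)
    header_bytes = 256 + 256 * ns
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"dyad {recording.dyad_id} {recording.role}", 80))
        fh.write(_pad(f"condition {recording.condition}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        for ch in recording.channels:
            fh.write(_pad(ch, 16))
        for _ in range(ns):
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in range(ns):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.2f}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.2f}"[:8], 8))
        for _ in range(ns):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(ns):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(ns):
            fh.write(_pad("BP filtered", 80))
        for _ in range(ns):
            fh.write(_pad(str(fs), 8))
        for _ in range(ns):
            fh.write(_pad("", 32))
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(chunk.tobytes())  # signal-major within record
    return path


def read_recording_edf(
    path: str | Path,
    dyad_id: str = "?",
    role: str = "infant",
    condition: str = "?",
) -> Recording:
    """Parse a 16-bit EDF file written by :func:`write_recording_edf`.

    Metadata not representable in EDF headers (role, condition) can be
    supplied by the caller; the patient field written by our exporter is
    parsed back when present.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError("not an EDF file: truncated header")
    n_records = int(raw[236:244].decode().strip())
    record_dur = float(raw[244:252].decode().strip())
    ns = int(raw[252:256].decode().strip())
    off = 256
    labels = [raw[off + 16 * i : off + 16 * (i + 1)].decode().strip() for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns  # skip transducer + phys dim
    phys_min = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
    off += 8 * ns
    phys_max = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
    off += 8 * ns
    dig_min = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
    off += 8 * ns
    dig_max = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
    off += 8 * ns + 80 * ns
    spr = [int(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    off += 8 * ns + 32 * ns

    patient = raw[8:88].decode().strip()
    if patient.startswith("dyad "):
        parts = patient.split()
        if len(parts) >= 3:
            dyad_id, role = parts[1], parts[2]
    rec_field = raw[88:168].decode().strip()
    if rec_field.startswith("condition "):
        condition = rec_field.split(" ", 1)[1]

    data = np.frombuffer(raw[off:], dtype="<i2")
    per_record = sum(spr)
    if data.size < n_records * per_record:
        raise ValueError("EDF data section shorter than header promises")
    data = data[: n_records * per_record].reshape(n_records, per_record)
    signal = np.empty((ns, n_records * spr[0]))
    bounds = np.cumsum([0] + spr)
    for i in range(ns):
        chunk = data[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        signal[i] = (chunk - dig_min[i]) * gain + phys_min[i]
    fs = spr[0] / record_dur
    return Recording(
        dyad_id=dyad_id,
        role=role,
        condition=condition,
        sampling_rate=fs,
        channels=labels,
        signal=signal,
    )


# ---------------------------------------------------------------- events & reports

def write_event_log(log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "onset_s", "offset_s"])
        for code, onset, offset in log.intervals:
            writer.writerow([code, f"{onset:.3f}", f"{offset:.3f}"])
    return path


def write_connectivity_tsv(maps: Iterable[ConnectivityMap], path: str | Path) -> Path:
    """Long-format export: one row per (dyad, condition, pair)."""
    rows = []
    for m in maps:
        for ai, a in enumerate(m.adult_channels):
            for ii, i in enumerate(m.infant_channels):
                rows.append(
                    {
                        "dyad_id": m.dyad_id,
                        "condition": m.condition,
                        "metric": m.metric,
                        "band": m.band.name,
                        "adult_ch": a,
                        "infant_ch": i,
                        "value": m.values[ai, ii],
                        "n_epochs": m.n_epochs_used,
                    }
                )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_stats_json(result: MassUnivariateResult, path: str | Path) -> Path:
    """JSON stats report; the null max-F sample goes to a TSV sidecar."""
    path = Path(path)
    path.write_text(json.dumps(result.to_dict(), indent=2))
    sidecar = path.with_suffix(".null_max_F.tsv")
    np.savetxt(sidecar, result.null_max_F, fmt="%.8g", header="null_max_F", comments="")
    return path
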