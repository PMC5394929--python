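"""Readers and writers for recordings and cohort tables.

A recording travels either as a CSV pair (``signal.csv`` with
``time,voltage`` columns and ``events.csv`` with ``onset_s``) or as a
single-channel EDF+ file with stimulus onsets stored as annotations.
Both carry a ``meta.json`` sidecar with subject and session fields.
Voltages are microvolts on disk and in memory; EDF quantizes to 16 bit
over the physical range of the trace.

The EDF writer is a minimal EDF+C implementation (one EEG signal plus
an annotation channel); reading goes through :mod:`mne`, so writer and
reader are independent code paths.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CohortTable,
    FormatError,
    Recording,
    Session,
    SubjectMeta,
    ValidationError,
)

_STIM_LABEL = "stim"


# ---------------------------------------------------------------------------
# metadata sidecar

def _meta_to_dict(rec: Recording) -> dict:
    return {
        "subject_id": rec.meta.subject_id,
        "genotype": rec.meta.genotype,
        "sex": rec.meta.sex,
        "dose": rec.session.dose,
        "session_index": rec.session.session_index,
        "fs": rec.fs,
        "n_samples": rec.n_samples,
    }


def _meta_from_dict(d: dict) -> tuple[SubjectMeta, Session]:
    meta = SubjectMeta(
        subject_id=str(d.get("subject_id", "unknown")),
        genotype=str(d.get("genotype", "WT")),
        sex=str(d.get("sex", "M")),
    )
    session = Session(
        dose=d.get("dose", "vehicle"), session_index=int(d.get("session_index", 0))
    )
    return meta, session


def _read_sidecar(path: Path) -> dict:
    side = path / "meta.json" if path.is_dir() else path.with_suffix(".json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


# ---------------------------------------------------------------------------
# CSV pair

def _write_csv_pair(rec: Recording, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs
    # %.17g guarantees bit-exact float round-trips through text
    pd.DataFrame({"time": t, "voltage": rec.samples}).to_csv(
        outdir / "signal.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame({"onset_s": rec.events}).to_csv(
        outdir / "events.csv", index=False, float_format="%.17g"
    )
    (outdir / "meta.json").write_text(json.dumps(_meta_to_dict(rec), indent=1))


def _read_csv_pair(indir: Path) -> Recording:
    sig_path = indir / "signal.csv"
    if not sig_path.exists():
        raise FormatError(f"missing signal.csv under {indir}")
    sig = pd.read_csv(sig_path, float_precision="round_trip")
    for col in ("time", "voltage"):
        if col not in sig.columns:
            raise FormatError(f"signal.csv missing column {col!r}")
    t = sig["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("signal.csv field 'time': need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
        raise FormatError("signal.csv field 'time': sampling must be uniform")
    side = _read_sidecar(indir)
    fs = float(side.get("fs", 1.0 / dt[0]))
    ev_path = indir / "events.csv"
    events = np.empty(0)
    if ev_path.exists():
        ev = pd.read_csv(ev_path, float_precision="round_trip")
        if len(ev):
            if "onset_s" not in ev.columns:
                raise FormatError("events.csv missing column 'onset_s'")
            events = np.sort(ev["onset_s"].to_numpy(dtype=float))
    meta, session = _meta_from_dict(side)
    samples = sig["voltage"].to_numpy(dtype=float)
    return Recording(samples, fs, events, meta, session)


# ---------------------------------------------------------------------------
# EDF+ (writer is hand-rolled; reader delegates to MNE)

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {value!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _edf_num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{p}f}}" for p in range(7, -1, -1)):
        s = fmt.format(value)
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise FormatError(f"cannot encode {value} in {width} EDF bytes")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got fs={fs}")
    fs = int(round(fs))
    n_rec = max(1, math.ceil(rec.n_samples / fs))
    padded = np.zeros(n_rec * fs)
    padded[: rec.n_samples] = rec.samples

    pmin, pmax = float(padded.min()), float(padded.max())
    if pmax <= pmin:
        pmin, pmax = pmin - 1.0, pmax + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin) / scale + dmin).astype("<i2")

    # one TAL block per 1 s record: timestamp TAL + any stimulus events
    tal_blocks = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00"
        for onset in rec.events:
            if r <= onset < r + 1:
                tal += f"+{onset:.6f}\x14{_STIM_LABEL}\x14\x00"
        tal_blocks.append(tal.encode("ascii"))
    annot_bytes = max(len(b) for b in tal_blocks) + 2
    annot_bytes += annot_bytes % 2  # even number of bytes (int16 samples)
    annot_ns = annot_bytes // 2

    n_signals = 2
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(f"X X X {rec.meta.subject_id}", 80),
            _edf_field(
                f"Startdate X X X X dose={rec.session.dose}"
                f" session={rec.session.session_index}",
                80,
            ),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_signals + 1), 8),
            _edf_field("EDF+C", 44),
            _edf_field(n_rec, 8),
            _edf_field("1", 8),
            _edf_field(n_signals, 4),
        ]
    )
    sig_fields = [
        (_edf_field("EEG", 16), _edf_field("EDF Annotations", 16)),
        (_edf_field("", 80), _edf_field("", 80)),
        (_edf_field("uV", 8), _edf_field("", 8)),
        (_edf_num(pmin, 8), _edf_field("-1", 8)),
        (_edf_num(pmax, 8), _edf_field("1", 8)),
        (_edf_field(dmin, 8), _edf_field(dmin, 8)),
        (_edf_field(dmax, 8), _edf_field(dmax, 8)),
        (_edf_field("", 80), _edf_field("", 80)),
        (_edf_field(fs, 8), _edf_field(annot_ns, 8)),
        (_edf_field("", 32), _edf_field("", 32)),
    ]
    header += b"".join(eeg + ann for eeg, ann in sig_fields)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[r * fs : (r + 1) * fs].tobytes())
            fh.write(tal_blocks[r].ljust(annot_bytes, b"\x00"))
    (path.with_suffix(".json")).write_text(json.dumps(_meta_to_dict(rec), indent=1))


def _read_edf(path: Path) -> Recording:
    import mne  # deferred: import is slow and only needed for EDF input

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as err:  # mne raises various types on malformed files
        raise FormatError(f"cannot parse EDF file {path}: {err}") from err
    data = raw.get_data()[0] * 1e6  # MNE scales EEG channels to volts
    fs = float(raw.info["sfreq"])
    events = np.sort(
        np.array(
            [a["onset"] for a in raw.annotations if a["description"] == _STIM_LABEL],
            dtype=float,
        )
    )
    side = _read_sidecar(path)
    meta, session = _meta_from_dict(side)
    n = int(side.get("n_samples", data.size))
    return Recording(data[:n], float(side.get("fs", fs)), events, meta, session)


# ---------------------------------------------------------------------------
# public API

def write_recording(rec: Recording, path, format: str = "csv") -> Path:
    """Write a recording as a CSV pair directory or an EDF+ file."""
    path = Path(path)
    if format == "csv":
        _write_csv_pair(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise FormatError(f"unknown recording format {format!r}")
    return path


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording; ``format`` inferred from the path when omitted.

    Events are returned sorted ascending; events outside the recorded
    duration raise :class:`ValidationError`.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_csv_pair(path)
    if format == "edf":
        return _read_edf(path)
    raise FormatError(f"unknown recording format {format!r}")


def write_cohort_table(table: CohortTable, path) -> Path:
    """Write a cohort table as long CSV; round-trips exactly."""
    if len(table) == 0 or not table.measures:
        raise ValidationError("refusing to write an empty cohort table")
    long = table.to_long().sort_values(["subject_id", "dose", "measure"])
    long.to_csv(path, index=False)
    return Path(path)


def read_cohort_table(path) -> CohortTable:
    long = pd.read_csv(path, dtype={"subject_id": str, "dose": str},
                       float_precision="round_trip")
    if "value" in long.columns:
        vals = pd.to_numeric(long["value"], errors="coerce")
        bad = long.loc[vals.isna() & long["value"].notna(), "value"]
        if len(bad):
            raise FormatError(f"non-numeric entries in column 'value': {bad.iloc[0]!r}")
        long["value"] = vals
    return CohortTable.from_long(long)
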