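"""Readers and writers for recordings, parcellations and result tables.

Two recording dialects are supported:

* ``edf`` — European Data Format, read through :func:`mne.io.read_raw_edf`.
  A minimal EDF+ writer (16-bit, single data record per block) is provided
  so that synthetic fixtures can be emitted in the same format real
  amplifiers produce.
* ``matrix`` — a TSV amplitude matrix (rows = channels, first column =
  label) accompanied by a JSON sidecar carrying ``fs``, ``labels`` and
  ``space``.

Connectivity matrices, parcellations and statistics tables travel as TSV
with mandatory row/column labels; run metadata as JSON.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    ConnectivityMatrix,
    DataError,
    FormatError,
    Parcellation,
    Recording,
    default_parcellation,
)

__all__ = [
    "read_recording",
    "write_recording",
    "load_parcellation",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_results",
]


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def read_recording(path: str | os.PathLike, format: str | None = None) -> Recording:
    """Read a recording from ``path``.

    ``format`` is ``"edf"`` or ``"matrix"``; inferred from the file suffix
    when omitted.  Matrix files require a JSON sidecar ``<path>.json``
    supplying at least ``fs``; labels default to the first TSV column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise FormatError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; the pipeline works in μV
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names), space="sensor")


def _read_matrix(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"matrix recording {path} needs a sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks required key 'fs'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise DataError(f"non-finite amplitudes in {path}")
    labels = meta.get("labels", [str(x) for x in df.index])
    return Recording(data=data, fs=float(meta["fs"]), labels=labels,
                     space=meta.get("space", "sensor"))


def write_recording(rec: Recording, path: str | os.PathLike,
                    format: str | None = None) -> Path:
    """Write a recording as EDF or TSV matrix + JSON sidecar."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "edf":
        _write_edf(rec, path)
        return path
    if format == "matrix":
        df = pd.DataFrame(rec.data, index=list(rec.labels))
        df.index.name = "label"
        df.to_csv(path, sep="\t", float_format="%.9g")
        meta = {"fs": rec.fs, "labels": list(rec.labels), "space": rec.space}
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        return path
    raise FormatError(f"unknown recording format {format!r}")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF+ writer: 16-bit samples, 1-second data records.

    Physical scaling spans the per-channel amplitude range, so the
    round-trip error is bounded by (range / 65534), well below thermal
    noise for EEG-scale signals.
    """
    n_ch = rec.n_channels
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    spr = fs  # samples per record (1-s records)
    n_rec = math.ceil(rec.n_samples / spr)
    total = n_rec * spr
    data = np.zeros((n_ch, total))
    data[:, : rec.n_samples] = rec.data

    def fld(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    hdr = b""
    hdr += fld("0", 8)
    hdr += fld("X X X X", 80)          # local patient id (anonymous)
    hdr += fld("Startdate X X X X", 80)
    hdr += fld("01.01.00", 8)
    hdr += fld("00.00.00", 8)
    hdr += fld(str(256 * (1 + n_ch)), 8)
    hdr += fld("EDF+C", 44)
    hdr += fld(str(n_rec), 8)
    hdr += fld("1", 8)                 # record duration, seconds
    hdr += fld(str(n_ch), 4)
    for lab in rec.labels:
        hdr += fld(lab, 16)
    hdr += b"".join(fld("EEG", 80) for _ in range(n_ch))
    hdr += b"".join(fld("uV", 8) for _ in range(n_ch))
    hdr += b"".join(fld(f"{v:.6g}", 8) for v in pmin)
    hdr += b"".join(fld(f"{v:.6g}", 8) for v in pmax)
    hdr += b"".join(fld(str(dmin), 8) for _ in range(n_ch))
    hdr += b"".join(fld(str(dmax), 8) for _ in range(n_ch))
    hdr += b"".join(fld("", 80) for _ in range(n_ch))
    hdr += b"".join(fld(str(spr), 8) for _ in range(n_ch))
    hdr += b"".join(fld("", 32) for _ in range(n_ch))

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def load_parcellation(source: str | os.PathLike = "builtin",
                      strict_networks: tuple[str, ...] | None = None) -> Parcellation:
    """Load a parcellation from the packaged default or a TSV file.

    The TSV must have columns ``region`` and ``network``.  With
    ``strict_networks`` given, any network label outside that set is an
    error.
    """
    if source == "builtin":
        return default_parcellation()
    path = Path(source)
    df = pd.read_csv(path, sep="\t")
    if not {"region", "network"} <= set(df.columns):
        raise FormatError(f"{path} must have columns 'region' and 'network'")
    regions = [str(r) for r in df["region"]]
    if len(set(regions)) != len(regions):
        raise DataError(f"duplicate region in {path}")
    network_of = dict(zip(regions, (str(n) for n in df["network"])))
    if strict_networks is not None:
        bad = sorted(set(network_of.values()) - set(strict_networks))
        if bad:
            raise DataError(f"unknown network labels {bad}; allowed {strict_networks}")
    return Parcellation(regions=regions, network_of=network_of)


# ---------------------------------------------------------------------------
# Matrices and result bundles
# ---------------------------------------------------------------------------

def write_matrix_tsv(mat: np.ndarray, labels: list[str],
                     path: str | os.PathLike) -> Path:
    """Write a square labelled matrix as TSV (labels on both axes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(mat, dtype=float), index=labels, columns=labels)
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_matrix_tsv(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column labels disagree")
    return df.to_numpy(dtype=float), labels


def write_results(bundle: Mapping[str, object], out_dir: str | os.PathLike) -> list[Path]:
    """Write a result bundle to ``out_dir``.

    Bundle values are dispatched on type: :class:`ConnectivityMatrix` →
    labelled TSV, :class:`pandas.DataFrame` → TSV (header always written,
    even when empty), dict → JSON.  Returns the written paths, sorted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in bundle.items():
        if isinstance(obj, ConnectivityMatrix):
            labels = list(obj.labels) if obj.labels is not None else [
                f"R{i+1:02d}" for i in range(obj.n_regions)
            ]
            written.append(write_matrix_tsv(obj.values, labels, out / f"{name}.tsv"))
        elif isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False, float_format="%.12g")
            written.append(p)
        elif isinstance(obj, Mapping):
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))
            written.append(p)
        else:
            raise TypeError(f"cannot serialise bundle entry {name!r} of type {type(obj)}")
    return sorted(written)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
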