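"""Readers and writers for simulated trEPR datasets.

Two on-disk forms are supported:

* **CSV** (schema ``treprsim-csv v1``): one header row carrying the
  time axis (μs), then one row per field point whose first column is
  the field value (mT) followed by the signal row.  Values are written
  with 12 significant digits; metadata is stored in ``#``-prefixed
  JSON header lines.
* **HDF5** (schema ``treprsim-h5 v1``): datasets ``field_mT``,
  ``time_us`` and ``signal`` at the root, metadata as a JSON string
  attribute.  Round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .spectrum import TrEPRDataset

__all__ = ["write_dataset", "read_dataset"]

_CSV_SCHEMA = "treprsim-csv v1"
_H5_SCHEMA = "treprsim-h5 v1"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise ValueError(f"unknown dataset format '{fmt}'")
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_dataset(ds: TrEPRDataset, path: str | Path, fmt: str | None = None) -> Path:
    """Write a dataset to CSV or HDF5 (format inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["schema"] = _H5_SCHEMA
            f.attrs["metadata"] = json.dumps(ds.metadata, sort_keys=True)
            f.create_dataset("field_mT", data=ds.field_axis)
            f.create_dataset("time_us", data=ds.time_axis)
            f.create_dataset("signal", data=ds.signal)
        return path
    lines = [f"# {_CSV_SCHEMA}", f"# metadata: {json.dumps(ds.metadata, sort_keys=True)}"]
    header = ["field_mT\\time_us"] + [f"{t:.12g}" for t in ds.time_axis]
    lines.append(",".join(header))
    for b, row in zip(ds.field_axis, ds.signal):
        lines.append(",".join([f"{b:.12g}"] + [f"{v:.12g}" for v in row]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_dataset(path: str | Path, fmt: str | None = None) -> TrEPRDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != _H5_SCHEMA:
                raise ValueError(f"{path} is not a {_H5_SCHEMA} file")
            meta = json.loads(f.attrs.get("metadata", "{}"))
            return TrEPRDataset(
                np.asarray(f["field_mT"]),
                np.asarray(f["time_us"]),
                np.asarray(f["signal"]),
                meta,
            )
    text = path.read_text().strip().splitlines()
    meta: dict = {}
    body = []
    for line in text:
        if line.startswith("#"):
            stripped = line.lstrip("# ")
            if stripped.startswith("metadata:"):
                meta = json.loads(stripped[len("metadata:"):])
        else:
            body.append(line)
    if not body:
        raise ValueError(f"{path}: empty CSV dataset")
    times = np.array([float(x) for x in body[0].split(",")[1:]])
    fields = []
    rows = []
    for line in body[1:]:
        cells = line.split(",")
        fields.append(float(cells[0]))
        rows.append([float(x) for x in cells[1:]])
    return TrEPRDataset(np.array(fields), times, np.array(rows), meta)
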