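"""File formats and run manifests.

Canonical formats are plain text for portability:

* FID — one complex sample per line, two whitespace-separated columns
  (real, imaginary); ``#`` starts a comment; an optional ``# n <int>``
  header declares the expected length.
* Schedule — "nuslist" style: one zero-based grid index per line, plus a
  mandatory ``# n <int>`` header carrying the full grid size.
* Peak model — YAML/JSON mapping with a ``peaks`` list of
  ``{frequency, amplitude, phase, decay}`` entries.

An HDF5 container mirror (datasets ``fid``/``schedule``, attributes ``n``,
``sw``) is provided for toolchains that prefer binary exchange.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .sampling import Schedule
from .signal_model import Fid, Peak, PeakList

__all__ = [
    "DataFormatError", "read_fid", "write_fid", "read_schedule",
    "write_schedule", "read_peaklist", "write_peaklist", "RunManifest",
]


class DataFormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _parse_header_n(line: str) -> int | None:
    parts = line[1:].split()
    if len(parts) == 2 and parts[0] == "n":
        try:
            return int(parts[1])
        except ValueError:
            return None
    return None


def read_fid(path: str | Path, format: str = "text") -> Fid:
    """Read a complex time-domain vector (see module docstring for formats)."""
    path = Path(path)
    if format == "container":
        import h5py

        with h5py.File(path, "r") as h5:
            return Fid(np.asarray(h5["fid"]), label=path.stem)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    declared_n = None
    samples = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            if declared_n is None:
                declared_n = _parse_header_n(line)
            continue
        if not line:
            continue
        cols = line.split()
        if len(cols) != 2:
            raise DataFormatError(
                f"{path}:{ln}: expected two columns (real imag), got {len(cols)}")
        try:
            samples.append(complex(float(cols[0]), float(cols[1])))
        except ValueError as exc:
            raise DataFormatError(f"{path}:{ln}: {exc}") from exc
    if not samples:
        raise DataFormatError(f"{path}: no samples found")
    if declared_n is not None and declared_n != len(samples):
        raise DataFormatError(
            f"{path}: header declares n={declared_n} but file has "
            f"{len(samples)} samples")
    return Fid(np.array(samples), label=path.stem)


def write_fid(fid: Fid, path: str | Path, format: str = "text",
              sw: float | None = None) -> None:
    """Write a FID; text round-trips bit-exactly via ``repr`` floats."""
    path = Path(path)
    if format == "container":
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("fid", data=fid.samples)
            h5.attrs["n"] = fid.n
            if sw is not None:
                h5.attrs["sw"] = sw
        return
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    lines = [f"# n {fid.n}"]
    lines += [f"{float(s.real)!r} {float(s.imag)!r}" for s in fid.samples]
    path.write_text("\n".join(lines) + "\n")


def read_schedule(path: str | Path) -> Schedule:
    """Read a nuslist-style schedule; input may be unsorted but not duplicated."""
    path = Path(path)
    n = None
    indices = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            if n is None:
                n = _parse_header_n(line)
            continue
        if not line:
            continue
        try:
            idx = int(line)
        except ValueError as exc:
            raise DataFormatError(f"{path}:{ln}: {exc}") from exc
        if idx < 0:
            raise DataFormatError(f"{path}:{ln}: negative index {idx}")
        indices.append(idx)
    if n is None:
        raise DataFormatError(f"{path}: missing '# n <int>' header")
    if not indices:
        raise DataFormatError(f"{path}: empty schedule")
    arr = np.array(sorted(indices))
    if np.any(np.diff(arr) == 0):
        raise DataFormatError(f"{path}: duplicate indices")
    if arr[-1] >= n:
        raise DataFormatError(f"{path}: index {arr[-1]} out of range for n={n}")
    return Schedule(arr, n)


def write_schedule(sched: Schedule, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# n {sched.n}"] + [str(i) for i in sched.indices]
    path.write_text("\n".join(lines) + "\n")


def read_peaklist(path: str | Path) -> PeakList:
    """Read a peak model from a YAML (or JSON — a YAML subset) mapping."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "peaks" not in doc:
        raise DataFormatError(f"{path}: expected a mapping with a 'peaks' list")
    peaks = []
    for i, entry in enumerate(doc["peaks"]):
        try:
            peaks.append(Peak(
                frequency=float(entry["frequency"]),
                amplitude=float(entry["amplitude"]),
                phase=float(entry.get("phase", 0.0)),
                decay=float(entry.get("decay", 0.0)),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise DataFormatError(f"{path}: peak {i}: {exc}") from exc
    return PeakList(peaks)


def write_peaklist(model: PeakList, path: str | Path) -> None:
    doc = {"peaks": [
        {"frequency": p.frequency, "amplitude": p.amplitude,
         "phase": p.phase, "decay": p.decay} for p in model]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclasses.dataclass
class RunManifest:
    """Everything needed to replay a CLI run exactly."""

    method: str
    config: dict
    seeds: dict
    inputs: dict  # path -> sha256 digest
    version: str
    elapsed_s: float = 0.0
    created: str = dataclasses.field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")

    @staticmethod
    def digest(path: str | Path) -> str:
        import hashlib

        return hashlib.sha256(Path(path).read_bytes()).hexdigest()
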