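"""Reading and writing EEG recordings (CSV dialect and EDF).

Two formats are supported:

* a human-diffable CSV dialect: ``# key=value`` comment-header lines
  (``fs``, ``phase``, ``animal``, ``treatment``, ``t0``) followed by one
  voltage value (microvolts) per line, with annotations in a sidecar
  ``<name>.annot.tsv`` (columns start, end, label, text);
* EDF (single channel, 16-bit).  Reading goes through :mod:`mne`; writing
  uses a minimal built-in EDF writer (no pre-installed package exports
  EDF).  Package metadata travels in the two 80-character EDF header id
  fields as ``key=value`` pairs.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

import numpy as np

from .recording import Annotation, EEGRecording

logger = logging.getLogger(__name__)

_CSV_KEYS = ("fs", "phase", "animal", "treatment", "t0")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


def _annot_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annot.tsv") if path.suffix == "" else path.parent / (
        path.stem + ".annot.tsv"
    )


# ---------------------------------------------------------------------------
# annotation sidecar


def write_annotations(annotations: list[Annotation], path: Path) -> None:
    lines = ["start\tend\tlabel\ttext"]
    for a in annotations:
        if not a.end > a.start:
            raise ValueError(f"zero/negative-length annotation [{a.start}, {a.end}]")
        lines.append(f"{a.start:.6f}\t{a.end:.6f}\t{a.label}\t{a.text}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: Path) -> list[Annotation]:
    out: list[Annotation] = []
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if i == 0 and line.startswith("start"):
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {i + 1}: expected >= 3 tab-separated fields")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 1}: non-numeric annotation bound") from exc
        text = parts[3] if len(parts) > 3 else ""
        out.append(Annotation(start, end, parts[2], text))
    return out


# ---------------------------------------------------------------------------
# CSV dialect


def write_csv(rec: EEGRecording, path: Path) -> None:
    path = Path(path)
    header = [
        f"# fs={rec.fs!r}",
        f"# phase={rec.phase}",
        f"# animal={rec.animal_id if rec.animal_id is not None else ''}",
        f"# treatment={rec.treatment}",
        f"# t0={rec.t0!r}",
    ]
    body = "\n".join(np.format_float_scientific(v, precision=9) for v in rec.samples)
    path.write_text("\n".join(header) + "\n" + body + "\n")
    if rec.annotations:
        write_annotations(rec.annotations, _annot_path(path))


def read_csv(path: Path, **overrides) -> EEGRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.*)$", line)
                if m:
                    meta[m.group(1)] = m.group(2).strip()
                continue
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric voltage value {line!r}"
                ) from exc
    meta.update({k: str(v) for k, v in overrides.items() if v is not None})
    if "fs" not in meta:
        raise ParseError(f"{path}: missing sampling rate ('# fs=' header line)")
    try:
        fs = float(meta["fs"])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric sampling rate {meta['fs']!r}") from exc
    annotations: list[Annotation] = []
    apath = _annot_path(path)
    if apath.exists():
        annotations = read_annotations(apath)
    animal = meta.get("animal") or None
    return EEGRecording(
        samples=np.asarray(samples, dtype=np.float64),
        fs=fs,
        phase=meta.get("phase", "pre-stun"),
        t0=float(meta.get("t0", 0.0)),
        animal_id=animal,
        treatment=meta.get("treatment", "unknown"),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# EDF

_EDF_UNITS = {"uV": 1.0, "mV": 1000.0}  # conversion to microvolts


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: Path) -> None:
    """Write a single-channel EDF file (16-bit, 1-s data records).

    The sampling rate must be a positive integer so that 1-s records hold
    an exact number of samples; the trailing partial record is zero-padded
    and the true sample count is recorded in the header id field so the
    reader can truncate.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs < 1:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))
    n = rec.n_samples
    n_records = math.ceil(n / spr)
    x = np.zeros(n_records * spr, dtype=np.float64)
    x[:n] = rec.samples
    pmax = float(np.max(np.abs(x)))
    if pmax == 0:
        pmax = 1.0
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((x - pmin) * scale + dmin).astype("<i2")

    patient = f"animal={rec.animal_id if rec.animal_id is not None else 'NA'}"
    recording_id = f"phase={rec.phase} treatment={rec.treatment} t0={rec.t0:.6g} n={n}"
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient, 80),
            _ascii(recording_id, 80),
            _ascii("01.01.17", 8),
            _ascii("00.00.00", 8),
            _ascii(256 + 256, 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(1, 4),
            # one signal header
            _ascii("EEG", 16),
            _ascii("", 80),
            _ascii("uV", 8),
            _ascii(f"{pmin:.6g}"[:8], 8),
            _ascii(f"{pmax:.6g}"[:8], 8),
            _ascii(dmin, 8),
            _ascii(dmax, 8),
            _ascii("", 80),
            _ascii(spr, 8),
            _ascii("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    if rec.annotations:
        write_annotations(rec.annotations, _annot_path(path))


def _parse_kv(text: str) -> dict[str, str]:
    return dict(m.groups() for m in re.finditer(r"(\w+)=(\S*)", text))


def _read_edf_header_meta(path: Path) -> tuple[dict[str, str], list[str]]:
    """Parse metadata key=value pairs and physical dimensions from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ParseError(f"{path}: truncated EDF header")
        meta = _parse_kv(head[8:88].decode("ascii", "replace"))
        meta.update(_parse_kv(head[88:168].decode("ascii", "replace")))
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ParseError(f"{path}: malformed EDF signal count field") from exc
        sig = fh.read(256 * ns)
    dims = [
        sig[ns * 96 + i * 8 : ns * 96 + (i + 1) * 8].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    return meta, dims


def read_edf(path: Path, **overrides) -> EEGRecording:
    import mne

    path = Path(path)
    meta, dims = _read_edf_header_meta(path)
    dim = dims[0]
    if dim not in _EDF_UNITS:
        raise ParseError(
            f"{path}: physical dimension {dim!r} not supported (expected uV or mV)"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) > 1:
        logger.warning("%s: %d channels; loading %r, skipping %r",
                       path, len(raw.ch_names), raw.ch_names[0], raw.ch_names[1:])
    fs = float(raw.info["sfreq"])
    # mne converts recognised physical dimensions (uV, mV, ...) to volts itself
    data = raw.get_data(picks=[0])[0] * 1e6
    meta = {**meta, **{k: str(v) for k, v in overrides.items() if v is not None}}
    n = int(meta.get("n", data.size))
    data = data[:n]
    annotations: list[Annotation] = []
    apath = _annot_path(path)
    if apath.exists():
        annotations = read_annotations(apath)
    animal = meta.get("animal")
    if animal in ("NA", "", None):
        animal = None
    return EEGRecording(
        samples=data,
        fs=fs,
        phase=meta.get("phase", "pre-stun"),
        t0=float(meta.get("t0", 0.0)),
        animal_id=animal,
        treatment=meta.get("treatment", "unknown"),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# dispatch


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format from {path}; pass format='csv' or 'edf'")


def read_recording(path, format: str | None = None, **overrides) -> EEGRecording:
    """Read an :class:`EEGRecording` from *path* (``csv`` or ``edf``).

    Keyword overrides (``phase``, ``animal``, ``treatment``, ``t0``, ``fs``)
    take precedence over metadata stored in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return read_csv(path, **overrides)
    if fmt == "edf":
        return read_edf(path, **overrides)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: EEGRecording, path, format: str | None = None) -> Path:
    """Write *rec* to *path*; returns the path written."""
    path = Path(path)
    fmt = _infer_format(path, format)
    for a in rec.annotations:
        if not a.end > a.start:
            raise ValueError(f"zero-length annotation [{a.start}, {a.end}] rejected at write")
    if fmt == "csv":
        write_csv(rec, path)
    elif fmt == "edf":
        write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
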