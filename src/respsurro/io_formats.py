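"""Read/write the two surrogate trace dialects and convert between them.

Two plain-text dialects are defined here (byte-exactly; see docs/formats.md):

* ``rpm_vxp_like`` — displacement-style file. ``#``-prefixed header lines
  ``version=1``, ``samples_per_second=<float>``, ``scale_factor=<float>``,
  then one comma-separated line per sample::

      amplitude,phase_placeholder,timestamp_ms,valid_flag,ttl_in,mark,ttl_out

  ``timestamp_ms`` is an integer (hence <= 1 ms round-trip quantization);
  ``mark`` is empty, ``Z`` (EOE) or ``P`` (EOI); ``ttl_in``/``ttl_out`` are
  0/1 edge indicators on the sample where the beam transition occurs.

* ``anzai_csv_like`` — pressure-style CSV with header ``time_s,pressure,ttl``;
  ``ttl`` is the per-sample 0/1 beam level; timestamps are float seconds.

These are documented local dialects faithful to the described *content*
(amplitude, timestamps, TTL in/out events, extrema marks) of the vendor
files, not claims about proprietary layouts. Beam intervals are half-open
``[on, off)`` everywhere. Both files of a pair share the origin t=0; no
implicit realignment is ever performed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .errors import ParseError, StateError, TraceValidationError
from .trace import MARK_EOE, MARK_EOI, RespTrace

logger = logging.getLogger(__name__)

_MARK_TO_CHAR = {MARK_EOI: "P", MARK_EOE: "Z"}
_CHAR_TO_MARK = {"P": MARK_EOI, "Z": MARK_EOE, "": 0}


@dataclasses.dataclass(frozen=True)
class FileDialect:
    """Format metadata for one of the two supported trace dialects."""

    name: str  # "rpm_vxp_like" | "anzai_csv_like"
    delimiter: str
    field_order: tuple[str, ...]
    header_keys: tuple[str, ...]


RPM_DIALECT = FileDialect(
    name="rpm_vxp_like",
    delimiter=",",
    field_order=("amplitude", "phase_placeholder", "timestamp_ms",
                 "valid_flag", "ttl_in", "mark", "ttl_out"),
    header_keys=("version", "samples_per_second", "scale_factor"),
)

ANZAI_DIALECT = FileDialect(
    name="anzai_csv_like",
    delimiter=",",
    field_order=("time_s", "pressure", "ttl"),
    header_keys=(),
)


def dialect_for(name: str) -> FileDialect:
    try:
        return {"rpm_vxp_like": RPM_DIALECT, "anzai_csv_like": ANZAI_DIALECT}[name]
    except KeyError:
        raise ParseError(f"unknown dialect {name!r}") from None


# --------------------------------------------------------------------- write
def write_trace(trace: RespTrace, path, dialect: FileDialect) -> None:
    """Write a trace in the given dialect; round-trip stable (see read_trace).

    A dialect/source_kind mismatch is allowed: conversion between dialects is
    explicit, never implicit.
    """
    path = Path(path)
    if dialect.name == "rpm_vxp_like":
        _write_rpm(trace, path)
    elif dialect.name == "anzai_csv_like":
        _write_anzai(trace, path)
    else:  # pragma: no cover - dialect_for guards this
        raise ParseError(f"unknown dialect {dialect.name!r}")


def _beam_edges(trace: RespTrace) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample ttl_in / ttl_out edge indicators from the beam_on level."""
    n = trace.n_samples
    b = np.zeros(n, dtype=np.int8) if trace.beam_on is None else trace.beam_on.astype(np.int8)
    d = np.diff(np.concatenate(([0], b)))
    ttl_in = (d == 1).astype(np.int8)
    ttl_out = (d == -1).astype(np.int8)
    return ttl_in, ttl_out


def _write_rpm(trace: RespTrace, path: Path) -> None:
    ttl_in, ttl_out = _beam_edges(trace)
    marks = trace.marks if trace.marks is not None else np.zeros(trace.n_samples, np.int8)
    fs = trace.sampling_rate if trace.sampling_rate is not None else 0.0
    lines = [
        "#version=1",
        f"#samples_per_second={float(fs)!r}",
        "#scale_factor=1.0",
    ]
    for i in range(trace.n_samples):
        ms = int(round(trace.timestamps[i] * 1000.0))
        mark = _MARK_TO_CHAR.get(int(marks[i]), "")
        lines.append(
            f"{float(trace.amplitudes[i])!r},0,{ms},1,{ttl_in[i]},{mark},{ttl_out[i]}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_anzai(trace: RespTrace, path: Path) -> None:
    b = np.zeros(trace.n_samples, np.int8) if trace.beam_on is None else trace.beam_on.astype(np.int8)
    lines = ["time_s,pressure,ttl"]
    for i in range(trace.n_samples):
        lines.append(f"{float(trace.timestamps[i])!r},{float(trace.amplitudes[i])!r},{b[i]}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- read
def read_trace(path, dialect: FileDialect) -> RespTrace:
    """Parse a trace file; raises ParseError with a line number on bad rows."""
    path = Path(path)
    if dialect.name == "rpm_vxp_like":
        return _read_rpm(path)
    if dialect.name == "anzai_csv_like":
        return _read_anzai(path)
    raise ParseError(f"unknown dialect {dialect.name!r}")


def _beam_from_edges(ttl_in: np.ndarray, ttl_out: np.ndarray, path: Path) -> np.ndarray:
    n = ttl_in.size
    beam = np.zeros(n, dtype=bool)
    state = False
    open_since = None
    for i in range(n):
        if ttl_out[i]:
            state = False
            open_since = None
        if ttl_in[i]:
            state = True
            open_since = i
        beam[i] = state
    if open_since is not None:
        logger.warning(
            "%s: ttl_in at sample %d has no matching ttl_out before EOF; "
            "beam_on held true through the final sample", path, open_since
        )
    return beam


def _read_rpm(path: Path) -> RespTrace:
    headers: dict[str, str] = {}
    ms_list: list[int] = []
    amps: list[float] = []
    marks: list[int] = []
    tin: list[int] = []
    tout: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ParseError("malformed header line", lineno)
                key, _, val = line[1:].partition("=")
                headers[key] = val
                continue
            parts = line.split(",")
            if len(parts) != 7:
                raise ParseError(f"expected 7 fields, got {len(parts)}", lineno)
            try:
                amps.append(float(parts[0]))
                ms_list.append(int(parts[2]))
                tin.append(int(parts[4]))
                tout.append(int(parts[6]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            if parts[5] not in _CHAR_TO_MARK:
                raise ParseError(f"unknown mark {parts[5]!r}", lineno)
            marks.append(_CHAR_TO_MARK[parts[5]])
    if not ms_list:
        raise ParseError(f"{path}: empty data section")
    t = np.asarray(ms_list, dtype=float) / 1000.0
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise TraceValidationError(f"{path}: non-monotone timestamps")
    beam = _beam_from_edges(np.asarray(tin), np.asarray(tout), path)
    fs = float(headers.get("samples_per_second", 0.0)) or None
    return RespTrace(
        timestamps=t,
        amplitudes=np.asarray(amps),
        beam_on=beam,
        marks=np.asarray(marks, dtype=np.int8),
        source_kind="displacement",
        sampling_rate=fs,
    )


def _read_anzai(path: Path) -> RespTrace:
    times: list[float] = []
    amps: list[float] = []
    ttl: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if lineno == 1:
                if line != "time_s,pressure,ttl":
                    raise ParseError(f"bad header {line!r}", lineno)
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(f"expected 3 fields, got {len(parts)}", lineno)
            try:
                times.append(float(parts[0]))
                amps.append(float(parts[1]))
                ttl.append(int(parts[2]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
    if not times:
        raise ParseError(f"{path}: empty data section")
    t = np.asarray(times)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise TraceValidationError(f"{path}: non-monotone timestamps")
    return RespTrace(
        timestamps=t,
        amplitudes=np.asarray(amps),
        beam_on=np.asarray(ttl, dtype=bool),
        source_kind="pressure",
    )


# ---------------------------------------------------------------- conversion
def convert_pressure_to_displacement_format(
    pressure: RespTrace, reference: RespTrace
) -> RespTrace:
    """Re-badge a pressure trace as displacement-file-compatible, transferring
    the reference's beam markers by timestamp alignment.

    The output keeps the pressure trace's timestamps and amplitudes exactly;
    a pressure sample is beam-on iff its timestamp lies inside a reference
    on-segment (closed on the left, open on the right). Both traces are
    assumed to share the t=0 trigger.
    """
    if reference.beam_on is None:
        raise StateError("reference trace carries no beam markers")
    lo = max(pressure.timestamps[0], reference.timestamps[0])
    hi = min(pressure.timestamps[-1], reference.timestamps[-1])
    if hi <= lo:
        raise TraceValidationError("pressure and reference time ranges do not overlap")
    out = pressure.with_beam_segments(reference.beam_segments())
    out.source_kind = "displacement"
    return out
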