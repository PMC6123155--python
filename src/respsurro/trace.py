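"""Core timestamped respiratory trace type shared by every pipeline stage.

A :class:`RespTrace` is a uniformly-or-irregularly sampled 1-D surrogate
signal with optional beam-on markers and optional EOI/EOE sample marks.
Beam-on intervals follow the half-open convention ``[on, off)`` everywhere.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import TraceValidationError

MARK_NONE = 0
MARK_EOI = 1
MARK_EOE = 2

SOURCE_KINDS = ("displacement", "pressure")


@dataclasses.dataclass
class RespTrace:
    """Timestamped 1-D respiratory surrogate signal.

    Parameters
    ----------
    timestamps : ndarray of float, seconds, strictly increasing, shared origin t=0
    amplitudes : ndarray of float, arbitrary units
    beam_on : ndarray of bool, per-sample beam state, or None if unknown
    marks : ndarray of int8 (MARK_NONE / MARK_EOI / MARK_EOE), or None
    source_kind : "displacement" or "pressure"
    sampling_rate : nominal rate in Hz (informational; timestamps are authoritative)
    """

    timestamps: np.ndarray
    amplitudes: np.ndarray
    beam_on: Optional[np.ndarray] = None
    marks: Optional[np.ndarray] = None
    source_kind: str = "displacement"
    sampling_rate: Optional[float] = None
    # Continuous generator model (synthetic traces only); excluded from equality.
    model: Optional[Callable[[np.ndarray], np.ndarray]] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.timestamps.ndim != 1 or self.amplitudes.ndim != 1:
            raise TraceValidationError("timestamps and amplitudes must be 1-D")
        n = self.timestamps.size
        if self.amplitudes.size != n:
            raise TraceValidationError(
                f"length mismatch: {n} timestamps vs {self.amplitudes.size} amplitudes"
            )
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise TraceValidationError("timestamps must be strictly increasing")
        if self.beam_on is not None:
            self.beam_on = np.asarray(self.beam_on, dtype=bool)
            if self.beam_on.size != n:
                raise TraceValidationError("beam_on length mismatch")
        if self.marks is not None:
            self.marks = np.asarray(self.marks, dtype=np.int8)
            if self.marks.size != n:
                raise TraceValidationError("marks length mismatch")
        if self.source_kind not in SOURCE_KINDS:
            raise TraceValidationError(
                f"source_kind must be one of {SOURCE_KINDS}, got {self.source_kind!r}"
            )
        if self.sampling_rate is None and n >= 2:
            self.sampling_rate = float(1.0 / np.median(np.diff(self.timestamps)))

    # ------------------------------------------------------------------ basic
    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def median_dt(self) -> float:
        if self.n_samples < 2:
            raise TraceValidationError("need >= 2 samples for a sampling interval")
        return float(np.median(np.diff(self.timestamps)))

    def copy(self) -> "RespTrace":
        return RespTrace(
            timestamps=self.timestamps.copy(),
            amplitudes=self.amplitudes.copy(),
            beam_on=None if self.beam_on is None else self.beam_on.copy(),
            marks=None if self.marks is None else self.marks.copy(),
            source_kind=self.source_kind,
            sampling_rate=self.sampling_rate,
            model=self.model,
        )

    # ------------------------------------------------------------------ marks
    @property
    def eoi_times(self) -> np.ndarray:
        if self.marks is None:
            return np.empty(0)
        return self.timestamps[self.marks == MARK_EOI]

    @property
    def eoe_times(self) -> np.ndarray:
        if self.marks is None:
            return np.empty(0)
        return self.timestamps[self.marks == MARK_EOE]

    def with_marks_at(self, eoi_times: Sequence[float], eoe_times: Sequence[float]) -> "RespTrace":
        """Return a copy whose marks label the samples nearest the given times.

        Times outside the sampled span are dropped.
        """
        out = self.copy()
        marks = np.zeros(self.n_samples, dtype=np.int8)
        for times, code in ((eoi_times, MARK_EOI), (eoe_times, MARK_EOE)):
            for t in np.asarray(times, dtype=float):
                if t < self.timestamps[0] or t > self.timestamps[-1]:
                    continue
                idx = int(np.argmin(np.abs(self.timestamps - t)))
                marks[idx] = code
        out.marks = marks
        return out

    # ------------------------------------------------------------------- beam
    def beam_segments(self) -> list[tuple[float, float]]:
        """Half-open ``[on, off)`` beam intervals reconstructed from beam_on.

        A run of on-samples starts at its first sample's timestamp and ends at
        the timestamp of the first off-sample after the run; a run extending to
        the end of the trace ends one median sampling interval past the last
        sample.
        """
        if self.beam_on is None or not self.beam_on.any():
            return []
        b = self.beam_on.astype(np.int8)
        d = np.diff(np.concatenate(([0], b, [0])))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        segs = []
        for s, e in zip(starts, stops):
            on = float(self.timestamps[s])
            if e < self.n_samples:
                off = float(self.timestamps[e])
            else:
                off = float(self.timestamps[-1] + self.median_dt)
            segs.append((on, off))
        return segs

    def with_beam_segments(self, segments: Sequence[tuple[float, float]]) -> "RespTrace":
        """Return a copy with beam_on set by half-open interval membership."""
        out = self.copy()
        b = np.zeros(self.n_samples, dtype=bool)
        t = self.timestamps
        for on, off in segments:
            if off <= on:
                raise TraceValidationError(f"beam segment ({on}, {off}) has off <= on")
            b |= (t >= on) & (t < off)
        out.beam_on = b
        return out

    # ------------------------------------------------------------------ misc
    def values_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the sampled amplitudes (edge-clamped)."""
        return np.interp(np.asarray(times, dtype=float), self.timestamps, self.amplitudes)


def uniform_timestamps(duration: float, sampling_rate: float) -> np.ndarray:
    """Uniform grid 0, 1/fs, ... covering [0, duration)."""
    n = int(round(duration * sampling_rate))
    return np.arange(n) / float(sampling_rate)


def traces_equal(a: RespTrace, b: RespTrace, *, atol: float = 0.0) -> bool:
    """Sample-for-sample equality (timestamps, amplitudes, beam, marks)."""
    if a.n_samples != b.n_samples:
        return False
    if not np.allclose(a.timestamps, b.timestamps, atol=atol, rtol=0.0):
        return False
    if not np.allclose(a.amplitudes, b.amplitudes, atol=atol, rtol=0.0):
        return False
    ab = np.zeros(a.n_samples, bool) if a.beam_on is None else a.beam_on
    bb = np.zeros(b.n_samples, bool) if b.beam_on is None else b.beam_on
    if not np.array_equal(ab, bb):
        return False
    am = np.zeros(a.n_samples, np.int8) if a.marks is None else a.marks
    bm = np.zeros(b.n_samples, np.int8) if b.marks is None else b.marks
    return bool(np.array_equal(am, bm))
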