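"""Global renormalization, extrema detection, cycle statistics, correlation.

The extremum detector implements a time-windowed local-max/min search (the
"moving searching range less than half breathing period" rule) with an
explicit, deterministic alternation-and-prominence pruning stage, plus a
programmatic override mechanism standing in for manual point adjustment.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    PairingError,
    TraceValidationError,
)
from .trace import RespTrace

logger = logging.getLogger(__name__)

PEAK = 1  # EOI
VALLEY = -1  # EOE


@dataclasses.dataclass
class ExtremaSet:
    """Alternating EOI (peak) / EOE (valley) landmarks of one trace."""

    eoi_times: np.ndarray
    eoe_times: np.ndarray
    eoi_indices: np.ndarray
    eoe_indices: np.ndarray
    search_window: float

    def events(self) -> list[tuple[int, int]]:
        """All extrema as (sample_index, type) sorted by index."""
        ev = [(int(i), PEAK) for i in self.eoi_indices]
        ev += [(int(i), VALLEY) for i in self.eoe_indices]
        return sorted(ev)

    def validate(self, amplitudes: np.ndarray) -> None:
        ev = self.events()
        for (i1, k1), (i2, k2) in zip(ev, ev[1:]):
            if k1 == k2:
                raise TraceValidationError("extrema do not alternate")
        for j, (i, k) in enumerate(ev):
            if k != PEAK:
                continue
            for nb in (j - 1, j + 1):
                if 0 <= nb < len(ev) and amplitudes[i] <= amplitudes[ev[nb][0]]:
                    raise TraceValidationError("EOI amplitude not above flanking EOE")


@dataclasses.dataclass
class BreathingCycle:
    """One EOE -> EOI -> EOE breathing cycle."""

    start_eoe_time: float
    eoi_time: float
    end_eoe_time: float
    period_T: float  # EOI-to-EOI period assigned to this cycle
    period_eoe: float  # EOE-to-EOE span (used for shape extraction)
    depth_d: float  # EOI amplitude - preceding EOE amplitude
    start_eoe_index: int = -1
    eoi_index: int = -1
    end_eoe_index: int = -1


@dataclasses.dataclass
class CycleStats:
    """Summary statistics of (optionally paired) breathing cycles."""

    period_mean: float
    period_sd: float
    depth_mean: float
    depth_sd: float
    n_cycles: int
    t_diff_range: Optional[tuple[float, float]] = None  # min/max of T_a - T_b
    d_diff_range: Optional[tuple[float, float]] = None  # min/max of d_a - d_b


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size >= 2 else 0.0


# ----------------------------------------------------------------- normalize
def normalize_global(trace: RespTrace) -> RespTrace:
    """Affinely map the whole trace's amplitude range onto [0, 100]."""
    a = trace.amplitudes
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise DegenerateInputError("constant trace cannot be renormalized")
    out = trace.copy()
    out.amplitudes = (a - lo) * (100.0 / (hi - lo))
    return out


# -------------------------------------------------------- windowed extrema
_WINDOW_EPS = 1e-9  # guards float round-off at exact window boundaries


def _left_window_max(t: np.ndarray, v: np.ndarray, half: float) -> np.ndarray:
    """For each i, max of v over samples j with ``t[i] - half <= t[j] < t[i]``.

    Monotonic-deque sliding maximum, O(n); -inf where the window is empty.
    """
    n = t.size
    lo = np.searchsorted(t, t - half, side="left")
    out = np.full(n, -np.inf)
    dq: deque[int] = deque()  # indices < i, increasing, v strictly decreasing
    for i in range(n):
        while dq and dq[0] < lo[i]:
            dq.popleft()
        if dq:
            out[i] = v[dq[0]]
        while dq and v[dq[-1]] <= v[i]:
            dq.pop()
        dq.append(i)
    return out


def _window_candidates(t: np.ndarray, a: np.ndarray, window: float, kind: int) -> list[int]:
    """Indices i with a[i] strictly better than all earlier in-window samples
    and at least as good as all later in-window samples (earliest-of-plateau
    tie-break). Monotonic-deque implementation, O(n)."""
    sign = 1.0 if kind == PEAK else -1.0
    v = sign * a
    n = t.size
    half = window / 2.0 + _WINDOW_EPS
    left = _left_window_max(t, v, half)
    # right pass = left pass on the time-reversed trace
    right = _left_window_max(-t[::-1], v[::-1], half)[::-1]
    out: list[int] = []
    for i in range(1, n - 1):
        # a truncated window at the trace boundary cannot confirm a true
        # extremum: require full window support on both sides, plus weak
        # dominance over the immediate neighbors
        if t[i] - t[0] < window / 2.0 or t[-1] - t[i] < window / 2.0:
            continue
        if v[i] > left[i] and v[i] >= right[i] and v[i] >= v[i - 1] and v[i] >= v[i + 1]:
            out.append(i)
    return out


def _collapse_runs(events: list[tuple[int, int]], a: np.ndarray) -> list[tuple[int, int]]:
    """Among consecutive same-type events keep the best (earliest on ties)."""
    out: list[tuple[int, int]] = []
    for idx, kind in events:
        if out and out[-1][1] == kind:
            pi, _ = out[-1]
            better = a[idx] > a[pi] if kind == PEAK else a[idx] < a[pi]
            if better:
                out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    return out


def _prominence_scores(events: list[tuple[int, int]], a: np.ndarray) -> list[float]:
    scores = []
    for j, (i, kind) in enumerate(events):
        nb = [events[k][0] for k in (j - 1, j + 1) if 0 <= k < len(events)]
        if not nb:
            scores.append(np.inf)
        elif kind == PEAK:
            scores.append(float(a[i] - max(a[k] for k in nb)))
        else:
            scores.append(float(min(a[k] for k in nb) - a[i]))
    return scores


def _prune(events: list[tuple[int, int]], a: np.ndarray, min_prominence: float) -> list[tuple[int, int]]:
    """Deterministic alternation + prominence pruning.

    Repeatedly removes the single weakest extremum whose prominence (peak:
    height above its higher flanking valley; valley: depth below its lower
    flanking peak) is under the threshold, re-collapsing same-type neighbors
    after each removal. Earliest event wins score ties.
    """
    events = _collapse_runs(sorted(events), a)
    while True:
        scores = _prominence_scores(events, a)
        worst = None
        for j, s in enumerate(scores):
            if s < min_prominence and (worst is None or s < scores[worst]):
                worst = j
        if worst is None:
            return events
        del events[worst]
        events = _collapse_runs(events, a)


def detect_extrema(
    trace: RespTrace,
    window: Optional[float] = None,
    min_prominence: float = 10.0,
    overrides: Optional[Sequence[tuple[float, str]]] = None,
) -> ExtremaSet:
    """Detect alternating EOI/EOE landmarks by time-windowed search.

    ``window=None`` triggers the two-pass scheme: a conservative 1 s first
    pass, then ``window = 0.4 x median inter-EOI gap``. ``min_prominence`` is
    in the trace's amplitude units (intended for the 0-100 global scale).
    ``overrides`` is a list of ``(time, label)`` pairs, label in
    ``{"EOI", "EOE"}``; each replaces the nearest detected extremum — the
    programmatic analogue of manually dragging a point.
    """
    if window is None:
        first = detect_extrema(trace, window=1.0, min_prominence=min_prominence)
        if first.eoi_times.size >= 2:
            gap = float(np.median(np.diff(first.eoi_times)))
            return detect_extrema(trace, window=0.4 * gap,
                                  min_prominence=min_prominence, overrides=overrides)
        return first
    if window <= 0:
        raise DegenerateInputError("window must be > 0")
    t, a = trace.timestamps, trace.amplitudes
    peaks = _window_candidates(t, a, window, PEAK)
    valleys = _window_candidates(t, a, window, VALLEY)
    events = [(i, PEAK) for i in peaks] + [(i, VALLEY) for i in valleys]
    events = _prune(events, a, min_prominence)
    if overrides:
        events = _apply_overrides(events, t, overrides)
    if not any(k == PEAK for _, k in events) or not any(k == VALLEY for _, k in events):
        raise DegenerateInputError("no alternating extrema found")
    eoi_idx = np.array([i for i, k in events if k == PEAK], dtype=int)
    eoe_idx = np.array([i for i, k in events if k == VALLEY], dtype=int)
    result = ExtremaSet(
        eoi_times=t[eoi_idx], eoe_times=t[eoe_idx],
        eoi_indices=eoi_idx, eoe_indices=eoe_idx, search_window=float(window),
    )
    result.validate(a)
    if eoi_idx.size >= 2:
        med = float(np.median(np.diff(t[eoi_idx])))
        if window >= med / 2.0:
            logger.warning("search window %.3f s >= half median period %.3f s", window, med)
    return result


def _apply_overrides(
    events: list[tuple[int, int]], t: np.ndarray,
    overrides: Sequence[tuple[float, str]],
) -> list[tuple[int, int]]:
    label_to_kind = {"EOI": PEAK, "EOE": VALLEY}
    events = list(events)
    for time, label in overrides:
        if label not in label_to_kind:
            raise TraceValidationError(f"override label must be EOI or EOE, got {label!r}")
        if not events:
            raise TraceValidationError("no detected extrema to override")
        j = int(np.argmin([abs(t[i] - time) for i, _ in events]))
        new_idx = int(np.argmin(np.abs(t - time)))
        events[j] = (new_idx, label_to_kind[label])
    events = sorted(set(events))
    for (i1, k1), (i2, k2) in zip(events, events[1:]):
        if k1 == k2:
            raise TraceValidationError("overrides break extrema alternation")
    return events


# -------------------------------------------------------------------- cycles
def segment_cycles(trace: RespTrace, extrema: ExtremaSet) -> list[BreathingCycle]:
    """One cycle per EOE -> EOE span containing exactly one EOI.

    ``period_T`` is the EOI-to-EOI gap to the following cycle (the paper's T;
    the last cycle uses the gap to the previous EOI); ``period_eoe`` is the
    EOE-to-EOE span; ``depth_d`` is EOI amplitude minus the preceding EOE's.
    """
    if extrema.eoi_indices.size < 2:
        raise InsufficientDataError("need >= 2 EOI to segment cycles")
    a = trace.amplitudes
    t = trace.timestamps
    ev = extrema.events()
    cycles: list[BreathingCycle] = []
    for j in range(len(ev) - 2):
        (i0, k0), (i1, k1), (i2, k2) = ev[j], ev[j + 1], ev[j + 2]
        if not (k0 == VALLEY and k1 == PEAK and k2 == VALLEY):
            continue
        cycles.append(BreathingCycle(
            start_eoe_time=float(t[i0]), eoi_time=float(t[i1]), end_eoe_time=float(t[i2]),
            period_T=np.nan, period_eoe=float(t[i2] - t[i0]),
            depth_d=float(a[i1] - a[i0]),
            start_eoe_index=i0, eoi_index=i1, end_eoe_index=i2,
        ))
    eoi_t = extrema.eoi_times
    for c in cycles:
        pos = int(np.searchsorted(eoi_t, c.eoi_time))
        if pos + 1 < eoi_t.size:
            c.period_T = float(eoi_t[pos + 1] - eoi_t[pos])
        elif pos >= 1:
            c.period_T = float(eoi_t[pos] - eoi_t[pos - 1])
        else:  # pragma: no cover - guarded by the >= 2 EOI precondition
            c.period_T = c.period_eoe
    return cycles


def _match_cycles(
    a: Sequence[BreathingCycle], b: Sequence[BreathingCycle]
) -> list[tuple[BreathingCycle, BreathingCycle]]:
    """Greedy one-to-one nearest-EOI matching within half the local period."""
    cand = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            dt = abs(ca.eoi_time - cb.eoi_time)
            if dt <= ca.period_T / 2.0:
                cand.append((dt, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a[i], b[j]))
    return pairs


def paired_cycle_stats(
    a: Sequence[BreathingCycle], b: Sequence[BreathingCycle]
) -> CycleStats:
    """Summary T/d statistics of trace A's cycles plus per-pair A-B ranges."""
    if not a or not b:
        raise InsufficientDataError("both traces need >= 1 cycle")
    pairs = _match_cycles(a, b)
    unmatched = max(1.0 - len(pairs) / len(a), 1.0 - len(pairs) / len(b))
    if unmatched > 0.20:
        raise PairingError(
            f"{unmatched:.0%} of cycles unmatched; traces not comparable"
        )
    t_a = np.array([pa.period_T for pa, _ in pairs])
    d_a = np.array([pa.depth_d for pa, _ in pairs])
    t_diff = np.array([pa.period_T - pb.period_T for pa, pb in pairs])
    d_diff = np.array([pa.depth_d - pb.depth_d for pa, pb in pairs])
    return CycleStats(
        period_mean=float(t_a.mean()), period_sd=_sd(t_a),
        depth_mean=float(d_a.mean()), depth_sd=_sd(d_a),
        n_cycles=len(pairs),
        t_diff_range=(float(t_diff.min()), float(t_diff.max())),
        d_diff_range=(float(d_diff.min()), float(d_diff.max())),
    )


def cycle_stats(cycles: Sequence[BreathingCycle]) -> CycleStats:
    """Single-trace T/d summary."""
    if not cycles:
        raise InsufficientDataError("no cycles")
    t = np.array([c.period_T for c in cycles])
    d = np.array([c.depth_d for c in cycles])
    return CycleStats(period_mean=float(t.mean()), period_sd=_sd(t),
                      depth_mean=float(d.mean()), depth_sd=_sd(d),
                      n_cycles=len(cycles))


# --------------------------------------------------------------- correlation
def common_grid(a: RespTrace, b: RespTrace) -> np.ndarray:
    """Uniform grid over the overlapping span at the finer median interval."""
    lo = max(a.timestamps[0], b.timestamps[0])
    hi = min(a.timestamps[-1], b.timestamps[-1])
    if hi <= lo:
        raise DegenerateInputError("traces do not overlap in time")
    dt = min(a.median_dt, b.median_dt)
    n = int(np.floor((hi - lo) / dt)) + 1
    return lo + np.arange(n) * dt


def trace_correlation(a: RespTrace, b: RespTrace) -> float:
    """Pearson correlation over the overlapping span on a common grid."""
    grid = common_grid(a, b)
    if grid.size < 2:
        raise DegenerateInputError("overlap shorter than 2 samples")
    xa = a.values_at(grid)
    xb = b.values_at(grid)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise DegenerateInputError("zero variance on the common grid")
    return float(np.corrcoef(xa, xb)[0, 1])
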