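"""EOI-aligned average breathing-cycle shape and limb-steepness comparison."""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError
from .trace import RespTrace
from .trace_analysis import ExtremaSet, PEAK, VALLEY

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = 0.04  # s
DEFAULT_THRESHOLD = 3.0  # 0-100 units of mean limb discrepancy

VERDICT_A = "A_steeper"
VERDICT_B = "B_steeper"
VERDICT_MATCHED = "matched"
VERDICT_UNDETERMINED = "undetermined"


@dataclasses.dataclass
class AlignedCycle:
    """One cycle re-origined at its EOI and renormalized to 0-100.

    ``rel_time < 0`` is the inhalation side, ``> 0`` the exhalation side;
    the amplitude at ``rel_time = 0`` is exactly 100. The lower of the two
    flanking EOE levels maps to 0, so the other endpoint may sit above 0
    under baseline drift.
    """

    rel_time: np.ndarray
    amplitude: np.ndarray


@dataclasses.dataclass
class AverageCycleShape:
    rel_time_grid: np.ndarray
    mean_amplitude: np.ndarray  # NaN where n_contributing < the minimum
    n_contributing: np.ndarray


@dataclasses.dataclass
class LimbComparison:
    exhale_verdict: str
    inhale_verdict: str
    exhale_score: float  # mean(B - A) on the exhale limb; >0 => A steeper
    inhale_score: float  # mean(B - A) on the inhale limb; >0 => A steeper
    threshold: float


def extract_aligned_cycles(trace: RespTrace, extrema: ExtremaSet) -> list[AlignedCycle]:
    """Per EOE->EOE cycle: re-origin time at the EOI and map amplitudes so the
    lower flanking EOE level -> 0 and the EOI -> 100.

    Cycles whose EOI sample is not the strict interior maximum are skipped
    with a warning.
    """
    t, a = trace.timestamps, trace.amplitudes
    ev = extrema.events()
    out: list[AlignedCycle] = []
    for j in range(len(ev) - 2):
        (i0, k0), (i1, k1), (i2, k2) = ev[j], ev[j + 1], ev[j + 2]
        if not (k0 == VALLEY and k1 == PEAK and k2 == VALLEY):
            continue
        seg = slice(i0, i2 + 1)
        if not (i0 < i1 < i2) or a[i1] < a[seg].max():
            logger.warning("cycle at t=%.2f s: EOI is not the strict interior maximum; skipped",
                           t[i1])
            continue
        baseline = min(a[i0], a[i2])
        denom = a[i1] - baseline
        if denom <= 0:
            logger.warning("cycle at t=%.2f s: zero depth; skipped", t[i1])
            continue
        out.append(AlignedCycle(
            rel_time=t[seg] - t[i1],
            amplitude=100.0 * (a[seg] - baseline) / denom,
        ))
    return out


def average_shape(
    cycles: Sequence[AlignedCycle],
    grid_step: float = DEFAULT_GRID_STEP,
    min_contributing: Optional[int] = None,
) -> AverageCycleShape:
    """Pointwise mean of the aligned cycles on a common rel_time grid.

    The grid consists of integer multiples of ``grid_step`` spanning the
    union of all cycles' ranges (and always contains 0, where every cycle is
    exactly 100). Grid points covered by fewer than ``min_contributing``
    cycles (default ``max(2, 20% of cycles)``) are masked as NaN.
    """
    if len(cycles) < 2:
        raise InsufficientDataError("need >= 2 aligned cycles to average")
    if min_contributing is None:
        min_contributing = max(2, math.ceil(0.2 * len(cycles)))
    lo = min(float(c.rel_time[0]) for c in cycles)
    hi = max(float(c.rel_time[-1]) for c in cycles)
    grid = np.arange(math.floor(lo / grid_step), math.ceil(hi / grid_step) + 1) * grid_step
    total = np.zeros(grid.size)
    count = np.zeros(grid.size, dtype=int)
    for c in cycles:
        inside = (grid >= c.rel_time[0]) & (grid <= c.rel_time[-1])
        total[inside] += np.interp(grid[inside], c.rel_time, c.amplitude)
        count[inside] += 1
    mean = np.full(grid.size, np.nan)
    ok = count >= min_contributing
    mean[ok] = total[ok] / count[ok]
    return AverageCycleShape(rel_time_grid=grid, mean_amplitude=mean, n_contributing=count)


def compare_limbs(
    shape_a: AverageCycleShape,
    shape_b: AverageCycleShape,
    threshold: float = DEFAULT_THRESHOLD,
) -> LimbComparison:
    """Classify per-limb steepness disagreement between two average shapes.

    Score per limb = weighted mean over the overlapping grid of (B - A),
    each point weighted by the harmonic mean of the two shapes' contributing
    cycle counts (sparsely covered tail points are noisy and carry little
    weight). A curve that is *steeper near the EOI* lies below the other over
    the limb interior, so score > threshold => A steeper, score < -threshold
    => B steeper, |score| < threshold => matched. Limbs with no overlapping
    defined grid points are flagged undetermined.
    """
    # grids are integer lattices of their step; align by rounded index
    def limb_score(sign: int) -> Optional[float]:
        ga, gb = shape_a.rel_time_grid, shape_b.rel_time_grid
        step = float(np.median(np.diff(ga)))
        ia = {int(round(t / step)): k for k, t in enumerate(ga)}
        ib = {int(round(t / step)): k for k, t in enumerate(gb)}
        diffs, weights = [], []
        for key, ka in ia.items():
            if sign * key <= 0 or key not in ib:
                continue
            kb = ib[key]
            va = shape_a.mean_amplitude[ka]
            vb = shape_b.mean_amplitude[kb]
            if np.isnan(va) or np.isnan(vb):
                continue
            na_, nb_ = shape_a.n_contributing[ka], shape_b.n_contributing[kb]
            diffs.append(vb - va)
            weights.append(2.0 * na_ * nb_ / (na_ + nb_))
        if not diffs:
            return None
        return float(np.average(diffs, weights=weights))

    def verdict(score: Optional[float]) -> str:
        if score is None:
            return VERDICT_UNDETERMINED
        if abs(score) < threshold:
            return VERDICT_MATCHED
        return VERDICT_A if score > 0 else VERDICT_B

    s_ex = limb_score(+1)  # exhalation: rel_time > 0
    s_in = limb_score(-1)  # inhalation: rel_time < 0
    return LimbComparison(
        exhale_verdict=verdict(s_ex), inhale_verdict=verdict(s_in),
        exhale_score=float("nan") if s_ex is None else s_ex,
        inhale_score=float("nan") if s_in is None else s_in,
        threshold=threshold,
    )
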