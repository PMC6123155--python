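"""Local-amplitude sorting of timestamped samples into 10 respiratory phases.

Phases 1-10 correspond to 100%Ex, 80%Ex, 60%Ex, 40%Ex, 20%Ex, 0%In, 20%In,
40%In, 60%In, 80%In. Each sample's amplitude fraction is computed against its
own limb's flanking EOI/EOE (local, per-cycle), and the sample takes the
phase of the nearest nominal level on its limb (midpoint bins). The EOI
sample belongs to the exhale limb (phase 1) and the EOE sample to the inhale
limb (phase 6).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .trace import RespTrace
from .trace_analysis import ExtremaSet, PEAK, VALLEY

logger = logging.getLogger(__name__)

PHASE_NAMES = {
    1: "100%Ex", 2: "80%Ex", 3: "60%Ex", 4: "40%Ex", 5: "20%Ex",
    6: "0%In", 7: "20%In", 8: "40%In", 9: "60%In", 10: "80%In",
}

# nominal amplitude fractions, ordered so ties break toward the lower phase index
EXHALE_LEVELS = ((1.0, 1), (0.8, 2), (0.6, 3), (0.4, 4), (0.2, 5), (0.0, 6))
INHALE_LEVELS = ((0.0, 6), (0.2, 7), (0.4, 8), (0.6, 9), (0.8, 10))

CLAMP_TOLERANCE = 0.02

LIMB_INHALE = "inhale"
LIMB_EXHALE = "exhale"


@dataclasses.dataclass(frozen=True)
class PhaseLabel:
    index: int  # 1-10

    @property
    def name(self) -> str:
        return PHASE_NAMES[self.index]


@dataclasses.dataclass
class SortedSample:
    time: float
    amplitude: float
    amplitude_fraction: float  # 0-1 of the local cycle depth
    limb: str  # "inhale" | "exhale"
    phase: PhaseLabel
    cycle_id: int
    sample_index: int


def nominal_level(phase_index: int, limb: str) -> float:
    """The amplitude fraction a phase nominally sits at on the given limb."""
    levels = EXHALE_LEVELS if limb == LIMB_EXHALE else INHALE_LEVELS
    for f, p in levels:
        if p == phase_index:
            return f
    raise ValueError(f"phase {phase_index} not on {limb} limb")


def _bin_phase(fraction: float, limb: str) -> int:
    """Nearest nominal level on the limb; ties go to the earlier list entry
    (toward the EOI on exhale, toward the EOE on inhale -> lower phase index)."""
    levels = EXHALE_LEVELS if limb == LIMB_EXHALE else INHALE_LEVELS
    best_phase, best_dist = None, None
    for f, p in levels:
        d = abs(fraction - f)
        if best_dist is None or d < best_dist:
            best_phase, best_dist = p, d
    return int(best_phase)


def assign_phases(trace: RespTrace, extrema: ExtremaSet) -> list[SortedSample]:
    """Sort every sample inside a complete half-cycle into one of 10 phases.

    Limbs run between consecutive opposite-type extrema; a limb's samples are
    ``[start, end)`` so the EOI lands on its exhale limb and the EOE on its
    inhale limb. Fractions outside [0, 1] by more than ``CLAMP_TOLERANCE``
    are excluded with a warning; smaller excursions are clamped.
    """
    t, a = trace.timestamps, trace.amplitudes
    ev = extrema.events()
    eoe_times = extrema.eoe_times
    out: list[SortedSample] = []
    n_excluded = 0
    for (i0, k0), (i1, k1) in zip(ev, ev[1:]):
        if k0 == k1:  # pragma: no cover - ExtremaSet alternates by contract
            continue
        if k0 == VALLEY and k1 == PEAK:
            limb = LIMB_INHALE
            a_eoe, a_eoi = a[i0], a[i1]
        else:
            limb = LIMB_EXHALE
            a_eoi, a_eoe = a[i0], a[i1]
        denom = a_eoi - a_eoe
        if denom <= 0:
            logger.warning("limb at t=%.2f s has non-positive depth; skipped", t[i0])
            continue
        for i in range(i0, i1):
            f = (a[i] - a_eoe) / denom
            if f < -CLAMP_TOLERANCE or f > 1.0 + CLAMP_TOLERANCE:
                n_excluded += 1
                continue
            f = min(max(f, 0.0), 1.0)
            cid = int(np.searchsorted(eoe_times, t[i], side="right"))
            out.append(SortedSample(
                time=float(t[i]), amplitude=float(a[i]), amplitude_fraction=float(f),
                limb=limb, phase=PhaseLabel(_bin_phase(f, limb)),
                cycle_id=cid, sample_index=i,
            ))
    # the final extremum sample closes the last limb
    if ev:
        i_last, k_last = ev[-1]
        prev = ev[-2] if len(ev) >= 2 else None
        if prev is not None and prev[1] != k_last:
            # the trailing EOI belongs to the exhale limb (phase 1);
            # the trailing EOE to the inhale limb (phase 6)
            limb = LIMB_EXHALE if k_last == PEAK else LIMB_INHALE
            f = 1.0 if k_last == PEAK else 0.0
            cid = int(np.searchsorted(eoe_times, t[i_last], side="right"))
            out.append(SortedSample(
                time=float(t[i_last]), amplitude=float(a[i_last]), amplitude_fraction=f,
                limb=limb, phase=PhaseLabel(_bin_phase(f, limb)),
                cycle_id=cid, sample_index=int(i_last),
            ))
    if n_excluded:
        logger.warning("%d samples excluded (fraction outside clamp tolerance)", n_excluded)
    return out


@dataclasses.dataclass
class PhaseOccupancy:
    counts: dict[int, int]  # phase index -> retained sample count
    time_coverage: dict[int, float]  # phase index -> approx. covered seconds
    empty_phases: list[int]


def phase_occupancy(sorted_samples: Sequence[SortedSample]) -> PhaseOccupancy:
    """Per-phase sample counts and approximate time coverage; flags empties."""
    counts = {p: 0 for p in range(1, 11)}
    for s in sorted_samples:
        counts[s.phase.index] += 1
    if len(sorted_samples) >= 2:
        times = np.sort([s.time for s in sorted_samples])
        dt = float(np.median(np.diff(times)))
    else:
        dt = 0.0
    coverage = {p: counts[p] * dt for p in counts}
    empty = [p for p, c in counts.items() if c == 0]
    if empty:
        logger.warning("empty phases: %s", empty)
    return PhaseOccupancy(counts=counts, time_coverage=coverage, empty_phases=empty)
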