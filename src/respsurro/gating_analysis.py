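"""Gating-window mismatch between a design surrogate and an applied surrogate.

A gate defined on one surrogate (amplitude thresholds on the 0-100 scale, or
a set of respiratory phases) is applied to both surrogates of a pair; the
disagreement is summarized as duty cycles, the Jaccard overlap of the two
beam-on time sets, and the residual internal motion during beam-on.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .errors import DegenerateInputError, ParameterError
from .phase_sorting import assign_phases
from .trace import RespTrace
from .trace_analysis import ExtremaSet, detect_extrema, normalize_global

logger = logging.getLogger(__name__)

DEFAULT_EXCURSION_MM = 20.0


class GatingWindow(BaseModel):
    """Beam-enable condition: amplitude band or phase subset."""

    model_config = ConfigDict(extra="forbid")

    mode: str = "amplitude"  # "amplitude" | "phase"
    lower: float = 0.0  # 0-100 amplitude units (amplitude mode)
    upper: float = 100.0
    phases: Optional[list[int]] = None  # phase indices 1-10 (phase mode)
    defined_on: str = "A"

    def model_post_init(self, context, /) -> None:
        if self.mode not in ("amplitude", "phase"):
            raise ParameterError("mode must be 'amplitude' or 'phase'")
        if self.mode == "amplitude" and self.lower >= self.upper:
            raise ParameterError("amplitude window needs lower < upper")
        if self.mode == "phase":
            if not self.phases:
                raise ParameterError("phase window needs a non-empty phase set")
            if any(p < 1 or p > 10 for p in self.phases):
                raise ParameterError("phase indices must be 1-10")


@dataclasses.dataclass
class BeamOnSet:
    """Union of maximal half-open beam-on intervals on a sample grid."""

    intervals: np.ndarray  # (n, 2) [start, stop)
    total_time: float
    duty_cycle: float  # fraction of the trace span

    @classmethod
    def from_mask(cls, timestamps: np.ndarray, mask: np.ndarray) -> "BeamOnSet":
        t = np.asarray(timestamps, dtype=float)
        dt = np.diff(t)
        dt = np.append(dt, np.median(dt) if dt.size else 0.0)
        span = float(dt.sum())
        mask = np.asarray(mask, dtype=bool)
        d = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        ivals = []
        for s, e in zip(starts, stops):
            ivals.append((t[s], t[e - 1] + dt[e - 1]))
        on_time = float(dt[mask].sum())
        return cls(
            intervals=np.asarray(ivals).reshape(-1, 2),
            total_time=on_time,
            duty_cycle=on_time / span if span > 0 else 0.0,
        )


@dataclasses.dataclass
class GatingMismatch:
    duty_cycle_design: float
    duty_cycle_applied: float
    beam_interval_overlap: float  # Jaccard of the two beam-on time sets
    residual_motion_design: float  # mm, internal-motion range during design beam-on
    residual_motion_applied: float

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in dataclasses.asdict(self).items()}


def apply_gate(
    window: GatingWindow,
    surrogate: RespTrace,
    extrema: Optional[ExtremaSet] = None,
) -> BeamOnSet:
    """Beam-on time set where the gate condition holds on this surrogate.

    Amplitude mode expects a 0-100 normalized surrogate and enables the beam
    for ``lower <= amplitude <= upper``. Phase mode enables exactly the
    samples sorted into the window's phases (extrema are detected if not
    supplied). A window outside the signal range yields an empty set with a
    warning, not an error.
    """
    t = surrogate.timestamps
    if window.mode == "amplitude":
        a = surrogate.amplitudes
        mask = (a >= window.lower) & (a <= window.upper)
        if not mask.any():
            logger.warning("amplitude window [%s, %s] outside signal range [%s, %s]",
                           window.lower, window.upper, a.min(), a.max())
    else:
        if extrema is None:
            extrema = detect_extrema(normalize_global(surrogate))
        wanted = set(window.phases or [])
        mask = np.zeros(t.size, dtype=bool)
        for s in assign_phases(surrogate, extrema):
            if s.phase.index in wanted:
                mask[s.sample_index] = True
    return BeamOnSet.from_mask(t, mask)


def _mask_on_grid(window: GatingWindow, surrogate: RespTrace, grid: np.ndarray) -> np.ndarray:
    """Gate membership resampled to a common grid by interval containment."""
    on = apply_gate(window, surrogate)
    mask = np.zeros(grid.size, dtype=bool)
    for s, e in on.intervals:
        mask |= (grid >= s) & (grid < e)
    return mask


def mismatch(
    window: GatingWindow,
    design_surrogate: RespTrace,
    applied_surrogate: RespTrace,
    internal: RespTrace,
    excursion_mm: float = DEFAULT_EXCURSION_MM,
) -> GatingMismatch:
    """Quantify the design-vs-delivery gating discrepancy.

    All traces are resampled to a common uniform grid (finest median interval
    over the intersection of spans). Residual motion is the range of the
    internal-trace-implied diaphragm position (``excursion_mm`` times the
    normalized internal amplitude) during each beam-on set.
    """
    lo = max(design_surrogate.timestamps[0], applied_surrogate.timestamps[0],
             internal.timestamps[0])
    hi = min(design_surrogate.timestamps[-1], applied_surrogate.timestamps[-1],
             internal.timestamps[-1])
    if hi <= lo:
        raise DegenerateInputError("traces do not share a common time span")
    dt = min(design_surrogate.median_dt, applied_surrogate.median_dt, internal.median_dt)
    grid = lo + np.arange(int(np.floor((hi - lo) / dt)) + 1) * dt

    dn = normalize_global(design_surrogate) if window.mode == "amplitude" else design_surrogate
    an = normalize_global(applied_surrogate) if window.mode == "amplitude" else applied_surrogate
    on_a = _mask_on_grid(window, dn, grid)
    on_b = _mask_on_grid(window, an, grid)
    if not on_a.any():
        raise DegenerateInputError("design beam-on set is empty")
    union = int((on_a | on_b).sum())
    overlap = float((on_a & on_b).sum()) / union if union else 1.0

    ia = internal.values_at(grid)
    frac = (ia - ia.min()) / np.ptp(ia) if np.ptp(ia) > 0 else np.zeros_like(ia)
    position = excursion_mm * frac

    def residual(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        p = position[mask]
        return float(p.max() - p.min())

    return GatingMismatch(
        duty_cycle_design=float(on_a.mean()),
        duty_cycle_applied=float(on_b.mean()),
        beam_interval_overlap=overlap,
        residual_motion_design=residual(on_a),
        residual_motion_applied=residual(on_b),
    )
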