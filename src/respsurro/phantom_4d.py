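"""Digital motion phantom: surrogate discrepancies -> per-phase anatomy mismatch.

A cine-style (step-and-shoot) acquisition samples a linearly coupled
diaphragm/lung phantom driven by the ground-truth internal motion; the frames
are then retrospectively sorted into 10 phases using a *surrogate* trace.
Sorting the same frames with two different surrogates and differencing the
per-phase lung volume and diaphragm apex position reproduces the structure of
a two-surrogate 4D-CT comparison.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .errors import DataInsufficiencyError, ParameterError, TraceValidationError
from .phase_sorting import LIMB_EXHALE, LIMB_INHALE, assign_phases, nominal_level
from .trace import RespTrace
from .trace_analysis import ExtremaSet

DEFAULT_FRAME_RATE = 2.0  # Hz (0.5 s frame period, matching the rotation time)


class PhantomGeometry(BaseModel):
    """Linear surrogate->anatomy coupling of the digital phantom."""

    model_config = ConfigDict(extra="forbid")

    diaphragm_base_position: float = 0.0  # mm, SI position at EOE
    diaphragm_excursion: float = 20.0  # mm peak-to-peak
    lung_volume_at_eoe: float = 3000.0  # mL
    volume_per_mm: float = 50.0  # mL per mm of apex displacement
    slice_thickness: float = 2.0  # mm
    n_couch_positions: int = 40
    couch_span: float = 400.0  # mm

    def model_post_init(self, context, /) -> None:
        if self.diaphragm_excursion <= 0:
            raise ParameterError("diaphragm_excursion must be > 0")
        if self.slice_thickness <= 0:
            raise ParameterError("slice_thickness must be > 0")
        if self.volume_per_mm <= 0:
            raise ParameterError("volume_per_mm must be > 0")
        if self.n_couch_positions < 1:
            raise ParameterError("n_couch_positions must be >= 1")


@dataclasses.dataclass
class AcquisitionSchedule:
    """Cine dwell schedule: per couch position a dwell window and frame rate.

    Each dwell should last at least one maximal breathing period (the data
    sufficiency condition) so every phase has a candidate frame.
    """

    dwell_starts: np.ndarray  # seconds, ordered
    dwell_duration: float  # seconds, shared by all positions
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.dwell_starts = np.asarray(self.dwell_starts, dtype=float)
        if self.dwell_duration <= 0 or self.frame_rate <= 0:
            raise ParameterError("dwell_duration and frame_rate must be > 0")
        if self.dwell_starts.size >= 2 and not np.all(np.diff(self.dwell_starts) >= 0):
            raise ParameterError("dwell_starts must be ordered")

    @classmethod
    def sequential(cls, n_positions: int, dwell_duration: float,
                   start: float = 0.0, frame_rate: float = DEFAULT_FRAME_RATE
                   ) -> "AcquisitionSchedule":
        starts = start + dwell_duration * np.arange(n_positions)
        return cls(dwell_starts=starts, dwell_duration=dwell_duration,
                   frame_rate=frame_rate)

    @property
    def n_positions(self) -> int:
        return int(self.dwell_starts.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.dwell_starts[0]), float(self.dwell_starts[-1] + self.dwell_duration)


@dataclasses.dataclass
class FrameSet:
    """Timestamped frames: couch index, acquisition time, true diaphragm position.

    Carries the phantom geometry it was acquired with, so reconstruction can
    quantize positions and derive volumes consistently.
    """

    couch_index: np.ndarray  # int
    frame_time: np.ndarray  # s
    true_position: np.ndarray  # mm
    geometry: PhantomGeometry = dataclasses.field(default_factory=PhantomGeometry)


@dataclasses.dataclass
class Phase4DResult:
    """Per-phase (1-10) anatomy under one surrogate's sorting."""

    lung_volume: np.ndarray  # mL, index 0 -> phase 1
    diaphragm_apex: np.ndarray  # mm, quantized to slice_thickness
    relative_displacement: np.ndarray  # mm, vs phase 6

    def as_dict(self) -> dict:
        return {
            "lung_volume_ml": [float(v) for v in self.lung_volume],
            "diaphragm_apex_mm": [float(v) for v in self.diaphragm_apex],
            "relative_displacement_mm": [float(v) for v in self.relative_displacement],
        }


@dataclasses.dataclass
class MismatchReport:
    """Per-phase A-B differences and their ranges over phases."""

    volume_diff_pct: np.ndarray  # 100*(A-B)/B per phase
    position_diff: np.ndarray  # mm, A-B per phase
    volume_diff_range: tuple[float, float]
    position_diff_range: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "volume_diff_pct": [float(v) for v in self.volume_diff_pct],
            "position_diff_mm": [float(v) for v in self.position_diff],
            "volume_diff_range_pct": [float(v) for v in self.volume_diff_range],
            "position_diff_range_mm": [float(v) for v in self.position_diff_range],
        }


def _quantize(x: float, step: float) -> float:
    # round-half-up, deterministic (avoids numpy banker's rounding)
    return math.floor(x / step + 0.5) * step


def simulate_acquisition(
    internal: RespTrace,
    geometry: PhantomGeometry,
    schedule: AcquisitionSchedule,
) -> FrameSet:
    """Record (couch, time, true diaphragm position) for every cine frame.

    The true position is ``base + excursion * f(t)`` where ``f`` is the
    internal amplitude normalized to [0, 1] over the whole trace (0 = EOE).
    """
    lo, hi = schedule.span
    if lo < internal.timestamps[0] or hi > internal.timestamps[-1] + 1e-9:
        raise TraceValidationError(
            f"schedule span [{lo}, {hi}] exceeds internal trace span "
            f"[{internal.timestamps[0]}, {internal.timestamps[-1]}]"
        )
    amin, amax = float(internal.amplitudes.min()), float(internal.amplitudes.max())
    if amax <= amin:
        raise TraceValidationError("internal trace is constant")
    couch_idx: list[int] = []
    times: list[float] = []
    n_frames = int(round(schedule.dwell_duration * schedule.frame_rate))
    for k in range(schedule.n_positions):
        ft = schedule.dwell_starts[k] + np.arange(n_frames) / schedule.frame_rate
        ft = ft[ft <= schedule.dwell_starts[k] + schedule.dwell_duration + 1e-12]
        couch_idx.extend([k] * ft.size)
        times.extend(ft.tolist())
    times_arr = np.asarray(times)
    frac = (internal.values_at(times_arr) - amin) / (amax - amin)
    pos = geometry.diaphragm_base_position + geometry.diaphragm_excursion * frac
    return FrameSet(couch_index=np.asarray(couch_idx, dtype=int),
                    frame_time=times_arr, true_position=pos, geometry=geometry)


def reconstruct_phases(
    frames: FrameSet,
    surrogate: RespTrace,
    extrema: ExtremaSet,
) -> Phase4DResult:
    """Sort the frames into 10 phases using the surrogate (not the internal
    motion) and extract per-phase anatomy.

    Per (couch, phase) cell the selected frame is the one whose surrogate
    amplitude fraction is nearest the phase's nominal level on the matching
    limb (phase 6 accepts both limbs; ties go to the earliest frame). The
    per-phase diaphragm apex is the maximum of the selected true positions
    over couch positions, quantized to the slice thickness; lung volume is
    linear in the apex displacement.
    """
    sorted_samples = assign_phases(surrogate, extrema)
    if not sorted_samples:
        raise DataInsufficiencyError("surrogate yields no sorted samples")
    s_times = np.array([s.time for s in sorted_samples])
    s_frac = np.array([s.amplitude_fraction for s in sorted_samples])
    s_limb = np.array([s.limb == LIMB_EXHALE for s in sorted_samples])  # True=exhale

    # map each frame to its nearest-in-time retained surrogate sample
    pos = np.searchsorted(s_times, frames.frame_time)
    pos = np.clip(pos, 1, s_times.size - 1)
    left_closer = (frames.frame_time - s_times[pos - 1]) <= (s_times[pos] - frames.frame_time)
    nearest = np.where(left_closer, pos - 1, pos)
    f_frac = s_frac[nearest]
    f_exhale = s_limb[nearest]

    couch_ids = np.unique(frames.couch_index)
    selected = np.full((couch_ids.size, 10), np.nan)
    for ci, c in enumerate(couch_ids):
        in_couch = frames.couch_index == c
        for p in range(1, 11):
            if p <= 5:
                limb_ok = f_exhale
                level = nominal_level(p, LIMB_EXHALE)
            elif p == 6:
                limb_ok = np.ones_like(f_exhale)
                level = 0.0
            else:
                limb_ok = ~f_exhale
                level = nominal_level(p, LIMB_INHALE)
            cand = in_couch & limb_ok.astype(bool)
            if not cand.any():
                raise DataInsufficiencyError(
                    f"no candidate frame for couch {int(c)}, phase {p}"
                )
            idx = np.flatnonzero(cand)
            dist = np.abs(f_frac[idx] - level)
            best = idx[np.lexsort((frames.frame_time[idx], dist))[0]]
            selected[ci, p - 1] = frames.true_position[best]

    geometry = frames.geometry
    apex = selected.max(axis=0)
    apex_q = np.array([_quantize(x, geometry.slice_thickness) for x in apex])
    volume = geometry.lung_volume_at_eoe + geometry.volume_per_mm * (
        apex_q - geometry.diaphragm_base_position
    )
    rel = apex_q - apex_q[5]  # phase 6 reference
    return Phase4DResult(lung_volume=volume, diaphragm_apex=apex_q,
                         relative_displacement=rel)


def compare_sortings(result_a: Phase4DResult, result_b: Phase4DResult) -> MismatchReport:
    """Per-phase A-B differences in volume (% of B) and apex position (mm)."""
    vol_pct = 100.0 * (result_a.lung_volume - result_b.lung_volume) / result_b.lung_volume
    pos = result_a.diaphragm_apex - result_b.diaphragm_apex
    return MismatchReport(
        volume_diff_pct=vol_pct, position_diff=pos,
        volume_diff_range=(float(vol_pct.min()), float(vol_pct.max())),
        position_diff_range=(float(pos.min()), float(pos.max())),
    )
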