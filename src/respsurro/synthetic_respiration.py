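"""Synthetic quasi-periodic breathing and controllably-distorted surrogates.

Ground-truth internal motion is generated from a raised-cosine-power cycle
family with per-cycle period/depth variability; a second surrogate is derived
from it with a known lag, per-limb time warps, a pointwise response
nonlinearity, gain/offset, and additive noise. Every downstream stage is
therefore testable against known injected discrepancies.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .errors import ParameterError, StateError
from .trace import RespTrace, uniform_timestamps

DEFAULT_DISPLACEMENT_RATE = 25.0  # Hz, displacement-style surrogate
DEFAULT_PRESSURE_RATE = 40.0  # Hz, pressure-style surrogate


class BreathingModelParams(BaseModel):
    """Parameters of the quasi-periodic internal-motion generator."""

    model_config = ConfigDict(extra="forbid")

    mean_period: float = 4.0  # s
    period_sd: float = 0.0  # s
    mean_depth: float = 100.0  # amplitude units
    depth_sd: float = 0.0
    plateau_exponent: float = 1.5  # >0; larger = longer EOE dwell
    baseline_drift_rate: float = 0.0  # amplitude units / s
    noise_sd: float = 0.0
    sampling_rate: float = DEFAULT_DISPLACEMENT_RATE  # Hz
    duration: float = 40.0  # s
    seed: int = 0

    def model_post_init(self, context, /) -> None:
        if self.mean_period <= 0:
            raise ParameterError("mean_period must be > 0")
        if self.period_sd < 0 or self.depth_sd < 0:
            raise ParameterError("period_sd and depth_sd must be >= 0")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if self.plateau_exponent <= 0:
            raise ParameterError("plateau_exponent must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.sampling_rate * self.mean_period < 10:
            raise ParameterError(
                "sampling_rate too low: need >= 10 samples per mean cycle "
                f"(got {self.sampling_rate * self.mean_period:.1f})"
            )
        if self.duration < 3 * self.mean_period:
            raise ParameterError("duration must cover >= 3 full mean cycles")


class SurrogateDistortion(BaseModel):
    """Known discrepancy applied to derive one surrogate from internal motion.

    ``lag`` > 0 means the distorted surrogate reaches each EOI *earlier* than
    its source (the paper's sign convention for the leading surrogate).
    Steepness warps are strictly increasing bijections of each limb's time
    interval onto itself, anchored at the EOI, so extrema counts and ordering
    are preserved.
    """

    model_config = ConfigDict(extra="forbid")

    lag: float = 0.0  # s
    exhale_steepness: float = 1.0  # >= 1
    inhale_steepness: float = 1.0  # > 0
    response_exponent: float = 1.0  # > 0
    extra_noise_sd: float = 0.0
    gain: float = 1.0
    offset: float = 0.0

    def model_post_init(self, context, /) -> None:
        if self.exhale_steepness < 1:
            raise ParameterError("exhale_steepness must be >= 1")
        if self.inhale_steepness <= 0:
            raise ParameterError("inhale_steepness must be > 0")
        if self.response_exponent <= 0:
            raise ParameterError("response_exponent must be > 0")
        if self.extra_noise_sd < 0:
            raise ParameterError("extra_noise_sd must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.lag == 0.0
            and self.exhale_steepness == 1.0
            and self.inhale_steepness == 1.0
            and self.response_exponent == 1.0
            and self.extra_noise_sd == 0.0
            and self.gain == 1.0
            and self.offset == 0.0
        )


class ScanTimeline(BaseModel):
    """CT beam-on/off schedule; segments are half-open ``[on, off)``."""

    model_config = ConfigDict(extra="forbid")

    scan_start: float = 0.0
    scan_stop: float = 40.0
    beam_segments: list[tuple[float, float]] = []

    def model_post_init(self, context, /) -> None:
        if self.scan_stop <= self.scan_start:
            raise ParameterError("scan_stop must exceed scan_start")
        prev_off = None
        for on, off in self.beam_segments:
            if off <= on:
                raise ParameterError(f"beam segment ({on}, {off}) has off <= on")
            if on < self.scan_start or off > self.scan_stop:
                raise ParameterError(
                    f"beam segment ({on}, {off}) outside [{self.scan_start}, {self.scan_stop}]"
                )
            if prev_off is not None and on < prev_off:
                raise ParameterError("beam segments must be non-overlapping and increasing")
            prev_off = off


@dataclasses.dataclass
class BreathingModel:
    """Continuous-time piecewise raised-cosine-power breathing waveform.

    Cycle k occupies ``[eoe_boundaries[k], eoe_boundaries[k+1])`` with period
    ``periods[k]``, depth ``depths[k]``, EOE level 0 at both boundaries and
    EOI (amplitude = depth) at mid-cycle. A linear baseline drift is added.
    """

    eoe_boundaries: np.ndarray  # len n_cycles + 1
    periods: np.ndarray
    depths: np.ndarray
    plateau_exponent: float
    baseline_drift_rate: float

    @property
    def eoi_times(self) -> np.ndarray:
        return self.eoe_boundaries[:-1] + self.periods / 2.0

    @property
    def eoe_times(self) -> np.ndarray:
        return self.eoe_boundaries

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, self.eoe_boundaries[0], self.eoe_boundaries[-1])
        k = np.clip(
            np.searchsorted(self.eoe_boundaries, tc, side="right") - 1,
            0,
            len(self.periods) - 1,
        )
        local = (tc - self.eoe_boundaries[k]) / self.periods[k]
        shape = 1.0 - np.abs(np.cos(np.pi * local)) ** (2.0 * self.plateau_exponent)
        return self.depths[k] * shape + self.baseline_drift_rate * t


def _build_model(params: BreathingModelParams) -> BreathingModel:
    ss = np.random.SeedSequence([params.seed, 0xB5EA7])
    rng = np.random.default_rng(ss)
    # Cover [-2*mean_period, duration + 2*mean_period] so lagged/warped
    # evaluation slightly outside the sampled span stays well defined.
    t0 = -2.0 * params.mean_period
    t_end = params.duration + 2.0 * params.mean_period
    boundaries = [t0]
    periods: list[float] = []
    depths: list[float] = []
    while boundaries[-1] < t_end:
        T = float(rng.normal(params.mean_period, params.period_sd))
        T = max(T, 0.3 * params.mean_period)
        d = float(rng.normal(params.mean_depth, params.depth_sd))
        d = max(d, 0.1 * params.mean_depth)
        periods.append(T)
        depths.append(d)
        boundaries.append(boundaries[-1] + T)
    return BreathingModel(
        eoe_boundaries=np.array(boundaries),
        periods=np.array(periods),
        depths=np.array(depths),
        plateau_exponent=params.plateau_exponent,
        baseline_drift_rate=params.baseline_drift_rate,
    )


def generate_internal_motion(params: BreathingModelParams) -> RespTrace:
    """Sample the ground-truth internal motion on a uniform grid.

    The returned trace carries EOI/EOE sample marks at the generator's true
    extremum times and keeps a reference to the continuous model so that
    :func:`distort_to_surrogate` can evaluate lags off the sampling grid.
    Deterministic for a fixed seed.
    """
    model = _build_model(params)
    t = uniform_timestamps(params.duration, params.sampling_rate)
    a = model(t)
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x1705E]))
        a = a + noise_rng.normal(0.0, params.noise_sd, t.size)
    trace = RespTrace(
        timestamps=t,
        amplitudes=a,
        beam_on=np.zeros(t.size, dtype=bool),
        source_kind="displacement",
        sampling_rate=params.sampling_rate,
        model=model,
    )
    in_span = lambda x: x[(x >= t[0]) & (x <= t[-1])]  # noqa: E731
    trace = trace.with_marks_at(in_span(model.eoi_times), in_span(model.eoe_times))
    trace.model = model
    return trace


def _limb_warp(u: np.ndarray, steepness: float) -> np.ndarray:
    # u = normalized time distance from the EOI on a limb, in [0, 1].
    # Strictly increasing bijection of [0,1]; derivative `steepness` at the EOI.
    return 1.0 - (1.0 - u) ** steepness


def _warp_times(
    t: np.ndarray,
    eoe_times: np.ndarray,
    eoi_times: np.ndarray,
    exhale_steepness: float,
    inhale_steepness: float,
) -> np.ndarray:
    """Map evaluation times through the per-cycle limb warps.

    Cycles are delimited by consecutive EOE times; each contains one EOI.
    Times before the first / after the last EOE (edge partial cycles) are
    left unwarped.
    """
    if exhale_steepness == 1.0 and inhale_steepness == 1.0:
        return t
    out = t.astype(float).copy()
    for k in range(len(eoe_times) - 1):
        e0, e1 = eoe_times[k], eoe_times[k + 1]
        inside = eoi_times[(eoi_times > e0) & (eoi_times < e1)]
        if inside.size != 1:
            continue
        p = float(inside[0])
        sel = (t >= e0) & (t < e1)
        if not sel.any():
            continue
        ts = t[sel]
        warped = ts.copy()
        inh = ts < p  # inhale limb: EOE -> EOI
        if inh.any():
            u = (p - ts[inh]) / (p - e0)
            warped[inh] = p - _limb_warp(u, inhale_steepness) * (p - e0)
        exh = ~inh  # exhale limb: EOI -> EOE
        if exh.any():
            u = (ts[exh] - p) / (e1 - p)
            warped[exh] = p + _limb_warp(u, exhale_steepness) * (e1 - p)
        out[sel] = warped
    return out


def distort_to_surrogate(
    trace: RespTrace,
    distortion: SurrogateDistortion,
    seed: int,
    timestamps: Optional[np.ndarray] = None,
) -> RespTrace:
    """Derive a distorted surrogate from a trace with ground-truth cycle marks.

    ``output(t) = nonlinearity(source(warp(t + lag)))`` per cycle, plus gain,
    offset and additive noise. With the default ``timestamps=None`` the output
    shares the input's time grid. The exact identity distortion returns a
    sample-for-sample copy.
    """
    has_model = trace.model is not None
    eoi_t = trace.model.eoi_times if has_model else trace.eoi_times
    eoe_t = trace.model.eoe_times if has_model else trace.eoe_times
    if eoi_t.size == 0 or eoe_t.size < 2:
        raise StateError(
            "distort_to_surrogate requires ground-truth cycle marks (EOI and >= 2 EOE)"
        )
    if timestamps is None and distortion.is_identity:
        return trace.copy()
    out_t = trace.timestamps if timestamps is None else np.asarray(timestamps, dtype=float)

    shifted = out_t + distortion.lag
    t_src = _warp_times(
        shifted, np.asarray(eoe_t, float), np.asarray(eoi_t, float),
        distortion.exhale_steepness, distortion.inhale_steepness,
    )
    if has_model and not distortion.is_identity:
        vals = trace.model(t_src)
    else:
        vals = np.interp(t_src, trace.timestamps, trace.amplitudes)

    if distortion.response_exponent != 1.0:
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            y = (vals - lo) / (hi - lo)
            vals = lo + (hi - lo) * y ** distortion.response_exponent
    vals = distortion.gain * vals + distortion.offset
    if distortion.extra_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD15C0]))
        vals = vals + rng.normal(0.0, distortion.extra_noise_sd, vals.size)

    out = RespTrace(
        timestamps=out_t.copy(),
        amplitudes=vals,
        beam_on=None,
        source_kind=trace.source_kind,
        sampling_rate=None,
        model=None,
    )
    # Beam state follows the source's segments by interval membership.
    if trace.beam_on is not None:
        out = out.with_beam_segments(trace.beam_segments())
    # Distorted extrema lead the source's by exactly `lag` (warps fix extrema).
    span = (out_t[0], out_t[-1])
    keep = lambda x: x[(x >= span[0]) & (x <= span[1])]  # noqa: E731
    out = out.with_marks_at(keep(np.asarray(eoi_t) - distortion.lag),
                            keep(np.asarray(eoe_t) - distortion.lag))
    return out


def generate_pair(
    params: BreathingModelParams,
    distortion_a: SurrogateDistortion,
    distortion_b: SurrogateDistortion,
    timeline: Optional[ScanTimeline] = None,
    rate_a: float = DEFAULT_DISPLACEMENT_RATE,
    rate_b: float = DEFAULT_PRESSURE_RATE,
) -> tuple[RespTrace, RespTrace, RespTrace]:
    """Generate (internal_motion, surrogate_A, surrogate_B) sharing t=0.

    Surrogate A is displacement-style at ``rate_a``, B pressure-style at
    ``rate_b``; both are stamped with the timeline's beam segments. The seed
    is split deterministically between the motion and each surrogate's noise.
    """
    internal = generate_internal_motion(params)
    t_a = uniform_timestamps(params.duration, rate_a)
    t_b = uniform_timestamps(params.duration, rate_b)
    surr_a = distort_to_surrogate(internal, distortion_a, seed=params.seed * 2 + 1,
                                  timestamps=t_a)
    surr_b = distort_to_surrogate(internal, distortion_b, seed=params.seed * 2 + 2,
                                  timestamps=t_b)
    surr_a.source_kind = "displacement"
    surr_b.source_kind = "pressure"
    if timeline is not None:
        segs = list(timeline.beam_segments)
        surr_a = surr_a.with_beam_segments(segs)
        surr_b = surr_b.with_beam_segments(segs)
    else:
        surr_a.beam_on = np.zeros(surr_a.n_samples, dtype=bool)
        surr_b.beam_on = np.zeros(surr_b.n_samples, dtype=bool)
    return internal, surr_a, surr_b


def identity_distortion() -> SurrogateDistortion:
    """The distortion that leaves a trace unchanged."""
    return SurrogateDistortion()


def write_ground_truth(trace: RespTrace, path) -> None:
    """Write the internal-motion trace as TSV: time, amplitude, depth fraction."""
    a = trace.amplitudes
    lo, hi = float(a.min()), float(a.max())
    frac = (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)
    with open(path, "w") as fh:
        fh.write("time_s\tinternal_amplitude\tamplitude_fraction\n")
        for t, amp, f in zip(trace.timestamps, a, frac):
            fh.write(f"{float(t)!r}\t{float(amp)!r}\t{float(f)!r}\n")


def read_ground_truth(path) -> RespTrace:
    """Read a ground-truth TSV written by :func:`write_ground_truth`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    return RespTrace(timestamps=data[:, 0], amplitudes=data[:, 1],
                     beam_on=np.zeros(data.shape[0], dtype=bool))
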