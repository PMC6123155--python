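"""End-to-end study orchestration: synthetic cohort -> full discrepancy report.

``run_full_study`` simulates N synthetic "patients" (per-patient distortion
parameters drawn from configured ranges), runs every analysis stage on each,
and emits a deterministic JSON report bundle: cohort period/depth statistics,
per-patient phase shifts (seconds and % of period), limb-steepness verdict
counts, per-phase phantom mismatch ranges, and gating mismatch.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io_formats
from .cycle_shape import average_shape, compare_limbs, extract_aligned_cycles
from .errors import RespSurroError
from .gating_analysis import GatingWindow, mismatch
from .phantom_4d import (
    AcquisitionSchedule,
    PhantomGeometry,
    compare_sortings,
    reconstruct_phases,
    simulate_acquisition,
)
from .phase_shift import ellipse_phase_shift, eoi_latency_shift
from .synthetic_respiration import (
    BreathingModelParams,
    ScanTimeline,
    SurrogateDistortion,
    generate_pair,
    write_ground_truth,
)
from .trace_analysis import (
    detect_extrema,
    normalize_global,
    paired_cycle_stats,
    segment_cycles,
    trace_correlation,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class CohortRanges(BaseModel):
    """Per-patient parameter draws for the synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = 5
    mean_period_range: tuple[float, float] = (2.5, 5.6)
    period_sd_frac: float = 0.05  # period_sd as a fraction of the mean period
    depth_sd_frac: float = 0.05
    lag_mean: float = 0.2  # s, applied to surrogate B (B leads)
    lag_sd: float = 0.1
    exhale_steepness_range: tuple[float, float] = (1.3, 2.0)
    inhale_steepness_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 1.0


class StudyConfig(BaseModel):
    """Single-YAML configuration of the full pipeline. Unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "study_out"
    log_level: str = "INFO"
    duration: float = 60.0
    cohort: CohortRanges = Field(default_factory=CohortRanges)
    simulate: BreathingModelParams = Field(default_factory=BreathingModelParams)
    distortion_a: SurrogateDistortion = Field(default_factory=SurrogateDistortion)
    distortion_b: SurrogateDistortion = Field(default_factory=SurrogateDistortion)
    timeline: Optional[ScanTimeline] = None
    geometry: PhantomGeometry = Field(default_factory=PhantomGeometry)
    dwell_periods: float = 1.5  # dwell duration as a multiple of the mean period
    frame_rate: float = 2.0
    gate: GatingWindow = Field(default_factory=lambda: GatingWindow(lower=0.0, upper=30.0))
    write_traces: bool = False
    make_plots: bool = False


def _analyze_pair(surr_a, surr_b, internal, config: StudyConfig) -> dict:
    """All analysis stages for one patient; returns a JSON-ready dict."""
    na, nb = normalize_global(surr_a), normalize_global(surr_b)
    ex_a, ex_b = detect_extrema(na), detect_extrema(nb)
    cyc_a = segment_cycles(na, ex_a)
    cyc_b = segment_cycles(nb, ex_b)
    stats = paired_cycle_stats(cyc_a, cyc_b)
    r = trace_correlation(na, nb)
    # shift(B relative to A): positive = B reaches EOI earlier
    latency = eoi_latency_shift(nb, na, ex_b, ex_a)
    ellipse = ellipse_phase_shift(nb, na, stats, latency=latency)
    shape_a = average_shape(extract_aligned_cycles(na, ex_a))
    shape_b = average_shape(extract_aligned_cycles(nb, ex_b))
    limbs = compare_limbs(shape_a, shape_b)

    # phantom: same frames, sorted by each surrogate
    dwell = config.dwell_periods * stats.period_mean
    n_pos = min(config.geometry.n_couch_positions,
                max(1, int(internal.duration // dwell)))
    schedule = AcquisitionSchedule.sequential(n_pos, dwell, frame_rate=config.frame_rate)
    frames = simulate_acquisition(internal, config.geometry, schedule)
    res_a = reconstruct_phases(frames, na, ex_a)
    res_b = reconstruct_phases(frames, nb, ex_b)
    phantom = compare_sortings(res_a, res_b)

    gate = mismatch(config.gate, na, nb, internal,
                    excursion_mm=config.geometry.diaphragm_excursion)

    return {
        "correlation": r,
        "cycle_stats": {
            "period_mean_s": stats.period_mean, "period_sd_s": stats.period_sd,
            "depth_mean": stats.depth_mean, "depth_sd": stats.depth_sd,
            "n_cycles": stats.n_cycles,
            "t_diff_range_s": list(stats.t_diff_range),
            "d_diff_range": list(stats.d_diff_range),
        },
        "phase_shift": {
            "mean_lag_s": latency.mean_lag, "sd_lag_s": latency.sd_lag,
            "mean_lag_pct": latency.mean_lag_pct, "sd_lag_pct": latency.sd_lag_pct,
            "ellipse_mean_lag_s": ellipse.mean_lag,
            "ellipse_degenerate": ellipse.degenerate,
        },
        "limb_comparison": {
            "exhale_verdict": limbs.exhale_verdict, "inhale_verdict": limbs.inhale_verdict,
            "exhale_score": limbs.exhale_score, "inhale_score": limbs.inhale_score,
        },
        "phantom": {"A": res_a.as_dict(), "B": res_b.as_dict(),
                    "mismatch": phantom.as_dict()},
        "gating": gate.as_dict(),
    }


def run_full_study(config: StudyConfig) -> dict:
    """Simulate and analyze a cohort; write report.json; return the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0407]))
    patients = []
    for pid in range(config.cohort.n_patients):
        mean_period = float(rng.uniform(*config.cohort.mean_period_range))
        lag = max(0.0, float(rng.normal(config.cohort.lag_mean, config.cohort.lag_sd)))
        exh = float(rng.uniform(*config.cohort.exhale_steepness_range))
        inh = float(rng.uniform(*config.cohort.inhale_steepness_range))
        params = config.simulate.model_copy(update={
            "mean_period": mean_period,
            "period_sd": config.cohort.period_sd_frac * mean_period,
            "depth_sd": config.cohort.depth_sd_frac * config.simulate.mean_depth,
            "noise_sd": 0.0,
            "duration": config.duration,
            "seed": config.seed * 1000 + pid,
        })
        dist_a = config.distortion_a.model_copy(
            update={"extra_noise_sd": config.cohort.noise_sd})
        dist_b = config.distortion_b.model_copy(update={
            "lag": lag, "exhale_steepness": exh, "inhale_steepness": inh,
            "extra_noise_sd": config.cohort.noise_sd,
        })
        internal, surr_a, surr_b = generate_pair(params, dist_a, dist_b, config.timeline)
        try:
            result = _analyze_pair(surr_a, surr_b, internal, config)
        except RespSurroError as exc:
            raise RespSurroError(f"patient {pid}: {type(exc).__name__}: {exc}") from exc
        result["patient_id"] = pid
        result["injected"] = {"lag_s": lag, "exhale_steepness": exh,
                              "inhale_steepness": inh, "mean_period_s": mean_period}
        patients.append(result)
        if config.write_traces:
            io_formats.write_trace(surr_a, out_dir / f"patient{pid:02d}_A.vxp",
                                   io_formats.RPM_DIALECT)
            io_formats.write_trace(surr_b, out_dir / f"patient{pid:02d}_B.csv",
                                   io_formats.ANZAI_DIALECT)
            write_ground_truth(internal, out_dir / f"patient{pid:02d}_GT.tsv")

    lags = np.array([p["phase_shift"]["mean_lag_s"] for p in patients])
    pcts = np.array([p["phase_shift"]["mean_lag_pct"] for p in patients])
    verdict_counts = {"exhale": {}, "inhale": {}}
    for limb in verdict_counts:
        for p in patients:
            v = p["limb_comparison"][f"{limb}_verdict"]
            verdict_counts[limb][v] = verdict_counts[limb].get(v, 0) + 1
    vol_ranges = [p["phantom"]["mismatch"]["volume_diff_range_pct"] for p in patients]
    pos_ranges = [p["phantom"]["mismatch"]["position_diff_range_mm"] for p in patients]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_patients": len(patients),
        "cohort_summary": {
            "mean_lag_s": float(lags.mean()),
            "sd_lag_s": float(np.std(lags, ddof=1)) if lags.size >= 2 else 0.0,
            "mean_lag_pct": float(pcts.mean()),
            "sd_lag_pct": float(np.std(pcts, ddof=1)) if pcts.size >= 2 else 0.0,
            "limb_verdicts": {k: dict(sorted(v.items())) for k, v in verdict_counts.items()},
            "volume_diff_range_pct": [float(np.mean([r[0] for r in vol_ranges])),
                                      float(np.mean([r[1] for r in vol_ranges]))],
            "position_diff_range_mm": [float(np.mean([r[0] for r in pos_ranges])),
                                       float(np.mean([r[1] for r in pos_ranges]))],
        },
        "patients": patients,
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    if config.make_plots:
        _make_plots(report, out_dir)
    return report


def _make_plots(report: dict, out_dir: Path) -> None:  # pragma: no cover - optional
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pids = [p["patient_id"] for p in report["patients"]]
    lags = [p["phase_shift"]["mean_lag_s"] for p in report["patients"]]
    sds = [p["phase_shift"]["sd_lag_s"] for p in report["patients"]]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(pids, lags, yerr=sds, color="tab:blue")
    ax.set_xlabel("patient")
    ax.set_ylabel("phase shift (s)")
    fig.tight_layout()
    fig.savefig(out_dir / "phase_shift.png", dpi=100)
    plt.close(fig)
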