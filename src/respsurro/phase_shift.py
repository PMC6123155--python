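"""Lag estimation between two traces: per-cycle EOI latency and ellipse fit.

Sign convention (fixed package-wide): positive lag means the FIRST argument
reaches end-of-inhalation earlier than the second.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .errors import FitError, InsufficientDataError
from .trace import RespTrace
from .trace_analysis import CycleStats, ExtremaSet, common_grid, normalize_global

SIGN_CONVENTION = "positive = first argument reaches EOI earlier"


@dataclasses.dataclass
class EllipseParams:
    """Geometric parameters of a direct least-squares conic fit."""

    center: np.ndarray  # (2,)
    semi_major: float
    semi_minor: float
    orientation: float  # major-axis angle, in (-pi/2, pi/2]
    implied_phase: float = float("nan")  # radians; set by ellipse_phase_shift


@dataclasses.dataclass
class PhaseShiftResult:
    per_cycle_lags: np.ndarray  # seconds, signed
    mean_lag: float
    sd_lag: float
    mean_lag_pct: float  # % of the local respiratory period
    sd_lag_pct: float
    n_pairs: int
    method: str  # "eoi_latency" | "ellipse"
    sign_convention: str = SIGN_CONVENTION
    ellipse: Optional[EllipseParams] = None
    degenerate: bool = False  # ellipse route: near-degenerate line, phi forced to 0


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size >= 2 else 0.0


# ------------------------------------------------------------- EOI latency
def eoi_latency_shift(
    a: RespTrace,
    b: RespTrace,
    extrema_a: ExtremaSet,
    extrema_b: ExtremaSet,
) -> PhaseShiftResult:
    """Per-cycle lag: ``lag_i = t_EOI_b(i) - t_EOI_a(i)`` over paired EOIs.

    EOIs are paired one-to-one by nearest time within half the local period;
    percentages use the first trace's per-cycle EOI-to-EOI periods.
    """
    ta = extrema_a.eoi_times
    tb = extrema_b.eoi_times
    if ta.size < 2 or tb.size < 2:
        raise InsufficientDataError("need >= 2 EOIs in each trace")
    periods_a = np.diff(ta)
    # local period of a's EOI i: gap to next EOI (last uses the previous gap)
    local_T = np.append(periods_a, periods_a[-1])
    cand = []
    for i in range(ta.size):
        for j in range(tb.size):
            dt = abs(tb[j] - ta[i])
            if dt <= local_T[i] / 2.0:
                cand.append((dt, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    if len(pairs) < 2:
        raise InsufficientDataError("fewer than 2 paired EOIs")
    pairs.sort()
    lags = np.array([tb[j] - ta[i] for i, j in pairs])
    pcts = np.array([100.0 * (tb[j] - ta[i]) / local_T[i] for i, j in pairs])
    return PhaseShiftResult(
        per_cycle_lags=lags,
        mean_lag=float(lags.mean()), sd_lag=_sd(lags),
        mean_lag_pct=float(pcts.mean()), sd_lag_pct=_sd(pcts),
        n_pairs=len(pairs), method="eoi_latency",
    )


# -------------------------------------------------------------- ellipse fit
def fit_ellipse(x: np.ndarray, y: np.ndarray) -> EllipseParams:
    """Direct least-squares conic fit constrained to an ellipse.

    Solves the scatter-matrix generalized eigenproblem (numerically stable
    block partition), so the returned conic is an ellipse by construction.
    Requires >= 6 non-collinear points; invariant under point permutation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise FitError("x and y must have equal length")
    if x.size < 6:
        raise FitError(f"need >= 6 points, got {x.size}")
    # center for conditioning
    mx, my = x.mean(), y.mean()
    xc, yc = x - mx, y - my
    # collinearity check via the 2x2 covariance
    cov = np.cov(np.vstack([xc, yc]))
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[1], 1.0):
        raise FitError("points are (nearly) collinear; no ellipse fit")

    D1 = np.column_stack([xc * xc, xc * yc, yc * yc])
    D2 = np.column_stack([xc, yc, np.ones_like(xc)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"degenerate scatter matrix: {exc}") from None
    M = S1 + S2 @ T
    # premultiply by inv(C1), C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    w, v = np.linalg.eig(M)
    # ellipse condition 4ac - b^2 > 0
    cond = 4.0 * v[0] * v[2] - v[1] ** 2
    good = np.where(np.isreal(w) & (cond > 0))[0]
    if good.size == 0:
        raise FitError("no ellipse solution (degenerate data)")
    a1 = np.real(v[:, good[0]])
    a2 = T @ a1
    A, B, C = a1
    D, E, F = a2
    # translate back to original coordinates
    D0 = D - 2 * A * mx - B * my
    E0 = E - 2 * C * my - B * mx
    F0 = F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my
    return _conic_to_ellipse(A, B, C, D0, E0, F0)


def _conic_to_ellipse(A, B, C, D, E, F) -> EllipseParams:
    den = B * B - 4 * A * C
    if den >= 0:
        raise FitError("conic is not an ellipse")
    x0 = (2 * C * D - B * E) / den
    y0 = (2 * A * E - B * D) / den
    Fc = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(Q)
    ax2 = -Fc / lam  # squared semi-axes
    if np.any(ax2 <= 0):
        raise FitError("degenerate ellipse (non-positive axis)")
    axes = np.sqrt(ax2)
    order = np.argsort(axes)[::-1]  # major first
    semi_major, semi_minor = float(axes[order[0]]), float(axes[order[1]])
    vmaj = vec[:, order[0]]
    theta = float(np.arctan2(vmaj[1], vmaj[0]))
    # fold into (-pi/2, pi/2]
    while theta <= -np.pi / 2:
        theta += np.pi
    while theta > np.pi / 2:
        theta -= np.pi
    return EllipseParams(center=np.array([x0, y0]), semi_major=semi_major,
                         semi_minor=semi_minor, orientation=theta)


def _angdist(t1: float, t2: float) -> float:
    """Distance between undirected axis angles (mod pi)."""
    d = abs(t1 - t2) % np.pi
    return min(d, np.pi - d)


def ellipse_phase_shift(
    a: RespTrace,
    b: RespTrace,
    stats: CycleStats,
    latency: Optional[PhaseShiftResult] = None,
) -> PhaseShiftResult:
    """Mean lag from the ellipse fitted to the (a(t), b(t)) scatter.

    Both traces are globally renormalized to 0-100 and resampled onto a
    common grid. For equal-amplitude quasi-sinusoidal signals the implied
    phase is ``phi = 2 atan(r_anti / r_diag)`` where ``r_diag`` is the
    semi-axis nearer the +45 deg diagonal; ``phi in (pi/2, pi]`` falls out
    automatically for anticorrelated pairs. The lag in seconds uses
    ``stats.period_mean``; the sign is copied from ``latency`` when given,
    else the magnitude is reported. Near-degenerate (line-like) scatter is
    flagged with ``phi = 0``, not raised.
    """
    an = normalize_global(a)
    bn = normalize_global(b)
    grid = common_grid(an, bn)
    xa = an.values_at(grid)
    xb = bn.values_at(grid)
    degenerate = False
    phi = 0.0
    ellipse: Optional[EllipseParams] = None
    try:
        ellipse = fit_ellipse(xa, xb)
        ratio = ellipse.semi_minor / ellipse.semi_major
        if ratio < 1e-4:
            degenerate = True
        else:
            if _angdist(ellipse.orientation, np.pi / 4) <= _angdist(
                ellipse.orientation + np.pi / 2, np.pi / 4
            ):
                r_diag, r_anti = ellipse.semi_major, ellipse.semi_minor
            else:
                r_diag, r_anti = ellipse.semi_minor, ellipse.semi_major
            phi = float(2.0 * np.arctan2(r_anti, r_diag))
            ellipse.implied_phase = phi
    except FitError:
        degenerate = True
    if degenerate:
        phi = 0.0
        if ellipse is not None:
            ellipse.implied_phase = 0.0
    sign = 1.0
    if latency is not None and latency.mean_lag < 0:
        sign = -1.0
    mean_lag = sign * phi * stats.period_mean / (2.0 * np.pi)
    return PhaseShiftResult(
        per_cycle_lags=np.empty(0),
        mean_lag=float(mean_lag), sd_lag=float("nan"),
        mean_lag_pct=float(sign * 100.0 * phi / (2.0 * np.pi)),
        sd_lag_pct=float("nan"),
        n_pairs=0, method="ellipse", ellipse=ellipse, degenerate=degenerate,
    )
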