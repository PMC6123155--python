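"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain nested loops over explicit definitions,
deliberately sharing no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np

PEAK = 1
VALLEY = -1


def brute_force_window_candidates(t, a, window, kind):
    """Exhaustive scan: i is a candidate iff a[i] beats every other sample in
    the +-window/2 time window (strictly better than earlier samples, at
    least as good as later ones). A candidate needs full window support
    inside the trace span and must weakly dominate its immediate
    neighbors."""
    n = len(t)
    out = []
    for i in range(1, n - 1):
        if kind == PEAK and (a[i] < a[i - 1] or a[i] < a[i + 1]):
            continue
        if kind == VALLEY and (a[i] > a[i - 1] or a[i] > a[i + 1]):
            continue
        if t[i] - t[0] < window / 2.0 or t[-1] - t[i] < window / 2.0:
            continue
        ok = True
        for j in range(n):
            if j == i or abs(t[j] - t[i]) > window / 2.0 + 1e-9:
                continue
            if kind == PEAK:
                if j < i and a[j] >= a[i]:
                    ok = False
                if j > i and a[j] > a[i]:
                    ok = False
            else:
                if j < i and a[j] <= a[i]:
                    ok = False
                if j > i and a[j] < a[i]:
                    ok = False
            if not ok:
                break
        if ok:
            out.append(i)
    return out


def brute_force_extrema(t, a, window, min_prominence):
    """Full naive pipeline: window scan, alternation collapse, prominence
    pruning (weakest-first). Returns (peak_indices, valley_indices)."""
    events = [(i, PEAK) for i in brute_force_window_candidates(t, a, window, PEAK)]
    events += [(i, VALLEY) for i in brute_force_window_candidates(t, a, window, VALLEY)]
    events.sort()

    def collapse(evs):
        res = []
        for idx, kind in evs:
            if res and res[-1][1] == kind:
                pidx, _ = res[-1]
                if (kind == PEAK and a[idx] > a[pidx]) or (kind == VALLEY and a[idx] < a[pidx]):
                    res[-1] = (idx, kind)
            else:
                res.append((idx, kind))
        return res

    events = collapse(events)
    while True:
        scores = []
        for j, (i, kind) in enumerate(events):
            nbrs = [events[k][0] for k in (j - 1, j + 1) if 0 <= k < len(events)]
            if not nbrs:
                scores.append(float("inf"))
            elif kind == PEAK:
                scores.append(a[i] - max(a[k] for k in nbrs))
            else:
                scores.append(min(a[k] for k in nbrs) - a[i])
        worst = None
        for j, s in enumerate(scores):
            if s < min_prominence and (worst is None or s < scores[worst]):
                worst = j
        if worst is None:
            break
        del events[worst]
        events = collapse(events)
    peaks = [i for i, k in events if k == PEAK]
    valleys = [i for i, k in events if k == VALLEY]
    return peaks, valleys


def brute_force_phase_sort(t, a, eoi_indices, eoe_indices):
    """Naive per-sample local-amplitude phase sorting.

    Returns dict sample_index -> (fraction, limb, phase_index) for every
    retained sample; mirrors the documented rules (EOI -> exhale/phase 1,
    EOE -> inhale/phase 6, nearest nominal level, ties to lower phase index,
    clamp tolerance 0.02).
    """
    events = sorted([(i, "EOI") for i in eoi_indices] + [(i, "EOE") for i in eoe_indices])
    exhale_levels = [(1.0, 1), (0.8, 2), (0.6, 3), (0.4, 4), (0.2, 5), (0.0, 6)]
    inhale_levels = [(0.0, 6), (0.2, 7), (0.4, 8), (0.6, 9), (0.8, 10)]
    out = {}
    for (i0, k0), (i1, k1) in zip(events, events[1:]):
        if k0 == k1:
            continue
        if k0 == "EOE":  # inhale limb EOE -> EOI
            limb = "inhale"
            a_eoe, a_eoi = a[i0], a[i1]
            levels = inhale_levels
        else:
            limb = "exhale"
            a_eoi, a_eoe = a[i0], a[i1]
            levels = exhale_levels
        if a_eoi - a_eoe <= 0:
            continue
        for i in range(i0, i1):  # limb samples [start, end)
            f = (a[i] - a_eoe) / (a_eoi - a_eoe)
            if f < -0.02 or f > 1.02:
                continue
            f = min(max(f, 0.0), 1.0)
            best = None
            bestd = None
            for level, phase in levels:
                d = abs(f - level)
                if bestd is None or d < bestd:  # strict: earlier entry wins ties
                    best, bestd = phase, d
            out[i] = (f, limb, best)
    # trailing extremum closes the final limb
    if len(events) >= 2 and events[-1][1] != events[-2][1]:
        i, k = events[-1]
        if k == "EOI":
            out[i] = (1.0, "exhale", 1)
        else:
            out[i] = (0.0, "inhale", 6)
    return out


def brute_force_beam_membership(times, segments):
    """Per-sample half-open [on, off) membership check."""
    out = []
    for t in times:
        on = False
        for s, e in segments:
            if s <= t < e:
                on = True
        out.append(on)
    return np.array(out, dtype=bool)


def brute_force_half_depth_crossing(t, a, eoi_idx, end_idx):
    """Time from the EOI to the 50%-of-depth crossing on the exhale limb,
    found by linear scan + interpolation between bracketing samples."""
    depth = a[eoi_idx] - a[end_idx]
    target = a[eoi_idx] - 0.5 * depth
    for i in range(eoi_idx, end_idx):
        if a[i] >= target >= a[i + 1]:
            frac = (a[i] - target) / (a[i] - a[i + 1]) if a[i] != a[i + 1] else 0.0
            return t[i] + frac * (t[i + 1] - t[i]) - t[eoi_idx]
    return np.nan
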