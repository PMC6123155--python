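import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respsurro import (
    BreathingModelParams,
    RespTrace,
    SurrogateDistortion,
    detect_extrema,
    generate_internal_motion,
    generate_pair,
    normalize_global,
    paired_cycle_stats,
    segment_cycles,
    trace_correlation,
)
from respsurro.errors import (
    DegenerateInputError,
    InsufficientDataError,
    PairingError,
)

from conftest import make_sinusoid
from oracles import brute_force_extrema


def random_breathing_trace(seed: int) -> RespTrace:
    rng = np.random.default_rng(seed)
    p = BreathingModelParams(
        mean_period=float(rng.uniform(2.5, 5.6)),
        period_sd=float(rng.uniform(0.0, 0.4)),
        depth_sd=float(rng.uniform(0.0, 8.0)),
        noise_sd=float(rng.uniform(0.0, 2.0)),
        plateau_exponent=float(rng.uniform(0.8, 2.0)),
        duration=45.0,
        seed=seed,
    )
    return normalize_global(generate_internal_motion(p))


class TestNormalizeGlobal:
    def test_simple(self):
        tr = RespTrace(timestamps=[0.0, 0.1, 0.2], amplitudes=[2.0, 4.0, 6.0])
        assert np.allclose(normalize_global(tr).amplitudes, [0.0, 50.0, 100.0])

    def test_idempotent(self):
        tr = RespTrace(timestamps=[0.0, 0.1, 0.2], amplitudes=[0.0, 25.0, 100.0])
        out = normalize_global(normalize_global(tr))
        assert np.allclose(out.amplitudes, tr.amplitudes)

    def test_negative_values(self):
        tr = RespTrace(timestamps=[0.0, 0.1, 0.2], amplitudes=[-1.0, 0.0, 3.0])
        assert np.allclose(normalize_global(tr).amplitudes, [0.0, 25.0, 100.0])

    def test_constant_trace_rejected(self):
        tr = RespTrace(timestamps=[0.0, 0.1], amplitudes=[5.0, 5.0])
        with pytest.raises(DegenerateInputError):
            normalize_global(tr)

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        tr = RespTrace(timestamps=np.arange(50) * 0.04, amplitudes=a)
        out = normalize_global(tr).amplitudes
        assert np.array_equal(np.argsort(a, kind="stable"), np.argsort(out, kind="stable"))


class TestDetectExtrema:
    def test_sinusoid_positions(self):
        tr = make_sinusoid()  # 50+50sin(2pi t/4), EOI at 1,5,9,...
        ex = detect_extrema(tr, window=1.5)
        dt = tr.median_dt
        expected_eoi = np.array([1.0, 5.0, 9.0, 13.0, 17.0])
        expected_eoe = np.array([3.0, 7.0, 11.0, 15.0, 19.0])
        assert ex.eoi_times.size == 5
        assert np.all(np.abs(ex.eoi_times - expected_eoi) <= dt)
        assert np.all(np.abs(ex.eoe_times - expected_eoe) <= dt)

    def test_noise_preserves_counts(self):
        tr = make_sinusoid()
        rng = np.random.default_rng(42)
        noisy = tr.copy()
        noisy.amplitudes = noisy.amplitudes + rng.normal(0, 2.0, tr.n_samples)
        ex_clean = detect_extrema(tr, window=1.5)
        ex_noisy = detect_extrema(noisy, window=1.5)
        assert ex_noisy.eoi_times.size == ex_clean.eoi_times.size
        assert ex_noisy.eoe_times.size == ex_clean.eoe_times.size

    def test_constant_trace(self):
        tr = RespTrace(timestamps=np.arange(100) * 0.04,
                       amplitudes=np.full(100, 50.0))
        with pytest.raises(DegenerateInputError):
            detect_extrema(tr, window=1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence(self, seed):
        tr = random_breathing_trace(seed)
        window, prom = 1.2, 10.0
        ex = detect_extrema(tr, window=window, min_prominence=prom)
        peaks, valleys = brute_force_extrema(tr.timestamps, tr.amplitudes, window, prom)
        assert list(ex.eoi_indices) == peaks
        assert list(ex.eoe_indices) == valleys

    def test_lag_invariant_counts(self):
        p = BreathingModelParams(duration=40.0, seed=5, period_sd=0.2)
        tr = normalize_global(generate_internal_motion(p))
        from respsurro import distort_to_surrogate
        base = generate_internal_motion(p)
        lagged = normalize_global(distort_to_surrogate(base, SurrogateDistortion(lag=0.3), 0))
        assert detect_extrema(tr).eoi_times.size == detect_extrema(lagged).eoi_times.size

    def test_override_replaces_nearest(self):
        tr = make_sinusoid()
        ex = detect_extrema(tr, window=1.5)
        # drag the EOI near t=5 to t=5.2
        ex2 = detect_extrema(tr, window=1.5, overrides=[(5.2, "EOI")])
        assert 5.2 in np.round(ex2.eoi_times, 6)
        assert ex2.eoi_times.size == ex.eoi_times.size

    def test_alternation_validated(self):
        tr = random_breathing_trace(3)
        ex = detect_extrema(tr)
        ev = ex.events()
        kinds = [k for _, k in ev]
        assert all(k1 != k2 for k1, k2 in zip(kinds, kinds[1:]))


class TestSegmentCycles:
    def test_sinusoid_periods(self):
        tr = make_sinusoid()
        cycles = segment_cycles(tr, detect_extrema(tr, window=1.5))
        assert len(cycles) == 4
        for c in cycles:
            assert c.period_T == pytest.approx(4.0, abs=tr.median_dt)

    def test_sinusoid_depths_after_normalization(self):
        tr = normalize_global(make_sinusoid())
        cycles = segment_cycles(tr, detect_extrema(tr, window=1.5))
        for c in cycles:
            assert c.depth_d == pytest.approx(100.0, abs=1.0)

    def test_odd_cycle_detected(self):
        # one 6 s cycle among 4 s cycles
        t = np.arange(0, 26, 0.04)
        phase = np.where(t < 8, 2 * np.pi * t / 4,
                         np.where(t < 14, 2 * np.pi * (8 / 4) + 2 * np.pi * (t - 8) / 6,
                                  2 * np.pi * (8 / 4 + 1) + 2 * np.pi * (t - 14) / 4))
        a = 50 - 50 * np.cos(phase)  # EOE at t=0
        tr = RespTrace(timestamps=t, amplitudes=a)
        cycles = segment_cycles(tr, detect_extrema(tr))
        periods = sorted(c.period_eoe for c in cycles)
        assert periods[-1] == pytest.approx(6.0, abs=2 * tr.median_dt)

    def test_insufficient_eoi(self):
        tr = make_sinusoid(duration=4.0)
        ex = detect_extrema(tr, window=1.5)
        if ex.eoi_indices.size < 2:
            with pytest.raises(InsufficientDataError):
                segment_cycles(tr, ex)


class TestPairedCycleStats:
    def _cycles(self, seed=0, lag=0.0):
        p = BreathingModelParams(duration=40.0, seed=seed, period_sd=0.2)
        _, a, b = generate_pair(p, SurrogateDistortion(), SurrogateDistortion(lag=lag))
        na, nb = normalize_global(a), normalize_global(b)
        return (segment_cycles(na, detect_extrema(na)),
                segment_cycles(nb, detect_extrema(nb)))

    def test_identical_traces_zero_ranges(self):
        ca, _ = self._cycles()
        stats = paired_cycle_stats(ca, ca)
        assert stats.t_diff_range == (0.0, 0.0)
        assert stats.d_diff_range == (0.0, 0.0)

    def test_lag_preserves_periods(self):
        ca, cb = self._cycles(lag=0.2)
        stats = paired_cycle_stats(ca, cb)
        dt = 1 / 25.0 + 1 / 40.0
        assert abs(stats.t_diff_range[0]) <= 2 * dt
        assert abs(stats.t_diff_range[1]) <= 2 * dt

    def test_unpairable_raises(self):
        ca, _ = self._cycles()
        shifted = [type(c)(start_eoe_time=c.start_eoe_time + 500.0,
                           eoi_time=c.eoi_time + 500.0,
                           end_eoe_time=c.end_eoe_time + 500.0,
                           period_T=c.period_T, period_eoe=c.period_eoe,
                           depth_d=c.depth_d) for c in ca]
        with pytest.raises(PairingError):
            paired_cycle_stats(ca, shifted)

    def test_depth_scaling_absorbed_by_global_normalization(self):
        # global renormalization maps both to 0-100, so a uniform 0.9x gain
        # disappears; depth differences reflect only per-cycle structure
        p = BreathingModelParams(duration=40.0, seed=3, depth_sd=5.0)
        _, a, b = generate_pair(p, SurrogateDistortion(),
                                SurrogateDistortion(gain=0.9))
        na, nb = normalize_global(a), normalize_global(b)
        ca = segment_cycles(na, detect_extrema(na))
        cb = segment_cycles(nb, detect_extrema(nb))
        stats = paired_cycle_stats(ca, cb)
        assert max(abs(stats.d_diff_range[0]), abs(stats.d_diff_range[1])) < 3.0


class TestTraceCorrelation:
    def test_self_correlation(self, sinusoid):
        assert trace_correlation(sinusoid, sinusoid) == pytest.approx(1.0)

    def test_negated(self, sinusoid):
        neg = sinusoid.copy()
        neg.amplitudes = -neg.amplitudes
        assert trace_correlation(sinusoid, neg) == pytest.approx(-1.0)

    @pytest.mark.parametrize("phi", [0.345, 0.1, 1.0, 2.0])
    def test_lagged_sinusoids_cos_phi(self, phi):
        # over whole periods, corr(sin(x), sin(x - phi)) = cos(phi)
        period, duration = 4.0, 40.0
        a = make_sinusoid(period=period, duration=duration, rate=50.0)
        b = make_sinusoid(period=period, duration=duration, rate=50.0, phase=-phi)
        assert trace_correlation(a, b) == pytest.approx(np.cos(phi), abs=2e-3)

    def test_affine_invariance(self, sinusoid):
        b = sinusoid.copy()
        b.amplitudes = 3.0 * b.amplitudes + 7.0
        assert trace_correlation(sinusoid, b) == pytest.approx(1.0)

    def test_symmetry(self):
        a = random_breathing_trace(1)
        b = random_breathing_trace(2)
        assert trace_correlation(a, b) == pytest.approx(trace_correlation(b, a))

    def test_zero_variance(self, sinusoid):
        flat = RespTrace(timestamps=sinusoid.timestamps,
                         amplitudes=np.full(sinusoid.n_samples, 1.0))
        with pytest.raises(DegenerateInputError):
            trace_correlation(sinusoid, flat)

    def test_no_overlap(self, sinusoid):
        other = RespTrace(timestamps=sinusoid.timestamps + 100.0,
                          amplitudes=sinusoid.amplitudes)
        with pytest.raises(DegenerateInputError):
            trace_correlation(sinusoid, other)


@settings(max_examples=20, deadline=None)
@given(gain=st.floats(0.1, 10.0), offset=st.floats(-50.0, 50.0))
def test_correlation_invariant_under_positive_affine(gain, offset):
    a = make_sinusoid(duration=12.0)
    b = a.copy()
    b.amplitudes = gain * b.amplitudes + offset
    assert trace_correlation(a, b) == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_normalize_bounds(seed):
    tr = random_breathing_trace(seed % 50)
    out = normalize_global(tr)
    assert out.amplitudes.min() == pytest.approx(0.0)
    assert out.amplitudes.max() == pytest.approx(100.0)
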