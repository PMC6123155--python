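import numpy as np
import pytest

from respsurro import (
    AcquisitionSchedule,
    PhantomGeometry,
    RespTrace,
    compare_sortings,
    detect_extrema,
    normalize_global,
    reconstruct_phases,
    simulate_acquisition,
)
from respsurro.errors import DataInsufficiencyError, ParameterError, TraceValidationError
from respsurro.phase_sorting import EXHALE_LEVELS, INHALE_LEVELS

from conftest import make_raised_cosine


def dense_sinusoid_setup(duration=130.0, period=4.0, lag=0.0,
                         n_couch=8, dwell=8.0, frame_rate=20.0):
    """Internal raised-cosine phantom drive plus a (possibly lagged) surrogate.

    A positive lag makes the surrogate reach each EOI earlier (it reads the
    internal motion `lag` seconds ahead).
    """
    internal = make_raised_cosine(period=period, duration=duration, rate=50.0)
    t = internal.timestamps
    surr = RespTrace(
        timestamps=t,
        amplitudes=100.0 * (1.0 - np.cos(2 * np.pi * (t + lag) / period)) / 2.0,
    )
    geometry = PhantomGeometry(n_couch_positions=n_couch)
    schedule = AcquisitionSchedule.sequential(n_couch, dwell, frame_rate=frame_rate)
    frames = simulate_acquisition(internal, geometry, schedule)
    ns = normalize_global(surr)
    return frames, ns, detect_extrema(ns), geometry


class TestSimulateAcquisition:
    def test_frame_count(self):
        frames, *_ = dense_sinusoid_setup(n_couch=5, dwell=8.0, frame_rate=2.0)
        assert frames.frame_time.size == 5 * int(8.0 * 2.0)

    def test_positions_span_base_to_excursion(self):
        frames, _, _, geom = dense_sinusoid_setup()
        assert frames.true_position.min() == pytest.approx(
            geom.diaphragm_base_position, abs=0.1)
        assert frames.true_position.max() == pytest.approx(
            geom.diaphragm_base_position + geom.diaphragm_excursion, abs=0.1)

    def test_schedule_exceeding_span_rejected(self):
        internal = make_raised_cosine(duration=20.0)
        schedule = AcquisitionSchedule.sequential(10, 8.0)
        with pytest.raises(TraceValidationError):
            simulate_acquisition(internal, PhantomGeometry(), schedule)

    def test_geometry_validation(self):
        with pytest.raises(ParameterError):
            PhantomGeometry(diaphragm_excursion=-1.0)
        with pytest.raises(ParameterError):
            PhantomGeometry(slice_thickness=0.0)


class TestReconstructPhases:
    def test_perfect_surrogate_nominal_levels(self):
        frames, ns, ex, geom = dense_sinusoid_setup()
        res = reconstruct_phases(frames, ns, ex)
        base, exc = geom.diaphragm_base_position, geom.diaphragm_excursion
        # phase 1 at EOI, phase 6 at EOE, intermediates at nominal fractions
        assert res.diaphragm_apex[0] == pytest.approx(base + exc, abs=geom.slice_thickness)
        assert res.diaphragm_apex[5] == pytest.approx(base, abs=geom.slice_thickness)
        for levels in (EXHALE_LEVELS, INHALE_LEVELS):
            for f, p in levels:
                expected = base + exc * f
                assert res.diaphragm_apex[p - 1] == pytest.approx(
                    expected, abs=geom.slice_thickness), f"phase {p}"

    def test_positions_quantized_to_slice(self):
        frames, ns, ex, geom = dense_sinusoid_setup()
        res = reconstruct_phases(frames, ns, ex)
        steps = res.diaphragm_apex / geom.slice_thickness
        assert np.allclose(steps, np.round(steps))

    def test_phase6_relative_zero(self):
        frames, ns, ex, _ = dense_sinusoid_setup()
        res = reconstruct_phases(frames, ns, ex)
        assert res.relative_displacement[5] == 0.0

    def test_volume_linear_in_apex(self):
        frames, ns, ex, geom = dense_sinusoid_setup()
        res = reconstruct_phases(frames, ns, ex)
        expected = geom.lung_volume_at_eoe + geom.volume_per_mm * (
            res.diaphragm_apex - geom.diaphragm_base_position)
        assert np.allclose(res.lung_volume, expected)

    def test_brute_force_cell_selection(self):
        # re-derive each (couch, phase) pick with explicit loops
        frames, ns, ex, geom = dense_sinusoid_setup(n_couch=3)
        res = reconstruct_phases(frames, ns, ex)
        from respsurro.phase_sorting import assign_phases
        samples = assign_phases(ns, ex)
        st = np.array([s.time for s in samples])
        sf = np.array([s.amplitude_fraction for s in samples])
        slb = np.array([s.limb for s in samples])
        levels = {p: f for f, p in EXHALE_LEVELS}
        levels.update({p: f for f, p in INHALE_LEVELS})
        apex = np.full(10, -np.inf)
        for p in range(1, 11):
            for c in np.unique(frames.couch_index):
                best, bestkey = None, None
                for k in np.flatnonzero(frames.couch_index == c):
                    j = int(np.argmin(np.abs(st - frames.frame_time[k])))
                    limb = slb[j]
                    if p <= 5 and limb != "exhale":
                        continue
                    if p >= 7 and limb != "inhale":
                        continue
                    key = (abs(sf[j] - levels[p]), frames.frame_time[k])
                    if bestkey is None or key < bestkey:
                        best, bestkey = k, key
                apex[p - 1] = max(apex[p - 1], frames.true_position[best])
        import math
        q = np.array([math.floor(x / geom.slice_thickness + 0.5) * geom.slice_thickness
                      for x in apex])
        assert np.array_equal(res.diaphragm_apex, q)

    def test_insufficient_cell_raises(self):
        # dwell far shorter than a period: some cell will be empty
        frames, ns, ex, _ = dense_sinusoid_setup(dwell=0.5, frame_rate=4.0,
                                                 n_couch=4)
        with pytest.raises(DataInsufficiencyError):
            reconstruct_phases(frames, ns, ex)


class TestCompareSortings:
    def test_identity_zero(self):
        frames, ns, ex, _ = dense_sinusoid_setup()
        res = reconstruct_phases(frames, ns, ex)
        rep = compare_sortings(res, res)
        assert np.all(rep.volume_diff_pct == 0.0)
        assert np.all(rep.position_diff == 0.0)
        assert rep.volume_diff_range == (0.0, 0.0)
        assert rep.position_diff_range == (0.0, 0.0)

    def test_lag_one_phase_circular_shift(self):
        period = 4.0
        frames, ns_a, ex_a, geom = dense_sinusoid_setup(period=period)
        _, ns_b, ex_b, _ = dense_sinusoid_setup(period=period, lag=period / 10.0)
        res_a = reconstruct_phases(frames, ns_a, ex_a)
        res_b = reconstruct_phases(frames, ns_b, ex_b)
        # surrogate B leads: its phase p selects anatomy that A labels p-1
        shifted = np.roll(res_a.diaphragm_apex, 1)
        assert np.max(np.abs(res_b.diaphragm_apex - shifted)) <= geom.slice_thickness

    def test_range_agreement_for_lag_only(self):
        # over all 10 phases the travelled range agrees between the two
        # sortings to within one reconstructed slice
        period = 4.0
        frames, ns_a, ex_a, geom = dense_sinusoid_setup(period=period)
        res_a = reconstruct_phases(frames, ns_a, ex_a)
        for lag in (0.3, period / 10.0):
            _, ns_b, ex_b, _ = dense_sinusoid_setup(period=period, lag=lag)
            res_b = reconstruct_phases(frames, ns_b, ex_b)
            assert abs(res_a.diaphragm_apex.min() - res_b.diaphragm_apex.min()) \
                <= geom.slice_thickness
            assert abs(res_a.diaphragm_apex.max() - res_b.diaphragm_apex.max()) \
                <= geom.slice_thickness

    def test_lag_sensitivity(self):
        period = 4.0
        frames, ns_a, ex_a, geom = dense_sinusoid_setup(period=period)
        res_a = reconstruct_phases(frames, ns_a, ex_a)
        _, ns0, ex0, _ = dense_sinusoid_setup(period=period, lag=0.0)
        res0 = reconstruct_phases(frames, ns0, ex0)
        assert np.max(np.abs(compare_sortings(res_a, res0).position_diff)) == 0.0
        _, nsl, exl, _ = dense_sinusoid_setup(period=period, lag=period / 10.0)
        resl = reconstruct_phases(frames, nsl, exl)
        assert np.max(np.abs(compare_sortings(res_a, resl).position_diff)) >= geom.slice_thickness

    def test_exhale_warp_concentrates_in_exhale_phases(self):
        # warp the surrogate's exhale limb: samples read higher fractions
        # during exhalation, displacing exhale-phase picks
        period, duration = 4.0, 130.0
        frames, ns_a, ex_a, geom = dense_sinusoid_setup(period=period,
                                                        duration=duration)
        t = ns_a.timestamps
        phase = (t / period) % 1.0
        f = (1.0 - np.cos(2 * np.pi * phase)) / 2.0
        # exhale half (phase > 0.5): apply fraction warp f -> f**0.5
        warped = np.where(phase > 0.5, 100.0 * f ** 0.5, 100.0 * f)
        surr = RespTrace(timestamps=t, amplitudes=warped)
        nb = normalize_global(surr)
        res_a = reconstruct_phases(frames, ns_a, ex_a)
        res_b = reconstruct_phases(frames, nb, detect_extrema(nb))
        rep = compare_sortings(res_a, res_b)
        exhale_mag = np.abs(rep.position_diff[1:5]).max()  # phases 2-5
        inhale_mag = np.abs(rep.position_diff[6:]).max()  # phases 7-10
        assert exhale_mag > 0
        assert exhale_mag >= inhale_mag
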