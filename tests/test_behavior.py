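"""Kinematic metric definitions: band splitting, closed forms, epoching,
and the geometric invariances of the metric library."""

import numpy as np
import pytest

from stnmes import behavior as bhv
from stnmes.behavior import (
    METRICS,
    SLOWNESS_DECAY,
    Trace,
    angular_metrics,
    epoch_metrics,
    instantaneous_metrics,
    kinematic_metrics,
    split_bands,
    tracking_errors,
    tremor_magnitude,
)

from conftest import make_trace


def _var(x):
    return float(np.var(x))


class TestSplitBands:
    def test_constant_trace_passes_dc_only(self):
        tr = make_trace(np.full(5000, 5.0), np.full(5000, 2.0))
        slow, trem = split_bands(tr)
        mid = slice(1500, 3500)
        assert np.allclose(slow.x[mid], 5.0, atol=1e-6)
        assert np.allclose(slow.y[mid], 2.0, atol=1e-6)
        assert np.allclose(trem.x[mid], 0.0, atol=1e-6)

    @pytest.mark.parametrize(
        "freq,into_tremor", [(6.0, True), (1.0, False)], ids=["6Hz", "1Hz"]
    )
    def test_sinusoid_routed_to_correct_band(self, freq, into_tremor):
        t = np.arange(10_000) / 1000.0
        tr = make_trace(np.sin(2 * np.pi * freq * t), np.zeros_like(t))
        slow, trem = split_bands(tr)
        mid = slice(2000, 8000)
        v_in = _var(tr.x[mid])
        v_trem = _var(trem.x[mid]) / v_in
        v_slow = _var(slow.x[mid]) / v_in
        if into_tremor:
            assert v_trem >= 0.90 and v_slow < 0.05
        else:
            assert v_slow >= 0.90 and v_trem < 0.05

    def test_too_short_trace_raises(self):
        tr = make_trace(np.zeros(500), np.zeros(500))
        with pytest.raises(ValueError, match="shorter than 1 s"):
            split_bands(tr)

    def test_nonuniform_grid_rejected(self):
        t = np.arange(2000) / 1000.0
        t[100] += 0.01
        with pytest.raises(ValueError, match="increasing|uniform"):
            Trace(t=t, x=np.zeros(2000), y=np.zeros(2000), fs=1000.0)


class TestTremorMagnitude:
    def test_zero_input_zero_output(self):
        tr = make_trace(np.zeros(3000), np.zeros(3000))
        assert np.allclose(tremor_magnitude(tr), 0.0)

    def test_pure_sinusoid_envelope_equals_amplitude(self):
        t = np.arange(6000) / 1000.0
        a = 0.7
        tr = make_trace(a * np.sin(2 * np.pi * 6 * t), np.zeros_like(t))
        tm = tremor_magnitude(tr)
        assert np.allclose(tm[1000:5000], a, rtol=0.02)

    def test_quadrature_pair_gives_sqrt2(self):
        t = np.arange(6000) / 1000.0
        a = 0.5
        tr = make_trace(a * np.sin(2 * np.pi * 6 * t), a * np.cos(2 * np.pi * 6 * t))
        tm = tremor_magnitude(tr)
        assert np.allclose(tm[1000:5000], a * np.sqrt(2), rtol=0.02)


class TestTrackingErrors:
    def test_identity_tracking_zeroes_everything(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(t)
        c = make_trace(x, x)
        tg = make_trace(x, x, role="target")
        ad, ve, ed = tracking_errors(c, tg)
        assert np.allclose(ad, 0) and np.allclose(ve, 0) and np.allclose(ed, 0)

    def test_absolute_distance_is_euclidean(self):
        c = make_trace(np.full(2000, 3.0), np.full(2000, 4.0))
        tg = make_trace(np.zeros(2000), np.zeros(2000), role="target")
        ad, _, _ = tracking_errors(c, tg)
        assert np.allclose(ad, 5.0)

    def test_vector_error_of_stationary_cursor(self):
        v = (0.8, -0.6)  # units per second
        t = np.arange(2000) / 1000.0
        tg = make_trace(v[0] * t, v[1] * t, role="target")
        c = make_trace(np.zeros_like(t), np.zeros_like(t))
        _, ve, _ = tracking_errors(c, tg)
        dt = 1e-3
        assert np.allclose(ve, np.hypot(*v) * dt, rtol=1e-6)


class TestKinematics:
    def test_stationary_cursor_has_unit_slowness(self):
        c = make_trace(np.full(1500, 1.0), np.zeros(1500))
        tg = make_trace(np.zeros(1500), np.zeros(1500), role="target")
        s_c, _, sl, _ = kinematic_metrics(c, tg)
        assert np.allclose(s_c, 0) and np.allclose(sl, 1.0)

    def test_slowness_half_life_speed(self):
        # invert exp(-0.042 * S) = 0.5
        s_half = np.log(2) / SLOWNESS_DECAY
        t = np.arange(1500) / 1000.0
        c = make_trace(s_half * 1000.0 * t, np.zeros_like(t))  # units/s -> units/ms
        tg = make_trace(np.zeros_like(t), np.zeros_like(t), role="target")
        _, _, sl, _ = kinematic_metrics(c, tg)
        assert np.allclose(sl, 0.5, rtol=1e-9)

    def test_comoving_traces_have_zero_speed_difference(self):
        t = np.arange(1500) / 1000.0
        x = np.sin(2 * np.pi * 0.5 * t)
        c = make_trace(x + 1.0, 2 * t)
        tg = make_trace(x, 2 * t, role="target")
        _, _, _, sd = kinematic_metrics(c, tg)
        assert np.allclose(sd, 0.0, atol=1e-12)


class TestAngles:
    @staticmethod
    def _two_point(c0, c1, t0, t1):
        """Traces with a prescribed first displacement segment."""
        n = 1000

        def ramp(a, b):
            out = np.full(n, float(b))
            out[0] = a
            return out

        c = make_trace(ramp(c0[0], c1[0]), ramp(c0[1], c1[1]))
        tg = make_trace(ramp(t0[0], t1[0]), ramp(t0[1], t1[1]), role="target")
        return c, tg

    @pytest.mark.parametrize(
        "cseg,expected",
        [((1.0, 0.0), 0.0), ((0.0, 1.0), np.pi / 2), ((-1.0, 0.0), np.pi)],
        ids=["parallel", "orthogonal", "antiparallel"],
    )
    def test_vector_angle_closed_forms(self, cseg, expected):
        c, tg = self._two_point((0, 0), cseg, (5, 5), (6, 5))  # target moves +x
        va, _, valid = angular_metrics(c, tg)
        assert valid[0]
        assert va[0] == pytest.approx(expected, abs=1e-9)

    def test_correction_angle_zero_when_chasing_along_heading(self):
        # cursor sits behind the target on its line of motion (+x)
        c, tg = self._two_point((0, 0), (0.5, 0), (1, 0), (2, 0))
        _, ca, valid = angular_metrics(c, tg)
        assert valid[0] and ca[0] == pytest.approx(0.0, abs=1e-9)

    def test_correction_angle_orthogonal_offset(self):
        # offset toward +x, target heading +y -> pi/2
        c, tg = self._two_point((0, 0), (0, 0.1), (1, 0), (1, 1e-3))
        _, ca, valid = angular_metrics(c, tg)
        assert valid[0] and ca[0] == pytest.approx(np.pi / 2, abs=1e-6)

    def test_degenerate_segments_flagged_not_imputed(self):
        c = make_trace(np.zeros(1000), np.zeros(1000))
        tg = make_trace(np.ones(1000), np.ones(1000), role="target")
        va, ca, valid = angular_metrics(c, tg)
        assert not valid.any()
        assert np.isnan(va).all() and np.isnan(ca).all()


class TestEpoching:
    def test_constant_series_and_row_count(self):
        t = np.arange(10_000) / 1000.0
        c = make_trace(np.sin(2 * np.pi * 0.3 * t), np.cos(2 * np.pi * 0.3 * t))
        tg = make_trace(
            np.sin(2 * np.pi * 0.3 * t + 0.2), np.cos(2 * np.pi * 0.3 * t + 0.2),
            role="target",
        )
        inst = instantaneous_metrics(c, tg)
        mm = epoch_metrics(inst, 1.0)
        assert len(mm) == 10
        assert list(mm.values.columns) == list(METRICS)

    def test_alternating_series_averages_to_midpoint(self):
        t = np.arange(1000) / 1000.0
        v = np.where(np.arange(1000) % 2 == 0, 0.0, 2.0)
        inst = bhv.InstantaneousMetrics(
            series={m: (t, v, np.ones(1000, bool)) for m in METRICS}, fs=1000.0
        )
        mm = epoch_metrics(inst, 0.1)
        assert np.allclose(mm.values.to_numpy(), 1.0)

    def test_one_second_epochs_nest_ten_100ms_epochs(self):
        rng = np.random.default_rng(3)
        t = np.arange(10_000) / 1000.0
        c = make_trace(
            np.sin(2 * np.pi * 0.2 * t) + 0.05 * rng.normal(size=t.size),
            np.cos(2 * np.pi * 0.15 * t),
        )
        tg = make_trace(np.sin(2 * np.pi * 0.2 * t + 0.3), np.cos(2 * np.pi * 0.15 * t + 0.3), role="target")
        inst = instantaneous_metrics(c, tg)
        coarse = epoch_metrics(inst, 1.0).values.to_numpy()
        fine = epoch_metrics(inst, 0.1).values.to_numpy()
        # all but the final coarse epoch contain ten full fine epochs
        nested = fine[:90].reshape(9, 10, len(METRICS)).mean(axis=1)
        assert np.allclose(coarse[:9], nested, rtol=1e-9, atol=1e-12)

    def test_epoch_len_below_two_samples_rejected(self):
        t = np.arange(2000) / 1000.0
        c = make_trace(np.sin(t), np.cos(t))
        tg = make_trace(np.sin(t), np.cos(t), role="target")
        inst = instantaneous_metrics(c, tg)
        with pytest.raises(ValueError):
            epoch_metrics(inst, 0.001)


class TestInvariances:
    @staticmethod
    def _session_traces(seed):
        rng = np.random.default_rng(seed)
        t = np.arange(8000) / 1000.0
        tx = 5 * np.sin(2 * np.pi * 0.12 * t)
        ty = 4 * np.sin(2 * np.pi * 0.2 * t + 1.0)
        cx = np.interp(t - 0.15, t, tx) + 0.2 * np.sin(2 * np.pi * 5.5 * t)
        cy = np.interp(t - 0.15, t, ty) + 0.1 * rng.normal(size=t.size)
        return make_trace(cx, cy), make_trace(tx, ty, role="target")

    @staticmethod
    def _metrics(c, tg):
        return epoch_metrics(instantaneous_metrics(c, tg), 1.0).values

    def test_translation_invariance_except_excursion(self):
        c, tg = self._session_traces(0)
        base = self._metrics(c, tg)
        dx, dy = 3.7, -1.2
        c2 = make_trace(c.x + dx, c.y + dy)
        tg2 = make_trace(tg.x + dx, tg.y + dy, role="target")
        shifted = self._metrics(c2, tg2)
        # first/last epochs carry the filter's boundary transient of the
        # shifted DC level; interior epochs must match exactly
        for m in METRICS:
            if m == "ED":
                continue
            # TM's Hilbert envelope spreads boundary effects further inward
            rtol = 1e-2 if m == "TM" else 1e-6
            assert np.allclose(base[m][1:-1], shifted[m][1:-1], rtol=rtol, atol=1e-8), m
        assert not np.allclose(base["ED"], shifted["ED"], atol=1e-3)

    def test_rotation_invariance_of_all_metrics(self):
        c, tg = self._session_traces(1)
        base = self._metrics(c, tg)
        th = 0.83
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cr = r @ np.vstack([c.x, c.y])
        tr = r @ np.vstack([tg.x, tg.y])
        rotated = self._metrics(
            make_trace(cr[0], cr[1]), make_trace(tr[0], tr[1], role="target")
        )
        for m in METRICS:
            assert np.allclose(base[m], rotated[m], rtol=1e-7, atol=1e-9), m

    def test_perfect_tracking_corner(self):
        t = np.arange(5000) / 1000.0
        x = 3 * np.sin(2 * np.pi * 0.2 * t)
        y = 2 * np.cos(2 * np.pi * 0.25 * t)
        inst = instantaneous_metrics(make_trace(x, y), make_trace(x, y, role="target"))
        for m in ("AD", "VE", "SD", "ED"):
            _, v, _ = inst[m]
            assert np.allclose(v, 0.0, atol=1e-9), m
        _, tm, _ = inst["TM"]
        # bounded by the band-pass stopband floor (~-50 dB of the excursion)
        assert np.max(np.abs(tm[1000:4000])) < 0.02
        # identical segments -> VA degenerate everywhere (C-bar == T-bar,
        # and O-bar == 0), flagged rather than imputed
        _, _, valid = inst["VA"]
        assert not valid.any()
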