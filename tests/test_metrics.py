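"""Model-free curve metrics: TTP, wash-in, washout, retention ratio."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glymphkin.concentration import ConcentrationSeries
from glymphkin.metrics import (
    compute_all_metrics,
    curve_metrics,
    retention_ratio,
    time_to_peak,
    wash_in_rate,
    wash_out_rate,
)

T3 = np.array([0.0, 30.0, 60.0])


def random_peaked_curve(rng):
    """Curve with a baseline, a strict interior peak and some decay."""
    t = np.array([0.0, 30, 60, 90, 120, 180, 240, 300])
    peak_idx = rng.integers(1, 5)
    y = np.empty_like(t)
    base = rng.uniform(0, 0.1)
    peak = base + rng.uniform(0.2, 1.0)
    y[: peak_idx + 1] = np.linspace(base, peak, peak_idx + 1)
    y[peak_idx:] = np.linspace(peak, rng.uniform(0.0, 0.05 * peak), t.size - peak_idx)
    return t, y


class TestTimeToPeak:
    def test_interior_peak(self):
        ttp, gd_max, flags = time_to_peak(T3, np.array([0.0, 1.0, 0.5]))
        assert (ttp, gd_max) == (30.0, 1.0) and not flags

    def test_monotone_curve_flagged_no_decay(self):
        ttp, _, flags = time_to_peak(T3, np.array([0.0, 0.5, 1.0]))
        assert ttp == 60.0 and "no_decay" in flags

    def test_tie_broken_by_earliest_time(self):
        ttp, _, _ = time_to_peak(T3, np.array([0.0, 1.0, 1.0]))
        assert ttp == 30.0

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            time_to_peak(np.array([]), np.array([]))


class TestWashInRate:
    def test_zero_baseline(self):
        assert wash_in_rate(T3, np.array([0.0, 1.0, 0.5])) == pytest.approx(1 / 30)

    def test_nonzero_baseline(self):
        t = np.array([0.0, 50.0, 100.0])
        assert wash_in_rate(t, np.array([0.2, 1.2, 0.5])) == pytest.approx(0.02)

    @given(shift=st.floats(-1.0, 1.0))
    def test_additive_shift_invariance(self, shift):
        y = np.array([0.1, 0.9, 0.4])
        assert wash_in_rate(T3, y + shift) == pytest.approx(wash_in_rate(T3, y))

    def test_flat_curve_undefined(self):
        with pytest.raises(ValueError):
            wash_in_rate(T3, np.full(3, 0.5))


class TestWashOutRate:
    def test_linear_decay_rate_equals_decay_slope(self):
        """Peak 1.0 at 30 min decaying linearly to 0 at 130 min: t90 = 40,
        t10 = 120, so the 90->10 slope is 0.8/80 = 0.01/min."""
        t = np.array([0.0, 30.0, 80.0, 130.0])
        y = np.array([0.0, 1.0, 0.5, 0.0])
        rate, flags = wash_out_rate(t, y)
        assert rate == pytest.approx(0.01, rel=1e-12)
        assert not flags

    def test_shallow_decay_sets_extrapolation_flag(self):
        t = np.array([0.0, 30.0, 150.0, 300.0])
        y = np.array([0.0, 1.0, 0.8, 0.5])
        rate, flags = wash_out_rate(t, y)
        assert "washout_extrapolated" in flags
        assert rate > 0

    def test_non_decaying_curve_flagged(self):
        rate, flags = wash_out_rate(T3, np.array([0.0, 0.5, 1.0]))
        assert np.isnan(rate) and "no_decay" in flags

    @given(scale=st.floats(0.1, 10.0))
    def test_homogeneity_under_amplitude_scaling(self, scale):
        t = np.array([0.0, 30.0, 80.0, 130.0])
        y = np.array([0.0, 1.0, 0.5, 0.0])
        rate, _ = wash_out_rate(t, y)
        rate_s, _ = wash_out_rate(t, scale * y)
        assert rate_s == pytest.approx(scale * rate, rel=1e-9)


class TestRetentionRatio:
    def test_boundary_cases(self):
        t = np.array([0.0, 30.0, 300.0])
        assert retention_ratio(t, np.array([0.1, 1.0, 0.1]))[0] == pytest.approx(0.0)
        assert retention_ratio(t, np.array([0.1, 1.0, 1.0]))[0] == pytest.approx(100.0)
        assert retention_ratio(t, np.array([0.1, 1.0, 0.55]))[0] == pytest.approx(50.0)

    @given(a=st.floats(0.2, 5.0), b=st.floats(-2.0, 2.0))
    def test_affine_invariance(self, a, b):
        t = np.array([0.0, 30.0, 120.0, 300.0])
        y = np.array([0.05, 0.8, 0.4, 0.2])
        r0, _ = retention_ratio(t, y)
        r1, _ = retention_ratio(t, a * y + b)
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_flat_curve_and_missing_t300(self):
        t = np.array([0.0, 30.0, 300.0])
        with pytest.raises(ValueError):
            retention_ratio(t, np.full(3, 0.4))
        t2 = np.array([0.0, 30.0, 280.0, 310.0])
        _, flags = retention_ratio(t2, np.array([0.0, 1.0, 0.4, 0.3]))
        assert "t300_missing" in flags


class TestFlagSoundness:
    def test_unflagged_rates_match_dense_grid_brute_force(self):
        """When washout is reported without flags, a brute-force crossing
        search on a dense grid gives the same rate."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(200):
            t, y = random_peaked_curve(rng)
            rate, flags = wash_out_rate(t, y)
            if flags or not np.isfinite(rate):
                continue
            dense_t = np.linspace(t[0], t[-1], 200001)
            dense_y = np.interp(dense_t, t, y)
            peak = dense_y.max()
            pk = int(np.argmax(dense_y))
            post_t, post_y = dense_t[pk:], dense_y[pk:]
            t90 = post_t[post_y <= 0.9 * peak][0]
            t10 = post_t[post_y <= 0.1 * peak][0]
            brute = 0.8 * peak / (t10 - t90)
            assert rate == pytest.approx(brute, abs=1e-4 * rate + 1e-9)
            checked += 1
        assert checked > 50


class TestComputeAllMetrics:
    def _series(self):
        t = np.array([0.0, 30, 60, 90, 120, 180, 240, 300])
        curve = np.array([0.0, 0.6, 0.5, 0.4, 0.3, 0.2, 0.12, 0.08])
        conc = np.zeros((4, 4, t.size))
        conc[:2] = curve
        conc[2:] = 0.5 * curve
        return ConcentrationSeries(conc, t), curve

    def test_uniform_region_reproduces_scalar_ops(self):
        series, curve = self._series()
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        table = compute_all_metrics(series, {"roi": mask})
        m = curve_metrics(series.times_min, curve)
        assert table.loc["roi", "wash_in_rate"] == pytest.approx(m.wash_in_rate)
        assert table.loc["roi", "wash_out_rate"] == pytest.approx(m.wash_out_rate)
        assert table.loc["roi", "retention_ratio_pct"] == pytest.approx(
            m.retention_ratio_pct
        )

    def test_union_region_equals_weighted_mean_of_parts(self):
        series, _ = self._series()
        top = np.zeros((4, 4), bool); top[:2] = True
        bottom = np.zeros((4, 4), bool); bottom[2:] = True
        union = top | bottom
        from glymphkin.concentration import roi_timecourse

        got = roi_timecourse(series, union)
        expected = (
            top.sum() * roi_timecourse(series, top)
            + bottom.sum() * roi_timecourse(series, bottom)
        ) / union.sum()
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_cohort_ordering_healthy_vs_impaired(self):
        """Slower influx/efflux kinetics must show higher 300-min retention,
        lower washout and lower wash-in at the cohort level, in every
        seeded replicate."""
        from glymphkin.kinetics import KineticParams
        from glymphkin.synthetic import generate_cohort_tscs

        healthy = KineticParams(0.08, 0.05, 0.02, 0.01)
        impaired = KineticParams(0.04, 0.02, 0.02, 0.01)
        for seed in range(5):
            ch, _, t = generate_cohort_tscs(healthy, n_subjects=6, seed=2 * seed)
            ci, _, _ = generate_cohort_tscs(impaired, n_subjects=6, seed=2 * seed + 1)

            def cohort_means(curves):
                ms = [curve_metrics(t, c) for c in curves]
                return (
                    np.mean([m.retention_ratio_pct for m in ms]),
                    np.mean([m.wash_out_rate for m in ms]),
                    np.mean([m.wash_in_rate for m in ms]),
                )

            ret_h, wo_h, wi_h = cohort_means(ch)
            ret_i, wo_i, wi_i = cohort_means(ci)
            assert ret_i > ret_h
            assert wo_i < wo_h
            assert wi_i < wi_h

    def test_empty_region_list_rejected(self):
        series, _ = self._series()
        with pytest.raises(ValueError):
            compute_all_metrics(series, {})
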