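"""Synthetic generators: determinism, closed forms, designed ground truth."""

import numpy as np
import pytest

from glymphkin.synthetic import (
    AcquisitionSpec,
    Box,
    InputFunctionSpec,
    NoiseSpec,
    PhantomSpec,
    TissueRegion,
    default_phantom,
    gamma_variate,
    generate_b1_pair,
    generate_cohort_tscs,
    generate_efflux_series,
    generate_flow_waveform,
    generate_spgr_series,
    generate_vessel_profile,
    impaired_phantom,
)
from glymphkin.t1map import compute_b1_map, spgr_signal


class TestSpecValidation:
    def test_flip_angles_must_increase(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(flip_angles_deg=(5.0, 2.0, 10.0))

    def test_b1_pair_must_be_double_angle(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(b1_angles_deg=(70.0, 120.0))

    def test_overlapping_regions_rejected(self):
        region = TissueRegion("a", Box((0.0, 0.5), (0.0, 0.5), (0.0, 0.5)), 1500, 1000)
        clash = TissueRegion("b", Box((0.2, 0.6), (0.2, 0.6), (0.2, 0.6)), 1500, 1000)
        with pytest.raises(ValueError):
            PhantomSpec(tissue_regions=(region, clash))

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(tissue_regions=())

    def test_noise_spec_requires_positive_snr(self):
        with pytest.raises(ValueError):
            NoiseSpec(model="rician", snr=-5)


class TestInputFunction:
    def test_gamma_variate_peaks_at_thirty_minutes(self):
        t = np.arange(0.0, 301.0, 0.5)
        c = gamma_variate(t, InputFunctionSpec())
        assert t[np.argmax(c)] == pytest.approx(30.0, abs=0.5)
        assert c.max() == pytest.approx(0.5)
        assert c[0] == 0.0 and np.all(c >= 0)


class TestGenerateSpgrSeries:
    def test_noiseless_signal_matches_closed_form(self, acq):
        stack, gt = generate_spgr_series(default_phantom((12, 12, 12)), acq)
        # pick a cortex voxel at a mid timepoint and check the one-line formula
        vox = tuple(np.argwhere(gt.region_labels == 1)[0])
        ti, ai = 3, 4
        expected = spgr_signal(
            1000.0, gt.t1_ms[vox][ti], acq.flip_angles_deg[ai], acq.tr_ms, 1.0
        )
        assert stack.data[vox][ti, ai] == pytest.approx(expected, rel=1e-12)

    def test_zero_flip_angle_limit_gives_zero_signal(self):
        assert spgr_signal(1000.0, 1500.0, 0.0, 16.0) == 0.0

    def test_seeded_noise_is_bit_identical(self, acq):
        noise = NoiseSpec(model="rician", snr=40, seed=42)
        ph = default_phantom((10, 10, 10))
        a, _ = generate_spgr_series(ph, acq, noise)
        b, _ = generate_spgr_series(ph, acq, noise)
        assert np.array_equal(a.data, b.data)

    def test_phantom_box_held_at_nominal_concentration_post_infusion(self, acq):
        ph = default_phantom((12, 12, 12))
        _, gt = generate_spgr_series(ph, acq)
        pm = gt.phantom_mask
        conc = gt.conc_mM[pm]
        assert np.all(conc[:, 0] == 0.0)
        np.testing.assert_allclose(conc[:, 1:], 0.1)

    def test_noiseless_outputs_are_nonnegative(self, acq):
        stack, gt = generate_spgr_series(default_phantom((10, 10, 10)), acq)
        assert stack.data.min() >= 0
        assert np.nanmin(gt.conc_mM) >= 0

    def test_impaired_phantom_halves_influx_and_efflux(self):
        h = default_phantom()
        i = impaired_phantom()
        for rh, ri in zip(h.tissue_regions, i.tissue_regions):
            if rh.params is None:
                continue
            assert ri.params.k1 == rh.params.k1 / 2
            assert ri.params.k2 == rh.params.k2 / 2
            assert ri.params.k3 == rh.params.k3


class TestGenerateB1Pair:
    def test_uniform_kappa_gives_double_angle_ratio(self, acq):
        ph = default_phantom((10, 10, 10))
        img1, img2 = generate_b1_pair(ph, acq)
        support = img1 > 0
        ratio = img2[support] / img1[support]
        np.testing.assert_allclose(ratio, 2 * np.cos(np.deg2rad(70.0)), rtol=1e-12)

    def test_round_trip_through_dam_estimator(self, acq):
        ph = default_phantom((10, 10, 10))
        kappa = np.full(ph.grid_shape, 1.07)
        img1, img2 = generate_b1_pair(ph, acq, kappa_map=kappa)
        b1 = compute_b1_map(img1, img2, acq.b1_angles_deg[0])
        np.testing.assert_allclose(b1.kappa[b1.valid], 1.07, atol=1e-12)

    def test_kappa_out_of_domain_rejected(self, acq):
        ph = default_phantom((10, 10, 10))
        with pytest.raises(ValueError):
            generate_b1_pair(ph, acq, kappa_map=np.full(ph.grid_shape, 1.4))

    def test_seeded_noise_determinism(self, acq):
        ph = default_phantom((10, 10, 10))
        n = NoiseSpec("rician", 30, 5)
        assert np.array_equal(generate_b1_pair(ph, acq, n)[0],
                              generate_b1_pair(ph, acq, n)[0])


class TestGenerateFlowWaveform:
    def test_equal_systolic_diastolic_gives_zero_indices(self):
        _, truth = generate_flow_waveform(systolic=1.0, diastolic=1.0)
        assert truth["pi"] == 0.0 and truth["ri"] == 0.0

    def test_designed_indices_from_printed_formulas(self):
        wf, truth = generate_flow_waveform(systolic=1.2, diastolic=0.8)
        assert truth["mean"] == pytest.approx(1.0)
        assert truth["pi"] == pytest.approx(0.4)
        assert truth["ri"] == pytest.approx(1.0 / 3.0)
        assert wf.values.max() <= 1.2 + 1e-12 and wf.values.min() >= 0.8 - 1e-12

    def test_seed_determinism_and_preconditions(self):
        n = NoiseSpec("gaussian", 20, 9)
        a, _ = generate_flow_waveform(noise=n)
        b, _ = generate_flow_waveform(noise=n)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError):
            generate_flow_waveform(systolic=0.8, diastolic=1.2)
        with pytest.raises(ValueError):
            generate_flow_waveform(rate_hz=70.0)  # violates fs > 2*rate


class TestGenerateVesselProfile:
    def test_designed_index_is_peri_over_extra(self):
        _, truth = generate_vessel_profile(peri_intensity=200, extra_intensity=100)
        assert truth["index"] == 2.0
        _, truth = generate_vessel_profile(peri_intensity=100, extra_intensity=100)
        assert truth["index"] == 1.0

    def test_zero_extra_intensity_refused(self):
        with pytest.raises(ValueError):
            generate_vessel_profile(peri_intensity=100, extra_intensity=0.0)

    def test_band_exceeding_profile_refused(self):
        with pytest.raises(ValueError):
            generate_vessel_profile(length_um=10.0, vessel_width_um=7.0, band_width_um=5.0)

    def test_cd31_peaks_at_center(self):
        prof, _ = generate_vessel_profile()
        center = prof.positions_um[np.argmax(prof.channels["cd31"])]
        assert abs(center) < 0.2


class TestGenerateEffluxSeries:
    def test_zero_plateau_gives_zero_corrected_series(self):
        series, _ = generate_efflux_series(plateau=0.0)
        np.testing.assert_allclose(series.corrected_intensity, 0.0)

    def test_background_subtraction_invariance(self):
        a, _ = generate_efflux_series(plateau=50.0, background_level=10.0)
        b, _ = generate_efflux_series(plateau=50.0, background_level=200.0)
        np.testing.assert_allclose(a.corrected_intensity, b.corrected_intensity)

    def test_timestamps_are_quarter_hourly_including_165(self):
        series, _ = generate_efflux_series(plateau=10.0)
        assert np.all(series.times_min % 15 == 0)
        assert 165.0 in series.times_min and series.times_min[-1] == 180.0

    def test_corrected_equals_designed_sigmoid(self):
        series, truth = generate_efflux_series(plateau=80.0, background_level=30.0)
        np.testing.assert_allclose(series.corrected_intensity, truth["designed_curve"])


class TestCohortGenerator:
    def test_determinism_and_shapes(self):
        from glymphkin.kinetics import KineticParams

        k = KineticParams(0.08, 0.05, 0.02, 0.01)
        a, pa, t = generate_cohort_tscs(k, n_subjects=4, seed=3)
        b, pb, _ = generate_cohort_tscs(k, n_subjects=4, seed=3)
        assert np.array_equal(a, b)
        assert a.shape == (4, t.size)
        assert all(np.all(p.as_array() > 0) for p in pa)
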