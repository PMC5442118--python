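"""Phantom geometry, region assignment, signal simulation and cohort sampling."""

import numpy as np
import pytest

from aarcmr.containers import (AAR_SALVAGED, BACKGROUND, BLOOD, INFARCT, REMOTE,
                               ASLConstants, default_ir_meta, default_t2_meta)
from aarcmr.phantom import (AcquisitionSettings, GroupSpec, PhantomConfig,
                            assign_regions, default_tissue_params,
                            effective_selective_t1, generate_cohort,
                            look_locker_parameters, make_geometry,
                            sample_cohort_parameters, sector_capacity,
                            simulate_histology, simulate_ir_series,
                            simulate_lge_image, simulate_t2_series)

from conftest import SMALL_ACQ


def brute_force_annulus_count(n, cy, cx, r_in, r_out):
    count = 0
    for y in range(n):
        for x in range(n):
            r = np.hypot(y - cy, x - cx)
            if r_in <= r < r_out:
                count += 1
    return count


class TestGeometry:
    def test_annulus_matches_exhaustive_pixel_scan(self):
        cfg = PhantomConfig()
        labels = make_geometry(cfg)
        assert labels.labels.shape == (7, 128, 128)
        cy, cx = cfg.lv_center
        for s in (0, 6):  # one span slice, one basal slice
            expected = brute_force_annulus_count(128, cy, cx,
                                                 cfg.r_inner[s], cfg.r_outer[s])
            assert int(labels.myocardium_mask[s].sum()) == expected

    def test_degenerate_inner_radius_gives_full_disk(self):
        cfg = PhantomConfig(matrix_size=64, n_slices=3, r_inner=(0, 0, 0),
                            r_outer=(15, 15, 12))
        labels = make_geometry(cfg)
        assert not labels.blood_mask.any()
        cy, cx = cfg.lv_center
        assert int(labels.myocardium_mask[0].sum()) == \
            brute_force_annulus_count(64, cy, cx, 0.0, 15.0)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(matrix_size=64, r_inner=(40,) * 7, r_outer=(45,) * 7)
        with pytest.raises(ValueError):
            PhantomConfig(r_inner=(12,) * 7, r_outer=(11,) * 7)

    def test_aar_span_must_exclude_basal_slices(self):
        with pytest.raises(ValueError):
            PhantomConfig(aar_slice_span=(0, 1, 2, 3, 4, 5))


class TestAssignRegions:
    @pytest.mark.parametrize("aar_fraction", [0.0, 0.3, 0.643])
    def test_achieved_fraction_within_quantization_bound(self, aar_fraction):
        cfg = PhantomConfig(aar_fraction=aar_fraction)
        labels = assign_regions(make_geometry(cfg), aar_fraction, 0.5,
                                cfg.aar_slice_span, 1.0, cfg.lv_center, 40.0)
        n_myo = int(labels.myocardium_mask.sum())
        achieved = labels.aar_mask.sum() / n_myo
        assert abs(achieved - aar_fraction) <= 2.0 / np.sqrt(n_myo)
        if aar_fraction == 0.0:
            assert not labels.aar_mask.any() and not labels.infarct_mask.any()

    def test_labels_partition_and_nesting(self, small_labels):
        lab = small_labels.labels
        assert set(np.unique(lab)) <= {BACKGROUND, BLOOD, REMOTE, AAR_SALVAGED, INFARCT}
        assert np.all(small_labels.infarct_mask <= small_labels.aar_mask)
        assert np.all(small_labels.aar_mask <= small_labels.myocardium_mask)
        assert np.all(small_labels.infarct_mask <= small_labels.edema)
        assert np.all(small_labels.edema <= small_labels.aar_mask)

    def test_aar_confined_to_span_and_contiguous_sector(self, small_labels):
        assert not small_labels.aar_mask[2:].any()  # basal slices stay remote
        # per span slice the AAR is one angular sector: angles form one interval
        cfg = PhantomConfig(matrix_size=64, n_slices=4)
        cy, cx = cfg.lv_center
        for s in range(2):
            ys, xs = np.nonzero(small_labels.aar_mask[s])
            ang = np.degrees(np.arctan2(ys - cy, xs - cx)) - 20.0
            ang = (ang + 180.0) % 360.0 - 180.0
            half_width = np.abs(ang).max()
            inside = small_labels.myocardium_mask[s] & ~small_labels.aar_mask[s]
            ys2, xs2 = np.nonzero(inside)
            ang2 = np.degrees(np.arctan2(ys2 - cy, xs2 - cx)) - 20.0
            ang2 = (ang2 + 180.0) % 360.0 - 180.0
            # non-AAR myocardium lies outside the sector (up to angular ties)
            assert (np.abs(ang2) > half_width - 1e-9).mean() > 0.99

    def test_edema_multiplier_pixel_ratio(self):
        cfg = PhantomConfig()
        labels = assign_regions(make_geometry(cfg), 0.598, 0.279,
                                cfg.aar_slice_span, 0.85, cfg.lv_center, 10.0)
        n_aar = int(labels.aar_mask.sum())
        ratio = labels.edema.sum() / n_aar
        assert abs(ratio - 0.85) <= 2.0 / np.sqrt(n_aar)

    def test_full_aar_impossible_with_remote_roi(self):
        cfg = PhantomConfig(aar_fraction=0.5)
        geo = make_geometry(cfg)
        cap = sector_capacity(geo, cfg.aar_slice_span)
        with pytest.raises(ValueError):
            assign_regions(geo, 1.0, 0.5, cfg.aar_slice_span)
        with pytest.raises(ValueError):
            assign_regions(geo, cap + 0.01, 0.5, cfg.aar_slice_span)


class TestSignalSimulation:
    def test_t2_series_is_monoexponential(self, small_labels, tissue_params):
        meta = default_t2_meta()
        stack = simulate_t2_series(small_labels, tissue_params, meta, noise_sd=0.0)
        s, y, x = [v[0] for v in np.nonzero(small_labels.remote_mask)]
        te = np.asarray(meta.te_list_ms)
        expected = tissue_params.remote.s0 * np.exp(-te / tissue_params.remote.t2_ms)
        np.testing.assert_allclose(stack.data[s, :, y, x], expected, rtol=1e-6)
        # S0=100, T2=25, TE=25 -> 100/e
        probe = 100.0 * np.exp(-25.0 / 25.0)
        assert probe == pytest.approx(36.788, abs=5e-4)

    def test_t2_series_matches_reference_generator(self, small_labels, tissue_params):
        """Bit-for-bit equality with an independent one-line reimplementation."""
        meta = default_t2_meta()
        stack = simulate_t2_series(small_labels, tissue_params, meta,
                                   noise_sd=2.0, seed=1)
        te = np.asarray(meta.te_list_ms)
        t2 = np.zeros(small_labels.labels.shape)
        s0 = np.zeros_like(t2)
        for code, reg in ((REMOTE, "remote"), (BLOOD, "blood"),
                          (AAR_SALVAGED, "aar_salvaged"), (INFARCT, "infarct")):
            region = getattr(tissue_params, reg)
            t2[small_labels.labels == code] = region.t2_ms
            s0[small_labels.labels == code] = region.s0
        with np.errstate(divide="ignore"):
            ref = s0[:, None] * np.exp(-te[None, :, None, None]
                                       / np.where(t2 > 0, t2, np.inf)[:, None])
        ref = ref + np.random.default_rng(1).normal(0, 2.0, ref.shape)
        np.testing.assert_array_equal(stack.data, ref.astype(np.float32))

    def test_ir_zero_perfusion_scope_symmetry(self, small_labels):
        params = default_tissue_params()
        for reg in (params.remote, params.aar_salvaged, params.infarct, params.blood):
            reg.mbf = 0.0
        params.aar_salvaged.mbf = params.infarct.mbf = params.remote.mbf = 0.0
        sel = simulate_ir_series(small_labels, params, default_ir_meta("selective"),
                                 noise_sd=0.0)
        glo = simulate_ir_series(small_labels, params, default_ir_meta("global"),
                                 noise_sd=0.0)
        np.testing.assert_array_equal(sel.data, glo.data)

    def test_ir_late_time_approaches_equilibrium_plateau(self, small_labels,
                                                         tissue_params):
        meta = default_ir_meta("global", n_points=40, t_last_s=60.0)
        stack = simulate_ir_series(small_labels, tissue_params, meta, noise_sd=0.0)
        s, y, x = [v[0] for v in np.nonzero(small_labels.remote_mask)]
        a, _, _ = look_locker_parameters(tissue_params.remote.t1_s,
                                         tissue_params.remote.s0, 5.0, 3.0)
        assert stack.data[s, -1, y, x] == pytest.approx(float(a), rel=1e-5)

    def test_apparent_t1_star_scalar_arithmetic(self):
        # independent scalar computation of 1/T1* = 1/T1_eff + |ln cos a|/tau
        _, _, t1_star = look_locker_parameters(1.5, 100.0, 5.0, 3.0)
        expected = 1.0 / (1.0 / 1.5 + abs(np.log(np.cos(np.deg2rad(5.0)))) / 0.003)
        assert float(t1_star) == pytest.approx(expected, rel=1e-12)

    def test_selective_t1_inverts_bpmbf_formula(self):
        constants = ASLConstants()
        t1 = np.array([1.55]); mbf = np.array([16.9])
        t1_sel = effective_selective_t1(t1, mbf, constants)
        recovered = 60.0 * (constants.lambda_ml_per_g / constants.t1_blood_s) \
            * (t1 / t1_sel - 1.0)
        assert recovered[0] == pytest.approx(16.9, rel=1e-12)

    def test_lge_identity_enhancement_is_uniform(self, small_labels):
        params = default_tissue_params()
        params.infarct.lge_enhancement = 1.0
        params.blood.lge_enhancement = 1.0
        stack = simulate_lge_image(small_labels, params, noise_sd=0.0)
        inside = small_labels.myocardium_mask | small_labels.blood_mask
        vals = stack.data[:, 0][inside]
        assert np.unique(vals).size == 1

    def test_flip_angle_bound_enforced(self, small_labels, tissue_params):
        with pytest.raises(ValueError):
            look_locker_parameters(1.5, 100.0, 95.0, 3.0)


class TestHistology:
    def test_identity_keeps_planimetry_truth(self, small_labels):
        from aarcmr.regional import planimetry
        hist = simulate_histology(small_labels)
        assert planimetry(hist) == planimetry(small_labels)
        assert hist.labels is not small_labels.labels

    def test_reslice_conserves_class_fractions(self):
        cfg = PhantomConfig()
        labels = assign_regions(make_geometry(cfg), 0.6, 0.5,
                                cfg.aar_slice_span, 1.0, cfg.lv_center, 0.0)
        hist = simulate_histology(labels, n_slices_out=5)
        assert hist.n_slices == 5
        for mask in ("myocardium_mask", "aar_mask", "infarct_mask"):
            f_in = getattr(labels, mask).mean()
            f_out = getattr(hist, mask).mean()
            assert abs(f_out - f_in) <= 0.02


class TestCohort:
    def test_empty_groups_give_empty_cohort(self):
        assert generate_cohort([GroupSpec("control", 64.3, 6.1, 50.6, 6.9,
                                          n_animals=0)], seed=1) == []

    def test_sampled_means_match_group_spec(self):
        """n=100 control draws: sample means within 2 SE of the group means."""
        spec = GroupSpec("control", 64.3, 6.1, 50.6, 6.9, n_animals=100)
        rows = sample_cohort_parameters([spec], seed=21)
        aar = 100.0 * np.array([r["aar_fraction"] for r in rows])
        isa = 100.0 * np.array([r["is_fraction_of_aar"] for r in rows])
        assert abs(aar.mean() - 64.3) <= 2 * 6.1 / np.sqrt(100)
        assert abs(isa.mean() - 50.6) <= 2 * 6.9 / np.sqrt(100)

    def test_same_seed_is_bit_identical(self):
        groups = [GroupSpec("control", 64.3, 6.1, 50.6, 6.9, n_animals=2)]
        acq = AcquisitionSettings(n_recovery_points=12, **SMALL_ACQ)
        a = generate_cohort(groups, seed=9, acquisition=acq)
        b = generate_cohort(groups, seed=9, acquisition=acq)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.labels_cmr.labels, y.labels_cmr.labels)
            np.testing.assert_array_equal(x.t2_stack.data, y.t2_stack.data)
            np.testing.assert_array_equal(x.ir_selective.data, y.ir_selective.data)
            np.testing.assert_array_equal(x.ir_global.data, y.ir_global.data)
            np.testing.assert_array_equal(x.lge_stack.data, y.lge_stack.data)
            assert x.truth == y.truth

    def test_rician_noise_mode_is_nonnegative(self, small_labels, tissue_params):
        stack = simulate_t2_series(small_labels, tissue_params, noise_sd=5.0,
                                   seed=3, noise_model="rician")
        assert (stack.data >= 0).all()
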