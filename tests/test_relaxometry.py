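"""T2 / Look-Locker fitting: exact recoveries, grid-search oracles, invariants."""

import numpy as np
import pytest

from aarcmr.containers import default_ir_meta, default_t2_meta
from aarcmr.phantom import simulate_ir_series, simulate_t2_series
from aarcmr.relaxometry import (FitOptions, correct_t1, fit_ll_pixel, fit_t1_map,
                                fit_t2_map, fit_t2_pixel, restore_polarity)

PROTOCOL_ECHOES = np.array([3.5, 7, 10, 12, 15, 17, 20, 25, 30])


def grid_search_t2(signal, te, t2_lo=1.0, t2_hi=300.0, n=40000):
    """Independent dense-grid least squares: S0 solved linearly per T2 value."""
    t2_grid = np.exp(np.linspace(np.log(t2_lo), np.log(t2_hi), n))
    e = np.exp(-te[None, :] / t2_grid[:, None])
    s0 = (e @ signal) / np.einsum("gt,gt->g", e, e)
    sse = np.sum((signal[None, :] - s0[:, None] * e) ** 2, axis=1)
    i = np.argmin(sse)
    return float(s0[i]), float(t2_grid[i])


def grid_search_ll(signal, ti, t_lo=0.05, t_hi=5.0, n=40000):
    """Dense T1* grid; (A, B) solved by linear least squares per grid point."""
    best = (np.inf, None)
    for t1s in np.exp(np.linspace(np.log(t_lo), np.log(t_hi), n)):
        x = np.exp(-ti / t1s)
        design = np.column_stack([np.ones_like(ti), -x])
        coef, *_ = np.linalg.lstsq(design, signal, rcond=None)
        sse = float(np.sum((design @ coef - signal) ** 2))
        if sse < best[0]:
            best = (sse, (float(coef[0]), float(coef[1]), float(t1s)))
    return best[1]


class TestT2Fit:
    def test_exact_monoexponential_recovery(self):
        te = np.array([10.0, 20.0, 30.0])
        signal = 100.0 * np.exp(-te / 10.0)
        s0, t2, diag = fit_t2_pixel(signal, te)
        assert t2 == pytest.approx(10.0, abs=1e-3)
        assert s0 == pytest.approx(100.0, abs=1e-3)
        assert diag["valid"]

    def test_noiseless_recovery_at_protocol_echoes(self):
        signal = 100.0 * np.exp(-PROTOCOL_ECHOES / 25.0)
        _, t2, _ = fit_t2_pixel(signal, PROTOCOL_ECHOES)
        assert t2 == pytest.approx(25.0, rel=1e-3)

    def test_matches_grid_search_oracle_on_noisy_pixels(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            t2_true = rng.uniform(15.0, 45.0)
            signal = 100.0 * np.exp(-PROTOCOL_ECHOES / t2_true) \
                + rng.normal(0, 5.0, PROTOCOL_ECHOES.size)
            _, t2_fit, _ = fit_t2_pixel(signal, PROTOCOL_ECHOES)
            _, t2_grid = grid_search_t2(signal, PROTOCOL_ECHOES)
            assert abs(t2_fit - t2_grid) / t2_grid < 0.005

    def test_too_few_echoes_rejected(self):
        with pytest.raises(ValueError):
            fit_t2_pixel([50.0, 30.0], [10.0, 20.0])

    def test_all_zero_signal_is_invalid_not_an_exception(self):
        _, _, diag = fit_t2_pixel(np.zeros(9), PROTOCOL_ECHOES)
        assert not diag["valid"]


class TestT2Map:
    def test_uniform_stack_gives_constant_map(self, small_labels, tissue_params):
        stack = simulate_t2_series(small_labels, tissue_params, noise_sd=0.0)
        mask = small_labels.remote_mask
        pmap = fit_t2_map(stack, mask)
        vals = pmap.values[mask]
        assert np.nanstd(vals) < 1e-4
        assert np.nanmean(vals) == pytest.approx(tissue_params.remote.t2_ms, rel=1e-5)

    def test_aar_median_exceeds_remote_median(self, noisy_control_animal):
        a = noisy_control_animal
        pmap = fit_t2_map(a.t2_stack, a.labels_cmr.myocardium_mask)
        aar_med = np.nanmedian(pmap.values[a.labels_cmr.aar_mask])
        rem_med = np.nanmedian(pmap.values[a.labels_cmr.remote_mask])
        assert aar_med > rem_med

    def test_empty_mask_yields_empty_map(self, small_labels, tissue_params, caplog):
        stack = simulate_t2_series(small_labels, tissue_params, noise_sd=0.0)
        pmap = fit_t2_map(stack, np.zeros_like(small_labels.labels, dtype=bool))
        assert pmap.n_valid == 0

    def test_mask_shape_mismatch_rejected(self, small_labels, tissue_params):
        stack = simulate_t2_series(small_labels, tissue_params, noise_sd=0.0)
        with pytest.raises(ValueError):
            fit_t2_map(stack, np.zeros((2, 8, 8), dtype=bool))

    def test_validity_accounting_partitions_mask(self, noisy_control_animal):
        a = noisy_control_animal
        mask = a.labels_cmr.myocardium_mask
        pmap = fit_t2_map(a.t2_stack, mask)
        n_valid = int((pmap.valid & mask).sum())
        assert n_valid + pmap.diagnostics["n_invalid"] == int(mask.sum())

    def test_median_error_monotone_in_noise(self, small_labels, tissue_params):
        """Same noise realization rescaled: error grows with noise level."""
        meta = default_t2_meta()
        base = simulate_t2_series(small_labels, tissue_params, meta, noise_sd=0.0)
        rng = np.random.default_rng(7)
        eps = rng.normal(0, 1.0, base.data.shape).astype(np.float32)
        mask = small_labels.remote_mask
        errors = []
        for sd in (1.0, 3.0, 6.0, 10.0):
            noisy = type(base)(base.data + sd * eps, meta)
            pmap = fit_t2_map(noisy, mask)
            err = np.abs(pmap.values[mask] - tissue_params.remote.t2_ms)
            errors.append(np.nanmedian(err))
        assert all(a <= b + 1e-9 for a, b in zip(errors, errors[1:]))


class TestPolarityRestoration:
    def test_magnitude_series_restored_to_signed_reference(self):
        ti = np.linspace(0.05, 10.0, 50)
        a, b, t1s = 34.0, 134.0, 0.52
        signed = a - b * np.exp(-ti / t1s)
        restored = restore_polarity(np.abs(signed), ti)
        np.testing.assert_allclose(restored, signed, rtol=1e-12)

    def test_all_positive_recovery_unchanged(self):
        ti = np.linspace(2.0, 10.0, 20)
        signed = 30.0 - 10.0 * np.exp(-ti / 1.0)  # late sampling, never negative
        restored = restore_polarity(signed.copy(), ti)
        np.testing.assert_allclose(restored, signed)


class TestLookLockerFit:
    def test_noiseless_three_parameter_recovery(self):
        ti = np.linspace(0.05, 10.0, 50)
        signal = 1.0 - 2.0 * np.exp(-ti / 1.2)
        opts = FitOptions(polarity_restoration=False)
        a, b, t1s, diag = fit_ll_pixel(signal, ti, opts)
        assert a == pytest.approx(1.0, rel=1e-6)
        assert b == pytest.approx(2.0, rel=1e-6)
        assert t1s == pytest.approx(1.2, rel=1e-6)

    def test_matches_grid_search_oracle_on_noisy_pixels(self):
        ti = np.linspace(0.05, 10.0, 50)
        rng = np.random.default_rng(3)
        a0, b0, t1s0 = 34.0, 134.0, 0.52
        clean = a0 - b0 * np.exp(-ti / t1s0)
        for _ in range(8):
            signal = clean + rng.normal(0, 5.0, ti.size)
            opts = FitOptions(polarity_restoration=False)
            _, _, t1s_fit, _ = fit_ll_pixel(signal, ti, opts)
            _, _, t1s_grid = grid_search_ll(signal, ti, n=20000)
            assert abs(t1s_fit - t1s_grid) / t1s_grid < 0.01

    def test_flat_series_flagged_invalid(self):
        ti = np.linspace(0.05, 10.0, 50)
        _, _, _, diag = fit_ll_pixel(np.full(50, 5.0), ti,
                                     FitOptions(polarity_restoration=False))
        assert not diag["valid"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_ll_pixel([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])


class TestT1Correction:
    def test_ideal_inversion_identity(self):
        assert correct_t1(1.0, 2.0, 0.7) == pytest.approx(0.7)

    def test_direct_formula_value(self):
        assert correct_t1(1.0, 1.8, 1.0) == pytest.approx(0.8)

    def test_unphysical_parameters_give_nan(self):
        assert np.isnan(correct_t1(1.0, 0.9, 1.0))
        assert np.isnan(correct_t1(-1.0, 2.0, 1.0))

    def test_simulator_round_trip(self, small_labels, tissue_params):
        """Fit + correction recovers the simulator's effective T1 exactly."""
        meta = default_ir_meta("global")
        stack = simulate_ir_series(small_labels, tissue_params, meta, noise_sd=0.0)
        mask = small_labels.myocardium_mask
        pmap = fit_t1_map(stack, mask)
        t1_expected = np.where(small_labels.edema,
                               np.nan, tissue_params.remote.t1_s)
        remote = small_labels.remote_mask
        rel = np.abs(pmap.values[remote] - tissue_params.remote.t1_s) \
            / tissue_params.remote.t1_s
        assert np.nanmax(rel) < 1e-3

    def test_selective_below_global_where_perfused(self, noiseless_control_animal,
                                                   noiseless_maps):
        a = noiseless_control_animal
        myo = a.labels_asl.myocardium_mask
        sel = noiseless_maps["t1_selective"].values
        glo = noiseless_maps["t1_global"].values
        assert np.all(sel[myo] < glo[myo])  # every myocardial pixel has mbf > 0

    def test_global_map_elevated_in_aar(self, noiseless_control_animal,
                                        noiseless_maps):
        a = noiseless_control_animal
        glo = noiseless_maps["t1_global"].values
        assert np.nanmedian(glo[a.labels_asl.aar_mask]) > \
            np.nanmedian(glo[a.labels_asl.remote_mask])
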