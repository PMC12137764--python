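"""Reconstruction pipeline: regridding, two-parameter correction,
GRAPPA, dual-polarity operations, and the known-trajectory oracle."""

import numpy as np
import pytest

from epighost.metrics import ghost_to_signal_ratio, object_and_ghost_masks
from epighost.phantoms import make_coils
from epighost.presets import (
    default_model,
    delay_model,
    factorial_protocol,
    ripple_protocol,
    tuned,
)
from epighost.recon import (
    TwoParamCorrection,
    apply_two_param,
    dual_polarity_average,
    dual_polarity_grappa,
    estimate_two_param,
    fft2c,
    fft_recon,
    grappa_apply,
    grappa_calibrate,
    ifft2c,
    nrmse,
    oracle_recon,
    reconstruct,
    regrid_lines,
    regrid_readout,
)
from epighost.signal import acquire_reference, simulate_acquisition
from epighost.waveforms import build_epi_train
from epighost.experiments import ground_truth_image, simulate_and_reconstruct


class TestRegrid:
    def test_identity_on_uniform_grid(self, rng):
        grid = (np.arange(64) - 32) / 175.0
        y = rng.normal(size=64) + 1j * rng.normal(size=64)
        out = regrid_readout(y, grid, grid)
        assert np.max(np.abs(out - y)) < 1e-12 * np.max(np.abs(y))

    def test_bandlimited_line_oracle(self):
        # band-limited test signal with known closed form
        x0, width = 11.0, 30.0
        f = lambda k: np.exp(-2j * np.pi * k * x0) * np.exp(-((k * width) ** 2))
        kmax = 0.27
        t = np.linspace(0, 1, 301)
        k_nonuni = kmax * (2 * t**1.5 / (t[-1] ** 1.5) - 1)  # compressed at start
        grid = np.linspace(-0.9 * kmax, 0.9 * kmax, 64)
        out = regrid_readout(f(k_nonuni), k_nonuni, grid)
        err = np.sqrt(np.mean(np.abs(out - f(grid)) ** 2))
        assert err < 0.005 * np.max(np.abs(f(grid)))

    def test_reversed_line_matches_forward(self, rng):
        k = np.sort(rng.uniform(-0.3, 0.3, size=200))
        y = np.exp(-2j * np.pi * k * 8.0) * np.exp(-((k * 20.0) ** 2))
        grid = np.linspace(-0.25, 0.25, 48)
        fwd = regrid_readout(y, k, grid)
        rev = regrid_readout(y[::-1], k[::-1], grid)
        assert np.max(np.abs(fwd - rev)) < 1e-9 * np.max(np.abs(fwd))

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            regrid_readout(np.zeros(4, complex), np.array([0.0, 1.0, 0.5, 2.0]),
                           np.linspace(0, 2, 4))


class TestTwoParam:
    def test_recovers_injected_delay_via_shift_theorem(self, phantom96):
        # a gradient delay on flat-top sampling is a constant kx offset,
        # i.e. a linear phase across the projection (Fourier shift)
        p = factorial_protocol(N=96, ramp_sampling=False)
        train = build_epi_train(p, +1)
        model = delay_model(2.0)
        ref = acquire_reference(phantom96, train, model=model)
        corr = estimate_two_param(ref)
        from epighost.units import K_PER_AREA

        dkx = 2.0 * K_PER_AREA * train.lobe.amplitude  # parity kx offset
        phi1_expected = 2 * np.pi * dkx * (p.fov_mm / p.matrix_size)
        assert corr.phi1_rad_per_pixel == pytest.approx(phi1_expected, abs=1e-3)

    def test_recovers_injected_constant_phase(self, phantom96, ripple96):
        train = build_epi_train(ripple96, +1)
        ref = acquire_reference(phantom96, train)
        phi0 = 0.12
        sgn = np.where(train.line_parity[: ref.n_lines] == 0, 1.0, -1.0)
        ref.samples = ref.samples * np.exp(1j * phi0 * sgn)[None, :, None]
        corr = estimate_two_param(ref)
        assert corr.phi0_rad == pytest.approx(phi0, abs=1e-3)
        assert abs(corr.phi1_rad_per_pixel) < 1e-4

    def test_clean_reference_estimates_zero(self, phantom96, ripple96):
        train = build_epi_train(ripple96, +1)
        corr = estimate_two_param(acquire_reference(phantom96, train))
        assert abs(corr.phi0_rad) < 1e-6
        assert abs(corr.phi1_rad_per_pixel) < 1e-6

    def test_apply_is_invertible(self, rng):
        ksp = rng.normal(size=(2, 8, 32)) + 1j * rng.normal(size=(2, 8, 32))
        parity = np.arange(8) % 2
        corr = TwoParamCorrection(0.3, 0.02)
        neg = TwoParamCorrection(-0.3, -0.02)
        out = apply_two_param(apply_two_param(ksp, parity, corr), parity, neg)
        assert np.max(np.abs(out - ksp)) < 1e-12 * np.max(np.abs(ksp))
        ident = apply_two_param(ksp, parity, TwoParamCorrection(0.0, 0.0))
        assert np.max(np.abs(ident - ksp)) < 1e-12 * np.max(np.abs(ksp))

    def test_correction_removes_delay_ghost(self, phantom96, masks96):
        obj, ghost = masks96
        p = factorial_protocol(N=96, ramp_sampling=False)
        model = delay_model(2.0)
        un, _ = simulate_and_reconstruct(phantom96, p, model, two_param=False)
        co, _ = simulate_and_reconstruct(phantom96, p, model, two_param=True)
        e_un = np.sum(np.abs(un.image[ghost]) ** 2)
        e_co = np.sum(np.abs(co.image[ghost]) ** 2)
        assert e_un / e_co >= 50.0


@pytest.fixture(scope="module")
def coil_data96(phantom96):
    coils = make_coils(96, 8, 175.0)
    train = build_epi_train(ripple_protocol(N=96), +1)
    return simulate_acquisition(phantom96, train, coils=coils, oversample=2)


class TestGrappa:
    def test_full_sampling_bypasses_grappa(self, coil_data96):
        res = reconstruct(coil_data96)
        assert res.provenance["grappa"] is False

    def test_synthesized_lines_match_measured(self, coil_data96):
        """Kernel trained on the center block reproduces held-out lines."""
        kgrid = regrid_lines(coil_data96)  # [coil, 96, 96] fully sampled
        R = 2
        acs = kgrid[:, 36:60, :]
        kernel = grappa_calibrate(acs, R=R)
        acquired = np.zeros(96, dtype=bool)
        acquired[::R] = True
        under = np.where(acquired[None, :, None], kgrid, 0.0)
        filled = grappa_apply(under, acquired, kernel)
        miss = ~acquired
        err = np.linalg.norm(filled[:, miss, :] - kgrid[:, miss, :])
        assert err / np.linalg.norm(kgrid[:, miss, :]) < 0.01

    def test_underdetermined_fit_raises(self, coil_data96):
        kgrid = regrid_lines(coil_data96)
        with pytest.raises(ValueError):
            grappa_calibrate(kgrid[:, 40:42, :], R=2)  # smaller than kernel

    def test_parity_corruption_is_amplified(self, phantom96, masks96):
        obj, ghost = masks96
        model = tuned(default_model(), ripple_protocol(N=96))
        coils = make_coils(96, 8, 175.0)
        r3, _ = simulate_and_reconstruct(
            phantom96, ripple_protocol(N=96, grappa_factor=3), model,
            coils=coils, oversample=2,
        )
        r1, _ = simulate_and_reconstruct(
            phantom96, ripple_protocol(N=96), model, coils=coils, oversample=2,
        )
        g3 = ghost_to_signal_ratio(r3.image, obj, ghost)
        g1 = ghost_to_signal_ratio(r1.image, obj, ghost)
        assert g3 >= g1


class TestFftRecon:
    def test_dc_delta_gives_constant_image(self):
        ksp = np.zeros((32, 32), complex)
        ksp[16, 16] = 1.0
        img, _ = fft_recon(ksp)
        assert np.max(np.abs(img - img[0, 0])) < 1e-12

    def test_roundtrip_identity(self, rng):
        img = rng.normal(size=(2, 32, 32)) + 1j * rng.normal(size=(2, 32, 32))
        back = ifft2c(fft2c(img))
        assert np.max(np.abs(back - img)) < 1e-12


class TestOracleRecon:
    def test_reduces_to_fft_on_nominal_data(self, phantom96, ripple96):
        train = build_epi_train(ripple96, +1)
        data = simulate_acquisition(phantom96, train)
        std = reconstruct(data)
        orc = oracle_recon(data)
        # the two paths differ only at the regridding-interpolation level
        assert nrmse(orc, std.image) < 1e-3

    def test_beats_mismatched_fft_on_perturbed_data(self, phantom96, ripple96):
        truth = ground_truth_image(phantom96, 96)
        model = tuned(default_model(), ripple96)
        train = build_epi_train(ripple96, +1)
        data = simulate_acquisition(phantom96, train, model=model)
        ref = acquire_reference(phantom96, train, model=model)
        std = reconstruct(data, reference=ref)
        orc = oracle_recon(data)
        assert nrmse(orc, truth) < 0.03
        assert nrmse(orc, truth) < nrmse(std.image, truth)

    def test_polarity_invariant(self, phantom96, ripple96):
        model = tuned(default_model(), ripple96)
        dp = simulate_acquisition(phantom96, build_epi_train(ripple96, +1), model=model)
        dm = simulate_acquisition(phantom96, build_epi_train(ripple96, -1), model=model)
        op, om = oracle_recon(dp), oracle_recon(dm)
        assert nrmse(op, om) < 1e-6


class TestDualPolarity:
    def test_average_identities(self, rng):
        img = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        g = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        assert np.array_equal(dual_polarity_average(img, img), img)
        out = dual_polarity_average(img + g, img - g)
        assert np.max(np.abs(out - img)) < 1e-12

    def test_sliding_window(self, rng):
        stack = rng.normal(size=(4, 8, 8)) + 1j * rng.normal(size=(4, 8, 8))
        out = dual_polarity_average(stack, mode="sliding")
        assert out.shape == (3, 8, 8)
        assert np.allclose(out[1], 0.5 * (stack[1] + stack[2]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dual_polarity_average(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDualPolarityGrappa:
    def _pair(self, phantom, protocol, model, coils=None):
        dp = simulate_acquisition(
            phantom, build_epi_train(protocol, +1), model=model, coils=coils,
            oversample=2,
        )
        dm = simulate_acquisition(
            phantom, build_epi_train(protocol, -1), model=model, coils=coils,
            oversample=2,
        )
        return dp, dm

    def test_noop_on_clean_data(self, phantom96):
        p = ripple_protocol(N=96)
        dp, dm = self._pair(phantom96, p, None)
        res = dual_polarity_grappa(dp, dm)
        std = reconstruct(dp)
        assert nrmse(res.image, std.image) < 0.01

    def test_corrects_global_delay(self, phantom96, masks96):
        obj, ghost = masks96
        p = factorial_protocol(N=96, ramp_sampling=False)
        dp, dm = self._pair(phantom96, p, delay_model(2.0))
        res = dual_polarity_grappa(dp, dm)
        un, _ = simulate_and_reconstruct(phantom96, p, delay_model(2.0), two_param=False)
        e_un = np.sum(np.abs(un.image[ghost]) ** 2)
        e_dpg = np.sum(np.abs(res.image[ghost]) ** 2)
        assert e_un / e_dpg >= 10.0

    def test_kx_localized_error_beats_it_but_not_averaging(self, phantom96, masks96):
        obj, ghost = masks96
        p = ripple_protocol(N=96)
        model = tuned(default_model(), p)
        dp, dm = self._pair(phantom96, p, model)
        res_dpg = dual_polarity_grappa(dp, dm)
        rp, rm = (reconstruct(d, reference=acquire_reference(
            phantom96, build_epi_train(p, d.train_polarity), model=model))
            for d in (dp, dm))
        avg = dual_polarity_average(rp.image, rm.image)
        e_dpg = np.sum(np.abs(res_dpg.image[ghost]) ** 2)
        e_avg = np.sum(np.abs(avg[ghost]) ** 2)
        assert e_dpg > e_avg


def test_end_to_end_clean_identity(phantom96, ripple96):
    truth = ground_truth_image(phantom96, 96)
    res, _ = simulate_and_reconstruct(phantom96, ripple96, None)
    assert nrmse(res.image, truth) < 0.02
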