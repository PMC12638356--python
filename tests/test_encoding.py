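"""Forward-model, coil-calibration and phase-correction tests."""

import numpy as np
import pytest

from grasemwi.encoding import (
    CoilSet,
    KSpaceData,
    b0_compensate_ag2,
    calibrate_coils_from_patch,
    encode,
    encode_adjoint,
    encode_subspace,
    estimate_b0_phase_maps,
    fft2c,
    ifft2c,
    navigator_phase_correction,
)
from grasemwi.evaluate import identity_basis
from grasemwi.phantom import SimulationConfig, make_brain_like_phantom, simulate_kspace
from grasemwi.sampling import SamplingMaskSet


def _random_setup(rng, n1=12, n2=10, J=4, C=3, density=0.5):
    coils = CoilSet(
        sensitivities=rng.standard_normal((C, n1, n2))
        + 1j * rng.standard_normal((C, n1, n2))
    )
    masks = (rng.random((n1, n2, J)) < density).astype(np.uint8)
    maskset = SamplingMaskSet(masks=masks, nominal_R=1 / density)
    return coils, maskset


class TestEncode:
    def test_constant_image_is_centered_delta(self):
        n = 8
        coils = CoilSet(sensitivities=np.ones((1, n, n), dtype=complex))
        maskset = SamplingMaskSet(masks=np.ones((n, n, 1), np.uint8), nominal_R=1)
        img = np.ones((n, n, 1), dtype=complex)
        k = encode(img, coils, maskset).data[0, :, :, 0]
        expected = np.zeros((n, n))
        expected[n // 2, n // 2] = n  # orthonormal FFT of a constant
        assert np.allclose(k, expected, atol=1e-12)

    def test_zero_mask_zero_output(self, rng):
        coils, maskset = _random_setup(rng, density=0.5)
        empty = SamplingMaskSet(masks=np.zeros_like(maskset.masks), nominal_R=1)
        x = rng.standard_normal((12, 10, 4)) + 0j
        assert np.all(encode(x, coils, empty).data == 0)

    def test_adjoint_dot_product(self, rng):
        coils, maskset = _random_setup(rng)
        x = rng.standard_normal((12, 10, 4)) + 1j * rng.standard_normal((12, 10, 4))
        y = rng.standard_normal((3, 12, 10, 4)) + 1j * rng.standard_normal((3, 12, 10, 4))
        lhs = np.vdot(y, encode(x, coils, maskset).data)
        rhs = np.vdot(encode_adjoint(KSpaceData(data=y), coils, maskset), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_adjoint_dot_product_with_phase_maps(self, rng):
        coils, maskset = _random_setup(rng)
        theta = rng.uniform(-np.pi, np.pi, (12, 10, 4))
        x = rng.standard_normal((12, 10, 4)) + 1j * rng.standard_normal((12, 10, 4))
        y = rng.standard_normal((3, 12, 10, 4)) + 1j * rng.standard_normal((3, 12, 10, 4))
        lhs = np.vdot(y, encode(x, coils, maskset, phase_maps=theta).data)
        rhs = np.vdot(encode_adjoint(KSpaceData(data=y), coils, maskset, phase_maps=theta), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_linearity(self, rng):
        coils, maskset = _random_setup(rng)
        x = rng.standard_normal((12, 10, 4)) + 1j * rng.standard_normal((12, 10, 4))
        y = rng.standard_normal((12, 10, 4)) + 1j * rng.standard_normal((12, 10, 4))
        lhs = encode(2.0 * x + 3j * y, coils, maskset).data
        rhs = 2.0 * encode(x, coils, maskset).data + 3j * encode(y, coils, maskset).data
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_full_mask_unit_coil_roundtrip(self, rng):
        n1, n2, J = 12, 10, 3
        coils = CoilSet(sensitivities=np.ones((1, n1, n2), dtype=complex))
        maskset = SamplingMaskSet(masks=np.ones((n1, n2, J), np.uint8), nominal_R=1)
        x = rng.standard_normal((n1, n2, J)) + 1j * rng.standard_normal((n1, n2, J))
        back = encode_adjoint(encode(x, coils, maskset), coils, maskset)
        assert np.allclose(back, x, atol=1e-12)


class TestEncodeSubspace:
    def test_identity_basis_equals_encode(self, rng):
        coils, maskset = _random_setup(rng)
        basis = identity_basis(4)
        x = rng.standard_normal((12, 10, 4)) + 1j * rng.standard_normal((12, 10, 4))
        assert np.allclose(
            encode_subspace(x, basis, coils, maskset).data,
            encode(x, coils, maskset).data,
            atol=1e-12,
        )

    def test_zero_alpha_zero_kspace(self, rng, grid40, mse_spec):
        from grasemwi.dictionary import build_model_dictionary, derive_subspace

        coils, maskset = _random_setup(rng, J=mse_spec.n_se)
        basis = derive_subspace(build_model_dictionary(grid40, [180.0], mse_spec), 4)
        alpha = np.zeros((12, 10, 4), dtype=complex)
        assert np.all(encode_subspace(alpha, basis, coils, maskset).data == 0)

    def test_matches_composed_pipeline(self, rng, grid40, mse_spec):
        from grasemwi.dictionary import build_model_dictionary, derive_subspace

        coils, maskset = _random_setup(rng, J=mse_spec.n_se)
        basis = derive_subspace(build_model_dictionary(grid40, [180.0], mse_spec), 4)
        alpha = rng.standard_normal((12, 10, 4)) + 1j * rng.standard_normal((12, 10, 4))
        direct = encode_subspace(alpha, basis, coils, maskset).data
        composed = encode(alpha @ basis.phi, coils, maskset).data
        assert np.allclose(direct, composed, atol=1e-12)


class TestCoilCalibration:
    def test_recovers_simulated_sensitivities(self):
        phantom = make_brain_like_phantom((48, 48), seed=3)
        cfg = SimulationConfig(
            config_id="AG2_caipis", R=1, noise_sigma=0.0, spec=_short_spec(), patch_size=(16, 16)
        )
        kspace, plan, _, _ = simulate_kspace(phantom, cfg)
        est = calibrate_coils_from_patch(kspace, (16, 16), plan.maskset)
        true = phantom.coils.sensitivities
        true_norm = true / np.sqrt((np.abs(true) ** 2).sum(axis=0, keepdims=True))
        support = phantom.support
        # compare magnitudes on the interior support (both RSS-normalized)
        err = np.abs(np.abs(est.sensitivities) - np.abs(true_norm))[:, support]
        assert np.mean(err) < 0.05

    def test_single_unit_coil_magnitude(self):
        n = 32
        img = np.zeros((n, n), dtype=complex)
        img[8:24, 8:24] = 1.0
        k = fft2c(img)[None, :, :, None]
        est = calibrate_coils_from_patch(KSpaceData(data=k), (12, 12))
        center = np.abs(est.sensitivities[0, 12:20, 12:20])
        assert np.allclose(center, 1.0, atol=1e-6)

    def test_scale_invariance(self, rng):
        k = rng.standard_normal((3, 16, 16, 2)) + 1j * rng.standard_normal((3, 16, 16, 2))
        a = calibrate_coils_from_patch(KSpaceData(data=k), (8, 8))
        b = calibrate_coils_from_patch(KSpaceData(data=2.0 * k), (8, 8))
        assert np.allclose(a.sensitivities, b.sensitivities, atol=1e-12)


def _short_spec():
    from grasemwi.phantom import default_echo_train

    return default_echo_train()


class TestNavigatorCorrection:
    def test_zero_phase_navigator_identity(self, rng):
        data = rng.standard_normal((3, 8, 16, 4)) + 1j * rng.standard_normal((3, 8, 16, 4))
        nav = np.abs(rng.standard_normal((16, 4))) + 0.1
        assert np.allclose(navigator_phase_correction(data, nav), data, atol=1e-12)

    def test_magnitudes_preserved(self, rng):
        data = rng.standard_normal((8, 16, 4)) + 1j * rng.standard_normal((8, 16, 4))
        nav = np.exp(1j * rng.uniform(-np.pi, np.pi, (16, 4)))
        out = navigator_phase_correction(data, nav)
        assert np.allclose(np.abs(out), np.abs(data), atol=1e-12)

    def test_linear_field_along_readout_corrected(self):
        """A field offset varying only along the readout axis phases the
        gradient echoes; removing the navigator phase makes them match the
        spin echo to well under 1% RMS."""
        n_fe = 64
        profile = np.exp(-((np.arange(n_fe) - 32) ** 2) / 200.0)  # 1D object
        omega = np.linspace(-2 * np.pi * 100, 2 * np.pi * 100, n_fe)  # rad/s
        offsets = np.array([-2.5e-3, 0.0, 2.5e-3])
        echoes = profile[:, None] * np.exp(1j * omega[:, None] * offsets[None, :])
        nav = echoes.copy()  # navigator sees the same phase evolution
        corrected = navigator_phase_correction(echoes, nav)
        se = corrected[:, 1]
        for j in (0, 2):
            rel = np.linalg.norm(corrected[:, j] - se) / np.linalg.norm(se)
            assert rel < 0.01

    def test_missing_echo_rejected(self, rng):
        data = rng.standard_normal((8, 4)) + 0j
        with pytest.raises(ValueError):
            navigator_phase_correction(data, np.ones((8, 3)))


@pytest.fixture(scope="module")
def ag2_sim():
    phantom = make_brain_like_phantom((48, 48), seed=5)
    cfg = SimulationConfig(
        config_id="AG2_caipis", R=1, noise_sigma=0.0, spec=_short_spec(), patch_size=(12, 12)
    )
    kspace, plan, truth, _ = simulate_kspace(phantom, cfg)
    return phantom, kspace, plan, truth


class TestB0Compensation:
    def test_zero_field_identity(self):
        phantom = make_brain_like_phantom((48, 48), seed=5, db0_max_hz=0.0)
        cfg = SimulationConfig(
            config_id="AG2_caipis", R=1, noise_sigma=0.0, spec=_short_spec(), patch_size=(12, 12)
        )
        kspace, plan, _, _ = simulate_kspace(phantom, cfg)
        corrected, theta = b0_compensate_ag2(
            kspace, phantom.coils, _short_spec(), (12, 12), plan.maskset
        )
        assert np.max(np.abs(theta)) < 1e-6
        assert np.allclose(corrected.data, kspace.data, atol=1e-10)

    def test_estimated_field_accurate(self, ag2_sim):
        phantom, kspace, plan, _ = ag2_sim
        omega, _ = estimate_b0_phase_maps(
            kspace, phantom.coils, _short_spec(), (12, 12), plan.maskset
        )
        err_hz = (omega - phantom.delta_b0)[phantom.support] / (2 * np.pi)
        field_hz = phantom.delta_b0[phantom.support] / (2 * np.pi)
        assert np.sqrt(np.mean(err_hz**2)) < 0.1 * np.sqrt(np.mean(field_hz**2))

    def test_phase_excursion_reduced_90_percent(self, ag2_sim):
        phantom, kspace, plan, truth = ag2_sim
        spec = _short_spec()
        _, theta = estimate_b0_phase_maps(
            kspace, phantom.coils, spec, (12, 12), plan.maskset
        )
        imgs = truth.images
        support = phantom.support
        se = spec.spin_echo_indices

        def excursion(x):
            total, weight = 0.0, 0.0
            for g in range(spec.n_se):
                j_se = se[g]
                for b in range(spec.n_ge + 1):
                    j = g * (spec.n_ge + 1) + b
                    if j == j_se:
                        continue
                    dphi = np.angle(x[..., j] * np.conj(x[..., j_se]))
                    w = np.abs(x[..., j_se]) * support
                    total += (w * dphi**2).sum()
                    weight += w.sum()
            return np.sqrt(total / weight)

        before = excursion(imgs)
        after = excursion(imgs * np.exp(-1j * theta))
        assert after <= 0.1 * before

    def test_magnitudes_unchanged(self, ag2_sim):
        phantom, kspace, plan, _ = ag2_sim
        corrected, _ = b0_compensate_ag2(
            kspace, phantom.coils, _short_spec(), (12, 12), plan.maskset
        )
        # full sampling: compensation is phase-only in the image domain
        mag_before = np.abs(ifft2c(kspace.data, axes=(1, 2)))
        mag_after = np.abs(ifft2c(corrected.data, axes=(1, 2)))
        assert np.allclose(mag_before, mag_after, atol=1e-10)
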