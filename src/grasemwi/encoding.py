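"""Multi-coil Fourier encoding and phase-correction steps.

The reconstruction operates per readout position on 2D phase-encode planes
(PE1 x PE2): the frequency-encode axis of the 3D scan is fully sampled and
already transformed.  The forward model of one coil c and echo j is

    mu_c = U . F C_c S

with U the binary sampling mask, F the centered orthonormal 2D Fourier
transform, C_c the coil sensitivity and S the echo image.  This module
provides the operator, its adjoint, a central-k-space coil calibration, and
the two phase-correction steps used by the GRASE configurations: navigator
(zero-phase-encode) correction along the frequency-encode axis, and
patch-based field-offset (B0) compensation for the separated-k-space
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epg import EchoTrainSpec
from .sampling import SamplingMaskSet

__all__ = [
    "CoilSet",
    "KSpaceData",
    "EchoImages",
    "fft2c",
    "ifft2c",
    "encode",
    "encode_adjoint",
    "encode_subspace",
    "calibrate_coils_from_patch",
    "navigator_phase_correction",
    "b0_compensate_ag2",
    "estimate_b0_phase_maps",
]


@dataclass(frozen=True)
class CoilSet:
    """Complex coil sensitivity maps, shape (C, PE1, PE2)."""

    sensitivities: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.sensitivities) ** 2).sum(axis=0))


@dataclass(frozen=True)
class KSpaceData:
    """Measured multi-coil k-space, shape (C, PE1, PE2, echo).

    Unsampled entries are exactly zero; the companion mask set identifies
    them.  ``sigma`` is the noise standard deviation per real/imaginary
    channel.
    """

    data: np.ndarray
    sigma: float = 0.0

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:3]


@dataclass(frozen=True)
class EchoImages:
    """Complex echo images, shape (PE1, PE2, echo)."""

    images: np.ndarray

    @property
    def n_echoes(self) -> int:
        return self.images.shape[-1]


def fft2c(x: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Centered orthonormal 2D FFT (DC at index floor(N/2))."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft2c(x: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def encode(
    images: EchoImages | np.ndarray,
    coils: CoilSet,
    maskset: SamplingMaskSet,
    phase_maps: np.ndarray | None = None,
) -> KSpaceData:
    """Forward model: per coil and echo, U . F (C_c S).

    ``phase_maps``, if given, is a (PE1, PE2, echo) array of phase angles
    applied in the image domain before encoding (used to re-insert an
    estimated field-offset phase into the model during compensated
    reconstruction).
    """
    s = images.images if isinstance(images, EchoImages) else np.asarray(images)
    sens = coils.sensitivities
    if s.shape[:2] != sens.shape[1:]:
        raise ValueError(f"image grid {s.shape[:2]} does not match coils {sens.shape[1:]}")
    if s.shape[-1] != maskset.n_echoes:
        raise ValueError(
            f"{s.shape[-1]} echoes but maskset has {maskset.n_echoes}"
        )
    if phase_maps is not None:
        s = s * np.exp(1j * phase_maps)
    weighted = sens[:, :, :, None] * s[None, :, :, :]
    k = fft2c(weighted, axes=(1, 2))
    k *= maskset.masks[None, :, :, :]
    return KSpaceData(data=k)


def encode_adjoint(
    kspace: KSpaceData | np.ndarray,
    coils: CoilSet,
    maskset: SamplingMaskSet,
    phase_maps: np.ndarray | None = None,
) -> np.ndarray:
    """Adjoint of :func:`encode`: sum_c conj(C_c) F^H (U . Z_c)."""
    z = kspace.data if isinstance(kspace, KSpaceData) else np.asarray(kspace)
    z = z * maskset.masks[None, :, :, :]
    imgs = ifft2c(z, axes=(1, 2))
    out = (np.conj(coils.sensitivities)[:, :, :, None] * imgs).sum(axis=0)
    if phase_maps is not None:
        out = out * np.exp(-1j * phase_maps)
    return out


def encode_subspace(
    alpha: np.ndarray,
    basis,
    coils: CoilSet,
    maskset: SamplingMaskSet,
    phase_maps: np.ndarray | None = None,
) -> KSpaceData:
    """Subspace forward model: U . F C_c (alpha Phi)."""
    if alpha.shape[-1] != basis.d:
        raise ValueError(f"alpha has {alpha.shape[-1]} maps but basis d={basis.d}")
    images = alpha @ basis.phi
    return encode(images, coils, maskset, phase_maps)


def _hann2(p1: int, p2: int) -> np.ndarray:
    w1 = np.hanning(p1 + 2)[1:-1]
    w2 = np.hanning(p2 + 2)[1:-1]
    return np.outer(w1, w2)


def _patch_slices(grid_shape, patch_edges):
    n1, n2 = grid_shape
    p1, p2 = patch_edges
    s1 = n1 // 2 - p1 // 2
    s2 = n2 // 2 - p2 // 2
    return slice(s1, s1 + p1), slice(s2, s2 + p2)


def patch_images(
    kspace: KSpaceData, patch_edges, apodize: bool = True
) -> np.ndarray:
    """Low-resolution per-coil echo images from the central k-space patch.

    The central ``patch_edges`` region is extracted per coil/echo, Hann
    apodized (suppressing ringing in downstream phase maps), zero-filled to
    the full grid and inverse transformed.  Returns (C, PE1, PE2, echo).
    """
    p1, p2 = patch_edges
    sl1, sl2 = _patch_slices(kspace.grid_shape, patch_edges)
    window = _hann2(p1, p2) if apodize else np.ones((p1, p2))
    padded = np.zeros_like(kspace.data)
    padded[:, sl1, sl2, :] = kspace.data[:, sl1, sl2, :] * window[None, :, :, None]
    return ifft2c(padded, axes=(1, 2))


def calibrate_coils_from_patch(
    kspace: KSpaceData,
    patch_edges,
    maskset: SamplingMaskSet | None = None,
    rel_threshold: float = 1e-3,
) -> CoilSet:
    """Coil sensitivities from the fully sampled central k-space patch.

    Low-resolution coil images of the first echo are normalized by their
    root-sum-of-squares magnitude; voxels below ``rel_threshold`` of the peak
    RSS get zero sensitivity.  Invariant to a global scaling of the data.
    """
    if maskset is not None:
        sl1, sl2 = _patch_slices(kspace.grid_shape, patch_edges)
        if not np.all(maskset.masks[sl1, sl2, 0] == 1):
            raise ValueError("central patch is not fully sampled in the first echo")
    low = patch_images(kspace, patch_edges)[..., 0]  # (C, PE1, PE2)
    rss = np.sqrt((np.abs(low) ** 2).sum(axis=0))
    floor = rel_threshold * rss.max()
    sens = np.where(rss[None] > floor, low / np.where(rss[None] > 0, rss[None], 1.0), 0.0)
    return CoilSet(sensitivities=sens)


def navigator_phase_correction(
    data: np.ndarray, navigator: np.ndarray
) -> np.ndarray:
    """Remove the navigator's frequency-encode phase profile per echo.

    ``data`` is a hybrid-space array (..., FE, echo) — image domain along
    the frequency-encode axis — and ``navigator`` is the zero-phase-encode
    readout signal (FE, echo) recorded without phase encoding.  Each echo's
    1D phase profile along FE, as estimated from the navigator, is removed
    from every line of that echo; magnitudes are untouched.
    """
    navigator = np.asarray(navigator)
    data = np.asarray(data)
    if navigator.shape[-1] != data.shape[-1]:
        raise ValueError(
            f"navigator covers {navigator.shape[-1]} echoes, data has {data.shape[-1]}"
        )
    phase = np.angle(navigator)
    return data * np.exp(-1j * phase)


def navigator_correct_composite(
    kspace: KSpaceData, plan, navigator: np.ndarray
) -> KSpaceData:
    """Zero-phase-encode correction of composite (AG0/AG1) k-space data.

    The navigator is the per-readout projection signal along the first
    spatial axis, recorded without phase encoding; its phase profile captures
    the field-offset phase each gradient echo accrues along that axis.  The
    data are brought to hybrid space (image domain along axis 1, k-space
    along axis 2), each column's phase profile for its source readout is
    removed, and the data transformed back and re-masked.  Magnitudes at the
    sampled locations are preserved.  Only the phase component separable
    along the corrected axis is removed — the in-plane remainder is the
    residual artifact characteristic of composite GRASE sampling.
    """
    phase = np.angle(np.asarray(navigator))  # (axis1, J)
    d = kspace.data
    h = np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(d, axes=1), axis=1, norm="ortho"), axes=1
    )
    # column pe2 of composite target m holds readout plan.source_echo[m, pe2]
    corr = np.exp(-1j * phase[:, plan.source_echo])  # (axis1, targets, pe2)
    h = h * corr.transpose(0, 2, 1)[None]
    out = np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(h, axes=1), axis=1, norm="ortho"), axes=1
    )
    out = out * plan.maskset.masks[None]
    return KSpaceData(data=out, sigma=kspace.sigma)


def estimate_b0_phase_maps(
    kspace: KSpaceData,
    coils: CoilSet,
    spec: EchoTrainSpec,
    patch_edges=(12, 12),
    maskset: SamplingMaskSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-voxel field-offset phase maps from the central patch.

    Low-resolution echo images are reconstructed from the fully sampled
    central patch and coil-combined.  Within each spin-echo group the phase
    accrued between readouts separated by time offset differences dDelta is
    wrapped to (-pi, pi] and fitted per voxel by least squares to a single
    angular frequency omega (rad/s) — the linear-phase model of a local field
    offset, whose phase is refocused at every spin echo.

    Returns ``(omega, theta)`` where ``omega`` is the (PE1, PE2) rad/s map
    and ``theta`` the (PE1, PE2, J) phase angles ``omega * Delta_j``.
    """
    if maskset is not None:
        sl1, sl2 = _patch_slices(kspace.grid_shape, patch_edges)
        if not np.all(maskset.masks[sl1, sl2, :] == 1):
            raise ValueError("central patch must be fully sampled in every echo")
    low = patch_images(kspace, patch_edges)  # (C, PE1, PE2, J)
    sens = coils.sensitivities
    denom = (np.abs(sens) ** 2).sum(axis=0)
    combined = (np.conj(sens)[:, :, :, None] * low).sum(axis=0)
    combined = np.where(denom[:, :, None] > 0, combined / np.where(denom[:, :, None] > 0, denom[:, :, None], 1.0), 0.0)

    offsets_s = spec.readout_offsets * 1e-3
    n_group = spec.n_ge + 1
    phases = np.angle(combined)
    num = np.zeros(kspace.grid_shape)
    den = 0.0
    for g in range(spec.n_se):
        for a in range(n_group - 1):
            j0 = g * n_group + a
            j1 = j0 + 1
            dphi = phases[..., j1] - phases[..., j0]
            dphi = np.angle(np.exp(1j * dphi))  # wrap to (-pi, pi]
            dt = offsets_s[j1] - offsets_s[j0]
            # weight by the pair's magnitude so empty voxels do not bias
            w = np.abs(combined[..., j0]) * np.abs(combined[..., j1])
            num += w * dphi * dt
            den = den + w * dt * dt
    omega = np.divide(num, den, out=np.zeros_like(num), where=np.asarray(den) > 0)
    theta = omega[:, :, None] * offsets_s[None, None, :]
    return omega, theta


def b0_compensate_ag2(
    kspace: KSpaceData,
    coils: CoilSet,
    spec: EchoTrainSpec,
    patch_edges=(12, 12),
    maskset: SamplingMaskSet | None = None,
) -> tuple[KSpaceData, np.ndarray]:
    """Patch-based field-offset compensation for separated k-spaces.

    The smooth phase maps estimated from the central calibration patch are
    conjugate-applied to each echo's image-domain representation (a
    convolution in k-space); the sampled locations are then re-extracted.
    After compensation only the residual (non-smooth) field offset remains,
    so a narrow dictionary regime (tens of Hz) applies downstream.  Returns
    the compensated k-space and the phase maps ``theta`` (PE1, PE2, J); for
    exact modelling of undersampled data, pass ``theta`` to the encoder
    instead of using the convolved data.
    """
    _, theta = estimate_b0_phase_maps(kspace, coils, spec, patch_edges, maskset)
    imgs = ifft2c(kspace.data, axes=(1, 2))
    imgs = imgs * np.exp(-1j * theta)[None]
    corrected = fft2c(imgs, axes=(1, 2))
    if maskset is not None:
        corrected = corrected * maskset.masks[None]
    return KSpaceData(data=corrected, sigma=kspace.sigma), theta
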