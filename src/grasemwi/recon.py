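"""Subspace-constrained reconstruction of multi-echo images.

The estimation problem is linear least squares in the subspace coefficients
alpha (one d-vector per voxel):

    alpha_hat = argmin_alpha  sum_c || Z_c - U . F C_c (alpha Phi) ||_2^2

solved by conjugate gradients on the normal equations from zero
initialization.  The noise level sigma scales the likelihood but not the
minimizer, so it does not enter the solver.  Echo images are synthesized as
S = alpha Phi.  A conventional fully sampled reference reconstruction
(inverse FFT plus sensitivity-weighted coil combination) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import SubspaceBasis
from .encoding import CoilSet, EchoImages, KSpaceData, encode, encode_adjoint, ifft2c
from .sampling import SamplingMaskSet

__all__ = ["SolverReport", "scr_solve", "expand_images", "reference_recon"]


@dataclass(frozen=True)
class SolverReport:
    """Convergence record of one SCR solve.

    ``relative_residual`` is ||Z - mu(alpha)|| / ||Z|| over all coils;
    ``data_match_fraction`` is its complement (the fraction of measured
    k-space energy explained by the subspace model).
    """

    iterations: int
    relative_residual: float
    converged: bool

    @property
    def data_match_fraction(self) -> float:
        return 1.0 - self.relative_residual


def _normal_op(
    alpha: np.ndarray,
    basis: SubspaceBasis,
    coils: CoilSet,
    maskset: SamplingMaskSet,
    phase_maps,
    tikhonov: float,
) -> np.ndarray:
    images = alpha @ basis.phi
    k = encode(images, coils, maskset, phase_maps)
    back = encode_adjoint(k, coils, maskset, phase_maps)
    out = back @ basis.phi.conj().T
    if tikhonov > 0:
        out = out + tikhonov * alpha
    return out


def scr_solve(
    kspace: KSpaceData,
    maskset: SamplingMaskSet,
    coils: CoilSet,
    basis: SubspaceBasis,
    tol: float = 1e-6,
    max_iter: int = 200,
    phase_maps: np.ndarray | None = None,
    tikhonov: float = 0.0,
) -> tuple[np.ndarray, SolverReport]:
    """Solve for the subspace coefficient maps.

    Returns ``(alpha, report)`` with ``alpha`` of shape (PE1, PE2, d).
    Conjugate gradients on the normal equations, zero initialization;
    ``tol`` is the relative tolerance on the normal-equation residual.
    Non-convergence within ``max_iter`` is flagged in the report and the
    current iterate returned.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if maskset.masks.sum() == 0:
        raise ValueError("maskset samples no k-space points")
    if kspace.data.shape[-1] != basis.n_echoes:
        raise ValueError(
            f"k-space has {kspace.data.shape[-1]} echoes, basis expects {basis.n_echoes}"
        )

    z_norm = np.linalg.norm(kspace.data)
    if z_norm == 0:
        alpha = np.zeros(maskset.grid_shape + (basis.d,), dtype=complex)
        return alpha, SolverReport(iterations=0, relative_residual=0.0, converged=True)

    # right-hand side b = A^H z
    b = encode_adjoint(kspace, coils, maskset, phase_maps) @ basis.phi.conj().T
    alpha = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs_old = np.vdot(r, r).real
    b_norm = np.sqrt(np.vdot(b, b).real)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ap = _normal_op(p, basis, coils, maskset, phase_maps, tikhonov)
        denom = np.vdot(p, ap).real
        if denom <= 0:
            break
        step = rs_old / denom
        alpha = alpha + step * p
        r = r - step * ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) <= tol * b_norm:
            converged = True
            break
        p = r + (rs_new / rs_old) * p
        rs_old = rs_new

    mu = encode(alpha @ basis.phi, coils, maskset, phase_maps)
    rel = float(np.linalg.norm(kspace.data - mu.data) / z_norm)
    return alpha, SolverReport(iterations=it, relative_residual=rel, converged=converged)


def expand_images(alpha: np.ndarray, basis: SubspaceBasis) -> EchoImages:
    """Synthesize echo images S = alpha Phi from coefficient maps."""
    if alpha.shape[-1] != basis.d:
        raise ValueError(f"alpha has {alpha.shape[-1]} maps, basis d={basis.d}")
    return EchoImages(images=alpha @ basis.phi)


def reference_recon(kspace: KSpaceData, coils: CoilSet) -> EchoImages:
    """Fully sampled reference: inverse FFT and sensitivity-weighted combine.

    Per echo: S = sum_c conj(C_c) F^H Z_c / sum_c |C_c|^2, zero where the
    sensitivity denominator vanishes.
    """
    imgs = ifft2c(kspace.data, axes=(1, 2))
    sens = coils.sensitivities
    num = (np.conj(sens)[:, :, :, None] * imgs).sum(axis=0)
    den = (np.abs(sens) ** 2).sum(axis=0)[:, :, None]
    combined = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return EchoImages(images=combined)
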