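"""Signal dictionaries and SVD-derived subspace bases.

The subspace-constrained reconstruction restricts every voxel's signal
evolution across the J echoes to a low-dimensional linear span.  The span is
computed from a dictionary of candidate evolutions:

* a model dictionary of EPG decay curves over a (T2, flip-angle) grid —
  each atom is the partial derivative of the multi-component voxel signal
  with respect to one spectral amplitude, i.e. the EPG curve of that T2;
* its GRASE extension, where each atom is additionally modulated by
  reversible dephasing (R2') and field-offset (dB0) factors at the
  gradient-echo time offsets;
* a data-driven dictionary whose atoms are the voxel evolutions of
  low-resolution echo images reconstructed from a fully sampled central
  k-space patch.

The basis is the set of leading right singular vectors of the atom matrix;
with thousands of atoms of length J it is computed exactly from the J x J
Gram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epg import EchoTrainSpec, T2Grid, epg_echo_amplitudes, grase_modulation

__all__ = [
    "Dictionary",
    "SubspaceBasis",
    "build_model_dictionary",
    "build_model_dictionary_ag2",
    "build_patch_dictionary",
    "derive_subspace",
    "project_onto_subspace",
]


@dataclass(frozen=True)
class Dictionary:
    """Matrix of candidate signal evolutions, one atom per row.

    ``atoms`` has shape (n_atoms, J).  ``meta`` carries per-atom provenance:
    a structured array of (t2, fa, r2_prime, delta_b0) for model dictionaries
    or source-voxel indices for patch dictionaries.
    """

    atoms: np.ndarray
    meta: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.atoms.shape[1]


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal subspace basis Phi of shape (d, J) with rows Phi Phi^H = I.

    ``energy_fraction`` is the cumulative squared-singular-value fraction of
    the dictionary captured by the d components.
    """

    phi: np.ndarray
    singular_values: np.ndarray
    energy_fraction: float

    @property
    def d(self) -> int:
        return self.phi.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.phi.shape[1]


_MODEL_META = np.dtype(
    [("t2", float), ("fa", float), ("r2_prime", float), ("delta_b0", float)]
)


def _epg_atom_block(grid: T2Grid, fa_list, spec: EchoTrainSpec) -> tuple[np.ndarray, np.ndarray]:
    """EPG curves for every (T2, FA) pair; returns (atoms, meta)."""
    fa_list = np.atleast_1d(np.asarray(fa_list, dtype=float))
    if fa_list.size == 0:
        raise ValueError("fa_list must be non-empty")
    if np.any((fa_list <= 0) | (fa_list > 180)):
        raise ValueError("flip angles must be in (0, 180] degrees")
    atoms = np.empty((grid.n * fa_list.size, spec.n_se))
    meta = np.zeros(grid.n * fa_list.size, dtype=_MODEL_META)
    i = 0
    for fa in fa_list:
        fa_spec = EchoTrainSpec(
            n_se=spec.n_se,
            esp=spec.esp,
            n_ge=spec.n_ge,
            ge_offsets=spec.ge_offsets,
            refocus_fa=float(fa),
            t1_assumed=spec.t1_assumed,
        )
        for t2 in grid.values:
            atoms[i] = epg_echo_amplitudes(float(t2), fa_spec)
            meta[i] = (t2, fa, 0.0, 0.0)
            i += 1
    return atoms, meta


def build_model_dictionary(grid: T2Grid, fa_list, spec: EchoTrainSpec) -> Dictionary:
    """Model dictionary for spin-echo trains: one EPG curve per (T2, FA).

    The atom for grid entry t is the derivative of the voxel decay with
    respect to the spectral amplitude s_t, i.e. the unit-amplitude EPG curve
    at that T2.  Atoms are stored complex for a uniform contract with the
    GRASE dictionary (their imaginary part is zero).
    """
    atoms, meta = _epg_atom_block(grid, fa_list, spec)
    return Dictionary(atoms=atoms.astype(complex), meta=meta)


def build_model_dictionary_ag2(
    grid: T2Grid,
    fa_list,
    r2p_list,
    db0_list,
    spec: EchoTrainSpec,
    max_atoms: int | None = None,
    seed: int | None = None,
) -> Dictionary:
    """GRASE model dictionary over the (T2, FA, R2', dB0) cross product.

    Each base EPG curve is expanded to the full readout train and modulated
    by ``exp(-|Delta_j| R2' + i dB0 Delta_j)`` (R2' in 1/s, dB0 in rad/s).
    When the cross product exceeds ``max_atoms``, a uniformly random subset
    of (T2, FA, R2', dB0) tuples is drawn reproducibly from ``seed``.
    """
    r2p_list = np.atleast_1d(np.asarray(r2p_list, dtype=float))
    db0_list = np.atleast_1d(np.asarray(db0_list, dtype=float))
    if r2p_list.size == 0 or db0_list.size == 0:
        raise ValueError("r2p_list and db0_list must be non-empty")
    if max_atoms is not None and max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")

    base_atoms, base_meta = _epg_atom_block(grid, fa_list, spec)
    n_base = base_atoms.shape[0]
    n_mod = r2p_list.size * db0_list.size
    total = n_base * n_mod

    if max_atoms is not None and total > max_atoms:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_atoms, replace=False)
        flat.sort()
    else:
        flat = np.arange(total)

    # flat index decomposes as (base, r2p, db0)
    base_idx, rem = np.divmod(flat, n_mod)
    r2p_idx, db0_idx = np.divmod(rem, db0_list.size)

    mods = grase_modulation(r2p_list[r2p_idx], db0_list[db0_idx], spec)
    expanded = np.repeat(base_atoms[base_idx], spec.n_ge + 1, axis=1)
    atoms = expanded * mods

    meta = base_meta[base_idx].copy()
    meta["r2_prime"] = r2p_list[r2p_idx]
    meta["delta_b0"] = db0_list[db0_idx]
    return Dictionary(atoms=atoms, meta=meta)


def build_patch_dictionary(patch_images: np.ndarray, rel_floor: float = 1e-6) -> Dictionary:
    """Data-driven dictionary from low-resolution echo images.

    ``patch_images`` is a complex array (..., J): the per-echo evolutions of
    the voxels of images reconstructed from a fully sampled central k-space
    patch.  One atom per voxel; voxels whose maximum magnitude across echoes
    falls below ``rel_floor`` times the global maximum are dropped.
    """
    patch_images = np.asarray(patch_images)
    if patch_images.ndim < 2:
        raise ValueError("patch_images must have a trailing echo axis")
    flat = patch_images.reshape(-1, patch_images.shape[-1])
    peak = np.abs(flat).max(axis=1)
    top = peak.max()
    if top == 0:
        raise ValueError("patch images contain no usable atoms (all zero)")
    keep = peak > rel_floor * top
    atoms = flat[keep].astype(complex)
    meta = np.flatnonzero(keep)
    return Dictionary(atoms=atoms, meta=meta)


def derive_subspace(dictionary: Dictionary, d: int, normalize: bool = True) -> SubspaceBasis:
    """Top-d right-singular-vector basis of the atom matrix.

    Atoms are l2-normalized first (by default) so that no parameter cell
    dominates the basis.  The singular structure is computed exactly from the
    J x J Gram matrix A^H A, which is cheap even for very large dictionaries.
    """
    J = dictionary.n_echoes
    if not (1 <= d < J):
        raise ValueError(f"require 1 <= d < J={J}, got d={d}")
    atoms = dictionary.atoms
    if normalize:
        norms = np.linalg.norm(atoms, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("dictionary contains an all-zero atom")
        atoms = atoms / norms
    gram = atoms.conj().T @ atoms
    evals, evecs = np.linalg.eigh(gram)
    evals = np.maximum(evals[::-1], 0.0)
    evecs = evecs[:, ::-1]
    phi = evecs[:, :d].conj().T
    singular_values = np.sqrt(evals)
    total = evals.sum()
    energy = float(evals[:d].sum() / total) if total > 0 else 0.0
    return SubspaceBasis(phi=phi, singular_values=singular_values, energy_fraction=energy)


def project_onto_subspace(
    signals: np.ndarray, basis: SubspaceBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Project signals (..., J) onto the basis.

    Returns ``(coefficients, residual_fraction)`` where coefficients have
    shape (..., d) and residual_fraction is the relative l2 error of the
    projection per signal (0 for a zero signal).
    """
    signals = np.asarray(signals)
    if signals.shape[-1] != basis.n_echoes:
        raise ValueError(
            f"signal length {signals.shape[-1]} does not match basis J={basis.n_echoes}"
        )
    coeff = signals @ basis.phi.conj().T
    recon = coeff @ basis.phi
    num = np.linalg.norm(signals - recon, axis=-1)
    den = np.linalg.norm(signals, axis=-1)
    resid = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return coeff, resid
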