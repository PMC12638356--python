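"""k-space undersampling patterns and GRASE acquisition plans.

Masks live on the two phase-encode axes (PE1 x PE2) of a 3D Cartesian scan;
the frequency-encode axis is fully sampled by every readout and handled
separately.  Three pattern families are provided:

* CAIPIRINHA — a sheared periodic lattice (R = R1 x R2 with an inter-row
  shift) that spreads aliasing across both phase-encode axes;
* shifted CAIPIRINHA — the same lattice cyclically shifted by one position
  per echo, so that different echoes sample complementary k-space points;
* Halton — a deterministic low-discrepancy point set distributed round-robin
  across echoes.

Acquisition plans describe how GRASE readouts fill k-space: the conventional
configuration (AG0) and its echo-shifted variant (AG1) interleave the
gradient echoes and the spin echo into bands of a shared composite k-space
per spin-echo index, while the separated configuration (AG2) gives every
readout its own k-space target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import qmc

from .epg import EchoTrainSpec

__all__ = [
    "SamplingMaskSet",
    "AcquisitionPlan",
    "caipirinha_mask",
    "shifted_caipirinha_maskset",
    "halton_maskset",
    "add_center_patch",
    "effective_acceleration",
    "configure_acquisition",
    "CONFIG_IDS",
]

CONFIG_IDS = ("AG0", "AG1_caipis", "AG1_halton", "AG2_caipis", "AG2_halton")


@dataclass(frozen=True)
class SamplingMaskSet:
    """Per-echo binary masks over the phase-encode plane.

    ``masks`` is a uint8 array (PE1, PE2, n_echoes) with 1 = sampled.
    ``nominal_R`` is the requested per-k-space acceleration; ``patch_size``
    records the edge lengths of a forced fully sampled central patch (0, 0)
    if none.
    """

    masks: np.ndarray
    nominal_R: float
    patch_size: tuple[int, int] = (0, 0)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.masks.shape[:2]

    @property
    def n_echoes(self) -> int:
        return self.masks.shape[2]


def _factorize_R(R: int, grid_shape) -> tuple[int, int]:
    """Default CAIPIRINHA factorization: R1 <= R2, R1 nearest to sqrt(R)."""
    best = None
    for r1 in range(1, int(np.sqrt(R)) + 1):
        if R % r1 == 0:
            best = (r1, R // r1)
    if best is None:  # pragma: no cover - r1=1 always divides
        raise ValueError(f"acceleration factor R={R} is not factorizable")
    return best


def caipirinha_mask(
    grid_shape,
    R: int,
    shift_step: int = 1,
    r1: int | None = None,
    r2: int | None = None,
) -> np.ndarray:
    """Single-echo CAIPIRINHA lattice mask of density 1/R.

    Samples points (i, j) with ``i % R1 == 0`` and
    ``j % R2 == (shift_step * (i // R1)) % R2``.  By default R1 <= R2 with
    R1 the largest divisor of R not exceeding sqrt(R); pass ``r1``/``r2``
    explicitly for a specific lattice cell.
    """
    n1, n2 = grid_shape
    if R < 1:
        raise ValueError("R must be >= 1")
    if r1 is None or r2 is None:
        r1, r2 = _factorize_R(int(R), grid_shape)
    if r1 * r2 != R:
        raise ValueError(f"r1*r2 = {r1 * r2} does not equal R = {R}")
    if r1 > n1 or r2 > n2:
        raise ValueError(f"factorization ({r1}, {r2}) does not fit grid {grid_shape}")
    i = np.arange(n1)[:, None]
    j = np.arange(n2)[None, :]
    mask = (i % r1 == 0) & (j % r2 == (shift_step * (i // r1)) % r2)
    return mask.astype(np.uint8)


def shifted_caipirinha_maskset(
    grid_shape,
    R: int,
    n_echoes: int,
    shift_step: int = 1,
    r1: int | None = None,
    r2: int | None = None,
    shift_axis: int = 1,
) -> SamplingMaskSet:
    """CAIPIRINHA lattice cyclically shifted by one position per echo.

    Echo j's mask is echo 0's mask rolled by j positions along
    ``shift_axis``, so successive echoes sample complementary points while
    each keeps density 1/R.
    """
    base = caipirinha_mask(grid_shape, R, shift_step, r1, r2)
    masks = np.stack(
        [np.roll(base, j, axis=shift_axis) for j in range(n_echoes)], axis=-1
    )
    return SamplingMaskSet(masks=masks, nominal_R=float(R))


def halton_maskset(
    grid_shape,
    R: int,
    n_echoes: int,
    bases: tuple[int, int] = (2, 3),
    skip: int = 0,
) -> SamplingMaskSet:
    """Low-discrepancy masks from a 2D Halton sequence.

    Successive Halton points are floor-scaled to the PE1 x PE2 grid and
    assigned round-robin across echoes; a point landing on a cell the current
    echo already samples is skipped (the next sequence element is used).
    Each echo receives exactly ``floor(N / R)`` samples.  Deterministic for
    fixed ``(bases, skip)``.
    """
    n1, n2 = grid_shape
    if bases != (2, 3):
        if len(set(bases)) != 2:
            raise ValueError("bases must be two distinct primes")
    n_total = n1 * n2
    per_echo = n_total // int(R)
    if per_echo < 1:
        raise ValueError(f"grid {grid_shape} too small for R={R}")

    sampler = qmc.Halton(d=2, scramble=False)
    if skip:
        sampler.fast_forward(skip)
    # scipy's Halton with default bases uses primes 2 and 3 for d=2
    masks = np.zeros((n1, n2, n_echoes), dtype=np.uint8)
    filled = np.zeros(n_echoes, dtype=int)
    echo = 0
    max_draws = 500 * n_total * max(n_echoes, 1)
    drawn = 0
    while filled.min() < per_echo:
        pts = sampler.random(4096)
        cells_i = np.minimum((pts[:, 0] * n1).astype(int), n1 - 1)
        cells_j = np.minimum((pts[:, 1] * n2).astype(int), n2 - 1)
        for ci, cj in zip(cells_i, cells_j):
            # advance to the next echo still needing samples
            while filled[echo] >= per_echo:
                echo = (echo + 1) % n_echoes
            if masks[ci, cj, echo] == 0:
                masks[ci, cj, echo] = 1
                filled[echo] += 1
                echo = (echo + 1) % n_echoes
                if filled.min() >= per_echo:
                    break
        drawn += 4096
        if drawn > max_draws:  # pragma: no cover - safety net
            raise RuntimeError("Halton mask generation failed to fill echoes")
    return SamplingMaskSet(masks=masks, nominal_R=float(R))


def add_center_patch(maskset: SamplingMaskSet, patch_edges) -> SamplingMaskSet:
    """Force a centered fully sampled calibration patch into every echo."""
    p1, p2 = patch_edges
    n1, n2 = maskset.grid_shape
    if p1 > n1 or p2 > n2:
        raise ValueError(f"patch {patch_edges} larger than grid {maskset.grid_shape}")
    if p1 <= 0 or p2 <= 0:
        return maskset
    masks = maskset.masks.copy()
    s1 = n1 // 2 - p1 // 2
    s2 = n2 // 2 - p2 // 2
    masks[s1 : s1 + p1, s2 : s2 + p2, :] = 1
    return replace(maskset, masks=masks, patch_size=(int(p1), int(p2)))


def effective_acceleration(maskset: SamplingMaskSet) -> float:
    """Total k-space points (grid x echoes) divided by sampled points."""
    sampled = int(maskset.masks.sum())
    if sampled == 0:
        raise ValueError("maskset has no sampled points")
    return maskset.masks.size / sampled


@dataclass(frozen=True)
class AcquisitionPlan:
    """How GRASE readouts fill undersampled k-space.

    ``maskset`` holds one mask per k-space target (composite spin-echo
    k-spaces for AG0/AG1; one per readout for AG2).  ``source_echo`` maps
    (k-space target, PE2 column) to the global readout index j in [0, J)
    whose signal fills that column; for AG2 every column of target k maps to
    readout k.  ``band_edges`` records the PE2 band boundaries of the
    composite configurations (empty for AG2).
    """

    config_id: str
    R: int
    spec: EchoTrainSpec
    maskset: SamplingMaskSet
    source_echo: np.ndarray
    band_edges: tuple[int, ...] = ()

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.maskset.grid_shape

    @property
    def n_targets(self) -> int:
        return self.maskset.n_echoes

    @property
    def separate_kspaces(self) -> bool:
        return self.config_id.startswith("AG2")


def _band_assignment(n2: int, n_bands: int) -> tuple[np.ndarray, tuple[int, ...]]:
    """Split PE2 columns into contiguous bands; the spin echo gets the center.

    Bands are assigned in chronological readout order (sorted time offsets);
    the band holding the zero-offset spin echo is the central one.  With the
    symmetric default offsets (-2.5, 0, +2.5 ms) this is simply chronological
    order: earliest gradient echo -> lowest PE2 band.
    """
    edges = np.linspace(0, n2, n_bands + 1).round().astype(int)
    band_of_col = np.empty(n2, dtype=int)
    for b in range(n_bands):
        band_of_col[edges[b] : edges[b + 1]] = b
    return band_of_col, tuple(int(e) for e in edges)


def configure_acquisition(
    config_id: str,
    grid_shape,
    R: int,
    spec: EchoTrainSpec,
    halton_bases: tuple[int, int] = (2, 3),
    halton_skip: int = 0,
) -> AcquisitionPlan:
    """Build the mask set and echo routing of one acquisition configuration.

    The overall acceleration R is defined against the fully sampled
    multi-spin-echo scan (one k-space per spin echo).  For the composite
    configurations (AG0/AG1) the gradient echoes contribute a factor
    (n_ge + 1) of the acceleration by filling bands of the shared k-space, so
    the per-k-space mask density is (n_ge + 1)/R; for AG2 every one of the
    J = n_se x (n_ge + 1) separate k-spaces is undersampled by the full R.
    All configurations acquire N x J / R lines in total.
    """
    if config_id not in CONFIG_IDS:
        raise ValueError(f"unknown configuration id {config_id!r}; expected one of {CONFIG_IDS}")
    n1, n2 = grid_shape
    n_group = spec.n_ge + 1

    if config_id.startswith("AG2"):
        n_targets = spec.n_echoes
        mask_R = int(R)
        if config_id == "AG2_halton":
            maskset = halton_maskset(grid_shape, mask_R, n_targets, halton_bases, halton_skip)
        else:
            maskset = shifted_caipirinha_maskset(grid_shape, mask_R, n_targets)
        source_echo = np.repeat(np.arange(n_targets)[:, None], n2, axis=1)
        return AcquisitionPlan(
            config_id=config_id,
            R=int(R),
            spec=spec,
            maskset=maskset,
            source_echo=source_echo,
        )

    # composite configurations: n_se k-spaces banded over PE2
    if R % n_group != 0:
        raise ValueError(
            f"composite configuration needs R divisible by n_ge+1={n_group}, got R={R}"
        )
    mask_R = R // n_group
    n_targets = spec.n_se
    if config_id == "AG0":
        base = caipirinha_mask(grid_shape, mask_R) if mask_R > 1 else np.ones(grid_shape, np.uint8)
        masks = np.repeat(base[:, :, None], n_targets, axis=2)
        maskset = SamplingMaskSet(masks=masks, nominal_R=float(mask_R))
    elif config_id == "AG1_halton":
        maskset = halton_maskset(grid_shape, mask_R, n_targets, halton_bases, halton_skip) \
            if mask_R > 1 else SamplingMaskSet(
                masks=np.ones((n1, n2, n_targets), np.uint8), nominal_R=1.0
            )
    else:  # AG1_caipis
        maskset = shifted_caipirinha_maskset(grid_shape, mask_R, n_targets) \
            if mask_R > 1 else SamplingMaskSet(
                masks=np.ones((n1, n2, n_targets), np.uint8), nominal_R=1.0
            )

    band_of_col, edges = _band_assignment(n2, n_group)
    # composite m, PE2 column with band b is filled by readout m*(n_ge+1)+b
    source_echo = (
        np.arange(n_targets)[:, None] * n_group + band_of_col[None, :]
    )
    return AcquisitionPlan(
        config_id=config_id,
        R=int(R),
        spec=spec,
        maskset=maskset,
        source_echo=source_echo,
        band_edges=edges,
    )
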