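"""Synthetic digital phantoms and the end-to-end k-space simulator.

The generator produces 2D phase-encode planes (one readout position of a 3D
scan) with the ingredients the reconstruction needs to be tested against:

* a brain-like object with white-matter, grey-matter and CSF compartments,
  each carrying a multi-component T2 spectrum on the conventional grid
  (WM: 15% myelin water at ~20 ms plus 85% at ~80 ms; GM: 5% at ~20 ms plus
  95% at ~90 ms; CSF: a single long-T2 component at ~1500 ms);
* smooth low-order-polynomial field-offset (dB0, up to +/-150 Hz) and
  reversible-dephasing (R2', 5--25 1/s) maps;
* smooth complex coil sensitivities (band-limited by construction);
* a vial phantom of single-T2 circular compartments emulating a
  relaxometry calibration object.

``simulate_kspace`` composes the voxel signal model (EPG decay, GRASE
modulation), the acquisition plan's echo-to-k-space routing (composite band
filling for AG0/AG1, separate k-spaces for AG2) and complex Gaussian noise
at the sampled locations.  All randomness is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import SubspaceBasis
from .encoding import CoilSet, EchoImages, KSpaceData, fft2c
from .epg import (
    EchoTrainSpec,
    T2Grid,
    build_t2_grid,
    grase_modulation,
    mse_voxel_signal,
)
from .sampling import AcquisitionPlan, SamplingMaskSet, configure_acquisition

__all__ = [
    "PhantomObject",
    "SimulationConfig",
    "make_brain_like_phantom",
    "make_vial_phantom",
    "simulate_kspace",
    "retrospective_undersample",
    "default_echo_train",
]

# tissue labels
BACKGROUND, WM, GM, CSF = 0, 1, 2, 3

# plausible-literature synthetic tissue values; configuration defaults, not
# measured claims
TISSUE_SPECTRA = {
    WM: ((20.0, 0.15), (80.0, 0.85)),
    GM: ((20.0, 0.05), (90.0, 0.95)),
    CSF: ((1500.0, 1.0),),
}
TISSUE_PD = {BACKGROUND: 0.0, WM: 0.70, GM: 0.85, CSF: 1.0}


def default_echo_train(n_ge: int = 2) -> EchoTrainSpec:
    """32-echo train with 10 ms spacing and +/-2.5 ms gradient-echo offsets."""
    offsets = (-2.5, 2.5)[:n_ge] if n_ge else ()
    return EchoTrainSpec(n_se=32, esp=10.0, n_ge=n_ge, ge_offsets=offsets)


@dataclass
class PhantomObject:
    """Ground-truth object: label map, spectra, field maps and coils."""

    labels: np.ndarray  # (PE1, PE2) int
    spectra: np.ndarray  # (PE1, PE2, n) non-negative, proton-density scaled
    delta_b0: np.ndarray  # (PE1, PE2) rad/s
    r2_prime: np.ndarray  # (PE1, PE2) 1/s
    coils: CoilSet
    grid: T2Grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def support(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def ground_truth_mwf(self) -> np.ndarray:
        """MWF computed from the planted spectra (NaN outside the object)."""
        total = self.spectra.sum(axis=-1)
        cut = self.spectra[..., :8].sum(axis=-1)
        return np.where(total > 0, cut / np.where(total > 0, total, 1.0), np.nan)

    def ground_truth_iet2(self) -> np.ndarray:
        """IET2 (ms) from the planted spectra (NaN where the window is empty)."""
        w = self.spectra[..., 8:21]
        mass = w.sum(axis=-1)
        logt = np.log(self.grid.values[8:21])
        with np.errstate(invalid="ignore"):
            out = np.exp((w * logt).sum(axis=-1) / np.where(mass > 0, mass, np.nan))
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one simulated acquisition."""

    config_id: str = "AG1_caipis"
    R: int = 3
    noise_sigma: float = 0.0
    seed: int = 0
    spec: EchoTrainSpec = field(default_factory=default_echo_train)
    patch_size: tuple[int, int] = (0, 0)
    halton_bases: tuple[int, int] = (2, 3)
    halton_skip: int = 0


def _nearest_grid_spectrum(grid: T2Grid, components) -> np.ndarray:
    s = np.zeros(grid.n)
    for t2, amp in components:
        idx = int(np.argmin(np.abs(grid.values - t2)))
        s[idx] += amp
    return s


def _smooth_field(shape, rng, low, high, order: int = 2) -> np.ndarray:
    """Low-order 2D polynomial field scaled into [low, high]."""
    n1, n2 = shape
    y = np.linspace(-1, 1, n1)[:, None]
    x = np.linspace(-1, 1, n2)[None, :]
    f = np.zeros(shape)
    for p in range(order + 1):
        for q in range(order + 1 - p):
            f += rng.normal() * (y**p) * (x**q)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return low + (high - low) * f


def _smooth_coils(shape, n_coils, rng) -> CoilSet:
    """Smooth complex sensitivities: Gaussian lobes around the FOV edge."""
    n1, n2 = shape
    y = np.linspace(-1, 1, n1)[:, None]
    x = np.linspace(-1, 1, n2)[None, :]
    sens = np.empty((n_coils, n1, n2), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cy, cx = 1.3 * np.sin(ang), 1.3 * np.cos(ang)
        width = rng.uniform(0.8, 1.2)
        mag = np.exp(-(((y - cy) ** 2 + (x - cx) ** 2)) / (2 * width**2))
        phase = rng.uniform(-np.pi, np.pi) + rng.uniform(-1, 1) * y + rng.uniform(-1, 1) * x
        sens[c] = mag * np.exp(1j * phase)
    return CoilSet(sensitivities=sens)


def make_brain_like_phantom(
    shape,
    seed: int = 0,
    grid: T2Grid | None = None,
    n_coils: int = 6,
    db0_max_hz: float = 150.0,
    r2p_range: tuple[float, float] = (5.0, 25.0),
) -> PhantomObject:
    """Brain-like 2D object with WM/GM/CSF compartments.

    A smooth elliptical head with a grey-matter rim, white-matter interior
    and CSF ventricles; smooth dB0 (bounded by ``db0_max_hz``), R2' in
    5--25 1/s, and ``n_coils`` smooth complex coils.  Deterministic per seed.
    """
    n1, n2 = shape
    if n1 < 16 or n2 < 16:
        raise ValueError(f"phantom shape must be at least 16x16, got {shape}")
    if grid is None:
        grid = build_t2_grid(40, 15.0, 2000.0)
    rng = np.random.default_rng(seed)

    y = np.linspace(-1, 1, n1)[:, None]
    x = np.linspace(-1, 1, n2)[None, :]
    r_head = (y / 0.88) ** 2 + (x / 0.72) ** 2
    r_inner = (y / 0.70) ** 2 + (x / 0.55) ** 2

    labels = np.full(shape, BACKGROUND, dtype=int)
    labels[r_head <= 1] = GM
    labels[r_inner <= 1] = WM
    # two CSF ventricle lobes near the center
    for sx in (-0.18, 0.18):
        r_vent = ((y + 0.05) / 0.22) ** 2 + ((x - sx) / 0.10) ** 2
        labels[(r_vent <= 1) & (labels != BACKGROUND)] = CSF

    spectra = np.zeros(shape + (grid.n,))
    for lab, comps in TISSUE_SPECTRA.items():
        base = _nearest_grid_spectrum(grid, comps) * TISSUE_PD[lab]
        spectra[labels == lab] = base

    db0_hz = _smooth_field(shape, rng, -db0_max_hz, db0_max_hz)
    delta_b0 = 2 * np.pi * db0_hz  # stored in rad/s
    r2_prime = _smooth_field(shape, rng, *r2p_range)
    coils = _smooth_coils(shape, n_coils, rng)
    return PhantomObject(
        labels=labels,
        spectra=spectra,
        delta_b0=delta_b0,
        r2_prime=r2_prime,
        coils=coils,
        grid=grid,
    )


def make_vial_phantom(
    shape,
    t2_list,
    seed: int = 0,
    grid: T2Grid | None = None,
    n_coils: int = 4,
) -> PhantomObject:
    """Vial phantom: disjoint circles, one single-T2 compartment each."""
    t2_list = list(t2_list)
    if not t2_list:
        raise ValueError("t2_list must be non-empty")
    n1, n2 = shape
    if grid is None:
        grid = build_t2_grid(40, 15.0, 2000.0)
    rng = np.random.default_rng(seed)

    n_vials = len(t2_list)
    radius = 0.9 / max(2.0, 1.3 * n_vials) if n_vials > 1 else 0.3
    if radius * min(n1, n2) / 2 < 1.5:
        raise ValueError(f"{n_vials} vials do not fit in grid {shape}")
    y = np.linspace(-1, 1, n1)[:, None]
    x = np.linspace(-1, 1, n2)[None, :]
    labels = np.full(shape, BACKGROUND, dtype=int)
    spectra = np.zeros(shape + (grid.n,))
    ring = 0.55 if n_vials > 1 else 0.0
    for v, t2 in enumerate(t2_list):
        ang = 2 * np.pi * v / n_vials
        cy, cx = ring * np.sin(ang), ring * np.cos(ang)
        inside = (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
        if (labels[inside] != BACKGROUND).any():
            raise ValueError("vials overlap; reduce their count or enlarge the grid")
        labels[inside] = v + 1
        spectra[inside] = _nearest_grid_spectrum(grid, ((t2, 1.0),))

    db0_hz = _smooth_field(shape, rng, -20.0, 20.0)
    coils = _smooth_coils(shape, n_coils, rng)
    return PhantomObject(
        labels=labels,
        spectra=spectra,
        delta_b0=2 * np.pi * db0_hz,
        r2_prime=_smooth_field(shape, rng, 5.0, 15.0),
        coils=coils,
        grid=grid,
    )


def phantom_echo_images(phantom: PhantomObject, spec: EchoTrainSpec) -> np.ndarray:
    """Noise-free complex readout images (PE1, PE2, J) of the object.

    The spin-echo decay is computed per unique spectrum (EPG), expanded to
    all readouts and modulated per voxel by the GRASE factors.
    """
    shape = phantom.shape
    flat = phantom.spectra.reshape(-1, phantom.grid.n)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    decays = np.stack(
        [mse_voxel_signal(u, phantom.grid, spec) for u in uniq], axis=0
    )
    se_images = decays[inverse].reshape(shape + (spec.n_se,))
    full = np.repeat(se_images, spec.n_ge + 1, axis=-1).astype(complex)
    full *= grase_modulation(phantom.r2_prime, phantom.delta_b0, spec)
    return full


def _route_composite(kspace_full: np.ndarray, plan: AcquisitionPlan) -> np.ndarray:
    """Assemble composite k-spaces: column pe2 of target m comes from the
    readout ``plan.source_echo[m, pe2]``'s k-space."""
    n_targets, n2 = plan.source_echo.shape
    out = np.empty(kspace_full.shape[:3] + (n_targets,), dtype=complex)
    for m in range(n_targets):
        out[..., m] = np.take_along_axis(
            kspace_full, plan.source_echo[m][None, None, :, None], axis=-1
        )[..., 0]
    return out


def simulate_kspace(
    phantom: PhantomObject, cfg: SimulationConfig
) -> tuple[KSpaceData, AcquisitionPlan, EchoImages, np.ndarray]:
    """Simulate a multi-coil acquisition of the phantom.

    Returns ``(kspace, plan, truth, navigator)``:

    * ``kspace`` — (C, PE1, PE2, targets) noisy undersampled measurements,
      routed per the plan (composite band filling or separate k-spaces);
    * ``plan`` — the acquisition plan (masks and routing);
    * ``truth`` — the noise-free complex readout images (PE1, PE2, J);
    * ``navigator`` — per-echo projection of the object onto the first axis
      (a zero-phase-encode readout stand-in), shape (PE1, J).

    Complex Gaussian noise of std ``cfg.noise_sigma`` per real/imaginary
    channel is added independently at the sampled locations.
    """
    spec = cfg.spec
    plan = configure_acquisition(
        cfg.config_id,
        phantom.shape,
        cfg.R,
        spec,
        halton_bases=cfg.halton_bases,
        halton_skip=cfg.halton_skip,
    )
    maskset = plan.maskset
    if cfg.patch_size != (0, 0):
        from .sampling import add_center_patch

        maskset = add_center_patch(maskset, cfg.patch_size)
        plan = AcquisitionPlan(
            config_id=plan.config_id,
            R=plan.R,
            spec=plan.spec,
            maskset=maskset,
            source_echo=plan.source_echo,
            band_edges=plan.band_edges,
        )

    truth = phantom_echo_images(phantom, spec)
    sens = phantom.coils.sensitivities
    weighted = sens[:, :, :, None] * truth[None]
    kfull = fft2c(weighted, axes=(1, 2))  # (C, PE1, PE2, J)

    if plan.separate_kspaces:
        routed = kfull
    else:
        routed = _route_composite(kfull, plan)

    data = routed * maskset.masks[None]
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = cfg.noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data = data + noise * maskset.masks[None]

    navigator = truth.sum(axis=1)  # (PE1, J) projection over PE2
    return (
        KSpaceData(data=data, sigma=cfg.noise_sigma),
        plan,
        EchoImages(images=truth),
        navigator,
    )


def retrospective_undersample(
    full_kspace: KSpaceData, maskset: SamplingMaskSet
) -> KSpaceData:
    """Zero out the k-space points a mask set does not sample."""
    if full_kspace.data.shape[1:] != maskset.masks.shape:
        raise ValueError(
            f"mask shape {maskset.masks.shape} does not match data {full_kspace.data.shape[1:]}"
        )
    return KSpaceData(
        data=full_kspace.data * maskset.masks[None], sigma=full_kspace.sigma
    )
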