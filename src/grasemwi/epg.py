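"""Multi-echo signal models for myelin-water imaging.

This module provides the building blocks of the voxel-level signal model:

* a logarithmic (geometric) T2 grid, conventionally 40 points spanning
  15--2000 ms so that consecutive values differ by ~13.4%;
* an Extended Phase Graph (EPG) simulation of CPMG spin-echo trains, which
  predicts echo amplitudes under imperfect refocusing (flip angle < 180deg),
  including the stimulated-echo pathways that make the decay deviate from a
  pure exponential;
* the multi-component magnitude decay of a voxel (a non-negative mixture of
  EPG curves over the T2 grid);
* the GRASE extension, which attenuates and phase-modulates gradient echoes
  acquired at a time offset from the spin echo via the reversible dephasing
  rate R2' and the local field offset dB0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "T2Grid",
    "EchoTrainSpec",
    "VoxelGraseParams",
    "build_t2_grid",
    "epg_echo_amplitudes",
    "mse_voxel_signal",
    "grase_voxel_signal",
]


@dataclass(frozen=True)
class T2Grid:
    """Geometric grid of candidate T2 relaxation times (ms).

    ``values[0]`` is ``t2_min`` and ``values[-1]`` is ``t2_max``; the ratio of
    consecutive values is constant.  Conventional myelin-water analysis uses
    ``n=40`` on [15, 2000] ms.
    """

    values: np.ndarray
    t2_min: float
    t2_max: float

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def step_ratio(self) -> float:
        """Constant ratio between consecutive grid values."""
        return float(self.values[1] / self.values[0])


def build_t2_grid(n: int, t2_min: float, t2_max: float) -> T2Grid:
    """Build an ``n``-point geometric T2 grid spanning [t2_min, t2_max] ms."""
    if n < 2:
        raise ValueError(f"T2 grid needs at least 2 points, got n={n}")
    if not (0 < t2_min < t2_max):
        raise ValueError(
            f"require 0 < t2_min < t2_max, got t2_min={t2_min}, t2_max={t2_max}"
        )
    values = np.exp(np.linspace(np.log(t2_min), np.log(t2_max), n))
    # pin the endpoints exactly
    values[0] = t2_min
    values[-1] = t2_max
    return T2Grid(values=values, t2_min=float(t2_min), t2_max=float(t2_max))


@dataclass(frozen=True)
class EchoTrainSpec:
    """Timing and pulse parameters of a (GRASE) multi-echo train.

    Parameters
    ----------
    n_se:
        Number of spin echoes (echo train length).
    esp:
        Echo spacing in ms; spin echo j occurs at ``j * esp``.
    n_ge:
        Gradient echoes recorded alongside each spin echo (0 for a plain
        multi-spin-echo train).
    ge_offsets:
        Time offsets (ms) of the gradient-echo readouts from their spin echo,
        e.g. ``(-2.5, 2.5)``.  Must have length ``n_ge``.
    refocus_fa:
        Refocusing flip angle in degrees (nominal 180).
    t1_assumed:
        Longitudinal relaxation time (ms) used by the EPG simulation; needed
        because stimulated-echo pathways store magnetization longitudinally.
    """

    n_se: int = 32
    esp: float = 10.0
    n_ge: int = 0
    ge_offsets: tuple[float, ...] = ()
    refocus_fa: float = 180.0
    t1_assumed: float = 1000.0

    def __post_init__(self):
        if self.n_se < 1:
            raise ValueError("n_se must be >= 1")
        if self.esp <= 0:
            raise ValueError("esp must be positive")
        if len(self.ge_offsets) != self.n_ge:
            raise ValueError(
                f"ge_offsets has length {len(self.ge_offsets)} but n_ge={self.n_ge}"
            )
        if not (0.0 < self.refocus_fa <= 180.0):
            raise ValueError("refocus_fa must be in (0, 180] degrees")

    @property
    def echo_times(self) -> np.ndarray:
        """Spin-echo times (ms): esp, 2*esp, ..., n_se*esp."""
        return self.esp * np.arange(1, self.n_se + 1)

    @property
    def n_echoes(self) -> int:
        """Total readout count J = n_se * (n_ge + 1)."""
        return self.n_se * (self.n_ge + 1)

    @property
    def readout_offsets(self) -> np.ndarray:
        """Per-readout time offset Delta_j (ms) from the parent spin echo.

        Readouts are ordered chronologically: within each spin-echo period the
        gradient/spin echoes appear sorted by offset (e.g. GE(-2.5), SE(0),
        GE(+2.5)), so the array has length ``n_echoes`` and is zero at every
        spin-echo position.
        """
        group = np.sort(np.asarray(self.ge_offsets + (0.0,), dtype=float))
        return np.tile(group, self.n_se)

    @property
    def spin_echo_indices(self) -> np.ndarray:
        """Indices of the spin-echo readouts within the full echo ordering."""
        return np.flatnonzero(self.readout_offsets == 0.0)

    @property
    def readout_times(self) -> np.ndarray:
        """Absolute time (ms) of every readout: SE time plus its offset."""
        se_times = np.repeat(self.echo_times, self.n_ge + 1)
        return se_times + self.readout_offsets


@dataclass(frozen=True)
class VoxelGraseParams:
    """Per-voxel GRASE modulation parameters.

    ``r2_prime`` is the reversible dephasing rate in 1/s (must be >= 0);
    ``delta_b0`` is the local field offset in rad/s.
    """

    r2_prime: float = 0.0
    delta_b0: float = 0.0

    def __post_init__(self):
        if self.r2_prime < 0:
            raise ValueError("r2_prime must be non-negative")


def _epg_rf_matrix(alpha: float, phase: float = 0.0) -> np.ndarray:
    """Mixing matrix of an RF pulse (flip alpha, phase) on (F+, F-, Z) states."""
    ca2 = np.cos(alpha / 2) ** 2
    sa2 = np.sin(alpha / 2) ** 2
    sa = np.sin(alpha)
    ep = np.exp(1j * phase)
    return np.array(
        [
            [ca2, ep**2 * sa2, -1j * ep * sa],
            [np.conj(ep) ** 2 * sa2, ca2, 1j * np.conj(ep) * sa],
            [-0.5j * np.conj(ep) * sa, 0.5j * ep * sa, np.cos(alpha)],
        ],
        dtype=complex,
    )


def epg_echo_amplitudes(t2: float, spec: EchoTrainSpec) -> np.ndarray:
    """Spin-echo amplitudes of a CPMG train via the Extended Phase Graph.

    Simulates a 90deg excitation followed by ``spec.n_se`` refocusing pulses
    of angle ``spec.refocus_fa`` about an axis 90deg from the excitation (the
    CPMG condition), with T2 decay over each half echo spacing and T1 decay of
    the stored longitudinal states.  Longitudinal regrowth is neglected (echo
    trains are short relative to TR).  Returns the real amplitude of each of
    the ``n_se`` spin echoes, in [0, 1].
    """
    if t2 <= 0:
        raise ValueError(f"t2 must be positive, got {t2}")
    n = spec.n_se
    alpha = np.deg2rad(spec.refocus_fa)
    e2 = np.exp(-0.5 * spec.esp / t2)
    e1 = np.exp(-0.5 * spec.esp / spec.t1_assumed)

    rf = _epg_rf_matrix(alpha, 0.0)

    # configuration states k = 0..n; rows are F+(k), F-(k), Z(k)
    state = np.zeros((3, n + 1), dtype=complex)
    state[0, 0] = 1.0  # transverse magnetization after ideal 90deg excitation

    echoes = np.empty(n, dtype=float)
    for j in range(n):
        # relax + dephase by one unit gradient over esp/2
        state[:2] *= e2
        state[2] *= e1
        state[0, 1:] = state[0, :-1]
        state[1, :-1] = state[1, 1:]
        state[1, -1] = 0.0
        state[0, 0] = np.conj(state[1, 0])
        # refocusing pulse
        state = rf @ state
        # relax + dephase over the second half period
        state[:2] *= e2
        state[2] *= e1
        state[0, 1:] = state[0, :-1]
        state[1, :-1] = state[1, 1:]
        state[1, -1] = 0.0
        state[0, 0] = np.conj(state[1, 0])
        echoes[j] = np.abs(state[0, 0])
    return echoes


def mse_voxel_signal(
    spectrum: np.ndarray, grid: T2Grid, spec: EchoTrainSpec
) -> np.ndarray:
    """Magnitude decay of a voxel with a multi-component T2 spectrum.

    The signal at spin echo j is the spectrum-weighted sum of EPG echo
    amplitude curves, one per grid T2.  Linear in the spectrum.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (grid.n,):
        raise ValueError(
            f"spectrum length {spectrum.shape} does not match grid n={grid.n}"
        )
    signal = np.zeros(spec.n_se)
    for amp, t2 in zip(spectrum, grid.values):
        if amp != 0.0:
            signal += amp * epg_echo_amplitudes(float(t2), spec)
    return signal


def grase_voxel_signal(
    mse_signal: np.ndarray, params: VoxelGraseParams, spec: EchoTrainSpec
) -> np.ndarray:
    """Expand a per-spin-echo signal to the full GRASE readout train.

    Each spin-echo value is replicated to its gradient-echo readouts and
    modulated by ``exp(-|Delta_j| * R2' + i * dB0 * Delta_j)`` with Delta_j
    the readout's time offset from the spin echo (R2' in 1/s, dB0 in rad/s,
    Delta_j converted from ms to s).  Spin-echo entries (Delta_j = 0) pass
    through unchanged.
    """
    mse_signal = np.asarray(mse_signal)
    if mse_signal.shape[-1] != spec.n_se:
        raise ValueError(
            f"signal has {mse_signal.shape[-1]} echoes, expected n_se={spec.n_se}"
        )
    offsets_s = spec.readout_offsets * 1e-3
    expanded = np.repeat(mse_signal, spec.n_ge + 1, axis=-1).astype(complex)
    modulation = np.exp(
        -np.abs(offsets_s) * params.r2_prime + 1j * params.delta_b0 * offsets_s
    )
    return expanded * modulation


def grase_modulation(
    r2_prime: np.ndarray, delta_b0: np.ndarray, spec: EchoTrainSpec
) -> np.ndarray:
    """Vectorized GRASE modulation factors.

    Broadcasts voxel maps of R2' (1/s) and dB0 (rad/s) against the readout
    offsets, returning ``(*map_shape, n_echoes)`` complex factors.
    """
    offsets_s = spec.readout_offsets * 1e-3
    r2p = np.asarray(r2_prime)[..., None]
    db0 = np.asarray(delta_b0)[..., None]
    return np.exp(-np.abs(offsets_s) * r2p + 1j * db0 * offsets_s)
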