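# grasemwi

Accelerated 3D-GRASE myelin-water imaging in Python: multi-echo signal
simulation, k-space undersampling design, subspace-constrained
reconstruction (SCR), and NNLS T2-spectrum mapping.

## The problem

Myelin water fraction (MWF) and the geometric mean T2 of the
intra-/extra-cellular water peak (IET2) are quantitative MRI markers of
myelin content, estimated from multi-echo spin-echo decays.  A voxel's
magnitude decay is modelled as a non-negative mixture over a logarithmic T2
grid,

    |S_x(j)| = Σ_t s_{t,x} · EPG(E, T2_t),   s_{t,x} ≥ 0,

with EPG the Extended Phase Graph echo-amplitude prediction (which accounts
for stimulated echoes under imperfect refocusing).  MWF is the spectral mass
below ~36 ms over the total; IET2 is the weighted geometric mean T2 of the
~40.9–184.4 ms window.  Acquiring the echo train is slow, so the scan is
undersampled and the echo images S are reconstructed jointly under a
low-rank constraint S = α Φ, where the basis Φ (d × J) comes from the SVD of
a dictionary of candidate signal evolutions and α solves

    α̂ = argmin_α Σ_c ‖Z_c − U ∘ F C_c (α Φ)‖².

The package implements three gradient-and-spin-echo acquisition
configurations (composite k-space with shared or echo-shifted masks, and
fully separated per-readout k-spaces), CAIPIRINHA and Halton mask families,
navigator and patch-based B0 phase corrections, and a synthetic brain-like
phantom generator that drives every experiment.  It is aimed at sequence and
reconstruction researchers prototyping undersampling strategies for
myelin-water mapping at desk scale.

## Worked example

Simulate an accelerated (R = 6) echo-shifted CAIPIRINHA acquisition of a
synthetic brain slice at first-echo SNR ≈ 100, reconstruct it through an
8-component model-dictionary subspace, and fit the maps:

```python
import numpy as np
from grasemwi import build_t2_grid
from grasemwi.phantom import (SimulationConfig, default_echo_train,
                              make_brain_like_phantom, simulate_kspace, WM,
                              phantom_echo_images)
from grasemwi.evaluate import default_basis_for, rmsd
from grasemwi.encoding import navigator_correct_composite
from grasemwi.recon import scr_solve, expand_images
from grasemwi.mapping import FittingConfig, map_volume

grid = build_t2_grid(40, 15.0, 2000.0)
print(f"T2 grid step: {100*(grid.step_ratio-1):.1f}%  "
      f"myelin cut: {grid.values[7]:.0f} ms  IE window: {grid.values[8]:.1f}-{grid.values[20]:.1f} ms")

spec = default_echo_train()                      # 32 spin echoes, 2 GEs at +/-2.5 ms
phantom = make_brain_like_phantom((64, 64), seed=7)
roi = phantom.labels == WM
truth_se = np.abs(phantom_echo_images(phantom, spec)[..., spec.spin_echo_indices])
sigma = truth_se[..., 0][roi].mean() / 100       # first-echo SNR ~ 100

cfg = SimulationConfig(config_id="AG1_caipis", R=6, noise_sigma=sigma, seed=7, spec=spec)
kspace, plan, _, navigator = simulate_kspace(phantom, cfg)
kspace = navigator_correct_composite(kspace, plan, navigator)

basis = default_basis_for("AG1_caipis", grid, spec, d=8)
alpha, report = scr_solve(kspace, plan.maskset, phantom.coils, basis, max_iter=150)
images = np.abs(expand_images(alpha, basis).images)
print(f"SCR: {report.iterations} CG iterations, data match {100*report.data_match_fraction:.2f}%")

_, mwf, iet2 = map_volume(images, grid, spec, roi, FittingConfig(fa_step=4.0))
print(f"WM MWF  RMSD vs truth: {rmsd(phantom.ground_truth_mwf(),  mwf.values,  roi):.3f}")
print(f"WM IET2 RMSD vs truth: {rmsd(phantom.ground_truth_iet2(), iet2.values, roi):.2f} ms")
```

Output:

```
T2 grid step: 13.4%  myelin cut: 36 ms  IE window: 40.9-184.4 ms
SCR: 15 CG iterations, data match 93.30%
WM MWF  RMSD vs truth: 0.104
WM IET2 RMSD vs truth: 8.65 ms
```

The numbers show the method's characteristic asymmetry: IET2 survives
six-fold acceleration (RMSD well under 10 ms), while MWF — driven by the
first echoes and amplified ~10× by the ill-conditioned spectrum split — is
already visibly degraded.  See `docs/methods.md` for why composite sampling
leaves a field-inhomogeneity artifact that the navigator correction can only
partially remove.

A command-line interface wraps the same pipeline
(`grasemwi make-mask / build-dictionary / simulate / reconstruct /
fit-maps / run-experiment`); each subcommand takes a YAML configuration and
records the configuration hash and seed in its outputs.

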