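"""File formats: HDF5 k-space containers, dictionary/basis stores, and
NIfTI parameter maps.

The k-space container layout (HDF5):

* ``data``      complex (C, PE1, PE2, echo) measurements
* ``masks``     uint8 (PE1, PE2, echo) sampling masks
* attributes    ``sigma`` plus the echo-train settings
  (``n_se``, ``esp_ms``, ``n_ge``, ``ge_offset_ms``, ``refocus_fa_deg``,
  ``t1_ms``)

Parameter maps are float32 NIfTI-1 with undefined voxels stored as NaN and
the voxel size recorded in the affine (2.4 mm isotropic for the default
synthetic grid).
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .dictionary import Dictionary, SubspaceBasis
from .encoding import KSpaceData
from .epg import EchoTrainSpec
from .mapping import ParameterMap
from .sampling import SamplingMaskSet

__all__ = [
    "write_kspace_container",
    "read_kspace_container",
    "write_basis",
    "read_basis",
    "write_map",
    "read_map",
]

DEFAULT_VOXEL_MM = 2.4


def write_kspace_container(
    path,
    kspace: KSpaceData,
    maskset: SamplingMaskSet,
    spec: EchoTrainSpec,
    provenance: dict | None = None,
) -> None:
    """Write measurements, masks and echo-train settings to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(kspace.data, dtype=np.complex128))
        f.create_dataset("masks", data=maskset.masks.astype(np.uint8))
        f.attrs["sigma"] = float(kspace.sigma)
        f.attrs["nominal_R"] = float(maskset.nominal_R)
        f.attrs["patch_size"] = list(maskset.patch_size)
        f.attrs["n_se"] = spec.n_se
        f.attrs["esp_ms"] = spec.esp
        f.attrs["n_ge"] = spec.n_ge
        f.attrs["ge_offset_ms"] = list(spec.ge_offsets)
        f.attrs["refocus_fa_deg"] = spec.refocus_fa
        f.attrs["t1_ms"] = spec.t1_assumed
        for key, val in (provenance or {}).items():
            f.attrs[f"prov_{key}"] = val


def read_kspace_container(path) -> tuple[KSpaceData, SamplingMaskSet, EchoTrainSpec]:
    """Read a k-space container; raises a schema error naming missing parts."""
    with h5py.File(path, "r") as f:
        for name in ("data", "masks"):
            if name not in f:
                raise KeyError(f"k-space container {path} is missing dataset {name!r}")
        data = f["data"][...]
        masks = f["masks"][...]
        attrs = dict(f.attrs)
    for name in ("n_se", "esp_ms", "n_ge", "refocus_fa_deg"):
        if name not in attrs:
            raise KeyError(f"k-space container {path} is missing attribute {name!r}")
    spec = EchoTrainSpec(
        n_se=int(attrs["n_se"]),
        esp=float(attrs["esp_ms"]),
        n_ge=int(attrs["n_ge"]),
        ge_offsets=tuple(float(g) for g in attrs.get("ge_offset_ms", [])),
        refocus_fa=float(attrs["refocus_fa_deg"]),
        t1_assumed=float(attrs.get("t1_ms", 1000.0)),
    )
    maskset = SamplingMaskSet(
        masks=masks,
        nominal_R=float(attrs.get("nominal_R", 1.0)),
        patch_size=tuple(int(p) for p in attrs.get("patch_size", (0, 0))),
    )
    return KSpaceData(data=data, sigma=float(attrs.get("sigma", 0.0))), maskset, spec


def write_basis(path, basis: SubspaceBasis, dictionary: Dictionary | None = None) -> None:
    """Serialize a subspace basis (and optionally its dictionary) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=basis.phi)
        f.create_dataset("singular_values", data=basis.singular_values)
        f.attrs["energy_fraction"] = basis.energy_fraction
        if dictionary is not None:
            f.create_dataset("atoms", data=dictionary.atoms)
            if dictionary.meta is not None:
                f.create_dataset("meta", data=dictionary.meta)


def read_basis(path) -> SubspaceBasis:
    with h5py.File(path, "r") as f:
        if "phi" not in f:
            raise KeyError(f"basis file {path} is missing dataset 'phi'")
        return SubspaceBasis(
            phi=f["phi"][...],
            singular_values=f["singular_values"][...],
            energy_fraction=float(f.attrs["energy_fraction"]),
        )


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def write_map(path, pmap: ParameterMap, voxel_mm: float = DEFAULT_VOXEL_MM) -> None:
    """Write a parameter map as float32 NIfTI; undefined voxels become NaN."""
    vol = np.asarray(pmap.values, dtype=np.float32)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    img = nib.Nifti1Image(vol, _affine(voxel_mm))
    img.header.set_zooms((voxel_mm,) * 3)
    nib.save(img, str(path))


def read_map(path, name: str = "") -> ParameterMap:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float32)
    if vol.ndim == 3 and vol.shape[2] == 1:
        vol = vol[:, :, 0]
    return ParameterMap(values=vol, roi=np.isfinite(vol), name=name)
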