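"""Volumetric data carriers shared by all modules.

A :class:`VolumeGrid` is a 3D scalar array on a regular anisotropic grid
(voxel spacing in mm, axial slices along the last axis).  CT volumes, dose
maps and distance maps are all carried this way; binary ROI masks are plain
boolean arrays on the same grid, grouped in a :class:`ROISet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "DoseMap", "ROISet", "load_volume", "save_volume"]


@dataclass
class VolumeGrid:
    """3D scalar field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; the last axis indexes axial slices.
    spacing : tuple of float
        Voxel size in mm along each axis.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch for {what}: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry and different values."""
        if values.shape != self.shape:
            raise ValueError(f"shape {values.shape} does not match grid {self.shape}")
        return VolumeGrid(values, self.spacing, self.origin)


# A dose map is a VolumeGrid whose values are absorbed dose in Gy.
DoseMap = VolumeGrid


@dataclass
class ROISet:
    """Named binary masks on a common grid.

    ``masks`` maps ROI name -> boolean array.  ``targets`` lists the names
    of target volumes (PTV, boost) in increasing prescription order,
    ``oars`` the organs at risk.  ``body`` names the external contour and
    ``in_field`` is the mask of voxels inside the treated field; everything
    outside it is "out of field".  ``prescriptions_gy`` maps each target
    name to its prescription dose.
    """

    masks: dict[str, np.ndarray]
    targets: list[str]
    oars: list[str]
    body: str
    in_field: np.ndarray
    prescriptions_gy: dict[str, float]
    n_fractions: int = 33
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)

    def __post_init__(self) -> None:
        if self.body not in self.masks:
            raise ValueError(f"body mask {self.body!r} missing from ROI set")
        if not self.targets:
            raise ValueError("ROI set needs at least one target")
        shapes = {m.shape for m in self.masks.values()} | {self.in_field.shape}
        if len(shapes) != 1:
            raise ValueError(f"ROI masks disagree on grid shape: {shapes}")
        for name in self.targets:
            if name not in self.masks:
                raise ValueError(f"target {name!r} has no mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks[self.body].shape

    @property
    def body_mask(self) -> np.ndarray:
        return self.masks[self.body]

    def target_union(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for name in self.targets:
            out |= self.masks[name]
        return out

    def normal_tissue(self) -> np.ndarray:
        """Body minus all targets."""
        return self.body_mask & ~self.target_union()


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0]).astype(float)
    aff[:3, 3] = origin
    return aff


def save_volume(vol: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return VolumeGrid(np.asarray(img.get_fdata()), spacing, origin)


def save_roiset(rois: ROISet, directory: str | Path) -> None:
    """Write one NIfTI mask per ROI plus the in-field mask and a JSON table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in rois.masks.items():
        save_volume(VolumeGrid(mask.astype(np.uint8), rois.spacing), directory / f"mask_{name}.nii.gz", dtype=np.uint8)
    save_volume(VolumeGrid(rois.in_field.astype(np.uint8), rois.spacing), directory / "mask__infield.nii.gz", dtype=np.uint8)
    meta = {
        "targets": rois.targets,
        "oars": rois.oars,
        "body": rois.body,
        "prescriptions_gy": rois.prescriptions_gy,
        "n_fractions": rois.n_fractions,
        "spacing": list(rois.spacing),
    }
    (directory / "rois.json").write_text(json.dumps(meta, indent=2))


def load_roiset(directory: str | Path) -> ROISet:
    directory = Path(directory)
    meta = json.loads((directory / "rois.json").read_text())
    masks = {}
    for p in sorted(directory.glob("mask_*.nii.gz")):
        name = p.name[len("mask_"):-len(".nii.gz")]
        if name == "_infield":
            continue
        masks[name] = load_volume(p).values > 0.5
    in_field = load_volume(directory / "mask__infield.nii.gz").values > 0.5
    return ROISet(
        masks=masks,
        targets=meta["targets"],
        oars=meta["oars"],
        body=meta["body"],
        in_field=in_field,
        prescriptions_gy={k: float(v) for k, v in meta["prescriptions_gy"].items()},
        n_fractions=int(meta["n_fractions"]),
        spacing=tuple(meta["spacing"]),
    )
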