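"""Reading CT volumes and reslicing them into the three anatomical planes.

The package works in a single canonical patient frame: array axis 0 runs
patient-right -> patient-left, axis 1 posterior -> anterior, axis 2
inferior -> superior (nibabel axis codes ``("L", "A", "S")``).  Fixing the
frame once makes the binocular left/right split unambiguous everywhere
downstream: low indices along the left-right axis are the patient's *right*
side, high indices the *left*.

Reslicing into axial / coronal / sagittal stacks is pure axis permutation —
no interpolation happens at this stage, so the voxel multiset is conserved
exactly and any stack can be folded back into the original volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import nibabel as nib
import numpy as np

#: canonical axis codes: index ascends toward patient Left, Anterior, Superior
CANONICAL_AXCODES = ("L", "A", "S")

HU_MIN, HU_MAX = -1100.0, 3100.0

PLANES = ("axial", "coronal", "sagittal")


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield units, in the canonical patient frame.

    Attributes
    ----------
    voxels : ndarray, shape (lr, pa, is)
        HU values; axis order left-right, posterior-anterior,
        inferior-superior (each ascending toward L / A / S).
    spacing : tuple of float
        Voxel edge lengths in mm along the three array axes.
    axes : tuple of str
        Axis codes of the array axes; always ``("L", "A", "S")`` after
        construction through the loaders.
    meta : dict
        Free-form source annotations (file paths, phantom parameters, ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axes: tuple[str, str, str] = CANONICAL_AXCODES
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"CTVolume expects a 3-D array, got {self.voxels.ndim}-D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume voxels must be finite")
        if float(self.voxels.min()) < HU_MIN or float(self.voxels.max()) > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.voxels.min()}, {self.voxels.max()}]"
            )
        if sorted(c[0] for c in self.axes) != ["A", "L", "S"]:
            raise ValueError(f"axes must be a bijection onto L/A/S, got {self.axes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")


@dataclass
class PlaneStack:
    """A stack of 2-D slices for one anatomical plane.

    ``images`` is ordered (height, width, slice).  ``lr_axis`` names which
    array axis separates patient left from right: the in-plane width for
    axial and coronal stacks, the slice index for sagittal stacks (each
    sagittal image contains only one orbit).  Along that axis, ascending
    index always runs patient-right -> patient-left.
    """

    images: np.ndarray
    plane: str
    lr_axis: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        expected = "slice" if self.plane == "sagittal" else "width"
        if self.lr_axis != expected:
            raise ValueError(f"{self.plane} stack must have lr_axis={expected!r}")
        if self.images.ndim != 3:
            raise ValueError("PlaneStack images must be 3-D (height, width, slice)")

    @property
    def n_slices(self) -> int:
        return self.images.shape[2]


def _canonicalize(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reorient array + affine so axes follow CANONICAL_AXCODES."""
    ornt = nib.orientations.io_orientation(affine)
    if np.any(np.isnan(ornt)):
        raise ValueError("affine does not determine a patient orientation (degenerate column)")
    target = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    xform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(data, xform)
    affine = affine @ nib.orientations.inv_ornt_aff(xform, data.shape)
    return data, affine


def load_nifti(path) -> CTVolume:
    """Load a NIfTI-1 scalar volume and reorient it to the canonical frame.

    The affine's dominant directions decide which array axis is which
    patient axis, so volumes stored with permuted or flipped axes load to
    the identical canonical CTVolume.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D scalar volume, got {data.ndim}-D")
    affine = np.asarray(img.affine, dtype=float)
    if np.linalg.matrix_rank(affine[:3, :3]) < 3:
        raise ValueError("affine is singular (zero or dependent column)")
    data, affine = _canonicalize(data.astype(np.float64), affine)
    spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return CTVolume(
        voxels=data,
        spacing=spacing,  # type: ignore[arg-type]
        axes=CANONICAL_AXCODES,
        meta={"source": str(path), "format": "nifti"},
    )


def save_nifti(vol: CTVolume, path) -> None:
    """Write a canonical CTVolume as NIfTI-1 (LAS affine)."""
    dx, dy, dz = vol.spacing
    # canonical LAS: RAS x decreases with index 0 ascending toward patient left
    affine = np.diag([-dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))


def load_dicom_series(directory_path) -> CTVolume:
    """Read a single-series DICOM directory into a canonical CTVolume.

    Slices are sorted by patient position along the slice normal, pixel
    values are rescaled to HU (raw * slope + intercept) and the volume is
    reoriented to the canonical frame from the orientation metadata.
    """
    from . import dicom_lite

    data, affine, meta = dicom_lite.read_series(directory_path)
    data, affine = _canonicalize(data, affine)
    spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    meta = dict(meta)
    meta["format"] = "dicom"
    return CTVolume(voxels=data, spacing=spacing, axes=CANONICAL_AXCODES, meta=meta)


def reslice_to_planes(vol: CTVolume) -> tuple[PlaneStack, PlaneStack, PlaneStack]:
    """Permute a canonical volume into axial, coronal and sagittal stacks.

    axial    slices are orthogonal to inferior-superior  (image h=PA, w=LR)
    coronal  slices are orthogonal to posterior-anterior (image h=IS, w=LR)
    sagittal slices are orthogonal to left-right         (image h=IS, w=PA)

    Pure transposes: every voxel appears exactly once in each stack.
    """
    v = vol.voxels
    dx, dy, dz = vol.spacing
    axial = PlaneStack(v.transpose(1, 0, 2), "axial", "width", spacing=(dy, dx, dz))
    coronal = PlaneStack(v.transpose(2, 0, 1), "coronal", "width", spacing=(dz, dx, dy))
    sagittal = PlaneStack(v.transpose(2, 1, 0), "sagittal", "slice", spacing=(dz, dy, dx))
    return axial, coronal, sagittal


def stack_to_volume(stack: PlaneStack) -> np.ndarray:
    """Invert :func:`reslice_to_planes` for one stack (exact, no interpolation)."""
    inverse = {"axial": (1, 0, 2), "coronal": (1, 2, 0), "sagittal": (2, 1, 0)}
    return stack.images.transpose(inverse[stack.plane])
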