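"""Deterministic preprocessing of plane stacks into network-ready inputs.

The pipeline turns a raw CT volume into three fixed-size stacks in [0, 1]:

    reslice -> HU window -> ROI crop -> in-plane resize -> slice resample
            -> min-max normalize

HU windowing keeps only orbital fat (−110..−10 HU) and extraocular muscle
(0..40 HU) and paints everything else (air, bone, brain) with a uniform
background value, so the network sees the two tissues whose remodelling
characterises Graves' orbitopathy.  Windowing runs *before* any
interpolation so resizing never blends bone intensities into the
soft-tissue range.  Every stage is deterministic; reruns are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.transform import resize as _sk_resize

from .ct_io import CTVolume, PlaneStack, reslice_to_planes

logger = logging.getLogger(__name__)

#: dual soft-tissue windows: orbital fat and extraocular muscle, in HU
DEFAULT_WINDOWS = ((-110.0, -10.0), (0.0, 40.0))
#: single soft-tissue window variant (fat + muscle merged)
SINGLE_WINDOW = ((-100.0, 40.0),)

TISSUE_THRESHOLD_HU = -300.0  # head tissue vs air, used by the auto-ROI


@dataclass
class PreprocessConfig:
    """Preprocessing parameters; defaults give the standard pipeline."""

    target_slices: int = 32
    axial_hw: tuple[int, int] = (128, 128)
    sagittal_hw: tuple[int, int] = (128, 128)
    coronal_hw: tuple[int, int] = (64, 128)
    hu_windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    background_fill: float = -1000.0
    crop_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        windows = sorted(tuple(w) for w in self.hu_windows)
        for lo, hi in windows:
            if not lo < hi:
                raise ValueError(f"window ({lo}, {hi}) needs low < high")
        for (_, hi), (lo, _) in zip(windows, windows[1:]):
            if lo <= hi:
                raise ValueError("HU windows must be disjoint")
        for dim in (self.target_slices, *self.axial_hw, *self.sagittal_hw, *self.coronal_hw):
            if dim <= 0 or dim % 2:
                raise ValueError("target dimensions must be positive and even")

    def target_hw(self, plane: str) -> tuple[int, int]:
        return {"axial": self.axial_hw, "coronal": self.coronal_hw,
                "sagittal": self.sagittal_hw}[plane]


@dataclass
class PlaneSet:
    """Network-ready triplet of preprocessed stacks, values in [0, 1].

    Shapes are (height, width, slice): axial (128, 128, 32),
    sagittal (128, 128, 32), coronal (64, 128, 32) at the defaults.
    """

    axial: np.ndarray
    sagittal: np.ndarray
    coronal: np.ndarray
    label: Optional[str] = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("axial", "sagittal", "coronal"):
            arr = getattr(self, name)
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError(f"{name} values outside [0, 1]")

    def plane(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _replace(stack: PlaneStack, images: np.ndarray) -> PlaneStack:
    return PlaneStack(images, stack.plane, stack.lr_axis, spacing=stack.spacing)


def resample_slice_count(stack: PlaneStack, target: int) -> PlaneStack:
    """Cubic-spline resample along the slice axis to exactly ``target`` slices.

    Slice positions are parametrised on [0, 1]; a not-a-knot cubic spline is
    evaluated at ``target`` equispaced positions, so polynomial intensity
    profiles up to degree 3 are reproduced exactly and an n -> n resample is
    the identity.
    """
    n = stack.n_slices
    if n < 2:
        raise ValueError("cannot spline-resample a single-slice stack")
    if n == target:
        return _replace(stack, stack.images.copy())
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, target)
    spline = CubicSpline(old, stack.images, axis=2)
    return _replace(stack, spline(new))


def _lr_symmetric(lo: int, hi: int, width: int) -> tuple[int, int]:
    """Expand [lo, hi) to be symmetric about the left-right midline."""
    mid = width / 2.0
    half = max(mid - lo, hi - mid)
    lo = int(np.floor(mid - half))
    hi = int(np.ceil(mid + half))
    return max(lo, 0), min(hi, width)


def _bbox_2d(stack: PlaneStack, margin_px_h: int, margin_px_w: int,
             symmetric_lr: bool) -> tuple[int, int, int, int]:
    tissue = stack.images > TISSUE_THRESHOLD_HU
    proj = tissue.any(axis=2)
    if not proj.any():
        raise ValueError("empty scan: no voxel above the tissue threshold")
    rows = np.flatnonzero(proj.any(axis=1))
    cols = np.flatnonzero(proj.any(axis=0))
    h, w = proj.shape
    r0 = max(int(rows[0]) - margin_px_h, 0)
    r1 = min(int(rows[-1]) + 1 + margin_px_h, h)
    c0 = max(int(cols[0]) - margin_px_w, 0)
    c1 = min(int(cols[-1]) + 1 + margin_px_w, w)
    if symmetric_lr:
        c0, c1 = _lr_symmetric(c0, c1, w)
    return r0, r1, c0, c1


def auto_roi(
    axial: PlaneStack, coronal: PlaneStack, sagittal: PlaneStack,
    crop_margin_mm: float = 5.0,
) -> dict[str, tuple[int, int, int, int]]:
    """Automatic region-of-interest boxes, one (r0, r1, c0, c1) per plane.

    The box encloses every voxel above −300 HU (head tissue vs air) across
    all slices, expanded by ``crop_margin_mm`` and clipped to the image.
    For axial and coronal stacks — whose width axis separates the orbits —
    the box is made symmetric about the left-right midline by expanding the
    smaller side, so the binocular split stays centred.
    """
    boxes = {}
    for stack in (axial, coronal, sagittal):
        mh = int(round(crop_margin_mm / stack.spacing[0]))
        mw = int(round(crop_margin_mm / stack.spacing[1]))
        boxes[stack.plane] = _bbox_2d(stack, mh, mw, stack.lr_axis == "width")
    return boxes


def crop_and_resize(stack: PlaneStack, bbox: tuple[int, int, int, int],
                    target_hw: tuple[int, int]) -> PlaneStack:
    """Crop each slice to ``bbox`` and bilinearly resize to ``target_hw``."""
    r0, r1, c0, c1 = bbox
    h, w = stack.images.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"degenerate or out-of-bounds bbox {bbox} for image ({h}, {w})")
    crop = stack.images[r0:r1, c0:c1, :]
    if crop.shape[:2] == tuple(target_hw):
        return _replace(stack, crop.copy())
    out_shape = (*target_hw, crop.shape[2])
    out = _sk_resize(crop, out_shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return _replace(stack, out)


def hu_window(stack: PlaneStack,
              windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
              background_fill: float = -1000.0) -> PlaneStack:
    """Keep voxels inside the HU windows (bounds inclusive), fill the rest."""
    img = stack.images
    keep = np.zeros(img.shape, dtype=bool)
    for lo, hi in windows:
        keep |= (img >= lo) & (img <= hi)
    return _replace(stack, np.where(keep, img, background_fill))


def normalize_unit(stack: PlaneStack) -> PlaneStack:
    """Affinely map the stack's global [min, max] onto [0, 1].

    The scope is the whole stack (not per slice) so inter-slice intensity
    relations survive.  A constant stack maps to all zeros.
    """
    img = stack.images
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return _replace(stack, np.zeros_like(img, dtype=np.float64))
    return _replace(stack, (img.astype(np.float64) - lo) / (hi - lo))


def preprocess_case(
    vol: CTVolume,
    cfg: PreprocessConfig | None = None,
    bbox_override: dict[str, tuple[int, int, int, int]] | None = None,
    label: Optional[str] = None,
    provenance: dict[str, Any] | None = None,
) -> PlaneSet:
    """Run the full deterministic pipeline on one CT volume."""
    cfg = cfg or PreprocessConfig()
    stacks = dict(zip(("axial", "coronal", "sagittal"), reslice_to_planes(vol)))
    stacks = {p: hu_window(s, cfg.hu_windows, cfg.background_fill)
              for p, s in stacks.items()}
    boxes = bbox_override or auto_roi(stacks["axial"], stacks["coronal"],
                                      stacks["sagittal"], cfg.crop_margin_mm)
    out = {}
    for plane, stack in stacks.items():
        stack = crop_and_resize(stack, boxes[plane], cfg.target_hw(plane))
        logger.debug("%s crop+resize -> %s", plane, stack.images.shape)
        stack = resample_slice_count(stack, cfg.target_slices)
        logger.debug("%s slice resample -> %s", plane, stack.images.shape)
        out[plane] = normalize_unit(stack).images
    return PlaneSet(
        axial=out["axial"], sagittal=out["sagittal"], coronal=out["coronal"],
        label=label, provenance=dict(provenance or {}),
    )
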