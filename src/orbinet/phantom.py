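"""Synthetic orbital CT phantoms with class-conditional Graves' orbitopathy signs.

Each phantom is a schematic head region in the canonical patient frame:
two mirrored orbital cavities bounded by bone, filled with fat, each
holding a spherical globe and four cylindrical extraocular muscles (EOMs)
converging toward the orbital apex, on an air background.  Disease classes
are realised as graded, monotone effects:

* EOM thickening  — muscle cylinder radius scaled (control 1.0, mild 1.3,
  moderate-to-severe 1.8);
* proptosis       — anterior globe displacement (0 / 1 / 4 mm);
* fat expansion   — orbital-cavity scale (1.0 / 1.05 / 1.15).

A configurable fraction of diseased cases is unilateral: the effects are
applied to one randomly chosen orbit while the other stays at control
values — exactly the asymmetry the binocular-comparison layer is meant to
detect.  Geometry is schematic (spheres and cylinders), which is enough to
carry the windowed-intensity contrast the classifier consumes; it does not
emulate real anatomy, scanner artifacts or optic-nerve involvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ct_io import CTVolume
from .preprocessing import PlaneSet, PreprocessConfig, preprocess_case

CLASSES = ("control", "mild", "moderate_severe")

GO_CLASSES = ("mild", "moderate_severe")


@dataclass
class PhantomParams:
    """Geometry and intensity parameters of the phantom generator."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)  # (lr, pa, is) voxels
    spacing_mm: float = 1.0
    globe_radius_mm: float = 12.0
    eom_base_radius_mm: float = 2.0
    eom_radius_multiplier: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "mild": 1.3, "moderate_severe": 1.8})
    proptosis_mm: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "mild": 1.0, "moderate_severe": 4.0})
    fat_expansion: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "mild": 1.05, "moderate_severe": 1.15})
    hu_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "air": (-1000.0, 0.0),
            "fat": (-70.0, 15.0),
            "muscle": (25.0, 8.0),
            "globe": (10.0, 5.0),
            "bone": (600.0, 50.0),
        })
    noise_sd_hu: float = 5.0
    asymmetry_prob: float = 0.2
    orbit_offset_mm: float = 16.0       # orbit centre distance from midline
    cavity_semiaxes_mm: tuple[float, float, float] = (15.0, 20.0, 14.0)
    bone_thickness_mm: float = 3.0
    eom_offset_mm: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        for tissue, window in (("fat", (-110.0, -10.0)), ("muscle", (0.0, 40.0))):
            mean = self.hu_means[tissue][0]
            if not window[0] < mean < window[1]:
                raise ValueError(f"{tissue} mean HU {mean} outside its window {window}")
        for grading in (self.eom_radius_multiplier, self.proptosis_mm, self.fat_expansion):
            if not grading["control"] <= grading["mild"] <= grading["moderate_severe"]:
                raise ValueError("class effects must be non-decreasing with severity")
        if not (self.eom_radius_multiplier["control"]
                < self.eom_radius_multiplier["mild"]
                < self.eom_radius_multiplier["moderate_severe"]):
            raise ValueError("EOM multipliers must be strictly increasing")


@dataclass
class LabeledDataset:
    """Ordered collection of preprocessed, labelled cases."""

    cases: list[tuple[PlaneSet, str]]
    params: PhantomParams
    seed: int

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.cases]

    def subset(self, classes: Sequence[str]) -> "LabeledDataset":
        keep = [case for case in self.cases if case[1] in classes]
        return LabeledDataset(keep, self.params, self.seed)


def class_effects(label: str, params: PhantomParams) -> dict[str, float]:
    """The (EOM multiplier, proptosis, fat scale) triple for one class."""
    return {
        "eom_mult": params.eom_radius_multiplier[label],
        "proptosis": params.proptosis_mm[label],
        "fat_scale": params.fat_expansion[label],
    }


def build_masks(params: PhantomParams,
                effects_by_side: dict[str, dict[str, float]]) -> dict[str, np.ndarray]:
    """Boolean tissue masks on the phantom grid, one orbit per side.

    ``effects_by_side`` maps ``"right"`` / ``"left"`` to an effects dict
    from :func:`class_effects`; the two sides may differ (unilateral
    disease).  Later tissues overwrite earlier ones when painted in the
    order bone -> fat -> muscle -> globe.
    """
    nx, ny, nz = params.grid_shape
    sp = params.spacing_mm
    x, y, z = np.meshgrid(np.arange(nx) * sp, np.arange(ny) * sp,
                          np.arange(nz) * sp, indexing="ij")
    x_mid = (nx - 1) * sp / 2.0
    yc = ny * sp * 0.55
    zc = (nz - 1) * sp / 2.0
    ax, ay, az = params.cavity_semiaxes_mm

    masks = {t: np.zeros(params.grid_shape, dtype=bool)
             for t in ("bone", "fat", "muscle", "globe")}

    for side, sign in (("right", -1.0), ("left", +1.0)):
        eff = effects_by_side[side]
        xc = x_mid + sign * params.orbit_offset_mm
        s = eff["fat_scale"]
        sax, say, saz = ax * s, ay * s, az * s
        if (xc - sax - params.bone_thickness_mm < 0
                or xc + sax + params.bone_thickness_mm > (nx - 1) * sp
                or zc - saz - params.bone_thickness_mm < 0):
            raise ValueError("grid too small to contain the orbital geometry")

        r2 = (((x - xc) / sax) ** 2 + ((y - yc) / say) ** 2 + ((z - zc) / saz) ** 2)
        cavity = r2 <= 1.0
        t = params.bone_thickness_mm
        shell = ((((x - xc) / (sax + t)) ** 2 + ((y - yc) / (say + t)) ** 2
                  + ((z - zc) / (saz + t)) ** 2) <= 1.0) & ~cavity
        shell &= y < yc + 0.5 * say  # anterior orbital opening
        masks["bone"] |= shell
        masks["fat"] |= cavity

        y_globe = yc + say - 4.0 + eff["proptosis"]
        if y_globe + params.globe_radius_mm > (ny - 1) * sp:
            raise ValueError("grid too small for the configured proptosis")
        globe = ((x - xc) ** 2 + (y - y_globe) ** 2
                 + (z - zc) ** 2) <= params.globe_radius_mm ** 2
        masks["globe"] |= globe

        radius = params.eom_base_radius_mm * eff["eom_mult"]
        y0, y1 = yc - say + 6.0, y_globe - 6.0
        within = (y >= y0) & (y <= y1)
        d = params.eom_offset_mm
        for ox, oz in ((d, 0.0), (-d, 0.0), (0.0, d), (0.0, -d)):
            cyl = ((x - (xc + ox)) ** 2 + (z - (zc + oz)) ** 2) <= radius ** 2
            masks["muscle"] |= cyl & within & ~globe

    masks["muscle"] &= ~masks["globe"]
    masks["fat"] &= ~(masks["muscle"] | masks["globe"])
    masks["bone"] &= ~(masks["fat"] | masks["muscle"] | masks["globe"])
    return masks


def generate_phantom(
    label: str,
    params: PhantomParams | None = None,
    rng: np.random.Generator | None = None,
    unilateral_side: Optional[str] = None,
) -> CTVolume:
    """Generate one labelled phantom volume in HU.

    Deterministic given (label, params, rng state).  For diseased classes a
    Bernoulli(``asymmetry_prob``) draw makes the case unilateral unless
    ``unilateral_side`` forces ``"left"``, ``"right"`` or ``"none"``.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}; expected one of {CLASSES}")
    params = params or PhantomParams()
    rng = rng or np.random.default_rng(params.seed)

    effects = {side: class_effects(label, params) for side in ("right", "left")}
    if label in GO_CLASSES:
        if unilateral_side is None:
            if rng.random() < params.asymmetry_prob:
                unilateral_side = "left" if rng.random() < 0.5 else "right"
            else:
                unilateral_side = "none"
        if unilateral_side in ("left", "right"):
            other = "right" if unilateral_side == "left" else "left"
            effects[other] = class_effects("control", params)
    else:
        unilateral_side = "none"

    masks = build_masks(params, effects)
    vol = np.full(params.grid_shape, params.hu_means["air"][0])
    for tissue in ("bone", "fat", "muscle", "globe"):
        mask = masks[tissue]
        mean, sd = params.hu_means[tissue]
        vol[mask] = mean + (sd * rng.standard_normal(int(mask.sum())) if sd else 0.0)
    if params.noise_sd_hu:
        vol += params.noise_sd_hu * rng.standard_normal(vol.shape)
    vol = np.clip(vol, -1090.0, 3090.0)

    meta = {
        "phantom": True, "label": label, "unilateral_side": unilateral_side,
        "effects": effects,
    }
    sp = params.spacing_mm
    return CTVolume(voxels=vol, spacing=(sp, sp, sp), meta=meta)


def generate_dataset(
    n_per_class: int,
    classes: Sequence[str] = CLASSES,
    params: PhantomParams | None = None,
    seed: int = 0,
    preprocess_cfg: PreprocessConfig | None = None,
) -> LabeledDataset:
    """Generate ``n_per_class`` preprocessed phantoms for every class.

    Per-case RNGs are derived from the master seed by a fixed counter
    scheme (``default_rng([seed, case_index])``), so any case can be
    regenerated in isolation and two runs with the same seed are identical.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for label in classes:
        if label not in CLASSES:
            raise ValueError(f"unknown class {label!r}")
    params = params or PhantomParams()
    cfg = preprocess_cfg or PreprocessConfig()
    cases: list[tuple[PlaneSet, str]] = []
    idx = 0
    for label in classes:
        for _ in range(n_per_class):
            rng = np.random.default_rng([seed, idx])
            vol = generate_phantom(label, params, rng)
            ps = preprocess_case(
                vol, cfg, label=label,
                provenance={"case_index": idx, "seed": [seed, idx],
                            "label": label,
                            "unilateral_side": vol.meta["unilateral_side"]},
            )
            cases.append((ps, label))
            idx += 1
    return LabeledDataset(cases=cases, params=params, seed=seed)
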