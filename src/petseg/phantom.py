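"""Synthetic FDG-PET phantoms of bulky, heterogeneous tumors.

Emulates post-reconstruction PET at summary level: a piecewise-constant
uptake map (background near SUV 1, tumor components at SUV 4-15, optional
adjacent hot "organ" confounders such as kidney/heart analogs), modulated by
a smooth multiplicative heterogeneity texture inside the tumor, blurred with
an isotropic Gaussian point-spread function (default 6.5 mm FWHM, matching
harmonized whole-body FDG protocols) and degraded with additive Gaussian
noise.  The pre-blur tumor support is the ground-truth VOI; a dilated copy
plays the role of the rough pre-marked mask given to observers.

No projection-space simulation is attempted: the target of the downstream
analysis is threshold behaviour on blurred, noisy uptake maps, for which
this image-space approximation is sufficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, SUVImage, Unit, dilate_mask

__all__ = [
    "Ellipsoid",
    "PhantomConfig",
    "PhantomCase",
    "generate_phantom",
    "make_scenario_suite",
    "FWHM_TO_SIGMA",
]

# FWHM = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Ellipsoid:
    """An axis-aligned ellipsoidal uptake component in mm coordinates."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    uptake_suv: float

    def __post_init__(self) -> None:
        if len(self.center_mm) != 3 or len(self.radii_mm) != 3:
            raise ValueError("center_mm and radii_mm must have 3 components")
        if not all(r > 0 for r in self.radii_mm):
            raise ValueError("ellipsoid radii must be > 0")
        if self.uptake_suv < 0:
            raise ValueError("uptake must be >= 0")

    @property
    def analytic_volume_ml(self) -> float:
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def support(self, shape, spacing) -> np.ndarray:
        """Boolean support on a voxel grid with centers at index*spacing."""
        axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        cx, cy, cz = self.center_mm
        rx, ry, rz = self.radii_mm
        return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0


@dataclass
class PhantomConfig:
    """Full recipe for one synthetic lesion image."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    tumors: list[Ellipsoid] = field(default_factory=list)
    confounders: list[Ellipsoid] = field(default_factory=list)
    texture_amplitude: float = 0.0       # relative sd of the multiplicative texture
    texture_scale_mm: float = 12.0       # correlation length of the texture
    psf_fwhm_mm: float = 6.5
    noise_sd_suv: float = 0.0
    rough_margin_mm: float = 8.0         # dilation building the rough pre-marked mask
    rough_includes_confounders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tumors:
            raise ValueError("phantom needs at least one tumor component")
        if self.background_suv < 0:
            raise ValueError("background uptake must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be >= 0")
        if self.noise_sd_suv < 0:
            raise ValueError("noise sd must be >= 0")
        if self.rough_margin_mm < 0:
            raise ValueError("rough-mask margin must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(eq=False)
class PhantomCase:
    """One simulated lesion: image, ground truth, rough mask, provenance."""

    image: SUVImage
    ground_truth: BinaryMask
    rough_mask: BinaryMask
    config: PhantomConfig
    seed: int
    lesion_id: str = "lesion"
    # Confounder voxels adjacent to the rough mask that careless manual edits
    # may annex; None when the scenario has no confounder.
    annex_region: BinaryMask | None = None

    def __post_init__(self) -> None:
        for other in (self.ground_truth, self.rough_mask):
            if other.shape != self.image.shape or not np.allclose(other.spacing, self.image.spacing):
                raise ValueError("image, ground truth and rough mask must share geometry")
        if np.any(self.ground_truth.values & ~self.rough_mask.values):
            raise ValueError("ground truth must be contained in the rough mask")


def _touches_boundary(support: np.ndarray) -> bool:
    return bool(
        support[0].any() or support[-1].any()
        or support[:, 0].any() or support[:, -1].any()
        or support[:, :, 0].any() or support[:, :, -1].any()
    )


def generate_phantom(config: PhantomConfig, lesion_id: str = "lesion") -> PhantomCase:
    """Render one phantom according to ``config``; bit-reproducible from its seed."""
    rng = np.random.default_rng(config.seed)
    shape, spacing = tuple(config.shape), tuple(config.spacing)

    uptake = np.full(shape, float(config.background_suv))

    conf_support = np.zeros(shape, dtype=bool)
    for organ in config.confounders:
        sup = organ.support(shape, spacing)
        uptake[sup] = organ.uptake_suv
        conf_support |= sup

    gt = np.zeros(shape, dtype=bool)
    for tumor in config.tumors:
        sup = tumor.support(shape, spacing)
        if _touches_boundary(sup):
            raise ValueError(f"tumor component {tumor} extends outside the grid")
        uptake[sup] = tumor.uptake_suv
        gt |= sup
    if not gt.any():
        raise ValueError("tumor support is empty on this grid")
    if np.any(gt & conf_support):
        raise ValueError("confounder organs must not overlap the tumor")

    if config.texture_amplitude > 0:
        field_ = rng.standard_normal(shape)
        sigma_vox = [config.texture_scale_mm / s for s in spacing]
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox, mode="reflect")
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        texture = np.clip(1.0 + config.texture_amplitude * field_, 0.1, None)
        uptake = np.where(gt, uptake * texture, uptake)

    if config.psf_fwhm_mm > 0:
        sigma_mm = config.psf_fwhm_mm * FWHM_TO_SIGMA
        blurred = ndimage.gaussian_filter(
            uptake, sigma=[sigma_mm / s for s in spacing], mode="reflect"
        )
    else:
        blurred = uptake

    if blurred[gt].max() <= config.background_suv:
        warnings.warn(
            "PSF blurring erased the tumor below background uptake", stacklevel=2
        )

    values = blurred
    if config.noise_sd_suv > 0:
        values = values + rng.normal(0.0, config.noise_sd_suv, size=shape)

    gt_mask = BinaryMask(values=gt, spacing=spacing)
    rough = dilate_mask(gt_mask, config.rough_margin_mm)
    annex = None
    if conf_support.any():
        near = dilate_mask(rough, 8.0).values & conf_support
        if not config.rough_includes_confounders:
            rough = BinaryMask(values=rough.values & ~conf_support, spacing=spacing)
        if near.any():
            annex = BinaryMask(values=near, spacing=spacing)

    return PhantomCase(
        image=SUVImage(values=values, spacing=spacing, unit=Unit.SUV),
        ground_truth=gt_mask,
        rough_mask=rough,
        config=config,
        seed=config.seed,
        lesion_id=lesion_id,
        annex_region=annex,
    )


# Geometry templates for the two voxel grids of the emulated acquisitions:
# an isotropic 4x4x4 mm grid and an anisotropic 3.1819x3.1819x2 mm grid.
_GRIDS = (
    ((48, 48, 48), (4.0, 4.0, 4.0)),
    ((56, 56, 88), (3.1819, 3.1819, 2.0)),
)


def make_scenario_suite(n_lesions: int = 20, seed: int = 0) -> list[PhantomCase]:
    """Deterministic suite of bulky-lesion scenarios.

    Spans both voxel grids, a range of MATVs including >300 mL lesions,
    heterogeneous textures, multi-component complex shapes, and at least one
    lesion adjacent to a hot confounder organ whose rough mask deliberately
    annexes part of it (the heart/kidney failure mode).
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_lesions):
        shape, spacing = _GRIDS[i % 2]
        extent = [n * s for n, s in zip(shape, spacing)]
        center = [e / 2.0 + rng.uniform(-4, 4) for e in extent]

        if i == 0:
            # guaranteed bulky lesion: sphere of radius 45 mm -> ~382 mL
            radii = (45.0, 45.0, 45.0)
        else:
            r = rng.uniform(18.0, 40.0)
            aniso = rng.uniform(0.8, 1.25, size=3)
            radii = tuple(np.clip(r * aniso, 12.0, 48.0))

        uptake = float(rng.uniform(5.0, 13.0))
        tumors = [Ellipsoid(tuple(center), tuple(radii), uptake)]
        if i % 5 == 3:
            # complex shape: second overlapping lobe with different uptake
            off = rng.uniform(-1.0, 1.0, size=3)
            off = off / np.linalg.norm(off) * 0.8 * min(radii)
            lobe_center = tuple(np.asarray(center) + off)
            lobe_radii = tuple(np.asarray(radii) * rng.uniform(0.45, 0.65))
            tumors.append(Ellipsoid(lobe_center, lobe_radii, uptake * rng.uniform(0.6, 0.9)))

        confounders = []
        rough_includes = False
        if i % 7 == 2:
            # hot organ just outside the lesion; rough mask annexes part of it
            direction = np.zeros(3)
            direction[int(rng.integers(3))] = 1.0
            organ_center = tuple(
                np.asarray(center) + direction * (max(radii) + 18.0)
            )
            confounders.append(Ellipsoid(organ_center, (14.0, 14.0, 14.0), uptake * 1.1))
            rough_includes = True

        cfg = PhantomConfig(
            shape=shape,
            spacing=spacing,
            background_suv=1.0,
            tumors=tumors,
            confounders=confounders,
            texture_amplitude=float(rng.uniform(0.08, 0.25)),
            texture_scale_mm=float(rng.uniform(10.0, 18.0)),
            psf_fwhm_mm=6.5,
            noise_sd_suv=float(rng.uniform(0.05, 0.15)),
            rough_margin_mm=8.0,
            rough_includes_confounders=rough_includes,
            seed=int(rng.integers(2**31)),
        )
        cases.append(generate_phantom(cfg, lesion_id=f"L{i:02d}"))
    return cases


def write_case(case: PhantomCase, out_dir) -> None:
    """Write image/truth/rough NIfTI volumes plus a JSON provenance sidecar."""
    from pathlib import Path
    from .imaging import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.image, out / "image.nii.gz")
    write_volume(case.ground_truth, out / "truth.nii.gz")
    write_volume(case.rough_mask, out / "rough.nii.gz")
    meta = {"lesion_id": case.lesion_id, "seed": case.seed, "config": case.config.to_dict()}
    (out / "meta.json").write_text(json.dumps(meta, indent=2, default=list))
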