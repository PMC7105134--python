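"""Threshold-based PET delineation algorithms and the gradient image.

Implements the four semi-automatic algorithms offered to observers in the
select-the-best workflow — 41% of SUVmax, fixed SUV 4, fixed SUV 2.5, and a
contrast-adapted method thresholding at 50% of SUVpeak with local background
correction — plus the percent-of-max interactive threshold and the
gradient-magnitude image that highlights uptake boundaries.

Inclusion is strictly greater-than throughout ("higher than" a cut); a
percent threshold of 100 therefore yields an empty mask.  All masks are
restricted to the inside of the rough pre-marked mask.  No connected-
component filtering is applied by default: hot neighboring organs leaking
into the VOI is a real failure mode this analysis must be able to exhibit;
``keep_largest_component`` is available as an opt-in post-process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, SUVImage, require_same_geometry

__all__ = [
    "ThresholdRule",
    "ThresholdResult",
    "AutoParams",
    "threshold_pct_max",
    "threshold_fixed",
    "suv_peak",
    "auto_segment",
    "gradient_image",
    "run_auto_panel",
    "keep_largest_component",
    "sphere_diameter_cm",
    "PANEL_LABELS",
]

PANEL_LABELS = ("41MAX", "SUV4", "SUV2.5", "AUTO")


class ThresholdRule(str, Enum):
    PCT_MAX = "pct_max"
    FIXED_SUV = "fixed_suv"
    AUTO = "auto"


@dataclass
class ThresholdResult:
    """A delineation produced by one thresholding rule."""

    mask: BinaryMask
    threshold_suv: float
    rule: ThresholdRule
    pct: float | None = None
    iterations: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.threshold_suv < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class AutoParams:
    """Parameters of the contrast-adapted (AUTO) method.

    The threshold fixed point is T = B + peak_fraction * (SUVpeak - B), with
    the local background B estimated as the mean image value in a shell of
    voxels whose mm-distance from the current VOI lies in
    (shell_inner_mm, shell_outer_mm].
    """

    peak_fraction: float = 0.50
    shell_inner_mm: float = 2.0
    shell_outer_mm: float = 10.0
    max_iter: int = 100
    tol_suv: float = 1e-3
    peak_radius_mm: float = 6.0  # 1 mL sphere quoted as 1.2 cm diameter
    damping: float = 0.6  # step fraction toward the raw update; avoids 2-cycles on noisy data

    def __post_init__(self) -> None:
        if not 0 < self.peak_fraction < 1:
            raise ValueError("peak_fraction must be in (0, 1)")
        if not self.shell_outer_mm > self.shell_inner_mm >= 0:
            raise ValueError("need shell_outer_mm > shell_inner_mm >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol_suv > 0:
            raise ValueError("tol_suv must be > 0")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")


def _require_nonempty(rough_mask: BinaryMask) -> None:
    if not rough_mask.values.any():
        raise ValueError("rough mask is empty")


def threshold_pct_max(image: SUVImage, rough_mask: BinaryMask, pct: float) -> ThresholdResult:
    """Select in-mask voxels strictly above ``pct``% of the in-mask SUVmax."""
    require_same_geometry(image, rough_mask)
    _require_nonempty(rough_mask)
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    suv_max = float(image.values[rough_mask.values].max())
    cut = pct / 100.0 * suv_max
    sel = rough_mask.values & (image.values > cut)
    return ThresholdResult(
        mask=BinaryMask(values=sel, spacing=image.spacing),
        threshold_suv=max(cut, 0.0),
        rule=ThresholdRule.PCT_MAX,
        pct=float(pct),
    )


def threshold_fixed(image: SUVImage, rough_mask: BinaryMask, suv_cut: float) -> ThresholdResult:
    """Select in-mask voxels with SUV strictly higher than ``suv_cut``."""
    require_same_geometry(image, rough_mask)
    if suv_cut < 0:
        raise ValueError("suv_cut must be >= 0")
    sel = rough_mask.values & (image.values > suv_cut)
    return ThresholdResult(
        mask=BinaryMask(values=sel, spacing=image.spacing),
        threshold_suv=float(suv_cut),
        rule=ThresholdRule.FIXED_SUV,
    )


def _sphere_kernel(spacing, radius_mm: float) -> np.ndarray:
    """Binary kernel of voxel-center offsets within radius_mm (mm Euclidean)."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx**2 + yy**2 + zz**2) <= radius_mm**2 + 1e-9


def suv_peak(
    image: SUVImage, rough_mask: BinaryMask, radius_mm: float = 6.0
) -> tuple[float, tuple[int, int, int]]:
    """Highest 1-mL spherical-neighborhood mean SUV within the rough mask.

    For every in-mask voxel, the mean of image values over voxels whose
    centers lie within ``radius_mm`` (default 6 mm, i.e. a 1.2 cm diameter
    sphere) of that voxel's center; sphere membership is spacing-aware and
    neighborhoods are clipped at the grid boundary.  Returns the maximum
    mean and the center voxel attaining it.
    """
    require_same_geometry(image, rough_mask)
    _require_nonempty(rough_mask)
    kernel = _sphere_kernel(image.spacing, radius_mm).astype(np.float64)
    sums = ndimage.convolve(image.values, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(image.values), kernel, mode="constant", cval=0.0)
    means = sums / counts
    means_in = np.where(rough_mask.values, means, -np.inf)
    idx = np.unravel_index(int(np.argmax(means_in)), image.shape)
    return float(means_in[idx]), tuple(int(i) for i in idx)


def auto_segment(
    image: SUVImage, rough_mask: BinaryMask, params: AutoParams | None = None
) -> ThresholdResult:
    """Contrast-adapted segmentation: 50% of SUVpeak with local background correction.

    Fixed-point iteration: threshold at T (initialized at
    peak_fraction*SUVpeak), estimate the background B as the mean value in a
    shell around the current VOI, update T = B + peak_fraction*(SUVpeak - B),
    repeat until the raw update moves less than ``tol_suv``.  The update is
    damped (T <- T + damping*(T_raw - T)): the raw map is piecewise constant
    in T on a discrete grid and can 2-cycle between two shell estimates on
    noisy data, while damping contracts onto one of them.  Convergence is
    still judged on the undamped residual, so on piecewise-constant data the
    reported threshold equals the analytic fixed point to within ``tol_suv``.
    """
    if params is None:
        params = AutoParams()
    require_same_geometry(image, rough_mask)
    _require_nonempty(rough_mask)

    peak, _ = suv_peak(image, rough_mask, radius_mm=params.peak_radius_mm)
    t = params.peak_fraction * peak
    iterations = 0
    converged = False
    for iterations in range(1, params.max_iter + 1):
        voi = rough_mask.values & (image.values > t)
        if voi.any():
            dist = ndimage.distance_transform_edt(~voi, sampling=image.spacing)
            shell = (dist > params.shell_inner_mm) & (dist <= params.shell_outer_mm)
        else:
            shell = np.zeros_like(voi)
        if shell.any():
            background = float(image.values[shell].mean())
        else:
            warnings.warn("AUTO: empty background shell, falling back to B = 0", stacklevel=2)
            background = 0.0
        t_new = background + params.peak_fraction * (peak - background)
        if abs(t_new - t) < params.tol_suv:
            t = t_new
            converged = True
            break
        t = t + params.damping * (t_new - t)
    if not converged:
        warnings.warn(f"AUTO did not converge in {params.max_iter} iterations", stacklevel=2)

    sel = rough_mask.values & (image.values > t)
    return ThresholdResult(
        mask=BinaryMask(values=sel, spacing=image.spacing),
        threshold_suv=max(float(t), 0.0),
        rule=ThresholdRule.AUTO,
        iterations=iterations,
        converged=converged,
    )


def gradient_image(image: SUVImage, sigma_mm=None) -> SUVImage:
    """Gradient-magnitude volume in SUV/mm, emphasizing uptake boundaries.

    Uses Gaussian-derivative filters (default sigma of one voxel pitch per
    axis) rather than plain central differences, which are noise-dominated
    on PET; derivatives are spacing-aware so the magnitude is per mm
    regardless of the grid.
    """
    if sigma_mm is None:
        sigma_vox = (1.0, 1.0, 1.0)
    else:
        sigma_vox = tuple(float(sigma_mm) / s for s in image.spacing)
    sq = np.zeros_like(image.values)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 1
        d = ndimage.gaussian_filter(image.values, sigma=sigma_vox, order=order, mode="reflect")
        sq += (d / image.spacing[axis]) ** 2
    return SUVImage(values=np.sqrt(sq), spacing=image.spacing, unit=image.unit)


def run_auto_panel(
    image: SUVImage, rough_mask: BinaryMask, auto_params: AutoParams | None = None
) -> dict[str, ThresholdResult]:
    """The four predefined segmentations of the select-the-best workflow.

    Returned in fixed order: 41MAX, SUV4, SUV2.5, AUTO.
    """
    return {
        "41MAX": threshold_pct_max(image, rough_mask, 41.0),
        "SUV4": threshold_fixed(image, rough_mask, 4.0),
        "SUV2.5": threshold_fixed(image, rough_mask, 2.5),
        "AUTO": auto_segment(image, rough_mask, auto_params),
    }


def keep_largest_component(mask: BinaryMask) -> BinaryMask:
    """Optional post-process retaining only the largest 26-connected component."""
    labels, n = ndimage.label(mask.values, structure=np.ones((3, 3, 3), dtype=bool))
    if n <= 1:
        return BinaryMask(values=mask.values.copy(), spacing=mask.spacing)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    return BinaryMask(values=labels == best, spacing=mask.spacing)


def sphere_diameter_cm(volume_ml: float) -> float:
    """Diameter in cm of a sphere of the given volume in mL (1 mL -> ~1.2 cm)."""
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    radius_cm = (3.0 * volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 2.0 * radius_cm
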