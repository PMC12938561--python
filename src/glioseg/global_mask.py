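"""Stage 1: whole-tumor binary mask from normalized FLAIR.

Per anatomical plane, every 2D slice is binarized with a Sauvola local
threshold

    T(x, y) = m(x, y) * (1 + k * (s(x, y) / R - 1))

where m and s are the mean and population standard deviation over a
W x W window (reflect-padded at the borders), then cleaned with
small-object removal, opening and closing. The three per-plane mask
stacks are fused voxelwise; the strict logical-AND fusion keeps only
voxels detected in all three orientations, trading a little sensitivity
for a large cut in orientation-specific false positives.

On [0, 1]-normalized data the dynamic-range constant defaults to
R = 0.5, half the possible range (the same ratio as the classical
R = 128 on 8-bit images).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

from glioseg.volume_io import BinaryMask

PLANES = ("axial", "coronal", "sagittal")
#: array axis whose fixed-index slices belong to each plane
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class SauvolaParams:
    """Local-threshold parameters: window size W, sensitivity k, range R."""

    window: int = 15
    k: float = 0.5
    R: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("k and R must be positive")


@dataclass(frozen=True)
class MorphologyParams:
    """Per-slice mask refinement parameters.

    ``min_component_size`` (S_min) is the largest 2D component size, in
    pixels, that is still discarded: components survive only if strictly
    larger. Opening removes speckle thinner than its disk; closing fills
    holes and gaps smaller than its disk. Components are found with
    8-connectivity in 2D (26-connectivity for the optional 3D cleanup).
    """

    min_component_size: int = 64
    opening_radius: int = 2
    closing_radius: int = 3
    # optional 3D cleanup applied after fusion (off by default)
    postfuse_enabled: bool = False
    min_component_size_3d: int = 50
    closing_radius_3d: int = 0

    def __post_init__(self) -> None:
        if self.min_component_size < 0 or self.opening_radius < 0 or self.closing_radius < 0:
            raise ValueError("sizes and radii must be >= 0")


class FusionStrategy(str, Enum):
    """Multi-planar vote rule: how many planes must detect a voxel."""

    AND = "AND"
    MAJORITY = "MAJORITY"
    OR = "OR"
    SINGLE_AXIAL = "SINGLE_AXIAL"


@dataclass
class PlanarMaskSet:
    """One whole-volume binary mask per anatomical plane."""

    axial: BinaryMask
    coronal: BinaryMask
    sagittal: BinaryMask

    def __post_init__(self) -> None:
        shapes = {self.axial.shape, self.coronal.shape, self.sagittal.shape}
        if len(shapes) != 1:
            raise ValueError(f"planar masks differ in shape: {shapes}")


def sauvola_threshold_map(slice2d: np.ndarray, params: SauvolaParams = SauvolaParams()
                          ) -> np.ndarray:
    """Per-pixel Sauvola threshold map for one 2D slice.

    Windowed mean and population standard deviation are computed with
    reflective border padding, so border thresholds are not biased toward
    zero.
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    if slice2d.ndim != 2:
        raise ValueError(f"non-2D input (ndim={slice2d.ndim})")
    w = params.window
    m = ndimage.uniform_filter(slice2d, size=w, mode="reflect")
    m2 = ndimage.uniform_filter(slice2d * slice2d, size=w, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    s = np.sqrt(var)
    return m * (1.0 + params.k * (s / params.R - 1.0))


def binarize(slice2d: np.ndarray, threshold_map: np.ndarray) -> np.ndarray:
    """Strictly-greater-than binarization against a per-pixel threshold."""
    slice2d = np.asarray(slice2d)
    threshold_map = np.asarray(threshold_map)
    if slice2d.shape != threshold_map.shape:
        raise ValueError(f"shape mismatch: {slice2d.shape} vs {threshold_map.shape}")
    return slice2d > threshold_map


def refine_slice(mask2d: np.ndarray, params: MorphologyParams = MorphologyParams()
                 ) -> np.ndarray:
    """Clean one binary slice: remove small components, open, close.

    Components of size <= ``min_component_size`` (8-connectivity) are
    dropped; the survivors are opened then closed with disk structuring
    elements. Removal and opening only ever delete pixels; closing is
    extensive (never removes pixels of its own input).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim != 2:
        raise ValueError(f"non-2D input (ndim={mask2d.ndim})")
    out = mask2d
    if params.min_component_size > 0 and out.any():
        out = skmorph.remove_small_objects(
            out, max_size=params.min_component_size, connectivity=2
        )
    if params.opening_radius > 0:
        out = skmorph.opening(out, skmorph.disk(params.opening_radius))
    if params.closing_radius > 0:
        out = skmorph.closing(out, skmorph.disk(params.closing_radius))
    return out


def threshold_plane(flair: np.ndarray, plane: str,
                    sauvola: SauvolaParams = SauvolaParams(),
                    morph: MorphologyParams = MorphologyParams(),
                    spacing=(1.0, 1.0, 1.0), method: str = "sauvola",
                    refine: bool = True) -> BinaryMask:
    """Threshold and refine every slice of one anatomical plane.

    The per-slice masks are stacked back into a 3D mask of the input's
    shape. ``plane`` selects the slicing axis (axial = axis 2, coronal =
    axis 1, sagittal = axis 0 after canonicalization). ``method`` picks
    the local Sauvola map or a global per-slice Otsu threshold (ablation
    arm); ``refine=False`` skips the morphological cleanup (ablation arm).
    """
    if plane not in PLANE_AXIS:
        raise ValueError(f"unknown plane: {plane!r} (expected one of {PLANES})")
    if method not in ("sauvola", "otsu"):
        raise ValueError(f"unknown threshold method: {method!r}")
    flair = np.asarray(flair, dtype=np.float64)
    axis = PLANE_AXIS[plane]
    moved = np.moveaxis(flair, axis, 0)
    out = np.empty(moved.shape, dtype=bool)
    for i in range(moved.shape[0]):
        sl = moved[i]
        if not (sl > 0).any():
            out[i] = False
            continue
        if method == "sauvola":
            t = sauvola_threshold_map(sl, sauvola)
        else:
            t = otsu_threshold_map(sl)
        m = binarize(sl, t)
        out[i] = refine_slice(m, morph) if refine else m
    return BinaryMask(np.moveaxis(out, 0, axis), spacing=tuple(spacing))


def fuse(masks: PlanarMaskSet, strategy: FusionStrategy = FusionStrategy.AND) -> BinaryMask:
    """Fuse the three planar masks voxelwise.

    AND keeps voxels present in all three planes, MAJORITY in at least
    two, OR in at least one; SINGLE_AXIAL returns the axial mask
    unchanged. AND-mask is always a subset of MAJORITY-mask, which is a
    subset of OR-mask.
    """
    strategy = FusionStrategy(strategy)
    a, c, s = masks.axial.data, masks.coronal.data, masks.sagittal.data
    if strategy is FusionStrategy.SINGLE_AXIAL:
        fused = a.copy()
    else:
        votes = a.astype(np.uint8) + c.astype(np.uint8) + s.astype(np.uint8)
        need = {FusionStrategy.AND: 3, FusionStrategy.MAJORITY: 2, FusionStrategy.OR: 1}[strategy]
        fused = votes >= need
    return BinaryMask(fused, spacing=masks.axial.spacing)


def postfuse_cleanup(mask: BinaryMask, morph: MorphologyParams = MorphologyParams()
                     ) -> BinaryMask:
    """Optional 3D cleanup of the fused mask (disabled by default).

    When enabled, removes 3D components of size <= ``min_component_size_3d``
    (26-connectivity) and applies a spherical closing of radius
    ``closing_radius_3d``.
    """
    if not morph.postfuse_enabled:
        return mask
    out = mask.data
    if morph.min_component_size_3d > 0 and out.any():
        out = skmorph.remove_small_objects(
            out, max_size=morph.min_component_size_3d, connectivity=3
        )
    if morph.closing_radius_3d > 0:
        out = skmorph.closing(out, skmorph.ball(morph.closing_radius_3d))
    return BinaryMask(out, spacing=mask.spacing)


def otsu_threshold_map(slice2d: np.ndarray, bins: int = 256) -> np.ndarray:
    """Single global Otsu threshold per slice, as a constant map (ablation arm)."""
    from skimage.filters import threshold_otsu

    slice2d = np.asarray(slice2d, dtype=np.float64)
    if slice2d.ndim != 2:
        raise ValueError(f"non-2D input (ndim={slice2d.ndim})")
    vals = slice2d[slice2d > 0]
    if vals.size == 0 or np.ptp(vals) < 1e-12:
        t = np.inf  # nothing to separate: empty mask
    else:
        t = threshold_otsu(vals, nbins=bins)
    return np.full(slice2d.shape, t)
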