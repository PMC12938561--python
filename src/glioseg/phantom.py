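"""Deterministic multi-modal tumor phantoms with ground truth.

The generator builds a brain-shaped ellipsoid containing a concentric
three-compartment lesion — necrotic core inside an enhancing rim inside an
edema shell — and fills each compartment with per-modality mean
intensities that follow the standard radiological signatures of glioma
subregions:

* enhancing tumor is the brightest class on T1ce (blood-brain-barrier
  disruption),
* edema is the brightest class on FLAIR/T2 with low T1ce,
* necrosis is the darkest class on both T1ce and FLAIR.

The non-lesional parenchyma is modeled as a dark, fluid-suppressed matrix
carrying punctate bright texture (small high-intensity speckles shared
across modalities). This reproduces the contrast regime an adaptive
local-threshold detector requires: a voxel is rejected only when it is
substantially darker than its local window mean, so lesion-versus-brain
separation demands windows whose mean is pulled well above the matrix
level while the bright texture itself stays below the small-object and
opening scales of the mask-refinement step. Real FLAIR parenchyma is
brighter and more homogeneous than this; see the methods note for what
phantom results do and do not imply about clinical data.

All randomness is driven by the spec's seed; identical specs produce
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from glioseg.volume_io import (
    EDEMA, ENHANCING, NECROSIS,
    BinaryMask, LabelVolume, MultiModalVolume,
)

#: parenchymal matrix level per modality (dark, fluid-suppressed on FLAIR)
DEFAULT_TISSUE_MEANS = {"T1": 0.30, "T1ce": 0.30, "T2": 0.25, "FLAIR": 0.10}
#: punctate bright texture level per modality
DEFAULT_SPECKLE_MEANS = {"T1": 0.55, "T1ce": 0.55, "T2": 0.50, "FLAIR": 0.45}
#: lesion compartment means per modality
DEFAULT_CLASS_MEANS = {
    NECROSIS: {"T1": 0.20, "T1ce": 0.15, "T2": 0.65, "FLAIR": 0.55},
    EDEMA: {"T1": 0.35, "T1ce": 0.35, "T2": 0.85, "FLAIR": 0.90},
    ENHANCING: {"T1": 0.45, "T1ce": 0.90, "T2": 0.55, "FLAIR": 0.75},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise model of one synthetic case.

    ``tumor_half_axes`` is the outer surface of the enhancing rim; the
    necrotic core spans ``core_fraction`` of those half-axes and the edema
    shell extends ``edema_margin`` voxels beyond the rim. Intensities are
    on a nominal [0, 1] scale; ``noise_sigma`` is the per-voxel additive
    Gaussian noise on that scale.
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_half_axes: Tuple[float, float, float] = (27.0, 25.0, 23.0)
    tumor_center: Tuple[float, float, float] = (32.0, 32.0, 32.0)
    tumor_half_axes: Tuple[float, float, float] = (9.0, 8.0, 7.0)
    core_fraction: float = 0.45
    edema_margin: float = 4.0
    tissue_means: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    speckle_means: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECKLE_MEANS))
    class_means: Dict[int, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_MEANS.items()}
    )
    speckle_density: float = 0.03
    speckle_radius: int = 1
    noise_sigma: float = 0.02
    include_t2: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        cm = self.class_means
        if not (cm[ENHANCING]["T1ce"] > cm[EDEMA]["T1ce"]
                and cm[ENHANCING]["T1ce"] > cm[NECROSIS]["T1ce"]):
            raise ValueError("enhancing tumor must have the highest T1ce mean")
        if not (cm[EDEMA]["FLAIR"] > cm[NECROSIS]["FLAIR"]):
            raise ValueError("edema must be brighter than necrosis on FLAIR")
        if not (cm[NECROSIS]["T1ce"] + cm[NECROSIS]["FLAIR"]
                < min(cm[EDEMA]["T1ce"] + cm[EDEMA]["FLAIR"],
                      cm[ENHANCING]["T1ce"] + cm[ENHANCING]["FLAIR"])):
            raise ValueError("necrosis must be the joint T1ce+FLAIR darkest class")

    @property
    def modalities(self) -> Tuple[str, ...]:
        return ("T1", "T1ce", "T2", "FLAIR") if self.include_t2 else ("T1", "T1ce", "FLAIR")


def _ellipsoid(shape, center, half_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, half_axes))
    return d <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()
                     ) -> tuple[MultiModalVolume, LabelVolume]:
    """Generate one synthetic multi-modal case and its ground-truth labels.

    Returns the intensity volume (zero outside the brain, skull-stripped
    convention) and a label volume with internal codes. Raises if the
    edema shell does not fit inside the brain ellipsoid.
    """
    shape = spec.shape
    brain_center = tuple((n - 1) / 2.0 for n in shape)
    brain = _ellipsoid(shape, brain_center, spec.brain_half_axes)

    core_ax = tuple(a * spec.core_fraction for a in spec.tumor_half_axes)
    edema_ax = tuple(a + spec.edema_margin for a in spec.tumor_half_axes)
    core = _ellipsoid(shape, spec.tumor_center, core_ax)
    rim = _ellipsoid(shape, spec.tumor_center, spec.tumor_half_axes)
    whole = _ellipsoid(shape, spec.tumor_center, edema_ax)
    if (whole & ~brain).any():
        raise ValueError("tumor (edema shell) extends outside the brain ellipsoid")

    labels = np.zeros(shape, dtype=np.int16)
    labels[whole] = EDEMA
    labels[rim] = ENHANCING
    labels[core] = NECROSIS

    rng = np.random.default_rng(spec.seed)
    # shared punctate texture geometry: same anatomy in every modality
    speckle = rng.random(shape) < spec.speckle_density
    if spec.speckle_radius > 0:
        speckle = ndimage.binary_dilation(
            speckle, structure=ndimage.generate_binary_structure(3, 1),
            iterations=spec.speckle_radius,
        )
    speckle &= brain

    data: Dict[str, np.ndarray] = {}
    for mod in spec.modalities:
        grid = np.zeros(shape, dtype=np.float64)
        grid[brain] = spec.tissue_means[mod]
        grid[speckle] = spec.speckle_means[mod]
        for code in (EDEMA, ENHANCING, NECROSIS):
            grid[labels == code] = spec.class_means[code][mod]
        if spec.noise_sigma > 0:
            grid[brain] += rng.normal(0.0, spec.noise_sigma, size=int(brain.sum()))
            np.clip(grid, 1e-6, None, out=grid, where=brain)
        data[mod] = grid

    volume = MultiModalVolume(data, spacing=spec.spacing)
    return volume, LabelVolume(labels, spacing=spec.spacing)


def brain_mask(spec: PhantomSpec) -> BinaryMask:
    """Boolean brain ellipsoid of a spec (for tests and diagnostics)."""
    center = tuple((n - 1) / 2.0 for n in spec.shape)
    return BinaryMask(_ellipsoid(spec.shape, center, spec.brain_half_axes),
                      spacing=spec.spacing)


# ---------------------------------------------------------------------------
# image-quality perturbation operators
# ---------------------------------------------------------------------------

PERTURBATION_KINDS = ("gaussian_noise", "bias_field", "downsample", "motion")


def _smooth_bias(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude]."""
    coarse = rng.normal(size=(4, 4, 4))
    fine = ndimage.zoom(coarse, [n / 4 for n in shape], order=3, mode="nearest")
    fine = fine[: shape[0], : shape[1], : shape[2]]
    peak = np.max(np.abs(fine))
    if peak > 0:
        fine = fine / peak
    return 1.0 + amplitude * fine


def perturb(volume: MultiModalVolume, kind: str, seed: int = 0, *,
            sigma: float = 0.05, amplitude: float = 0.2, factor: int = 2,
            slice_fraction: float = 0.125) -> MultiModalVolume:
    """Apply one seeded image-quality perturbation to every modality.

    Kinds
    -----
    ``gaussian_noise``
        Adds i.i.d. Gaussian noise of standard deviation ``sigma`` to
        brain voxels (intensity scale [0, 1]).
    ``bias_field``
        Multiplies by a smooth low-frequency field whose deviation from 1
        peaks at ``amplitude`` (20% by default).
    ``downsample``
        Block-averages by ``factor`` then replicates back to the original
        grid, emulating a coarser acquisition (e.g. 1 mm -> 2 mm).
    ``motion``
        Replaces ``slice_fraction`` of axial slices with shifted, blurred
        copies, emulating intra-scan movement.
    """
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind: {kind!r}")
    rng = np.random.default_rng(seed)
    out: Dict[str, np.ndarray] = {}

    if kind == "gaussian_noise":
        for mod, grid in volume.data.items():
            g = grid.copy()
            pos = g > 0
            if sigma > 0:
                g[pos] += rng.normal(0.0, sigma, size=int(pos.sum()))
                g[pos] = np.maximum(g[pos], 1e-6)
            out[mod] = g
    elif kind == "bias_field":
        fld = _smooth_bias(volume.shape, amplitude, rng)
        for mod, grid in volume.data.items():
            g = grid * fld
            g[grid <= 0] = 0.0
            out[mod] = g
    elif kind == "downsample":
        for mod, grid in volume.data.items():
            sh = grid.shape
            pad = [(0, (-n) % factor) for n in sh]
            g = np.pad(grid, pad, mode="edge")
            ns = tuple(n // factor for n in g.shape)
            blocks = g.reshape(ns[0], factor, ns[1], factor, ns[2], factor)
            coarse = blocks.mean(axis=(1, 3, 5))
            up = np.repeat(np.repeat(np.repeat(coarse, factor, 0), factor, 1), factor, 2)
            up = up[: sh[0], : sh[1], : sh[2]]
            up[grid <= 0] = 0.0
            out[mod] = up
    else:  # motion
        n_ax = volume.shape[2]
        n_bad = max(1, int(round(slice_fraction * n_ax)))
        bad = rng.choice(n_ax, size=n_bad, replace=False)
        shifts = rng.integers(1, 3, size=n_bad) * rng.choice([-1, 1], size=n_bad)
        for mod, grid in volume.data.items():
            g = grid.copy()
            for idx, sh in zip(bad, shifts):
                sl = np.roll(grid[:, :, idx], int(sh), axis=0)
                g[:, :, idx] = ndimage.gaussian_filter(sl, sigma=1.0)
            g[grid <= 0] = 0.0
            out[mod] = g

    return volume.with_data(out)


def perturbed_spec(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Same phantom geometry under a different random seed."""
    return replace(spec, seed=seed)
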